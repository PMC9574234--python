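"""Synthetic finger-tapping sessions with a known latent attentional state.

Every downstream stage of the pipeline (behavioral markers, pupil
deconvolution, ordinal regression, fMRI GLMs) is testable against sessions
generated here, with the generating truth retained.

The generative story: a latent mind-wandering intensity follows a slowly
mixing mean-reverting (Ornstein-Uhlenbeck) process squashed into (0, 1) by a
logistic map. High state raises tapping-time jitter (higher BV), biases the
left/right choice toward habitual alternation (lower AE), shrinks event-evoked
pupil responses (perceptual decoupling), and pushes thought-probe responses
toward the off-task end of the six-point scale via an ordered-probit link with
subject random intercepts.

The task layout mirrors the study design: 27 subjects, 18 random + 9
alternating ~1-min blocks in pseudorandom order with no two alternating blocks
adjacent, metronome stimuli every 750 ms, 74-87 stimuli per block (mean 80),
and a thought probe one metronome period after the last stimulus of each
block, i.e. between 55.5 and 65.25 s after the first stimulus (60 s mean).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, signal as sp_signal
from scipy.special import expit

from ._rng import child_rng
from .pupil import PupilTrace, prf

__all__ = [
    "SimConfig",
    "LatentParams",
    "PupilGenParams",
    "SubjectParams",
    "LatentStateTraj",
    "SimulatedSession",
    "simulate_latent_state",
    "stimulus_count_distribution",
    "simulate_block_structure",
    "simulate_taps",
    "simulate_probe_response",
    "simulate_pupil",
    "simulate_bold",
    "simulate_nuisance",
    "simulate_session",
    "simulate_probit_study",
    "PROBE_CUTPOINTS",
]

#: default ordered-probit cutpoints for probe-response generation, placed so
#: that roughly 36% of responses fall in the off-task half of the scale and
#: the mean response is near 3 under the default latent-state scaling.
PROBE_CUTPOINTS = (-1.80, -0.64, 0.52, 1.68, 2.84)


@dataclass
class SimConfig:
    """Study design parameters; defaults are the task's own conditions."""

    n_subjects: int = 27
    n_random_blocks: int = 18
    n_alternating_blocks: int = 9
    soa: float = 0.750
    stimuli_per_block_mean: float = 80.0
    stimuli_per_block_range: tuple[int, int] = (74, 87)
    probe_display: float = 6.0
    probe_jitter_max: float = 1.0
    instruction_duration: float = 4.0
    pupil_fs: float = 250.0
    tr: float = 1.8
    seed: int = 0

    def validate(self) -> "SimConfig":
        lo, hi = self.stimuli_per_block_range
        if not (lo <= self.stimuli_per_block_mean <= hi):
            raise ValueError("stimuli_per_block_mean outside stimuli_per_block_range")
        if lo < 2 or hi < lo:
            raise ValueError("invalid stimuli_per_block_range")
        for name in ("soa", "probe_display", "instruction_duration", "pupil_fs", "tr"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.probe_jitter_max < 0:
            raise ValueError("probe_jitter_max must be >= 0")
        if min(self.n_subjects, self.n_random_blocks) < 1 or self.n_alternating_blocks < 0:
            raise ValueError("counts must be positive")
        return self


@dataclass
class LatentParams:
    """Mean-reverting latent-state process: OU with time constant tau (s) and
    stationary SD sigma, squashed by the logistic function."""

    tau: float = 30.0
    sigma: float = 1.0
    start: float | None = None  # latent-scale start; None = stationary draw


@dataclass
class PupilGenParams:
    baseline: float = 1000.0      # arbitrary pupil-area units
    tonic_state_gain: float = 60.0  # units per unit of (0.5 - state)
    drift_sd: float = 15.0        # stationary SD of the extra slow OU drift
    drift_tau: float = 20.0
    phasic_amp: float = 30.0      # event-evoked response amplitude at state 0
    decoupling: float = 0.6       # fractional amplitude loss per state unit
    noise_sd: float = 2.0
    blink_min_frac: float = 0.05
    blink_duration: tuple[float, float] = (0.1, 0.3)


@dataclass
class SubjectParams:
    intercept_shift: float = 0.0   # ordered-probit random intercept u_subject
    iti_sd_base: float = 0.030     # tap jitter SD (s) at state 0
    iti_sd_gain: float = 0.050     # additional jitter SD per state unit
    rep_bias_gain: float = 0.35    # alternation-bias growth per state unit
    blink_rate: float = 15.0       # blinks per minute
    pupil_params: PupilGenParams = field(default_factory=PupilGenParams)

    def __post_init__(self):
        if self.iti_sd_base <= 0:
            raise ValueError("iti_sd_base must be positive")

    def rep_bias(self, state) -> np.ndarray:
        """Repetition bias in [0, 0.5]; taps alternate with probability 1 - rep_bias.

        0.5 is a fair coin (maximal entropy); lower values bias the sequence
        toward the habitual L-R-L-R pattern.
        """
        return np.clip(0.5 - self.rep_bias_gain * np.asarray(state, dtype=float), 0.0, 0.5)


@dataclass
class LatentStateTraj:
    times: np.ndarray
    latent: np.ndarray  # OU scale
    state: np.ndarray   # logistic(latent), in (0, 1)

    def at(self, t) -> np.ndarray:
        """State interpolated at arbitrary times."""
        return np.interp(np.asarray(t, dtype=float), self.times, self.state)


def simulate_latent_state(
    duration: float,
    params: LatentParams | None = None,
    rng: np.random.Generator | None = None,
    *,
    dt: float = 0.25,
) -> LatentStateTraj:
    """Discretized OU process through a logistic map on a regular grid.

    Uses the exact AR(1) discretization, so the latent lag-1 autocorrelation
    at step dt is exp(-dt/tau).
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    params = params or LatentParams()
    if params.tau <= 0:
        raise ValueError("tau must be positive")
    rng = rng or np.random.default_rng()
    n = int(np.floor(duration / dt)) + 1
    a = np.exp(-dt / params.tau)
    innov_sd = params.sigma * np.sqrt(1.0 - a * a)
    e = rng.standard_normal(n) * innov_sd
    x0 = params.start if params.start is not None else rng.standard_normal() * params.sigma
    e[0] = 0.0
    # AR(1) filtering: x[k] = a x[k-1] + e[k], x[0] = x0
    x = sp_signal.lfilter([1.0], [1.0, -a], e, zi=np.array([a * x0]))[0]
    x[0] = x0
    times = np.arange(n) * dt
    return LatentStateTraj(times, x, expit(x))


def stimulus_count_distribution(
    mean: float = 80.0, support: tuple[int, int] = (74, 87)
) -> tuple[np.ndarray, np.ndarray]:
    """Discrete triangular weights on ``support``, exponentially tilted so the
    distribution's mean equals ``mean`` exactly."""
    lo, hi = support
    k = np.arange(lo, hi + 1)
    base = np.minimum(k - lo + 1, hi - k + 1).astype(float)

    def mean_at(lam: float) -> float:
        w = base * np.exp(lam * (k - lo))
        w /= w.sum()
        return float(w @ k)

    if not (mean_at(-20.0) - 1e-9 <= mean <= mean_at(20.0) + 1e-9):
        raise ValueError(f"mean {mean} unattainable on support {support}")
    lam = optimize.brentq(lambda l: mean_at(l) - mean, -20.0, 20.0)
    w = base * np.exp(lam * (k - lo))
    return k, w / w.sum()


def _block_order(n_random: int, n_alternating: int, rng: np.random.Generator) -> np.ndarray:
    """Uniform order over sequences with no two adjacent alternating blocks.

    Alternating positions are a uniform draw of non-adjacent slots (classic
    stars-and-bars bijection), which is exactly the uniform distribution over
    admissible orders.
    """
    n = n_random + n_alternating
    if n_alternating > (n + 1) // 2:
        raise ValueError("cannot avoid adjacent alternating blocks")
    if n_alternating == 0:
        return np.array(["random"] * n)
    picks = np.sort(rng.choice(n - n_alternating + 1, size=n_alternating, replace=False))
    positions = picks + np.arange(n_alternating)
    order = np.array(["random"] * n, dtype=object)
    order[positions] = "alternating"
    return order


def simulate_block_structure(
    config: SimConfig,
    rng: np.random.Generator | None = None,
    *,
    n_random: int | None = None,
    n_alternating: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Block table and stimulus table for one session.

    Returns ``(blocks, stimuli)``. Block time zero is the first metronome
    onset of the session; each block starts ``instruction_duration`` after
    the previous probe display ends. ``probe_onset`` is one SOA after the
    last stimulus, so relative to the block's first stimulus it equals
    ``n_stimuli * soa``.
    """
    config.validate()
    rng = rng or np.random.default_rng(config.seed)
    nr = config.n_random_blocks if n_random is None else n_random
    na = config.n_alternating_blocks if n_alternating is None else n_alternating
    order = _block_order(nr, na, rng)
    counts_k, counts_p = stimulus_count_distribution(
        config.stimuli_per_block_mean, config.stimuli_per_block_range
    )
    n_stim = rng.choice(counts_k, size=len(order), p=counts_p)
    jitter = rng.uniform(0.0, config.probe_jitter_max, size=len(order))
    blocks, stims = [], []
    t = 0.0
    for b, (cond, n) in enumerate(zip(order, n_stim)):
        first = t + config.instruction_duration
        onsets = first + config.soa * np.arange(n)
        probe = onsets[-1] + config.soa
        blocks.append({
            "block": b, "condition": cond, "n_stimuli": int(n),
            "block_start": first, "probe_onset": probe,
            "probe_onset_rel": probe - first, "probe_jitter": jitter[b],
        })
        stims.append(pd.DataFrame({"block": b, "onset": onsets}))
        t = probe + config.probe_display + jitter[b]
    return pd.DataFrame(blocks), pd.concat(stims, ignore_index=True)


def simulate_taps(
    state,
    stimulus_onsets,
    subject: SubjectParams,
    rng: np.random.Generator,
    *,
    condition: str = "random",
) -> pd.DataFrame:
    """One tap per stimulus with state-dependent timing jitter and hand choice.

    ``state`` may be a scalar, an array aligned with the stimuli, or a
    :class:`LatentStateTraj`. In alternating blocks the hand sequence is a
    strict L-R-L-R; in random blocks the hand alternates with probability
    ``1 - rep_bias(state)``.
    """
    onsets = np.asarray(stimulus_onsets, dtype=float)
    if onsets.size == 0:
        raise ValueError("block has no stimulus onsets")
    if isinstance(state, LatentStateTraj):
        s = state.at(onsets)
    else:
        s = np.broadcast_to(np.asarray(state, dtype=float), onsets.shape)
    sd = subject.iti_sd_base + subject.iti_sd_gain * s
    times = onsets + rng.standard_normal(onsets.size) * sd
    if condition == "alternating":
        hands = np.arange(onsets.size) % 2
    else:
        alt = rng.random(onsets.size) < (1.0 - subject.rep_bias(s))
        hands = np.zeros(onsets.size, dtype=int)
        hands[0] = rng.integers(2)
        for i in range(1, onsets.size):
            hands[i] = 1 - hands[i - 1] if alt[i] else hands[i - 1]
    return pd.DataFrame({"onset": times, "hand": np.where(hands == 0, "L", "R"), "stim_onset": onsets})


def simulate_probe_response(
    x,
    betas,
    cutpoints,
    u_subject: float,
    rng: np.random.Generator,
    *,
    noise_sd: float = 1.0,
) -> int:
    """Draw an ordinal response 1..K+1 from the ordered-probit model.

    Latent ``y* = x . beta + u_subject + eps`` with standard-normal eps is
    bracketed by the strictly increasing cutpoints.
    """
    c = np.asarray(cutpoints, dtype=float)
    if np.any(np.diff(c) <= 0):
        raise ValueError("cutpoints must be strictly increasing")
    eta = float(np.dot(np.asarray(x, dtype=float), np.asarray(betas, dtype=float))) + u_subject
    y_star = eta + rng.standard_normal() * noise_sd
    return int(np.searchsorted(c, y_star) + 1)


def simulate_pupil(
    state: LatentStateTraj,
    events: pd.DataFrame,
    subject: SubjectParams,
    config: SimConfig,
    rng: np.random.Generator,
    *,
    t_start: float = 0.0,
    duration: float | None = None,
) -> PupilTrace:
    """Pupil trace = tonic baseline + PRF responses + noise, with blink gaps.

    The tonic component is the baseline plus a state-coupled term (larger
    pupil at low mind-wandering state) plus an independent slow OU drift.
    Phasic amplitudes shrink linearly with state (perceptual decoupling).
    Blinks are Poisson dropouts during which the signal collapses toward
    zero and the mask is cleared.
    """
    if config.pupil_fs <= 0:
        raise ValueError("pupil_fs must be positive")
    pp = subject.pupil_params
    if duration is None:
        duration = float(state.times[-1]) - t_start
    n = int(np.round(duration * config.pupil_fs)) + 1
    t = t_start + np.arange(n) / config.pupil_fs
    s = state.at(t)
    # slow drift: OU sampled on a coarse grid, interpolated -> smooth tonic
    drift_traj = simulate_latent_state(
        duration + 1.0, LatentParams(tau=pp.drift_tau, sigma=pp.drift_sd), rng, dt=0.25
    )
    drift = np.interp(t - t_start, drift_traj.times, drift_traj.latent)
    tonic = pp.baseline + pp.tonic_state_gain * (0.5 - s) + drift

    onsets = np.sort(np.asarray(events["onset"], dtype=float))
    if onsets.size and np.any(np.diff(onsets) < 0):
        raise ValueError("events must be sorted")
    impulses = np.zeros(n)
    amp = pp.phasic_amp * (1.0 - pp.decoupling * state.at(onsets))
    idx = np.round((onsets - t_start) * config.pupil_fs).astype(int)
    ok = (idx >= 0) & (idx < n)
    np.add.at(impulses, idx[ok], amp[ok])
    kernel = prf(np.arange(int(4.0 * config.pupil_fs)) / config.pupil_fs)
    phasic = sp_signal.fftconvolve(impulses, kernel)[:n]

    size = tonic + phasic + rng.standard_normal(n) * pp.noise_sd
    mask = np.ones(n, dtype=bool)
    n_blinks = rng.poisson(subject.blink_rate / 60.0 * duration)
    for on in np.sort(rng.uniform(t_start, t_start + duration, size=n_blinks)):
        dur = rng.uniform(*pp.blink_duration)
        env_t = [on, on + 0.25 * dur, on + 0.75 * dur, on + dur]
        env = np.interp(t, env_t, [1.0, pp.blink_min_frac, pp.blink_min_frac, 1.0],
                        left=1.0, right=1.0)
        inside = (t >= on) & (t <= on + dur)
        size = size * env
        mask[inside] = False
    return PupilTrace(fs=config.pupil_fs, time=t, size=size, mask=mask, events=events.reset_index(drop=True))


def simulate_bold(
    design: np.ndarray,
    truth_map: np.ndarray,
    noise_sd: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """4D BOLD array: voxel time series = X @ beta_voxel + white noise.

    ``design`` is (n_volumes, p); ``truth_map`` is (nx, ny, nz, p).
    Returns (nx, ny, nz, n_volumes).
    """
    X = np.asarray(design, dtype=float)
    B = np.asarray(truth_map, dtype=float)
    if B.ndim != 4 or B.shape[-1] != X.shape[1]:
        raise ValueError(f"truth_map last axis {B.shape} must match design columns {X.shape[1]}")
    Y = np.einsum("xyzp,tp->xyzt", B, X)
    if noise_sd > 0:
        Y = Y + rng.standard_normal(Y.shape) * noise_sd
    return Y


def simulate_nuisance(n_volumes: int, rng: np.random.Generator) -> pd.DataFrame:
    """Smooth random-walk nuisance series (CSF, WM, FD, six motion params)."""
    cols = {}
    names = ["csf", "wm", "trans_x", "trans_y", "trans_z", "rot_x", "rot_y", "rot_z"]
    for name in names:
        w = np.cumsum(rng.standard_normal(n_volumes)) * 0.05
        b, a = sp_signal.butter(2, 0.2)
        cols[name] = sp_signal.filtfilt(b, a, w)
    cols["fd"] = np.abs(sp_signal.filtfilt(*sp_signal.butter(2, 0.3), rng.standard_normal(n_volumes))) * 0.1
    return pd.DataFrame(cols)


@dataclass
class SimulatedSession:
    config: SimConfig
    subjects: dict[int, SubjectParams]
    blocks: pd.DataFrame       # subject, block, condition, ..., response
    taps: pd.DataFrame         # subject, block, condition, onset, hand
    stimuli: pd.DataFrame      # subject, block, onset
    pupil: dict[int, PupilTrace]
    truth: dict


def _draw_subject_params(rng: np.random.Generator, sigma_u: float) -> SubjectParams:
    return SubjectParams(
        intercept_shift=float(rng.standard_normal() * sigma_u),
        iti_sd_base=float(np.exp(rng.normal(np.log(0.030), 0.2))),
        iti_sd_gain=float(np.exp(rng.normal(np.log(0.050), 0.2))),
        rep_bias_gain=float(np.clip(rng.normal(0.35, 0.05), 0.1, 0.5)),
        blink_rate=float(rng.uniform(10.0, 25.0)),
    )


def simulate_session(
    config: SimConfig,
    *,
    include_pupil: bool = True,
    latent: LatentParams | None = None,
    state_loading: float = 0.6,
    time_loading: float = 0.09,
    sigma_u: float = 0.5,
    cutpoints=PROBE_CUTPOINTS,
    probe_window: float = 18.75,
) -> SimulatedSession:
    """Generate a complete multi-subject study.

    Probe responses follow an ordered probit whose latent predictor combines
    the (session-z-scored) mean latent state over the ``probe_window`` seconds
    before each probe, a linear time-on-task drift (``time_loading`` per
    block, centered), and the subject random intercept.
    """
    config.validate()
    latent = latent or LatentParams()
    seed = config.seed
    subjects: dict[int, SubjectParams] = {}
    trajs: dict[int, LatentStateTraj] = {}
    all_blocks, all_taps, all_stims = [], [], []
    drivers = []
    for s in range(config.n_subjects):
        subjects[s] = _draw_subject_params(child_rng(seed, "subject_params", s), sigma_u)
        rng_b = child_rng(seed, "blocks", s)
        blocks, stims = simulate_block_structure(config, rng_b)
        session_end = blocks["probe_onset"].iloc[-1] + config.probe_display + config.probe_jitter_max
        traj = simulate_latent_state(session_end, latent, child_rng(seed, "state", s))
        trajs[s] = traj
        rng_t = child_rng(seed, "taps", s)
        taps = []
        for _, blk in blocks.iterrows():
            on = stims.loc[stims["block"] == blk["block"], "onset"].to_numpy()
            tp = simulate_taps(traj, on, subjects[s], rng_t, condition=blk["condition"])
            tp["block"] = blk["block"]
            tp["condition"] = blk["condition"]
            taps.append(tp)
        taps = pd.concat(taps, ignore_index=True)
        for df in (blocks, stims, taps):
            df["subject"] = s
        # probe driver: mean state over the window preceding the probe
        for _, blk in blocks.iterrows():
            tt = np.linspace(blk["probe_onset"] - probe_window, blk["probe_onset"], 40)
            drivers.append(float(traj.at(tt).mean()))
        all_blocks.append(blocks)
        all_taps.append(taps)
        all_stims.append(stims)
    blocks = pd.concat(all_blocks, ignore_index=True)
    taps = pd.concat(all_taps, ignore_index=True)
    stimuli = pd.concat(all_stims, ignore_index=True)

    drv = np.asarray(drivers)
    drv_z = (drv - drv.mean()) / max(drv.std(), 1e-12)
    n_blocks = config.n_random_blocks + config.n_alternating_blocks
    time_c = blocks["block"].to_numpy(dtype=float) + 1 - (n_blocks + 1) / 2.0
    responses = []
    rng_r = child_rng(seed, "responses")
    for i, (_, blk) in enumerate(blocks.iterrows()):
        eta_x = state_loading * drv_z[i] + time_loading * time_c[i]
        responses.append(
            simulate_probe_response([eta_x], [1.0], cutpoints,
                                    subjects[int(blk["subject"])].intercept_shift, rng_r)
        )
    blocks["response"] = responses
    blocks["state_driver"] = drv_z

    pupil: dict[int, PupilTrace] = {}
    if include_pupil:
        for s in range(config.n_subjects):
            sb = stimuli[stimuli["subject"] == s]
            st = taps[taps["subject"] == s]
            pr = blocks[blocks["subject"] == s]
            events = pd.concat([
                pd.DataFrame({"onset": sb["onset"], "kind": "stimulus"}),
                pd.DataFrame({"onset": st["onset"], "kind": "tap"}),
                pd.DataFrame({"onset": pr["probe_onset"], "kind": "probe"}),
            ]).sort_values("onset", ignore_index=True)
            pupil[s] = simulate_pupil(trajs[s], events, subjects[s], config, child_rng(seed, "pupil", s))

    truth = {
        "latent": latent, "state_loading": state_loading, "time_loading": time_loading,
        "sigma_u": sigma_u, "cutpoints": tuple(cutpoints), "trajectories": trajs,
    }
    return SimulatedSession(config, subjects, blocks, taps, stimuli, pupil, truth)


def simulate_probit_study(
    n_subjects: int,
    n_probes: int,
    betas: dict[str, float],
    *,
    cutpoints,
    sigma_u: float,
    seed: int,
    interactions: tuple[tuple[str, str], ...] = (),
) -> pd.DataFrame:
    """Draw a probe-response table directly from the hierarchical ordered probit.

    ``betas`` maps covariate names to true coefficients. A covariate named
    ``time`` is the probe number 1..n_probes (centered); all others are iid
    standard normal; names like ``a:b`` listed in ``interactions`` are
    products of the named columns. Returns a long table with the covariates,
    ``subject`` and ``response``.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(0xB1,)))
    c = np.asarray(cutpoints, dtype=float)
    rows = []
    names = list(betas)
    for s in range(n_subjects):
        u = rng.standard_normal() * sigma_u
        cov: dict[str, np.ndarray] = {}
        for name in names:
            if ":" in name:
                continue
            if name == "time":
                t = np.arange(1, n_probes + 1, dtype=float)
                cov[name] = t - t.mean()
            else:
                cov[name] = rng.standard_normal(n_probes)
        for a, b in interactions:
            cov[f"{a}:{b}"] = cov[a] * cov[b]
        eta = sum(betas[k] * cov[k] for k in names) + u
        y_star = eta + rng.standard_normal(n_probes)
        resp = np.searchsorted(c, y_star) + 1
        for i in range(n_probes):
            rows.append({"subject": s, **{k: cov[k][i] for k in names}, "response": int(resp[i])})
    return pd.DataFrame(rows)
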