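# Methods

This note records the models, the free parameters and their defaults, the
numerical choices, and what the synthetic-data generator does and does not
emulate. Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Task model and time base

A session is 27 blocks per subject — 18 "random" and 9 "alternating" — in a
uniform random order constrained so that no two alternating blocks are
adjacent (sampled exactly via the non-adjacent-combination bijection, not by
rejection). Each block holds `n` metronome stimuli at a 750-ms stimulus
onset asynchrony, `n` drawn from a discrete triangular distribution on
74..87 exponentially tilted so its mean is exactly 80; the thought probe
onset is one SOA after the last stimulus, hence 55.5–65.25 s after the first
stimulus of the block (60 s mean). Instructions (4 s) precede each block and
the probe display (6 s + U(0,1) s jitter) follows it. All times are seconds,
session-relative. Events TSV files follow BIDS conventions (tab-separated,
'.' decimal, `n/a` for missing).

## Latent attentional state

Mind-wandering intensity is a stationary Ornstein–Uhlenbeck process
(time constant τ = 30 s, stationary SD 1, exact AR(1) discretization at
0.25-s steps) mapped through the logistic function into (0, 1). The paradigm
treats mind wandering as slowly fluctuating episodes spanning many seconds;
any bounded, slowly mixing process with that property would do — the OU
choice is the simplest one whose lag-1 autocorrelation has a closed form
(`exp(−Δt/τ)`), which the tests verify. The state drives, linearly:

- tap-timing jitter SD: `iti_sd_base + iti_sd_gain · state`
  (defaults 30 ms + 50 ms/state-unit, log-normally jittered per subject);
- hand choice in random blocks: taps alternate with probability
  `1 − rep_bias(state)`, `rep_bias = clip(0.5 − 0.35·state, 0, 0.5)` — at
  state 0 a fair coin (maximal entropy), rising state biasing the sequence
  toward the habitual L-R-L-R pattern (falling AE). Alternating blocks
  alternate deterministically;
- phasic pupil amplitude: scaled by `1 − 0.6·state` (perceptual decoupling);
- tonic pupil: baseline + 60·(0.5 − state) arbitrary units, plus an
  independent smooth OU drift (τ = 20 s, SD 15, generated on a 0.25-s grid
  and interpolated so the baseline is genuinely slow);
- probe responses: ordered probit with latent predictor
  `0.6·z(statē) + 0.09·(block − 14) + u_subject`, `σ_u = 0.5`, where
  `statē` is the mean state over the 18.75 s before the probe and z() is
  session-wide standardization. Cutpoints (−1.80, −0.64, 0.52, 1.68, 2.84)
  were placed analytically — once, before any test was run — so that the
  marginal response distribution has mean ≈ 3 and ≈ 36% of responses in the
  off-task half of the scale, the regime the task is known to produce.

All randomness descends from one root seed through named
`SeedSequence` children (`wandertap._rng`), so sessions are bit-reproducible
and adding a consumer never shifts existing streams.

Blink artifacts are Poisson (default 15/min per subject, U(10,25) across
subjects), 100–300 ms long, rendered as steep dips toward zero with the
sample mask cleared.

## Behavioral markers

BV is the sample SD (ddof = 1) of the 24 intervals among the 25 taps at or
before the anchor (probe or stimulus onset); "the 25 taps" is read as 24
intervals, with the window size configurable. The raw SD is floored at 1 ms
before the log — real data cannot reach exact zero variance but noiseless
synthetic data can. The tap stream is used raw (missing/double taps
included); windows count taps, not stimuli.

AE uses exact matching on the binary hand sequence with self-matches
included, m = 2, and *aligned index ranges*: both `Φ^m` and `Φ^(m+1)` sum
over window starts i = 1..N−m, so AE is the mean of `ln(B_i/A_i)` with
`B_i` the match count of the m-window at i and `A_i` that of its
(m+1)-extension. Under this convention AE is exactly 0 for any
deterministic sequence and provably bounded by ln 2 for binary sequences
(each context contributes `B·H(a/B) ≤ B ln 2`); with unaligned ranges the
statistic can go slightly negative on finite periodic sequences, which
contradicts the defining property that a strictly alternating window has
zero entropy. The transform `−ln(ln 2 − AE)` is guarded at the singularity
by ε = 1e−6.

Marker standardization is *grand* z-scoring (pooled mean/SD, ddof = 0) over
the analysis set after exclusions: BV over all included probes, AE over
included random-block probes (it is undefined for alternating blocks).
Pupil features are z-scored *within* subject instead, to remove absolute
pupil-size differences.

Split-point dichotomization picks the cutpoint in {1..5} whose off-task
share is nearest 0.5, ties toward the smaller cutpoint (labelling more
probes off-task), so a subject using only "clearly/partly on-task" still
contributes a contrast. The fixed alternative labels responses ≥ 4
off-task.

## Pupil preprocessing and deconvolution

Defaults: velocity threshold k = 5 robust (MAD) SDs on a 10-ms-smoothed
first difference; blink merge distance 200 ms; interpolation margin 100 ms;
Butterworth order 2 applied forward–backward (zero phase), 5-Hz cutoff;
decimation to 250 Hz with an any-masked rule per cell. All exposed in
configuration — on real recordings these are tuned per subject by
inspection, and the defaults only encode sensible magnitudes.

The PRF is normalized to unit peak so NNLS coefficients are amplitudes in
signal units; the shape (n = 10, t_max = 900 ms) fixes only the kernel, not
its scale. Tonic estimation: pass 1 fits a penalized cubic smoothing spline
(roughness λ = 0.1 s³) through troughs with prominence ≥ 5% of the robust
signal range (lower-envelope bin minima every 2 s when fewer than 4 troughs
exist); each later pass (default 3) subtracts the NNLS-modeled responses
and refits a stiffer spline (λ = 1) to the *whole* residual, which after
subtraction is the baseline itself — this alternation converges, whereas
refitting through residual minima is biased low and diverges. The final
curve is clipped pointwise to stay at or below the signal, preserving the
defining constraint of the decomposition. Beyond the outermost fit points
the curve is held constant rather than extrapolated.

Identifiability: with events much denser than the PRF width (the task's
750-ms SOA, plus taps), a sustained response pedestal is indistinguishable
from a baseline shift, so absolute phasic amplitudes are identified only up
to that pedestal; the within-subject z-scoring of per-trial features removes
exactly this ambiguity. Exact amplitude recovery (tested to 1e−6) holds for
well-separated events. The pipeline deconvolves per block (first stimulus
− 2 s to probe + 2 s) to keep the NNLS design dense-matrix sized.

Trial features: tonic at the stimulus-onset sample; phasic as the sum of
coefficients within ±200 ms of the onset (the stimulus/tap collinearity is
resolved by summing, never by interpreting individual coefficients);
missing fraction over [onset, onset + SOA) — the trial span for the
40%-missing rule is not otherwise defined. Per-probe features average the
valid trials among the 25 preceding the probe; a probe with no valid trial
in the window is excluded.

## Hierarchical ordered probit

Likelihood as in the README; subject intercepts are marginalized per subject
with Gauss–Hermite quadrature (15 nodes by default; the tests verify
agreement with Monte-Carlo integration to 1%), reducing the sampled space to
β, the 5 cutpoints and σ_u (10–11 dimensions). Cutpoints are parameterized
as (c₁, log-increments) with the Jacobian added; σ_u as log σ_u.

Priors (the analysis model's own choice, configurable): Normal(0, 2.5) on
coefficients, Student-t(3, 0, 2.5) on each cutpoint, half-Student-t(3, 0,
2.5) on σ_u — standard weakly-informative regression defaults.

Sampling: affine-invariant stretch-move ensembles (emcee), walkers started
in a tight ball around the L-BFGS posterior mode. Four independent
ensembles of 24 walkers serve as chains for split-R-hat and ESS (arviz);
defaults of 500 warmup sweeps and 500 retained sweeps (12 000 draws per
chain) were sized so R-hat < 1.01 on study-scale designs. Ensemble draws
are more autocorrelated than gradient-based draws, so the reliability gate
(R-hat < 1.01, warning otherwise) is the operative control, not the raw
draw count. Fits are deterministic given the spec (seed included).

Reporting: posterior mean; 95% HDI by the sorted shortest-window rule (ties
to the lower start); evidence ratios from draw proportions with unanimous
draws reported as ∞ (the draw count bounds the resolvable odds at the total
number of draws); Bayesian R² per draw as
`(var(Xβ) + σ_u²) / (var(Xβ) + σ_u² + 1)` — latent scale, unit probit
residual variance, subject-intercept variance counted as explained. The
directional convention is fixed per model: ER₊ for time, BV, BV×AE, tonic
and tonic×phasic; ER₋ for AE and phasic.

## fMRI GLMs

The double-gamma HRF is the canonical difference of two gamma densities
(modes 6 s and 16 s, undershoot ratio 1/6, unit peak, configurable). Event
columns are built as boxcars on a 50-ms grid, convolved, and sampled at the
volume times (TR = 1.8 s). BV/AE/tonic marker series are slow and
time-lagged by construction, so they are resampled by nearest-anchor hold
*without* convolution (midpoint ties to the earlier anchor; volumes before
the first anchor take its value); a linear-interpolation mode exists behind
a flag since the two descriptions of this step disagree in the source
material. Phasic amplitudes are treated as modulated impulses and convolved.
DCT drift columns are the orthonormalized DCT-II set with periods above
128 s, excluding the constant.

Voxelwise OLS uses the pseudoinverse; contrast t values map to z through
matched tail probabilities (stable in both tails). Thresholding labels
z > 2.3 voxels into 26-connected components; Gaussian-random-field
cluster p-values are deliberately not computed — a minimum-cluster-size
parameter substitutes, and the output metadata records this deviation.
Atlas overlap is computed over non-white-matter suprathreshold voxels
against disjoint binarized parcels (nearest-neighbor, label-preserving
resampling); if any such voxel is covered by no parcel the 100% contract is
broken and the computation fails loudly rather than renormalizing. Dice is
`2|A∩B|/(|A|+|B|)`, defined 0 (with a warning) for two empty maps.

Nuisance series (CSF, WM, FD, motion) are generated as smoothed random
walks; extracting them from images is out of scope.

## Problem sizes used by tests and the acceptance script

Unit and property tests run on reduced designs (e.g. 4-subject sessions,
100-Hz pupil traces, 12³-voxel volumes) chosen so each check exercises the
same code paths as the full design at a fraction of the cost; the
generator's *parameters* are never reduced, only counts and rates. The
probit interval-calibration test uses 50 replicate 27×18 studies with
2-ensemble, 800-draw fits — enough for HDI endpoints, not for publication
diagnostics. The acceptance script fits 4 ensembles × 2 000 draws per model.
Posterior means are stable across these settings; interval endpoints move
by a few percent.

## What the generator does not emulate

No audio or stimulus presentation, no reaction-time outliers beyond Gaussian
jitter, no missing/double taps by default (injection hooks exist), no
hemodynamic nonlinearity, head motion, or physiological noise in BOLD, no
gaze-position artifacts, and pupil blinks as clean dips rather than measured
eyelid transients. Passing tests therefore demonstrate correctness of the
estimators under the stated generative assumptions — not robustness to
every artifact of real recordings, which is why every preprocessing
threshold stays configurable.

## Known limitations

- The ordered-probit sampler is a full-posterior but gradient-free method;
  very large designs (thousands of probes) would favor an HMC backend.
- Absolute phasic amplitudes are unidentified under dense event trains (see
  above); only within-subject-standardized features should be interpreted.
- Cluster-level inference is size-thresholding only; no FWE control.
- `run_pipeline` caches on the configuration hash; editing code without
  changing the configuration requires clearing the output directory.
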