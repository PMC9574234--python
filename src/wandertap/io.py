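"""File formats, configuration and pipeline orchestration.

Conventions: all times are seconds, session-relative (0 at the first sample /
first volume). Tabular outputs are BIDS-style TSV (tab-separated, UTF-8, '.'
decimal, 'n/a' for missing); pupil traces are CSV with columns time_s, pupil;
volumes are NIfTI-1. Every run writes a manifest recording the configuration
hash, produced artifacts with checksums, and warnings, so any artifact can be
regenerated bit-identically from its manifest (all stochastic stages carry
explicit seeds).
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import behavior, probit, pupil as pupil_mod
from .synth import SimConfig, SimulatedSession, simulate_bold, simulate_nuisance, simulate_session

__all__ = [
    "PipelineConfig",
    "RunManifest",
    "write_events",
    "read_events",
    "write_pupil_csv",
    "read_pupil_csv",
    "save_nifti",
    "load_nifti",
    "run_pipeline",
    "report",
]

log = logging.getLogger("wandertap")

EVENT_COLUMNS = ["onset", "duration", "trial_type", "hand", "block", "condition", "response"]
REQUIRED_EVENT_COLUMNS = ["onset", "duration", "trial_type"]


def write_events(session: SimulatedSession, path) -> Path:
    """Write taps, stimuli and probes as one BIDS-style events TSV."""
    frames = []
    taps = session.taps
    frames.append(pd.DataFrame({
        "onset": taps["onset"], "duration": 0.0, "trial_type": "tap",
        "hand": taps["hand"], "block": taps["block"], "condition": taps["condition"],
        "response": "n/a", "subject": taps["subject"],
    }))
    stim = session.stimuli.merge(session.blocks[["subject", "block", "condition"]],
                                 on=["subject", "block"])
    frames.append(pd.DataFrame({
        "onset": stim["onset"], "duration": 0.0, "trial_type": "stimulus",
        "hand": "n/a", "block": stim["block"], "condition": stim["condition"],
        "response": "n/a", "subject": stim["subject"],
    }))
    blocks = session.blocks
    frames.append(pd.DataFrame({
        "onset": blocks["probe_onset"], "duration": session.config.probe_display + blocks["probe_jitter"],
        "trial_type": "probe", "hand": "n/a", "block": blocks["block"],
        "condition": blocks["condition"], "response": blocks["response"],
        "subject": blocks["subject"],
    }))
    df = pd.concat(frames, ignore_index=True).sort_values(["subject", "onset"], kind="stable")
    path = Path(path)
    df.to_csv(path, sep="\t", index=False, na_rep="n/a", float_format="%.6f")
    return path


def read_events(path) -> dict[str, pd.DataFrame]:
    """Read an events TSV back into taps / stimuli / probes tables.

    Validates required columns and per-subject onset ordering.
    """
    df = pd.read_csv(path, sep="\t", na_values=["n/a"])
    missing = [c for c in REQUIRED_EVENT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"events file {path} missing required columns: {missing}")
    for _, g in df.groupby(df.get("subject", pd.Series(0, index=df.index))):
        if not g["onset"].is_monotonic_increasing:
            raise ValueError(f"events file {path} has unsorted onsets")
    taps = df[df["trial_type"] == "tap"].copy()
    stimuli = df[df["trial_type"] == "stimulus"].copy()
    probes = df[df["trial_type"] == "probe"].copy()
    probes = probes.rename(columns={"onset": "probe_onset"})
    if len(probes):
        probes["response"] = probes["response"].astype(int)
    return {"taps": taps, "stimuli": stimuli, "probes": probes, "all": df}


def write_pupil_csv(trace: pupil_mod.PupilTrace, path) -> Path:
    path = Path(path)
    pd.DataFrame({"time_s": trace.time, "pupil": trace.size,
                  "valid": trace.mask.astype(int)}).to_csv(path, index=False, float_format="%.6f")
    return path


def read_pupil_csv(path, fs: float | None = None) -> pupil_mod.PupilTrace:
    df = pd.read_csv(path)
    t = df["time_s"].to_numpy(dtype=float)
    if fs is None:
        steps = np.diff(t)
        fs = 1.0 / np.median(steps)
    mask = df["valid"].to_numpy(dtype=bool) if "valid" in df.columns else None
    return pupil_mod.PupilTrace(fs=float(fs), time=t, size=df["pupil"].to_numpy(float), mask=mask)


def save_nifti(data: np.ndarray, affine: np.ndarray, path) -> Path:
    import nibabel as nib

    nib.save(nib.Nifti1Image(np.asarray(data, dtype=np.float32), affine), str(path))
    return Path(path)


def load_nifti(path):
    import nibabel as nib

    img = nib.load(str(path))
    return np.asarray(img.dataobj), img.affine


@dataclass
class PipelineConfig:
    """End-to-end pipeline configuration. Unknown keys are rejected."""

    out_dir: str = "wandertap_out"
    sim: SimConfig = field(default_factory=SimConfig)
    include_pupil: bool = True
    pupil_cutoff_hz: float = 5.0
    pupil_velocity_k: float = 5.0
    pupil_margin: float = 0.1
    pupil_merge_distance: float = 0.2
    probe_window_trials: int = 25
    missing_max: float = 0.4
    probit: probit.ModelSpec = field(default_factory=probit.ModelSpec)
    run_probit: bool = True
    glm_shape: tuple[int, int, int] = (12, 12, 12)
    glm_noise_sd: float = 1.0
    verbosity: str = "INFO"

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "sim" in d:
            sim_known = {f.name for f in fields(SimConfig)}
            bad = set(d["sim"]) - sim_known
            if bad:
                raise ValueError(f"unknown sim config keys: {sorted(bad)}")
            d["sim"] = SimConfig(**d["sim"])
        if "probit" in d:
            d["probit"] = probit.ModelSpec(**d["probit"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class RunManifest:
    config_hash: str
    stages: list[str]
    artifacts: dict[str, str]       # name -> path
    checksums: dict[str, str]
    warnings: list[str]

    def save(self, path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(asdict(self), indent=2))
        return path

    @classmethod
    def load(cls, path) -> "RunManifest":
        return cls(**json.loads(Path(path).read_text()))


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig, *, stages=("simulate", "behavior", "pupil", "probit")) -> RunManifest:
    """Execute the requested stages, reusing cached artifacts when the
    configuration hash matches a previous run's manifest."""
    logging.basicConfig(level=getattr(logging, config.verbosity, logging.INFO))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest_path = out / "manifest.json"
    cfg_hash = config.hash()
    cached: RunManifest | None = None
    if manifest_path.exists():
        try:
            prev = RunManifest.load(manifest_path)
            if prev.config_hash == cfg_hash and all(Path(p).exists() for p in prev.artifacts.values()):
                cached = prev
        except (json.JSONDecodeError, TypeError):
            pass
    artifacts: dict[str, str] = dict(cached.artifacts) if cached else {}
    warns: list[str] = []
    done: list[str] = list(cached.stages) if cached else []

    session: SimulatedSession | None = None

    def need(stage: str) -> bool:
        return stage in stages and (cached is None or stage not in done)

    def get_session() -> SimulatedSession:
        nonlocal session
        if session is None:
            session = simulate_session(config.sim, include_pupil=config.include_pupil)
        return session

    with warnings.catch_warnings(record=True) as wrec:
        warnings.simplefilter("always")
        if need("simulate"):
            log.info("stage simulate: %d subjects", config.sim.n_subjects)
            s = get_session()
            artifacts["events"] = str(write_events(s, out / "events.tsv"))
            for subj, trace in s.pupil.items():
                artifacts[f"pupil_sub-{subj:02d}"] = str(
                    write_pupil_csv(trace, out / f"pupil_sub-{subj:02d}.csv"))
            truth = {"state_loading": s.truth["state_loading"], "time_loading": s.truth["time_loading"],
                     "sigma_u": s.truth["sigma_u"], "cutpoints": list(s.truth["cutpoints"]),
                     "seed": config.sim.seed}
            (out / "truth.json").write_text(json.dumps(truth, indent=2))
            artifacts["truth"] = str(out / "truth.json")
            done.append("simulate")

        if need("behavior"):
            log.info("stage behavior")
            s = get_session()
            feats = behavior.probe_features(s.taps, s.blocks, window=config.probe_window_trials)
            feats = behavior.standardize_features(feats)
            feats.to_csv(out / "probe_features.tsv", sep="\t", index=False, na_rep="n/a")
            artifacts["probe_features"] = str(out / "probe_features.tsv")
            done.append("behavior")

        if need("pupil") and config.include_pupil:
            log.info("stage pupil: block-wise deconvolution")
            s = get_session()
            feats = pd.read_csv(artifacts["probe_features"], sep="\t", na_values=["n/a"])
            pupil_rows = _pupil_stage(s, config)
            feats = feats.merge(pupil_rows, on=["subject", "probe_index"], how="left")
            feats["excluded"] = feats["excluded"] | feats["pupil_excluded"].fillna(False)
            feats.to_csv(out / "probe_features.tsv", sep="\t", index=False, na_rep="n/a")
            done.append("pupil")

        if need("probit") and config.run_probit:
            log.info("stage probit: model 1")
            feats = pd.read_csv(artifacts["probe_features"], sep="\t", na_values=["n/a"])
            fit1 = probit.run_model1(feats, config.probit)
            fit1.summary().to_csv(out / "probit_model1.tsv", sep="\t", index=False)
            artifacts["probit_model1"] = str(out / "probit_model1.tsv")
            if config.include_pupil and "tonic" in feats.columns and feats["tonic"].notna().any():
                log.info("stage probit: model 2")
                fit2 = probit.run_model2(feats, config.probit)
                fit2.summary().to_csv(out / "probit_model2.tsv", sep="\t", index=False)
                artifacts["probit_model2"] = str(out / "probit_model2.tsv")
            done.append("probit")

        if need("glm"):
            log.info("stage glm: single-subject marker-regressor recovery")
            s = get_session()
            glm_arts = _glm_stage(s, config, out)
            artifacts.update(glm_arts)
            done.append("glm")

        warns.extend(str(w.message) for w in wrec)

    checksums = {name: _checksum(Path(p)) for name, p in artifacts.items() if Path(p).exists()}
    manifest = RunManifest(cfg_hash, sorted(set(done)), artifacts, checksums, warns)
    manifest.save(manifest_path)
    (out / "report.md").write_text(report(manifest))
    return manifest


def _pupil_stage(session: SimulatedSession, config: PipelineConfig) -> pd.DataFrame:
    """Per-block deconvolution and per-probe tonic/phasic averaging."""
    rows = []
    for subj, trace in session.pupil.items():
        pre = pupil_mod.preprocess(
            trace, velocity_k=config.pupil_velocity_k, margin=config.pupil_margin,
            merge_distance=config.pupil_merge_distance, cutoff=config.pupil_cutoff_hz,
            target_fs=trace.fs,
        )
        blocks = session.blocks[session.blocks["subject"] == subj]
        trial_frames = []
        for _, blk in blocks.iterrows():
            stim = session.stimuli[(session.stimuli["subject"] == subj)
                                   & (session.stimuli["block"] == blk["block"])]["onset"].to_numpy()
            lo = stim[0] - 2.0
            hi = min(blk["probe_onset"] + 2.0, pre.time[-1])
            i0, i1 = np.searchsorted(pre.time, [lo, hi])
            seg = pupil_mod.PupilTrace(pre.fs, pre.time[i0:i1], pre.size[i0:i1], pre.mask[i0:i1])
            ev = trace.events
            seg_events = ev[(ev["onset"] >= seg.time[0]) & (ev["onset"] <= seg.time[-1])
                            & ev["kind"].isin(["stimulus", "tap"])]["onset"].to_numpy()
            dec = pupil_mod.deconvolve(seg, np.sort(seg_events))
            tf = pupil_mod.trial_features(dec, seg, stim, trial_span=session.config.soa)
            tf["block"] = blk["block"]
            trial_frames.append(tf)
        trials = pd.concat(trial_frames, ignore_index=True)
        trials["subject"] = subj
        trials = pupil_mod.zscore_within_subject(trials)
        pf = pupil_mod.probe_pupil_features(
            trials, blocks["probe_onset"].to_numpy(),
            window=config.probe_window_trials, missing_max=config.missing_max)
        pf["subject"] = subj
        pf["probe_index"] = blocks["block"].to_numpy() + 1
        rows.append(pf.rename(columns={"excluded": "pupil_excluded"})[
            ["subject", "probe_index", "tonic", "phasic", "pupil_excluded"]])
    return pd.concat(rows, ignore_index=True)


def _glm_stage(session: SimulatedSession, config: PipelineConfig, out: Path) -> dict[str, str]:
    """Simulate BOLD for subject 0 with a BV-coupled region and recover it.

    Builds the subject's design (event, marker, drift and nuisance columns),
    plants a cuboid whose signal follows the BV marker regressor, fits the
    voxelwise GLM, thresholds at z > 2.3, and writes the z map (NIfTI), the
    atlas-overlap table against a synthetic full-cover parcellation, and the
    Dice coefficient against the planted truth region.
    """
    from . import glm as glm_mod
    from ._rng import child_rng

    tr = session.config.tr
    subj = 0
    blocks = session.blocks[session.blocks["subject"] == subj]
    stims = session.stimuli[session.stimuli["subject"] == subj]
    taps = session.taps[session.taps["subject"] == subj]
    scan_end = blocks["probe_onset"].max() + session.config.probe_display
    n_vol = int(scan_end / tr)

    markers = behavior.sliding_markers(
        taps["onset"], taps["hand"], np.sort(stims["onset"].to_numpy()))
    bv = markers["bv_log"].to_numpy()
    bv = (bv - np.nanmean(bv)) / np.nanstd(bv)
    bv_col = glm_mod.marker_regressor(markers["onset"], bv, tr, n_vol)
    metro = glm_mod.events_to_regressor(stims["onset"].to_numpy(), 0.0, tr, n_vol)
    nuis = simulate_nuisance(n_vol, child_rng(session.config.seed, "nuisance", subj))
    X = glm_mod.build_design({
        "metronome": metro, "bv": bv_col,
        **{c: nuis[c].to_numpy() for c in nuis.columns},
    })
    dct = glm_mod.dct_basis(n_vol, tr)
    for j in range(dct.shape[1]):
        X[f"dct{j + 1}"] = dct[:, j]

    shape = tuple(config.glm_shape)
    truth_region = np.zeros(shape, dtype=bool)
    lo = [max(1, s // 4) for s in shape]
    hi = [max(2, s // 2) for s in shape]
    truth_region[lo[0]:hi[0] + 2, lo[1]:hi[1] + 2, lo[2]:hi[2] + 2] = True
    beta_map = np.zeros(shape + (X.shape[1],))
    beta_map[truth_region, list(X.columns).index("bv")] = 1.0
    Y = simulate_bold(X.to_numpy(), beta_map, config.glm_noise_sd,
                      child_rng(session.config.seed, "bold", subj))
    contrast = np.zeros(X.shape[1])
    contrast[list(X.columns).index("bv")] = 1.0
    fitted = glm_mod.fit_glm(Y, X, contrast)
    th = glm_mod.threshold_map(fitted["z"], 2.3, min_cluster=4)

    half = shape[2] // 2
    parcels = {"anterior": np.zeros(shape, bool), "posterior": np.zeros(shape, bool)}
    parcels["anterior"][:, :, :half] = True
    parcels["posterior"][:, :, half:] = True
    overlap = glm_mod.atlas_overlap(th["mask"], parcels)
    summary = overlap.rename_axis("parcel").reset_index()
    summary.loc[len(summary)] = ["dice_vs_truth", glm_mod.dice(th["mask"], truth_region)]
    summary.to_csv(out / "glm_overlap.tsv", sep="\t", index=False)

    affine = np.diag([2.0, 2.0, 2.0, 1.0])
    arts = {
        "glm_zmap": str(save_nifti(fitted["z"], affine, out / "glm_zmap.nii.gz")),
        "glm_truth": str(save_nifti(truth_region.astype(np.float32), affine,
                                    out / "glm_truth_region.nii.gz")),
        "glm_overlap": str(out / "glm_overlap.tsv"),
    }
    return arts


def report(manifest: RunManifest) -> str:
    """Markdown summary of a completed run."""
    lines = ["# wandertap run report", "", f"Configuration hash: `{manifest.config_hash}`", ""]
    for name in ("probit_model1", "probit_model2"):
        path = manifest.artifacts.get(name)
        if not path or not Path(path).exists():
            continue
        df = pd.read_csv(path, sep="\t")
        lines.append(f"## {name.replace('_', ' ')}")
        lines.append("")
        lines.append("| parameter | mean | 95% HDI | ER | R-hat |")
        lines.append("|---|---|---|---|---|")
        for _, r in df.iterrows():
            er = "" if pd.isna(r["er"]) else ("inf" if np.isinf(r["er"]) else f"{r['er']:.2f}")
            rh = "" if pd.isna(r["rhat"]) else f"{r['rhat']:.3f}"
            lines.append(f"| {r['parameter']} | {r['mean']:.3f} "
                         f"| [{r['hdi_lo']:.3f}, {r['hdi_hi']:.3f}] | {er} | {rh} |")
        lines.append("")
    overlap_path = manifest.artifacts.get("glm_overlap")
    if overlap_path and Path(overlap_path).exists():
        df = pd.read_csv(overlap_path, sep="\t")
        lines.append("## glm overlap")
        lines.append("")
        lines.append("| parcel | percent |")
        lines.append("|---|---|")
        for _, r in df.iterrows():
            lines.append(f"| {r['parcel']} | {r['percent']:.1f} |")
        lines.append("")
    if manifest.warnings:
        lines.append("## Warnings")
        lines.extend(f"- {w}" for w in manifest.warnings)
        lines.append("")
    lines.append("## Artifacts")
    lines.extend(f"- {name}: `{path}`" for name, path in sorted(manifest.artifacts.items()))
    lines.append("")
    return "\n".join(lines)
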