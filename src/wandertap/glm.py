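"""Design matrices, mass-univariate GLMs, thresholding and atlas overlap.

Task events (taps, metronome stimuli, probe onsets) are convolved with a
canonical double-gamma hemodynamic response function; block and pre-probe
intervals enter as HRF-convolved boxcars; the sliding behavioral markers (BV,
AE) and tonic pupil size are already smooth, slow signals and are resampled to
the volume grid by nearest-neighbor hold without further convolution, while
phasic pupil amplitudes are convolved like events. Nuisance columns (CSF, WM,
FD, motion) are passed through, and a discrete-cosine basis models scanner
drift. Voxelwise ordinary least squares yields contrast t statistics that are
mapped to z scores; suprathreshold voxels (z > 2.3 by default) are grouped
into 26-connected clusters with an optional minimum size (cluster-level
random-field p-values are deliberately not computed). Thresholded maps are
summarized as percentage overlap with binarized atlas parcellations, white
matter excluded, and compared between maps with the Dice coefficient.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.stats import gamma, norm, t as t_dist

__all__ = [
    "double_gamma_hrf",
    "events_to_regressor",
    "preprobe_boxcars",
    "marker_regressor",
    "dct_basis",
    "build_design",
    "fit_glm",
    "threshold_map",
    "atlas_overlap",
    "dice",
    "resample_labels_nearest",
]

_DT = 0.05  # high-resolution grid step (s) for boxcar construction


def double_gamma_hrf(t, *, peak: float = 6.0, undershoot: float = 16.0,
                     ratio: float = 1.0 / 6.0, width: float = 1.0) -> np.ndarray:
    """Canonical double-gamma HRF, unit peak.

    Difference of two gamma densities with modes at ``peak`` and
    ``undershoot`` seconds and undershoot amplitude ``ratio``; 0 for t < 0.
    """
    if peak <= 0 or undershoot <= peak or ratio < 0:
        raise ValueError("require 0 < peak < undershoot and ratio >= 0")
    t = np.asarray(t, dtype=float)
    h = (gamma.pdf(t, a=1 + peak / width, scale=width)
         - ratio * gamma.pdf(t, a=1 + undershoot / width, scale=width))
    h = np.where(t < 0, 0.0, h)
    m = np.max(np.abs(h))
    return h / m if m > 0 else h


def _volume_times(n_volumes: int, tr: float) -> np.ndarray:
    return np.arange(n_volumes) * tr


def events_to_regressor(
    onsets,
    durations,
    tr: float,
    n_volumes: int,
    *,
    amplitudes=None,
    hrf_kwargs: dict | None = None,
    dt: float = _DT,
) -> np.ndarray:
    """HRF-convolved event column sampled at the volume times.

    Events are laid out as boxcars (impulses of one ``dt`` bin when the
    duration is 0) on a ``dt`` grid, convolved, then sampled at ``k * tr``.
    Onsets beyond the scan are dropped with a warning.
    """
    onsets = np.atleast_1d(np.asarray(onsets, dtype=float))
    durations = np.broadcast_to(np.asarray(durations, dtype=float), onsets.shape)
    amplitudes = (np.ones_like(onsets) if amplitudes is None
                  else np.broadcast_to(np.asarray(amplitudes, dtype=float), onsets.shape))
    scan_end = n_volumes * tr
    keep = onsets < scan_end
    if not keep.all():
        warnings.warn(f"dropping {np.sum(~keep)} event(s) beyond the scan end")
    n_hi = int(np.ceil(scan_end / dt)) + 1
    u = np.zeros(n_hi)
    for on, du, am in zip(onsets[keep], durations[keep], amplitudes[keep]):
        i0 = int(np.round(on / dt))
        i1 = max(i0 + 1, int(np.round((on + du) / dt)))
        u[i0:min(i1, n_hi)] += am
    h = double_gamma_hrf(np.arange(int(32.0 / dt)) * dt, **(hrf_kwargs or {}))
    conv = np.convolve(u, h)[:n_hi] * dt
    vt = _volume_times(n_volumes, tr)
    return np.interp(vt, np.arange(n_hi) * dt, conv)


def preprobe_boxcars(
    probe_onsets,
    off_task,
    tr: float,
    n_volumes: int,
    *,
    interval: float = 10.0,
    block_starts=None,
) -> tuple[np.ndarray, np.ndarray]:
    """Two HRF-convolved boxcar columns for the ``interval`` seconds before
    off-task vs on-task probes.

    A boxcar is truncated at its block start when the probe falls earlier
    than ``interval`` into the block. Returns ``(off_column, on_column)``.
    """
    probes = np.asarray(probe_onsets, dtype=float)
    off = np.asarray(off_task, dtype=bool)
    starts = None if block_starts is None else np.asarray(block_starts, dtype=float)
    onsets, durations = [], []
    for i, p in enumerate(probes):
        lo = p - interval
        if starts is not None:
            lo = max(lo, float(starts[i]))
        onsets.append(lo)
        durations.append(p - lo)
    onsets = np.asarray(onsets)
    durations = np.asarray(durations)

    def col(sel):
        if not sel.any():
            return np.zeros(n_volumes)
        return events_to_regressor(onsets[sel], durations[sel], tr, n_volumes)

    return col(off), col(~off)


def marker_regressor(
    anchor_times,
    values,
    tr: float,
    n_volumes: int,
    *,
    mode: str = "nearest",
) -> np.ndarray:
    """Resample a single-trial marker series to the volume grid.

    ``mode='nearest'`` holds each value to the nearest anchor (no HRF; the
    sliding-window series is already smooth and time-lagged); ``'linear'``
    interpolates between anchors; ``'convolve'`` treats the series as
    amplitude-modulated impulses at the anchors and convolves with the HRF
    (used for phasic pupil amplitudes). Volumes before the first anchor take
    the first value (zero for 'convolve').
    """
    at = np.asarray(anchor_times, dtype=float)
    v = np.asarray(values, dtype=float)
    ok = np.isfinite(v)
    at, v = at[ok], v[ok]
    if at.size == 0:
        raise ValueError("empty marker series")
    vt = _volume_times(n_volumes, tr)
    if mode == "convolve":
        return events_to_regressor(at, 0.0, tr, n_volumes, amplitudes=v)
    if mode == "linear":
        return np.interp(vt, at, v)
    if mode == "nearest":
        idx = np.clip(np.searchsorted(at, vt, side="left"), 0, at.size - 1)
        left = np.clip(idx - 1, 0, at.size - 1)
        use_left = (np.abs(vt - at[left]) <= np.abs(at[idx] - vt)) & (idx > 0)
        return v[np.where(use_left, left, idx)]
    raise ValueError(f"unknown mode {mode!r}")


def dct_basis(n_volumes: int, tr: float, cutoff_s: float = 128.0) -> np.ndarray:
    """Orthonormal DCT-II drift columns with periods longer than ``cutoff_s``.

    Component k has frequency k / (2 N TR); the constant term is excluded
    (model an intercept separately).
    """
    n = np.arange(n_volumes)
    k_max = int(np.floor(2.0 * n_volumes * tr / cutoff_s))
    cols = [np.cos(np.pi * k * (2 * n + 1) / (2.0 * n_volumes)) for k in range(1, k_max + 1)]
    if not cols:
        return np.zeros((n_volumes, 0))
    X = np.column_stack(cols)
    return X / np.linalg.norm(X, axis=0)


def build_design(columns: dict[str, np.ndarray], *, add_intercept: bool = True) -> pd.DataFrame:
    """Assemble named columns into a design-matrix DataFrame."""
    X = pd.DataFrame(columns)
    if add_intercept:
        X.insert(0, "intercept", 1.0)
    return X


def fit_glm(Y: np.ndarray, X, contrast) -> dict:
    """Voxelwise OLS and a contrast z map.

    ``Y`` is (nx, ny, nz, T); ``X`` a (T, p) array or DataFrame; ``contrast``
    a length-p vector. Contrast t values are converted to z scores through
    the normal quantile map. Rank deficiency is reported with the offending
    columns.
    """
    Xdf = X if isinstance(X, pd.DataFrame) else pd.DataFrame(np.asarray(X))
    Xm = Xdf.to_numpy(dtype=float)
    T, p = Xm.shape
    if Y.shape[-1] != T:
        raise ValueError(f"design rows ({T}) must equal volumes ({Y.shape[-1]})")
    rank = np.linalg.matrix_rank(Xm)
    if rank < p:
        _, R = np.linalg.qr(Xm)
        bad = [str(Xdf.columns[j]) for j in range(p) if abs(R[j, j]) < 1e-10 * abs(R).max()]
        warnings.warn(f"design matrix rank deficient (rank {rank} < {p}); suspect columns: {bad}")
    shape = Y.shape[:3]
    Yf = Y.reshape(-1, T).T                                    # (T, V)
    pinv = np.linalg.pinv(Xm)
    beta = pinv @ Yf                                           # (p, V)
    resid = Yf - Xm @ beta
    dof = max(T - rank, 1)
    mse = np.sum(resid ** 2, axis=0) / dof
    c = np.asarray(contrast, dtype=float)
    var_c = float(c @ (pinv @ pinv.T) @ c)
    with np.errstate(divide="ignore", invalid="ignore"):
        tval = (c @ beta) / np.sqrt(mse * var_c)
    tval = np.nan_to_num(tval)
    # t -> z through matched tail probabilities, stable in both tails
    z = np.where(tval >= 0,
                 -norm.ppf(np.clip(t_dist.sf(tval, dof), 1e-300, 1.0)),
                 norm.ppf(np.clip(t_dist.cdf(tval, dof), 1e-300, 1.0)))
    return {
        "beta": beta.T.reshape(*shape, p),
        "z": z.reshape(shape),
        "t": tval.reshape(shape),
        "dof": dof,
        "columns": [str(col) for col in Xdf.columns],
    }


def threshold_map(zmap: np.ndarray, z_primary: float = 2.3, min_cluster: int = 0) -> dict:
    """Suprathreshold 26-connected clusters.

    Returns the binary mask, the cluster label volume and the surviving
    cluster sizes. Cluster-level random-field inference is not performed;
    ``min_cluster`` substitutes for it (recorded in the metadata).
    """
    z = np.asarray(zmap, dtype=float)
    if not np.isfinite(z).all():
        raise ValueError("z map contains non-finite values")
    supra = z > z_primary
    labels, n = ndimage.label(supra, structure=np.ones((3, 3, 3), dtype=int))
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    keep = np.flatnonzero(sizes >= max(min_cluster, 1)) + 1
    mask = np.isin(labels, keep)
    out_labels = np.where(mask, labels, 0)
    return {
        "mask": mask,
        "labels": out_labels,
        "cluster_sizes": {int(k): int(sizes[k - 1]) for k in keep},
        "meta": {"z_primary": z_primary, "min_cluster": int(min_cluster),
                 "cluster_p": "not computed (connected-component size rule)"},
    }


def atlas_overlap(mask: np.ndarray, parcellations: dict[str, np.ndarray],
                  wm_mask: np.ndarray | None = None) -> pd.Series:
    """Percentage of suprathreshold voxels in each parcel, WM excluded.

    All volumes must share one grid. Parcels must be disjoint; if any
    non-WM suprathreshold voxel belongs to no parcel the 100% contract is
    violated and a ``ValueError`` carrying the counts is raised.
    """
    m = np.asarray(mask, dtype=bool)
    if wm_mask is not None:
        m = m & ~np.asarray(wm_mask, dtype=bool)
    total = int(m.sum())
    if total == 0:
        return pd.Series({name: 0.0 for name in parcellations}, name="percent")
    cover = np.zeros_like(m, dtype=int)
    counts = {}
    for name, parcel in parcellations.items():
        pm = np.asarray(parcel, dtype=bool)
        if pm.shape != m.shape:
            raise ValueError(f"parcellation {name!r} not on the analysis grid")
        cover += pm.astype(int)
        counts[name] = int((m & pm).sum())
    if np.any(cover[m] > 1):
        raise ValueError("parcellations overlap on suprathreshold voxels")
    unassigned = int((m & (cover == 0)).sum())
    if unassigned:
        raise ValueError(
            f"{unassigned} of {total} suprathreshold voxels match no parcel; "
            f"per-parcel counts: {counts}"
        )
    return pd.Series({k: 100.0 * v / total for k, v in counts.items()}, name="percent")


def dice(map_a: np.ndarray, map_b: np.ndarray) -> float:
    """Dice coefficient 2|A n B| / (|A| + |B|); 0 (with a warning) if both empty."""
    a = np.asarray(map_a, dtype=bool)
    b = np.asarray(map_b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("maps must share a grid")
    denom = int(a.sum()) + int(b.sum())
    if denom == 0:
        warnings.warn("both maps empty; Dice defined as 0")
        return 0.0
    return 2.0 * int((a & b).sum()) / denom


def resample_labels_nearest(src: np.ndarray, src_affine: np.ndarray,
                            dst_shape: tuple[int, int, int], dst_affine: np.ndarray) -> np.ndarray:
    """Label-preserving nearest-neighbor resampling between voxel grids."""
    from scipy.ndimage import map_coordinates

    dst_idx = np.indices(dst_shape).reshape(3, -1)
    world = dst_affine @ np.vstack([dst_idx, np.ones(dst_idx.shape[1])])
    src_idx = np.linalg.inv(src_affine) @ world
    out = map_coordinates(np.asarray(src), src_idx[:3], order=0, mode="constant", cval=0)
    return out.reshape(dst_shape)
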