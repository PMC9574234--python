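"""Behavioral mind-wandering markers for the finger-tapping task.

Two markers are computed on 25-tap windows: behavioral variability (BV), the
standard deviation of the inter-tap intervals, log-transformed; and approximate
entropy (AE) of the binary left/right hand sequence with subsequence length
m = 2 and exact symbol matching, transformed as ``-ln(ln 2 - AE)``. Both are
grand-z-scored across subjects before entering the regression models.

AE here uses the conditional-probability form: both window sums run over the
same index range ``i = 1..N-m``, so the statistic is the average of
``ln(B_i / A_i)`` where ``B_i`` counts matches of the length-m window at ``i``
and ``A_i`` counts matches of its length-(m+1) extension. For a binary
alphabet this is exactly 0 for deterministic sequences (e.g. strict
alternation) and bounded above by ln 2, the entropy rate of a fair coin.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "intertap_intervals",
    "behavioral_variability",
    "approximate_entropy",
    "transform_ae",
    "zscore_grand",
    "sliding_markers",
    "probe_features",
    "standardize_features",
    "split_point_dichotomize",
    "fixed_dichotomize",
    "DichotomizationResult",
    "LN2",
    "BV_FLOOR",
    "AE_EPS",
]

LN2 = float(np.log(2.0))

#: floor on the raw ITI standard deviation (seconds) before the log transform;
#: real tapping never reaches exactly zero variance but noiseless synthetic
#: data can, and ln(0) is undefined.
BV_FLOOR = 1e-3

#: guard before the -ln(ln2 - AE) transform at the AE = ln 2 singularity.
AE_EPS = 1e-6


def _as_times(taps) -> np.ndarray:
    t = np.asarray(taps, dtype=float)
    if t.ndim != 1:
        raise ValueError("tap timestamps must be one-dimensional")
    return t


def intertap_intervals(taps) -> np.ndarray:
    """Consecutive differences of tap timestamps (seconds).

    Raises ``ValueError`` for fewer than two taps or non-increasing times.
    """
    t = _as_times(taps)
    if t.size < 2:
        raise ValueError("need at least 2 taps to form intervals")
    iti = np.diff(t)
    if np.any(iti <= 0):
        raise ValueError("tap timestamps must be strictly increasing")
    return iti


def behavioral_variability(taps, *, floor: float = BV_FLOOR) -> tuple[float, float]:
    """Return ``(bv_raw, bv_log)`` for one tap window.

    ``bv_raw`` is the sample SD (ddof=1) of the inter-tap intervals among the
    taps in the window; ``bv_log = ln(max(bv_raw, floor))``.
    """
    iti = intertap_intervals(taps)
    bv_raw = float(np.std(iti, ddof=1)) if iti.size > 1 else 0.0
    return bv_raw, float(np.log(max(bv_raw, floor)))


def _encode_hands(seq) -> np.ndarray:
    a = np.asarray(seq)
    if a.dtype.kind in "UOS":
        mapped = np.where(np.char.upper(a.astype(str)) == "L", 0, np.where(np.char.upper(a.astype(str)) == "R", 1, -1))
    else:
        mapped = a.astype(int)
    mapped = np.asarray(mapped, dtype=int)
    if not np.isin(mapped, (0, 1)).all():
        raise ValueError("hand sequence must be binary (L/R or 0/1)")
    return mapped


def approximate_entropy(seq, m: int = 2) -> float:
    """Approximate entropy (nats) of a binary sequence, exact matching.

    ``AE = Phi^m - Phi^(m+1)`` with both sums over windows starting at
    ``i = 1..N-m`` and self-matches included. 0 means perfectly regular,
    ln 2 is the binary upper bound.
    """
    x = _encode_hands(seq)
    n = x.size
    if m < 1:
        raise ValueError("m must be >= 1")
    if n < m + 1:
        raise ValueError(f"sequence of length {n} too short for m={m}")
    n_win = n - m
    # encode windows as integers (base 2) for O(N) counting
    pow2 = 2 ** np.arange(m + 1)

    def codes(k: int) -> np.ndarray:
        w = np.lib.stride_tricks.sliding_window_view(x, k)[:n_win]
        return w @ pow2[:k]

    cm = codes(m)
    cm1 = codes(m + 1)
    counts_m = np.bincount(cm, minlength=2 ** m)
    counts_m1 = np.bincount(cm1, minlength=2 ** (m + 1))
    b = counts_m[cm].astype(float)   # matches of the m-window at i
    a = counts_m1[cm1].astype(float)  # matches of its (m+1)-extension
    return float(np.mean(np.log(b / a)))


def transform_ae(ae: float) -> float:
    """Variance-stabilizing transform ``-ln(ln 2 - AE)``.

    AE is capped at ``ln 2 - AE_EPS`` so the transform stays finite; values
    outside [0, ln 2] (beyond float tolerance) are rejected.
    """
    if not (-1e-12 <= ae <= LN2 + 1e-12):
        raise ValueError(f"AE={ae} outside [0, ln 2]")
    return float(-np.log(LN2 - min(ae, LN2 - AE_EPS)))


def zscore_grand(values) -> np.ndarray:
    """Z-score over the pooled values (grand mean / SD, ddof=0).

    NaNs are ignored in the moments and propagated in the output.
    """
    v = np.asarray(values, dtype=float)
    mu = np.nanmean(v)
    sd = np.nanstd(v)
    if not np.isfinite(sd) or sd == 0:
        raise ValueError("zero variance: cannot z-score")
    return (v - mu) / sd


def sliding_markers(
    tap_times,
    tap_hands,
    stimulus_onsets,
    *,
    condition: str = "random",
    window: int = 25,
) -> pd.DataFrame:
    """Single-trial BV/AE series for one block.

    Starting at the ``window``-th stimulus onset, each anchor gets BV (and AE,
    random blocks only) computed on the last ``window`` recorded taps at or
    before that onset — the raw tap stream, double/missing taps included.
    Anchors with fewer than ``window`` preceding taps get NaN.
    """
    t = np.asarray(tap_times, dtype=float)
    order = np.argsort(t, kind="stable")
    t = t[order]
    hands = _encode_hands(np.asarray(tap_hands)[order])
    onsets = np.asarray(stimulus_onsets, dtype=float)
    anchors = onsets[window - 1:]
    rows = []
    for anchor in anchors:
        k = int(np.searchsorted(t, anchor, side="right"))
        rec: dict = {"onset": anchor, "bv_raw": np.nan, "bv_log": np.nan,
                     "ae_raw": np.nan, "ae_trans": np.nan}
        if k >= window:
            w_t = t[k - window:k]
            w_h = hands[k - window:k]
            rec["bv_raw"], rec["bv_log"] = behavioral_variability(w_t)
            if condition == "random":
                ae = approximate_entropy(w_h, m=2)
                rec["ae_raw"] = ae
                rec["ae_trans"] = transform_ae(ae)
        rows.append(rec)
    return pd.DataFrame(rows, columns=["onset", "bv_raw", "bv_log", "ae_raw", "ae_trans"])


def probe_features(taps: pd.DataFrame, blocks: pd.DataFrame, *, window: int = 25) -> pd.DataFrame:
    """One feature row per thought probe.

    ``taps`` needs columns subject, block, onset, hand; ``blocks`` needs
    subject, block, condition, probe_onset, response. BV/AE are computed on
    the ``window`` taps preceding each probe; the probe index (block number
    within the session, 1-based) is the time covariate. Probes with fewer
    than ``window`` preceding taps are flagged excluded.
    """
    rows = []
    for (subject,), sub_blocks in blocks.groupby(["subject"]):
        sub_taps = taps[taps["subject"] == subject]
        for _, blk in sub_blocks.sort_values("block").iterrows():
            bt = sub_taps[sub_taps["block"] == blk["block"]]
            t = bt["onset"].to_numpy(dtype=float)
            h = bt["hand"].to_numpy()
            k = int(np.searchsorted(np.sort(t), blk["probe_onset"], side="right"))
            rec = {
                "subject": subject,
                "probe_index": int(blk["block"]) + 1,
                "condition": blk["condition"],
                "response": int(blk["response"]),
                "bv_raw": np.nan, "bv_log": np.nan, "ae_raw": np.nan, "ae_trans": np.nan,
                "excluded": False, "reason": "",
            }
            if k < window:
                rec["excluded"] = True
                rec["reason"] = f"fewer than {window} taps precede the probe"
            else:
                order = np.argsort(t, kind="stable")
                t_s, h_s = t[order], np.asarray(h)[order]
                w_t = t_s[k - window:k]
                w_h = h_s[k - window:k]
                rec["bv_raw"], rec["bv_log"] = behavioral_variability(w_t)
                if blk["condition"] == "random":
                    ae = approximate_entropy(w_h, m=2)
                    rec["ae_raw"] = ae
                    rec["ae_trans"] = transform_ae(ae)
            rows.append(rec)
    return pd.DataFrame(rows)


def standardize_features(features: pd.DataFrame) -> pd.DataFrame:
    """Grand-z-score the transformed markers over the analysis set.

    BV is standardized over all included probes (both conditions); AE over
    included random-condition probes only, matching its definition.
    Adds columns ``bv`` and ``ae``.
    """
    out = features.copy()
    inc = ~out["excluded"].astype(bool)
    out["bv"] = np.nan
    out["ae"] = np.nan
    out.loc[inc, "bv"] = zscore_grand(out.loc[inc, "bv_log"])
    rnd = inc & (out["condition"] == "random")
    out.loc[rnd, "ae"] = zscore_grand(out.loc[rnd, "ae_trans"])
    return out


@dataclass
class DichotomizationResult:
    """Subject-specific median-split of ordinal probe responses."""

    cutpoint: int                 # responses > cutpoint are off-task
    labels: np.ndarray            # boolean, True = off-task
    off_task_proportion: float


def split_point_dichotomize(responses) -> DichotomizationResult:
    """Choose the cutpoint in {1..5} whose off-task share is nearest 50%.

    Ties break toward the smaller cutpoint (labelling more probes off-task),
    so a subject answering only categories 1 and 2 gets category 2 labelled
    off-task.
    """
    r = np.asarray(responses, dtype=int)
    if r.size == 0:
        raise ValueError("no responses")
    best_cut, best_err = None, np.inf
    for cut in range(1, 6):
        prop = float(np.mean(r > cut))
        err = abs(prop - 0.5)
        if err < best_err - 1e-12:
            best_cut, best_err = cut, err
    labels = r > best_cut
    return DichotomizationResult(best_cut, labels, float(np.mean(labels)))


def fixed_dichotomize(responses) -> np.ndarray:
    """Fixed split: responses in the upper half of the scale (>= 4) are off-task."""
    return np.asarray(responses, dtype=int) >= 4
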