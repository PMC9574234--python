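import warnings

import numpy as np
import pytest

from wandertap import behavior, synth


@pytest.fixture(scope="session")
def small_session():
    """A reduced study (4 subjects, 6 random + 3 alternating blocks), no pupil."""
    cfg = synth.SimConfig(n_subjects=4, n_random_blocks=6, n_alternating_blocks=3, seed=42)
    return synth.simulate_session(cfg, include_pupil=False)


@pytest.fixture(scope="session")
def paper_scale_features():
    """Probe-feature table from a full-scale study (27 subjects, 18+9 blocks)."""
    cfg = synth.SimConfig(seed=9)
    sess = synth.simulate_session(cfg, include_pupil=False)
    feats = behavior.probe_features(sess.taps, sess.blocks)
    return behavior.standardize_features(feats)


@pytest.fixture(autouse=True)
def _quiet_rhat_warnings():
    """Reduced-draw test fits may trip the reliability warning by design."""
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="split-R-hat")
        yield


def brute_force_apen(seq, m=2):
    """Independent window-counting oracle for approximate entropy.

    Counts matches by direct tuple comparison over the aligned index range
    i = 1..N-m; kept deliberately naive (pure Python, no vectorization).
    """
    s = [int(v) for v in seq]
    n = len(s)
    n_win = n - m
    total = 0.0
    for i in range(n_win):
        b = sum(1 for j in range(n_win) if s[j:j + m] == s[i:i + m])
        a = sum(1 for j in range(n_win) if s[j:j + m + 1] == s[i:i + m + 1])
        total += np.log(b / a)
    return total / n_win
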