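"""Seed management.

All stochastic stages derive their generators from a single root seed through
:class:`numpy.random.SeedSequence`. Named children are obtained by hashing a
tuple of string keys into the spawn key, so adding a new consumer never
perturbs the streams of existing ones.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["child_seed_sequence", "child_rng"]


def _key_to_int(key: str | int) -> int:
    if isinstance(key, (int, np.integer)):
        return int(key)
    return zlib.crc32(str(key).encode("utf-8"))


def child_seed_sequence(seed: int, *keys: str | int) -> np.random.SeedSequence:
    """Return a named child SeedSequence of ``seed``.

    Keys identify the consumer (e.g. ``("subject", 3, "taps")``) and are mapped
    deterministically onto the spawn key.
    """
    return np.random.SeedSequence(seed, spawn_key=tuple(_key_to_int(k) for k in keys))


def child_rng(seed: int, *keys: str | int) -> np.random.Generator:
    """Generator seeded by the named child stream of ``seed``."""
    return np.random.default_rng(child_seed_sequence(seed, *keys))
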