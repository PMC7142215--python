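"""Shared numerical helpers."""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream", "check_finite_array"]


def substream(seed: int | None, key: str) -> np.random.Generator:
    """Return an RNG on an independently keyed substream of a master seed.

    Every stochastic estimator in the package draws from ``substream(seed, name)``
    with its own fixed ``name``, so results are reproducible regardless of the
    order in which estimators are called.
    """
    if seed is None:
        return np.random.default_rng()
    spawn_key = zlib.crc32(key.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence(int(seed), spawn_key=(spawn_key,)))


def check_finite_array(a, name: str) -> np.ndarray:
    a = np.asarray(a, dtype=float)
    if not np.all(np.isfinite(a)):
        raise ValueError(f"{name} contains non-finite values")
    return a
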