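"""Shared helpers: seeded substreams and block pooling."""
from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream", "block_reduce_mean", "block_reduce_sum"]


def substream(seed: int, name: str) -> np.random.Generator:
    """Named, reproducible child stream of a single top-level seed.

    All randomness in the package flows from one integer seed; each
    consumer (fold assignment, bootstrap, permutation, ...) asks for its
    own named stream so that enlarging one analysis never perturbs another.
    """
    tag = zlib.crc32(name.encode("utf8"))
    return np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, tag]))


def _edges(size: int, n: int) -> np.ndarray:
    return np.linspace(0, size, n + 1).astype(int)


def block_reduce_sum(arr: np.ndarray, grid: int) -> np.ndarray:
    """Sum ``arr`` over a grid × grid partition of its last two axes."""
    h, w = arr.shape[-2:]
    re = _edges(h, grid)[:-1]
    ce = _edges(w, grid)[:-1]
    out = np.add.reduceat(arr, re, axis=-2)
    out = np.add.reduceat(out, ce, axis=-1)
    return out


def block_reduce_mean(arr: np.ndarray, grid: int) -> np.ndarray:
    """Mean of ``arr`` over a grid × grid partition of its last two axes."""
    h, w = arr.shape[-2:]
    sums = block_reduce_sum(arr, grid)
    counts = block_reduce_sum(np.ones((h, w)), grid)
    return sums / counts
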