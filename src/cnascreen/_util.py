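"""Shared helpers: deterministic per-entity RNG streams and chromosome ordering."""

from __future__ import annotations

import zlib

import numpy as np
import pandas as pd


def rng_for(seed: int, *keys: str | int) -> np.random.Generator:
    """Return a Generator whose stream depends on ``seed`` and string/int keys.

    String keys are hashed with CRC32, so the stream for e.g. a given sample id
    does not depend on the order samples are processed in.
    """
    entropy = [int(seed) & 0x7FFFFFFF]
    for k in keys:
        entropy.append(zlib.crc32(str(k).encode()) if isinstance(k, str) else int(k) & 0xFFFFFFFF)
    return np.random.default_rng(np.random.SeedSequence(entropy))


def chrom_categorical(chroms: pd.Series) -> pd.Categorical:
    """Categorical preserving order of first appearance (genome file order)."""
    cats = pd.unique(chroms)
    return pd.Categorical(chroms, categories=cats, ordered=True)


def as_1d_float(x) -> np.ndarray:
    a = np.asarray(x, dtype=float).ravel()
    return a
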