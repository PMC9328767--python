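"""Small numerical helpers shared across modules."""

from __future__ import annotations

import logging

import numpy as np

logger = logging.getLogger("eventisc")


def zscore(x: np.ndarray, axis: int = -1) -> np.ndarray:
    """Z-score along `axis` using population (ddof=0) statistics.

    Constant slices come back as all zeros rather than NaN so that
    downstream correlations can detect them explicitly.
    """
    x = np.asarray(x, dtype=float)
    mu = x.mean(axis=axis, keepdims=True)
    sd = x.std(axis=axis, keepdims=True)
    out = np.zeros_like(x)
    np.divide(x - mu, sd, out=out, where=sd > 0)
    return out


def pearson_lastaxis(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pearson r between `a` and `b` along the last axis (broadcasting).

    Returns NaN where either input is constant along the last axis.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a0 = a - a.mean(axis=-1, keepdims=True)
    b0 = b - b.mean(axis=-1, keepdims=True)
    num = (a0 * b0).sum(axis=-1)
    den = np.sqrt((a0**2).sum(axis=-1) * (b0**2).sum(axis=-1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = num / den
    return np.where(den > 0, r, np.nan)


def child_seed(seed: int, *stream: int) -> int:
    """Derive a deterministic 31-bit child seed from a parent seed and stream ids."""
    ss = np.random.SeedSequence([int(seed), *[int(s) for s in stream]])
    return int(ss.generate_state(1)[0] % (2**31 - 1))


def as_pvt(data: np.ndarray) -> np.ndarray:
    """Coerce a subject array to canonical (parcels, features, time) layout.

    2-D input (parcels, time) is treated as a single feature per parcel.
    """
    data = np.asarray(data, dtype=float)
    if data.ndim == 2:
        return data[:, None, :]
    if data.ndim == 3:
        return data
    raise ValueError(f"subject data must be 2-D or 3-D, got shape {data.shape}")
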