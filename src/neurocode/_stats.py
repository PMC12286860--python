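"""Shared correlation helpers. Undefined correlations (zero variance) are NaN."""

from __future__ import annotations

import numpy as np


def pearson_rows(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pearson r between corresponding rows of two (n, d) arrays."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    ac = a - a.mean(axis=1, keepdims=True)
    bc = b - b.mean(axis=1, keepdims=True)
    num = (ac * bc).sum(axis=1)
    den = np.sqrt((ac**2).sum(axis=1) * (bc**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = num / den
    r[den == 0] = np.nan
    return r


def pearson_cols(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pearson r between corresponding columns of two (n, d) arrays."""
    return pearson_rows(a.T, b.T)


def cross_correlation(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """All-pairs correlation matrix (d_x, d_y) between columns of x and y."""
    xz = x - x.mean(axis=0)
    yz = y - y.mean(axis=0)
    sx = xz.std(axis=0)
    sy = yz.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (xz.T @ yz) / (len(x) * np.outer(sx, sy))
    r[sx == 0, :] = np.nan
    r[:, sy == 0] = np.nan
    return r
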