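"""Rank-correlation helpers shared across the pipeline.

Everything downstream of normalization is rank-based, so Spearman
correlation matrices are computed in one place.  Ties get average ranks
(:func:`scipy.stats.rankdata` default); rows/columns with zero rank
variance have undefined correlation and are reported as NaN rather than
raising inside numpy.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import rankdata

__all__ = ["spearman_rows", "spearman_pairs", "rank_transform"]


def rank_transform(x: np.ndarray, axis: int = 1) -> np.ndarray:
    """Average ranks along ``axis`` (float64 output)."""
    return rankdata(np.asarray(x, dtype=float), axis=axis)


def spearman_rows(x: np.ndarray) -> np.ndarray:
    """Spearman correlation matrix among the rows of ``x``.

    Parameters
    ----------
    x
        2-D array, observations in columns.

    Returns
    -------
    Symmetric ``(n_rows, n_rows)`` matrix; rows that are constant across
    columns yield NaN in their row/column (undefined rank correlation).
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 2:
        raise ValueError("expected a 2-D array")
    r = rank_transform(x, axis=1)
    r = r - r.mean(axis=1, keepdims=True)
    norm = np.sqrt((r * r).sum(axis=1))
    ok = norm > 0
    with np.errstate(invalid="ignore", divide="ignore"):
        rn = np.where(ok[:, None], r / np.where(norm[:, None] == 0, 1.0, norm[:, None]), np.nan)
        c = rn @ rn.T
    c[~ok, :] = np.nan
    c[:, ~ok] = np.nan
    np.clip(c, -1.0, 1.0, out=c)
    if ok.any():
        idx = np.where(ok)[0]
        c[idx, idx] = 1.0
    return c


def spearman_pairs(a: np.ndarray, b: np.ndarray) -> float:
    """Spearman correlation of two 1-D vectors; NaN if either is constant."""
    a = rank_transform(np.asarray(a, dtype=float)[None, :], axis=1)[0]
    b = rank_transform(np.asarray(b, dtype=float)[None, :], axis=1)[0]
    a = a - a.mean()
    b = b - b.mean()
    na, nb = np.sqrt((a * a).sum()), np.sqrt((b * b).sum())
    if na == 0 or nb == 0:
        return float("nan")
    return float(np.clip((a @ b) / (na * nb), -1.0, 1.0))
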