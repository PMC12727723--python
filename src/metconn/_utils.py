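"""Shared numerical helpers."""

from __future__ import annotations

import numpy as np
from scipy import stats

#: Clip correlations this far from +/-1 before atanh so the transform is finite.
FISHER_CLIP = 1e-12


def upper_tri(mat: np.ndarray, mask: np.ndarray | None = None) -> np.ndarray:
    """Strict upper-triangle entries of a square matrix as a 1-D vector.

    ``mask`` (boolean, same shape) optionally restricts which entries are kept
    (used by null-model variants whose ineligible pairs must not enter
    comparisons).
    """
    iu = np.triu_indices(mat.shape[0], k=1)
    vals = np.asarray(mat)[iu]
    if mask is not None:
        vals = vals[np.asarray(mask)[iu]]
    return vals


def fisher_z(r) -> np.ndarray:
    r = np.clip(np.asarray(r, dtype=float), -1 + FISHER_CLIP, 1 - FISHER_CLIP)
    return np.arctanh(r)


def fisher_aggregate(rs) -> float:
    """Mean of Fisher z-transformed correlations, mapped back through tanh."""
    return float(np.tanh(np.mean(fisher_z(rs))))


def spawn_seeds(seed: int, n: int) -> list[int]:
    """Derive ``n`` independent child seeds (< 2**31) from one master seed."""
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]


def morans_i(values: np.ndarray, weights: np.ndarray) -> float:
    """Moran's I spatial autocorrelation of a parcel map.

    ``weights`` is a symmetric nonnegative spatial weight matrix (typically
    the binary adjacency); the diagonal is ignored.
    """
    x = np.asarray(values, dtype=float)
    w = np.asarray(weights, dtype=float).copy()
    np.fill_diagonal(w, 0.0)
    z = x - x.mean()
    denom = (z**2).sum()
    s0 = w.sum()
    if denom == 0 or s0 == 0:
        return np.nan
    return float(len(x) / s0 * (z @ w @ z) / denom)


def rankdata_rows(X: np.ndarray) -> np.ndarray:
    """Row-wise midranks (Spearman building block)."""
    return stats.rankdata(X, axis=1)


def spearman_matrix(X: np.ndarray) -> np.ndarray:
    """Spearman correlation between the *rows* of ``X`` as a full matrix."""
    R = rankdata_rows(X)
    C = np.corrcoef(R)
    return C
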