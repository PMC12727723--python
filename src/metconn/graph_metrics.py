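"""Network statistics for topology and cross-modal comparison.

Density-based binarization of weighted similarity matrices, the rich-club
coefficient (strict degree-> k convention), degree centrality, higher-order
connectivity (matrix powers, with a cosine-normalized variant),
communicability model fitting M = exp(g S), absolute nodal correlations,
label-agreement scores (Hungarian overlap, normalized mutual information),
the streamline-count structural weight formula with its consensus filter,
and the Gini coefficient of parcel sizes.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy import stats
from scipy.linalg import expm
from scipy.optimize import linear_sum_assignment, minimize_scalar
from sklearn.metrics import normalized_mutual_info_score

logger = logging.getLogger(__name__)


@dataclass
class BinaryGraph:
    """Undirected simple graph obtained by density thresholding."""

    node_ids: np.ndarray
    edges: frozenset            # (low, high) id pairs
    edge_density: float

    def graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(int(i) for i in self.node_ids)
        g.add_edges_from(self.edges)
        return g

    def adjacency_matrix(self) -> np.ndarray:
        n = len(self.node_ids)
        idx = {int(p): i for i, p in enumerate(self.node_ids)}
        A = np.zeros((n, n))
        for i, j in self.edges:
            A[idx[i], idx[j]] = A[idx[j], idx[i]] = 1.0
        return A


@dataclass
class StructuralConnectivity:
    """Length- and volume-normalized streamline connectivity."""

    node_ids: np.ndarray
    S: np.ndarray
    ns: np.ndarray
    lengths: np.ndarray
    volumes: np.ndarray


def binarize(W: np.ndarray, rho: float,
             node_ids: np.ndarray | None = None) -> BinaryGraph:
    """Keep the top ``rho`` fraction of edges by absolute weight.

    Negative weights are rectified before thresholding; ties at the cutoff
    are broken toward the smaller (i, j) pair so the edge count is exact.
    """
    W = np.asarray(W, dtype=float)
    n = W.shape[0]
    if not (0 < rho <= 1):
        raise ValueError("rho must be in (0, 1]")
    ids = np.asarray(node_ids) if node_ids is not None else np.arange(n)
    iu = np.triu_indices(n, k=1)
    weights = np.abs(W[iu])
    total = len(weights)
    m_keep = int(round(rho * total))
    if m_keep < 1:
        raise ValueError(f"rho={rho} keeps fewer than one edge")
    order = sorted(range(total),
                   key=lambda k: (-weights[k], iu[0][k], iu[1][k]))
    kept = order[:m_keep]
    edges = frozenset((int(min(ids[iu[0][k]], ids[iu[1][k]])),
                       int(max(ids[iu[0][k]], ids[iu[1][k]])))
                      for k in kept)
    return BinaryGraph(node_ids=ids, edges=edges,
                       edge_density=m_keep / total)


def rich_club(graph: BinaryGraph | nx.Graph, k: int) -> float:
    """Rich-club coefficient over nodes with degree strictly greater than k.

    ``phi(k) = 2 E_{>k} / (N_{>k} (N_{>k} - 1))``; returns NaN when fewer
    than two nodes survive the degree cut.
    """
    g = graph.graph() if isinstance(graph, BinaryGraph) else graph
    rich = {u for u, d in g.degree() if d > k}
    if len(rich) < 2:
        return math.nan
    e = sum(1 for u, v in g.edges() if u in rich and v in rich)
    return 2.0 * e / (len(rich) * (len(rich) - 1))


def degree_centrality(graph: BinaryGraph | nx.Graph) -> dict:
    """Degree of every node (sums to twice the edge count)."""
    g = graph.graph() if isinstance(graph, BinaryGraph) else graph
    return dict(g.degree())


def higher_order(A: np.ndarray, m: int, cosine: bool = False) -> np.ndarray:
    """m-th order connectivity: the matrix power ``A^m``.

    Entry (i, j) sums the products of weights over all length-m index
    chains from i to j. With ``cosine=True`` the power is normalized by its
    diagonal, ``C_ij = (A^m)_ij / sqrt((A^m)_ii (A^m)_jj)``, the cosine
    similarity of half-walk profiles.
    """
    if m < 1:
        raise ValueError("order m must be >= 1")
    A = np.asarray(A, dtype=float)
    P = np.linalg.matrix_power(A, m)
    if not cosine:
        return P
    diag = np.sqrt(np.clip(np.diag(P), 0, None))
    with np.errstate(divide="ignore", invalid="ignore"):
        C = P / np.outer(diag, diag)
    C[~np.isfinite(C)] = 0.0
    return C


@dataclass
class CommunicabilityFit:
    g: float
    predicted: np.ndarray
    score: float               # mean nodal Spearman, predicted vs observed
    mse: float
    normalized: bool           # S divided by its spectral radius before fit


def communicability_fit(S: np.ndarray, M_obs: np.ndarray,
                        g_bounds: tuple = (0.0, 10.0),
                        normalize: str = "auto") -> CommunicabilityFit:
    """Fit the decay parameter of the communicability model M = exp(g S).

    ``g`` minimizes the mean squared difference between the off-diagonal
    entries of ``exp(g S)`` and of the observed matrix (bounded scalar
    search). When the exponential would overflow at the upper bound the
    matrix is normalized by its spectral radius first (``normalize="auto"``;
    ``"always"``/``"never"`` force the choice). The score is the mean over
    nodes of the Spearman correlation between predicted and observed
    off-diagonal connectivity profiles.
    """
    S = np.asarray(S, dtype=float)
    M_obs = np.asarray(M_obs, dtype=float)
    if not np.allclose(S, S.T, atol=1e-10):
        raise ValueError("S must be symmetric")
    n = S.shape[0]
    lam = float(np.max(np.abs(np.linalg.eigvalsh(S)))) if n else 0.0
    normalized = normalize == "always"
    if normalize == "auto" and lam * g_bounds[1] > 500.0:
        warnings.warn("exp(g S) would overflow; refitting with the "
                      "spectrally normalized matrix", stacklevel=2)
        normalized = True
    Sf = S / lam if (normalized and lam > 0) else S
    off = ~np.eye(n, dtype=bool)
    target = M_obs[off]

    def loss(g):
        pred = expm(g * Sf)
        return float(np.mean((pred[off] - target) ** 2))

    res = minimize_scalar(loss, bounds=g_bounds, method="bounded",
                          options={"xatol": 1e-8})
    g = float(res.x)
    predicted = expm(g * Sf)
    scores = []
    for i in range(n):
        keep = off[i]
        if np.ptp(predicted[i, keep]) == 0 or np.ptp(M_obs[i, keep]) == 0:
            continue
        scores.append(stats.spearmanr(predicted[i, keep],
                                      M_obs[i, keep]).statistic)
    score = float(np.mean(scores)) if scores else math.nan
    return CommunicabilityFit(g=g, predicted=predicted, score=score,
                              mse=float(res.fun), normalized=normalized)


def absolute_nodal_correlation(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """|Pearson| between each node's connectivity profiles in A and B.

    The self-entry (index i) is removed from both row profiles; nodes with
    a constant profile get NaN and are logged.
    """
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    if A.shape != B.shape or A.shape[0] != A.shape[1]:
        raise ValueError("A and B must be square with the same node set")
    n = A.shape[0]
    out = np.empty(n)
    for i in range(n):
        keep = np.arange(n) != i
        a, b = A[i, keep], B[i, keep]
        if np.ptp(a) == 0 or np.ptp(b) == 0:
            logger.warning("constant profile at node %d; score undefined", i)
            out[i] = math.nan
            continue
        out[i] = abs(stats.pearsonr(a, b).statistic)
    return out


def overlap_score(labels_a, labels_b) -> tuple[float, dict]:
    """Best one-to-one class matching between two labelings (Hungarian).

    Builds the contingency table, solves the assignment maximizing matched
    items, and returns (matched / total, class mapping a -> b).
    """
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.size == 0 or b.size == 0 or a.shape != b.shape:
        raise ValueError("labelings must be non-empty and the same length")
    cls_a = np.unique(a)
    cls_b = np.unique(b)
    C = np.zeros((len(cls_a), len(cls_b)))
    for i, ca in enumerate(cls_a):
        for j, cb in enumerate(cls_b):
            C[i, j] = np.sum((a == ca) & (b == cb))
    rows, cols = linear_sum_assignment(-C)
    matched = C[rows, cols].sum()
    mapping = {cls_a[i]: cls_b[j] for i, j in zip(rows, cols)}
    return float(matched / a.size), mapping


def nmi_score(map_a, map_b) -> float:
    """Normalized mutual information between two categorical maps in [0, 1].

    Degenerate single-class inputs are defined as 0 (and logged), since
    mutual information carries no signal there.
    """
    a = np.asarray(map_a)
    b = np.asarray(map_b)
    if len(np.unique(a)) < 2 or len(np.unique(b)) < 2:
        logger.warning("single-class labeling: NMI defined as 0")
        return 0.0
    return float(normalized_mutual_info_score(a, b))


def structural_weights(ns: np.ndarray, lengths: np.ndarray,
                       volumes: np.ndarray,
                       node_ids: np.ndarray | None = None
                       ) -> StructuralConnectivity:
    """Streamline counts normalized by mean length and endpoint volumes.

    ``S_ij = ns_ij / (l_ij * (V_i + V_j))``; pairs with no streamlines get
    weight 0, and a zero length with a positive count is an error.
    """
    ns = np.asarray(ns, dtype=float)
    lengths = np.asarray(lengths, dtype=float)
    volumes = np.asarray(volumes, dtype=float)
    if not np.allclose(ns, ns.T):
        raise ValueError("ns must be symmetric")
    if np.any(volumes <= 0):
        raise ValueError("volumes must be positive")
    if np.any((ns > 0) & (lengths <= 0)):
        raise ValueError("zero length with positive streamline count")
    vsum = volumes[:, None] + volumes[None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        S = ns / (lengths * vsum)
    S[ns == 0] = 0.0
    np.fill_diagonal(S, 0.0)
    ids = node_ids if node_ids is not None else np.arange(ns.shape[0])
    return StructuralConnectivity(node_ids=np.asarray(ids), S=S, ns=ns,
                                  lengths=lengths, volumes=volumes)


def consensus_filter(connectomes: list, threshold: float = 0.5) -> np.ndarray:
    """Keep pairs with nonzero weight in at least ``threshold`` of subjects."""
    mats = [c.S if isinstance(c, StructuralConnectivity) else np.asarray(c)
            for c in connectomes]
    if not mats:
        raise ValueError("empty connectome list")
    present = np.mean([m != 0 for m in mats], axis=0)
    return present >= threshold


def gini(sizes) -> float:
    """Gini coefficient of a positive size distribution, in [0, 1)."""
    x = np.asarray(list(sizes), dtype=float)
    if x.size == 0:
        raise ValueError("empty size list")
    if np.any(x <= 0):
        raise ValueError("sizes must be positive")
    diff_sum = np.abs(x[:, None] - x[None, :]).sum()
    return float(diff_sum / (2.0 * x.size ** 2 * x.mean()))
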