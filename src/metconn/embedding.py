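"""One-dimensional spatial modes of similarity matrices.

The "metabolic similarity mode" (MS mode) is a 1-D embedding of the rows of
a similarity matrix: PCA for denoising (default 50 components) followed by
1-D t-SNE with PCA initialization. Because a 1-D stochastic embedding has
arbitrary sign and scale, modes are canonicalized: the sign is chosen so the
mode increases caudally-to-rostrally when centroids are available (else so
the first region sits at or below the median), and values are min-max
scaled to [0, 1].

The module also reconstructs the t-SNE-filtered similarity matrix from the
mode through the Student-t kernel, reports ISOMAP intrinsic-dimensionality
profiles, embeds structural connectopies with UMAP, and clusters mode maps
with 1-D Gaussian mixtures.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.sparse.csgraph import connected_components, shortest_path
from sklearn.decomposition import PCA
from sklearn.manifold import TSNE
from sklearn.mixture import GaussianMixture
from sklearn.neighbors import kneighbors_graph

from .scheme import ParcelScheme


@dataclass
class ModeMap:
    """A scalar spatial mode per region, with embedding metadata."""

    region_ids: np.ndarray
    mu: np.ndarray
    metadata: dict = field(default_factory=dict)

    def validate(self) -> None:
        if len(self.mu) != len(self.region_ids):
            raise ValueError("mu length must match region ids")
        if not np.all(np.isfinite(self.mu)):
            raise ValueError("mode values must be finite")

    def to_tsv(self, path) -> None:
        pd.DataFrame({"parcel_id": self.region_ids,
                      "mu": self.mu}).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "ModeMap":
        df = pd.read_csv(path, sep="\t")
        return cls(region_ids=df["parcel_id"].to_numpy(),
                   mu=df["mu"].to_numpy(dtype=float))


@dataclass
class FilteredMatrix:
    """Student-t kernel reconstruction of a similarity matrix from a mode.

    ``Q`` holds the kernel weights (off-diagonal entries sum to 1 over all
    ordered pairs); ``R = 2Q - 1`` restores the correlation-like range.
    """

    region_ids: np.ndarray
    Q: np.ndarray
    R: np.ndarray


def _canonicalize(mu: np.ndarray, region_ids: np.ndarray,
                  scheme: ParcelScheme | None) -> np.ndarray:
    mu = np.asarray(mu, dtype=float).ravel().copy()
    if scheme is not None:
        idx = scheme.index_of
        y = np.asarray([scheme.centroids[idx[int(r)], 1] for r in region_ids])
        rho = stats.spearmanr(mu, y).statistic if np.ptp(mu) > 0 else 0.0
        if np.isfinite(rho) and rho < 0:
            mu = -mu
    elif np.ptp(mu) > 0 and mu[0] > np.median(mu):
        mu = -mu
    span = np.ptp(mu)
    if span > 0:
        mu = (mu - mu.min()) / span
    else:
        mu = np.zeros_like(mu)
    return mu


def reduce_mode(matrix: np.ndarray,
                pca_dims: int = 50,
                perplexity: float = 30.0,
                early_exaggeration: float = 12.0,
                seed: int = 0,
                region_ids: np.ndarray | None = None,
                scheme: ParcelScheme | None = None,
                max_iter: int = 1000) -> ModeMap:
    """PCA -> 1-D t-SNE mode of the rows of a similarity matrix.

    ``pca_dims`` is capped at ``n - 1`` and ``perplexity`` at the largest
    value t-SNE accepts for the problem size. The returned mode is
    canonicalized (see module docstring); the achieved KL divergence and the
    effective parameters are recorded in ``metadata``.
    """
    X = np.asarray(matrix, dtype=float)
    n = X.shape[0]
    if X.shape[1] != n:
        raise ValueError("expected a square similarity matrix")
    if not np.allclose(X, X.T, atol=1e-8):
        raise ValueError("expected a symmetric matrix")
    ids = np.asarray(region_ids) if region_ids is not None else np.arange(n)

    dims = int(min(pca_dims, n - 1, X.shape[1]))
    Xp = PCA(n_components=dims, svd_solver="full").fit_transform(X)
    perp = float(min(perplexity, max((n - 2) / 3.0, 1.5)))
    tsne = TSNE(n_components=1, perplexity=perp,
                early_exaggeration=early_exaggeration, init="pca",
                random_state=seed, max_iter=max_iter)
    emb = tsne.fit_transform(Xp).ravel()
    mu = _canonicalize(emb, ids, scheme)
    mode = ModeMap(region_ids=ids, mu=mu, metadata={
        "reduction": "pca+tsne", "pca_dims": dims, "perplexity": perp,
        "early_exaggeration": early_exaggeration, "seed": seed,
        "max_iter": max_iter, "kl_divergence": float(tsne.kl_divergence_),
        "n_iter": int(tsne.n_iter_)})
    mode.validate()
    return mode


def reconstruct_filtered(mode: ModeMap) -> FilteredMatrix:
    """Student-t kernel matrix of the mode, normalized over ordered pairs.

    ``q_ij = (1 + (mu_i - mu_j)^2)^-1 / sum_{k != l} (1 + (mu_k - mu_l)^2)^-1``
    with the diagonal excluded from the normalizing sum; ``R = 2q - 1``
    off-diagonal with unit diagonal.
    """
    mode.validate()
    mu = mode.mu
    n = len(mu)
    d2 = (mu[:, None] - mu[None, :]) ** 2
    K = 1.0 / (1.0 + d2)
    off = ~np.eye(n, dtype=bool)
    Q = np.zeros((n, n))
    Q[off] = K[off] / K[off].sum()
    R = 2.0 * Q - 1.0
    np.fill_diagonal(R, 1.0)
    return FilteredMatrix(region_ids=mode.region_ids, Q=Q, R=R)


def isomap_variance_profile(matrix: np.ndarray,
                            neighbor_sizes=(3, 5, 8, 12, 16, 20),
                            n_components: int = 10) -> pd.DataFrame:
    """Fraction of geodesic variance per embedding component, per k.

    For each neighbourhood size ``k`` a symmetric k-NN graph on the row
    vectors is built, geodesic distances are computed by shortest paths, and
    the spectrum of the double-centered geodesic Gram matrix gives the
    variance fraction captured by each component (classical MDS reading of
    ISOMAP). Raises when a neighbourhood graph is disconnected, naming k.
    """
    X = np.asarray(matrix, dtype=float)
    n = X.shape[0]
    rows = []
    for k in neighbor_sizes:
        if k >= n:
            raise ValueError(f"neighbourhood size {k} >= n={n}")
        G = kneighbors_graph(X, n_neighbors=int(k), mode="distance")
        G = G.maximum(G.T)  # symmetrize
        ncomp, _ = connected_components(G, directed=False)
        if ncomp > 1:
            raise ValueError(f"geodesic graph disconnected at k={k}")
        D = shortest_path(G, method="D", directed=False)
        J = np.eye(n) - np.ones((n, n)) / n
        B = -0.5 * J @ (D ** 2) @ J
        eig = np.linalg.eigvalsh(B)[::-1]
        pos = eig[eig > 0]
        total = pos.sum()
        frac = np.zeros(n_components)
        m = min(n_components, len(pos))
        frac[:m] = pos[:m] / total
        rows.append({"k": int(k), **{f"component_{i + 1}": frac[i]
                                     for i in range(n_components)}})
    return pd.DataFrame(rows)


def embed_connectopy(structural: np.ndarray,
                     seed: int = 0,
                     region_ids: np.ndarray | None = None,
                     scheme: ParcelScheme | None = None,
                     n_neighbors: int = 15,
                     min_dist: float = 0.1) -> ModeMap:
    """First UMAP component of structural-connectivity row profiles.

    Canonicalized like :func:`reduce_mode`.
    """
    import umap  # deferred: slow import

    S = np.asarray(structural, dtype=float)
    if np.any(S < 0):
        raise ValueError("structural matrix must be nonnegative")
    n = S.shape[0]
    ids = np.asarray(region_ids) if region_ids is not None else np.arange(n)
    nn = int(min(n_neighbors, max(n - 2, 2)))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        emb = umap.UMAP(n_components=1, n_neighbors=nn, min_dist=min_dist,
                        random_state=seed).fit_transform(S).ravel()
    mu = _canonicalize(emb, ids, scheme)
    mode = ModeMap(region_ids=ids, mu=mu, metadata={
        "reduction": "umap", "n_neighbors": nn, "min_dist": min_dist,
        "seed": seed})
    mode.validate()
    return mode


def cluster_mode_map(mode: ModeMap, k: int, seed: int = 0,
                     n_init: int = 5) -> np.ndarray:
    """1-D Gaussian-mixture labels of a mode map, ordered by component mean.

    Label 0 is the component with the smallest mean, so the labelling is
    stable under affine rescaling of the mode.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    n = len(mode.mu)
    if k > n:
        raise ValueError(f"k={k} exceeds number of regions n={n}")
    if k == 1:
        return np.zeros(n, dtype=int)
    x = mode.mu.reshape(-1, 1)
    gm = GaussianMixture(n_components=k, random_state=seed, n_init=n_init,
                        covariance_type="full", reg_covar=1e-10)
    raw = gm.fit_predict(x)
    order = np.argsort(gm.means_.ravel(), kind="stable")
    relabel = np.empty(k, dtype=int)
    relabel[order] = np.arange(k)
    return relabel[raw]
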