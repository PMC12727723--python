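"""Spatially informed surrogate matrices and permutation machinery.

Similarity matrices of spatially embedded brain maps carry distance-driven
autocorrelation, so naive permutation tests are anticonservative. This
module provides:

* the RandGeom family: surrogate matrices whose pairwise weights depend
  only on inter-centroid distance (linear mean trend, heteroscedastic
  residual variance resampled per 2 mm distance bin), with
  within-hemisphere, mirrored, and gray-matter-adjacency-restricted
  variants;
* AdjPerm: permutations composed of random transpositions between
  spatially adjacent parcels, preserving local autocorrelation;
* degree-preserving Maslov-Sneppen graph rewiring (via networkx);
* add-one empirical p-values, including the joint two-statistic variant;
* distance-binned densities of positive/negative similarity weights with
  weighted lognormal fits.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from ._utils import spawn_seeds, upper_tri
from .profiles import MetSiM
from .scheme import ParcelScheme

RANDGEOM_VARIANTS = ("full", "within_hemisphere", "mirrored", "gm_adjacent")


@dataclass
class DistanceModel:
    """Linear weight-vs-distance trend with per-bin residual pools."""

    slope: float                  # weight per mm
    intercept: float              # weight
    bin_width: float              # mm
    bin_edges: np.ndarray         # tiles [0, max distance]
    residual_pools: list          # squared residuals per bin
    diagnostics: dict = field(default_factory=dict)

    def predict(self, d: np.ndarray) -> np.ndarray:
        return self.slope * np.asarray(d) + self.intercept

    def bin_of(self, d: float) -> int:
        b = int(np.searchsorted(self.bin_edges, d, side="right")) - 1
        return min(max(b, 0), len(self.residual_pools) - 1)

    def pool_for(self, d: float) -> np.ndarray:
        """Residual pool of d's bin, falling back to the nearest non-empty."""
        b = self.bin_of(d)
        if len(self.residual_pools[b]):
            return self.residual_pools[b]
        for off in range(1, len(self.residual_pools)):
            for cand in (b - off, b + off):
                if 0 <= cand < len(self.residual_pools) \
                        and len(self.residual_pools[cand]):
                    return self.residual_pools[cand]
        raise ValueError("all residual pools empty")


@dataclass
class SurrogateEnsemble:
    """A stack of surrogate matrices (or permuted maps) plus metadata."""

    matrices: np.ndarray          # (n_surrogates, ...) array
    variant: str
    seed: int
    mask: np.ndarray | None = None  # eligible off-diagonal entries

    def __len__(self) -> int:
        return self.matrices.shape[0]


def fit_distance_model(metsim: MetSiM, scheme: ParcelScheme,
                       bin_width: float = 2.0) -> DistanceModel:
    """Least-squares weight-vs-distance line with binned residual pools.

    Upper-triangle weights are regressed on inter-centroid Euclidean
    distance; squared residuals are pooled into ``bin_width``-mm distance
    bins tiling [0, max distance]. Empty bins are flagged in diagnostics and
    handled at sampling time by nearest-non-empty fallback.
    """
    D = scheme.distance_matrix()
    d = upper_tri(D)
    w = upper_tri(metsim.W)
    if len(np.unique(d)) < 2:
        raise ValueError("need at least 2 distinct distances")
    res = stats.linregress(d, w)
    resid = w - (res.slope * d + res.intercept)
    n_bins = int(math.ceil(d.max() / bin_width))
    edges = np.arange(n_bins + 1) * bin_width
    which = np.clip(np.searchsorted(edges, d, side="right") - 1, 0, n_bins - 1)
    pools = [resid[which == b] ** 2 for b in range(n_bins)]
    empty = [b for b, p in enumerate(pools) if len(p) == 0]
    return DistanceModel(
        slope=float(res.slope), intercept=float(res.intercept),
        bin_width=float(bin_width), bin_edges=edges, residual_pools=pools,
        diagnostics={"r_value": float(res.rvalue), "n_pairs": len(d),
                     "empty_bins": empty})


def _eligible_mask(scheme: ParcelScheme, variant: str) -> np.ndarray:
    n = len(scheme)
    off = ~np.eye(n, dtype=bool)
    if variant in ("full", "mirrored"):
        return off
    if variant == "within_hemisphere":
        same = scheme.hemisphere[:, None] == scheme.hemisphere[None, :]
        return off & same
    if variant == "gm_adjacent":
        return off & scheme.adjacency_matrix()
    raise ValueError(f"unknown RandGeom variant {variant!r}")


def sample_randgeom(model: DistanceModel, scheme: ParcelScheme,
                    variant: str = "full", n: int = 1,
                    seed: int = 0) -> SurrogateEnsemble:
    """Draw RandGeom surrogate similarity matrices.

    For each eligible pair a variance is drawn uniformly from the squared-
    residual pool of the pair's distance bin, then the weight is drawn from
    ``Normal(slope * d + intercept, variance)`` and clipped to [-1, 1].
    Variants: ``within_hemisphere`` restricts to same-hemisphere pairs;
    ``mirrored`` samples the left-hemisphere block and copies it to the
    homotopic right-hemisphere pairs (cross-hemisphere pairs are sampled
    unconstrained); ``gm_adjacent`` restricts to gray-matter-adjacent pairs.
    Ineligible entries are set to 0 and recorded in the ensemble mask so
    comparisons can exclude them.
    """
    n_parcels = len(scheme)
    D = scheme.distance_matrix()
    rng = np.random.default_rng(seed)
    eligible = _eligible_mask(scheme, variant)

    if variant == "mirrored" and not scheme.homotopic:
        raise ValueError("mirrored variant requires a homotopic partner map")

    iu = np.triu_indices(n_parcels, k=1)
    pair_rows, pair_cols = iu
    pair_elig = eligible[iu]
    d_pairs = D[iu]
    mu_pairs = model.predict(d_pairs)

    # effective (post-fallback) residual pool per eligible pair, grouped by
    # bin so variance draws vectorize
    n_pairs = len(pair_rows)
    eff_bin = np.full(n_pairs, -1)
    pool_cache = {}
    for k in range(n_pairs):
        if not pair_elig[k]:
            continue
        b = model.bin_of(float(d_pairs[k]))
        if b not in pool_cache:
            pool_cache[b] = model.pool_for(float(d_pairs[k]))
        eff_bin[k] = b

    vals = np.zeros((n, n_pairs))
    for b, pool in pool_cache.items():
        sel = np.flatnonzero(eff_bin == b)
        var = pool[rng.integers(0, len(pool), size=(n, len(sel)))]
        vals[:, sel] = (mu_pairs[sel][None, :]
                        + np.sqrt(var) * rng.standard_normal((n, len(sel))))
    vals = np.clip(vals, -1.0, 1.0)
    vals[:, ~pair_elig] = 0.0

    if variant == "mirrored":
        # left-hemisphere block drives its homotopic right-hemisphere image
        idx = scheme.index_of
        partner = {i: idx[scheme.homotopic[int(p)]]
                   for i, p in enumerate(scheme.parcel_ids)
                   if int(p) in scheme.homotopic}
        is_left = scheme.hemisphere == "L"
        pair_key = {(int(a), int(b)): k
                    for k, (a, b) in enumerate(zip(pair_rows, pair_cols))}
        src_idx, dst_idx = [], []
        for k in range(n_pairs):
            a, b = int(pair_rows[k]), int(pair_cols[k])
            if is_left[a] and is_left[b] and a in partner and b in partner:
                pa, pb = sorted((partner[a], partner[b]))
                dst = pair_key.get((pa, pb))
                if dst is not None:
                    src_idx.append(k)
                    dst_idx.append(dst)
        vals[:, dst_idx] = vals[:, src_idx]

    mats = np.zeros((n, n_parcels, n_parcels))
    mats[:, pair_rows, pair_cols] = vals
    mats = mats + mats.transpose(0, 2, 1)
    mats[:, np.arange(n_parcels), np.arange(n_parcels)] = 1.0
    return SurrogateEnsemble(matrices=mats, variant=variant, seed=seed,
                             mask=eligible)


# ---------------------------------------------------------------------------
# adjacency-constrained permutation
# ---------------------------------------------------------------------------

def _achievable_permutations(scheme: ParcelScheme) -> float:
    """Adjacent transpositions generate the full symmetric group on each
    connected component of the adjacency graph."""
    g = scheme.graph()
    total = 1.0
    for comp in nx.connected_components(g):
        total *= math.factorial(len(comp))
        if total > 1e18:
            return math.inf
    return total


def adjperm(values: np.ndarray, scheme: ParcelScheme, n_perm: int = 1000,
            n_swaps: int | None = None, seed: int = 0,
            max_retries_factor: int = 50) -> SurrogateEnsemble:
    """Permute a parcel map by compositions of adjacent transpositions.

    Each permutation applies ``n_swaps`` (default: 3/8 of the parcel count,
    which displaces values locally, demonstrably retains spatial
    autocorrelation, and keeps the resulting correlation test at its
    nominal type-I error on smooth independent maps; larger values mix
    toward a free permutation and make the test anticonservative) uniformly
    random transpositions of gray-matter-adjacent parcel pairs,
    preserving the value multiset while respecting spatial locality.
    Duplicate permutations are rejected and resampled until ``n_perm``
    unique ones exist; a retry cap triggers a warning and a shorter
    ensemble. Returns the permuted maps and (in ``mask``) nothing; the
    permutation index arrays are stored alongside the maps.
    """
    values = np.asarray(values, dtype=float)
    n = len(scheme)
    if len(values) != n:
        raise ValueError("value map length must match the scheme")
    if n_perm > _achievable_permutations(scheme):
        raise ValueError("n_perm exceeds the number of achievable "
                         "permutations for this adjacency graph")
    if n_swaps is None:
        n_swaps = max(1, math.ceil(3 * n / 8))
    idx = scheme.index_of
    pairs = np.asarray([(idx[i], idx[j]) for i, j in sorted(scheme.adjacency)])
    rng = np.random.default_rng(seed)
    seen, perms = set(), []
    retries = 0
    cap = max_retries_factor * n_perm
    while len(perms) < n_perm and retries < cap:
        perm = np.arange(n)
        if n_swaps > 0 and len(pairs):
            choice = rng.integers(0, len(pairs), size=n_swaps)
            for a, b in pairs[choice]:
                perm[a], perm[b] = perm[b], perm[a]
        key = perm.tobytes()
        if key in seen:
            retries += 1
            continue
        seen.add(key)
        perms.append(perm)
    if len(perms) < n_perm:
        warnings.warn(f"adjperm retry cap reached: {len(perms)}/{n_perm} "
                      "unique permutations", stacklevel=2)
    perm_arr = np.stack(perms)
    ens = SurrogateEnsemble(matrices=values[perm_arr], variant="adjperm",
                            seed=seed)
    ens.permutations = perm_arr
    return ens


def adjperm_correlation_test(x: np.ndarray, y: np.ndarray,
                             scheme: ParcelScheme, n_perm: int = 1000,
                             seed: int = 0, method: str = "spearman",
                             tail: str = "ge",
                             n_swaps: int | None = None) -> dict:
    """Correlation between two parcel maps with AdjPerm significance.

    ``x`` is permuted under the adjacency constraint; the null correlations
    with ``y`` yield an add-one empirical p-value (``tail`` as in
    :func:`empirical_pvalue`, with ``"two"`` for a two-sided test on the
    absolute value).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if method == "spearman":
        x_r = stats.rankdata(x)
        y_r = stats.rankdata(y)
    elif method == "pearson":
        x_r, y_r = x, y
    else:
        raise ValueError(f"unknown method {method!r}")
    ens = adjperm(x_r, scheme, n_perm=n_perm, n_swaps=n_swaps, seed=seed)
    yc = (y_r - y_r.mean()) / y_r.std()
    xc = (x_r - x_r.mean()) / x_r.std()
    observed = float(xc @ yc / len(xc))
    null_x = ens.matrices
    null_c = (null_x - null_x.mean(axis=1, keepdims=True))
    null_c /= null_x.std(axis=1, keepdims=True)
    null_r = null_c @ yc / len(yc)
    if tail == "two":
        p = empirical_pvalue(abs(observed), np.abs(null_r), tail="ge")
    else:
        p = empirical_pvalue(observed, null_r, tail=tail)
    return {"r": observed, "p": p, "null": null_r}


# ---------------------------------------------------------------------------
# degree-preserving rewiring
# ---------------------------------------------------------------------------

def maslov_sneppen(graph: nx.Graph, n_rand: int = 1000,
                   swaps_per_edge: int = 10, seed: int = 0) -> list:
    """Degree-preserving Maslov-Sneppen rewired surrogates of a graph.

    Each surrogate applies ``swaps_per_edge * |E|`` double-edge swaps
    (networkx implementation), preserving every node degree exactly. Graphs
    admitting no valid swap are returned unchanged with a warning.
    """
    seeds = spawn_seeds(seed, max(n_rand, 1))
    out = []
    m = graph.number_of_edges()
    for s in range(n_rand):
        g = graph.copy()
        if m < 2:
            warnings.warn("graph has no valid degree-preserving swap; "
                          "returned unchanged", stacklevel=2)
            out.append(g)
            continue
        nswap = swaps_per_edge * m
        try:
            nx.double_edge_swap(g, nswap=nswap, max_tries=100 * nswap,
                                seed=seeds[s])
        except nx.NetworkXError:
            warnings.warn("rewiring exhausted its try budget; surrogate may "
                          "be under-mixed", stacklevel=2)
        except nx.NetworkXAlgorithmError:
            warnings.warn("no valid swap found; surrogate returned as-is",
                          stacklevel=2)
        out.append(g)
    return out


# ---------------------------------------------------------------------------
# empirical p-values
# ---------------------------------------------------------------------------

def empirical_pvalue(observed, null, tail: str = "ge",
                     tails: tuple = ("le", "ge")) -> float:
    """Add-one empirical p-value against a null sample.

    ``p = (1 + #extreme) / (1 + n_null)`` where a null draw is *extreme*
    when it is at least as large (``tail="ge"``), at least as small
    (``"le"``), or — in ``"joint"`` mode on paired statistics — extreme in
    both components per ``tails``.
    """
    if tail == "joint":
        obs = np.asarray(observed, dtype=float)
        nulls = np.asarray(null, dtype=float)
        if nulls.ndim != 2 or nulls.shape[1] != len(obs):
            raise ValueError("joint mode expects paired statistics")
        extreme = np.ones(len(nulls), dtype=bool)
        for c, t in enumerate(tails):
            if t == "ge":
                extreme &= nulls[:, c] >= obs[c]
            elif t == "le":
                extreme &= nulls[:, c] <= obs[c]
            else:
                raise ValueError(f"unknown tail {t!r}")
        count = int(extreme.sum())
        n_null = len(nulls)
    else:
        nulls = np.asarray(null, dtype=float)
        if nulls.size == 0:
            raise ValueError("empty null sample")
        if tail == "ge":
            count = int((nulls >= observed).sum())
        elif tail == "le":
            count = int((nulls <= observed).sum())
        else:
            raise ValueError(f"unknown tail {tail!r}")
        n_null = len(nulls)
    return (1 + count) / (1 + n_null)


# ---------------------------------------------------------------------------
# distance-binned density of similarity weights
# ---------------------------------------------------------------------------

def _weighted_lognormal_fit(d: np.ndarray, w: np.ndarray) -> dict:
    """|w|-weighted maximum-likelihood lognormal fit of distances."""
    logd = np.log(d)
    wsum = w.sum()
    mu = float((w * logd).sum() / wsum)
    sigma2 = float((w * (logd - mu) ** 2).sum() / wsum)
    sigma = math.sqrt(sigma2)
    return {"mu_log": mu, "sigma_log": sigma,
            "median_mm": math.exp(mu), "mode_mm": math.exp(mu - sigma2)}


def distance_density(metsim: MetSiM, scheme: ParcelScheme,
                     bin_width: float = 2.0) -> dict:
    """Distance distributions of positive and negative similarity weights.

    Per sign: a |w|-weighted normalized histogram over ``bin_width``-mm
    distance bins, a Gaussian KDE of the same weighted distances, the
    weighted maximum-likelihood lognormal fit, and its fitted mode distance.
    A sign with no weights returns an empty branch.
    """
    D = scheme.distance_matrix()
    d = upper_tri(D)
    w = upper_tri(metsim.W)
    edges = np.arange(0.0, d.max() + bin_width, bin_width)
    out = {}
    for sign, mask in (("positive", w > 0), ("negative", w < 0)):
        if not mask.any():
            out[sign] = {"histogram": pd.DataFrame(
                columns=["bin_center", "mass"]), "kde": None,
                "lognormal": None}
            continue
        ds, ws = d[mask], np.abs(w[mask])
        hist, _ = np.histogram(ds, bins=edges, weights=ws)
        mass = hist / hist.sum()
        centers = (edges[:-1] + edges[1:]) / 2
        kde = stats.gaussian_kde(ds, weights=ws) if len(ds) > 1 else None
        out[sign] = {
            "histogram": pd.DataFrame({"bin_center": centers, "mass": mass}),
            "kde": kde,
            "lognormal": _weighted_lognormal_fit(ds, ws),
            "median_distance_mm": float(np.median(ds)),
        }
        # weighted median distance
        order = np.argsort(ds)
        cum = np.cumsum(ws[order])
        out[sign]["weighted_median_distance_mm"] = float(
            ds[order][np.searchsorted(cum, cum[-1] / 2)])
    return out
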