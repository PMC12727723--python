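"""Study-scale evaluation experiments on synthetic data.

Self-contained routines that exercise the full pipeline under the default
synthetic study conditions and measure how well each stage recovers what
the generator planted: the metabolic-similarity-mode axis, the principal
path's node ordering, the communicability decay parameter, the RandGeom
regression line, the calibration of the permutation tests, and the
qualitative distance/stability phenomena the similarity structure is
expected to show. Used by the acceptance suite and the reproduction
script; every routine takes an explicit seed and returns plain dicts.

Problem sizes: axis recovery and the distance-structure experiments run at
the native 210-parcel scale; the path-search and calibration experiments
use smaller schemes (exhaustive path enumeration and per-surrogate
re-embedding grow combinatorially, and the statistical questions they
answer do not require scale).
"""

from __future__ import annotations

import numpy as np
from scipy import stats
from scipy.linalg import expm

from ._utils import spawn_seeds, upper_tri
from .embedding import ModeMap, isomap_variance_profile, reduce_mode
from .graph_metrics import communicability_fit
from .nulls import (adjperm_correlation_test, empirical_pvalue,
                    fit_distance_model, sample_randgeom)
from .principal_path import PathSearchConfig, find_principal_path
from .profiles import (MetSiM, compute_metsim, compute_profiles,
                       filter_regions, leave_one_metabolite_out,
                       perturb_voxels)
from .synthetic import (generate_parcel_scheme, generate_structural_connectivity,
                        generate_voxel_metabolites, _smooth_field)
from .graph_metrics import structural_weights


def _build_metsim(scheme, vox, K_pert, seed):
    retained = filter_regions(vox, scheme, min_voxels=1)
    reps = perturb_voxels(vox, K_pert, seed=seed)
    profiles = compute_profiles(reps, scheme, retained)
    return compute_metsim(profiles)


def mode_axis_recovery(seed: int, n_per_hemisphere: int = 105,
                       K_pert: int = 50) -> dict:
    """|Spearman| between the PCA->t-SNE mode and the planted axis."""
    s = spawn_seeds(seed, 4)
    scheme = generate_parcel_scheme(n_per_hemisphere, seed=s[0])
    vox, truth = generate_voxel_metabolites(scheme, seed=s[1])
    metsim = _build_metsim(scheme, vox, K_pert, s[2])
    mode = reduce_mode(metsim.W, region_ids=metsim.region_ids, scheme=scheme,
                       seed=s[3])
    rho = stats.spearmanr(mode.mu, truth.planted_axis).statistic
    return {"spearman_abs": float(abs(rho)), "n": len(scheme),
            "scheme": scheme, "truth": truth, "metsim": metsim, "mode": mode}


def path_order_recovery(seed: int, n_per_hemisphere: int = 14,
                        M: int = 500) -> dict:
    """Principal-path node order vs the planted axis on a planted gradient.

    The mode is the planted axis itself, so the experiment isolates the
    path-search algorithm: the recovered path should traverse the
    hemisphere's cortical graph in axis order.
    """
    s = spawn_seeds(seed, 3)
    scheme = generate_parcel_scheme(n_per_hemisphere, seed=s[0])
    _, truth = generate_voxel_metabolites(scheme, seed=s[1])
    mode = ModeMap(region_ids=scheme.parcel_ids, mu=truth.planted_axis)
    g = scheme.graph(hemisphere="R", superregions=("cortex",))
    # the cortex-only subgraph may fragment; search the largest component
    import networkx as nx
    comp = max(nx.connected_components(g), key=len)
    g = g.subgraph(comp).copy()
    idx = scheme.index_of
    ax = {p: truth.planted_axis[idx[p]] for p in g.nodes}
    start = min(g.nodes, key=ax.get)
    end = max(g.nodes, key=ax.get)
    res, table = find_principal_path(mode, scheme, g, start, end,
                                     PathSearchConfig(M=M, seed=s[2]))
    path_ax = [ax[p] for p in res.gamma]
    rho = stats.spearmanr(np.arange(len(path_ax)), path_ax).statistic
    return {"spearman": float(rho), "n": len(res.gamma), "result": res,
            "n_candidates": len(table), "scheme": scheme, "truth": truth,
            "graph": g, "mode": mode}


def communicability_recovery(seed: int, n: int = 30, g_true: float = 0.3
                             ) -> dict:
    """Refit g from a matrix manufactured as exp(g_true * S)."""
    scheme = generate_parcel_scheme(max(n // 2, 4), seed=seed)
    sc = generate_structural_connectivity(scheme, seed=seed + 1)
    S = structural_weights(sc.ns, sc.lengths,
                           scheme.n_voxels * 125.0).S
    S = S / np.abs(np.linalg.eigvalsh(S)).max()
    M_obs = expm(g_true * S)
    fit = communicability_fit(S, M_obs, g_bounds=(0.0, 5.0))
    return {"g_true": g_true, "g_fit": fit.g,
            "abs_error": abs(fit.g - g_true), "score": fit.score,
            "n": len(scheme)}


def randgeom_regression_recovery(seed: int, n_per_hemisphere: int = 105,
                                 slope: float = -0.004,
                                 intercept: float = 0.45,
                                 noise_sd: float = 0.05) -> dict:
    """Recover a known weight-vs-distance line from noisy weights."""
    s = spawn_seeds(seed, 2)
    scheme = generate_parcel_scheme(n_per_hemisphere, seed=s[0])
    rng = np.random.default_rng(s[1])
    D = scheme.distance_matrix()
    W = slope * D + intercept + rng.normal(0, noise_sd, D.shape)
    W = np.clip((W + W.T) / 2, -1, 1)
    np.fill_diagonal(W, 1.0)
    model = fit_distance_model(MetSiM(region_ids=scheme.parcel_ids, W=W),
                               scheme)
    return {"slope_rel_err": abs(model.slope - slope) / abs(slope),
            "intercept_rel_err": abs(model.intercept - intercept)
            / abs(intercept),
            "model": model, "n": len(scheme)}


def joint_path_test_calibration(seed: int, n_per_hemisphere: int = 8,
                                n_ensemble: int = 250, n_repeats: int = 200,
                                alpha: float = 0.05, M: int = 100,
                                tsne_iter: int = 300,
                                statistic: str = "cost") -> dict:
    """Type-I error of the joint gradient/entropy test under the null.

    A RandGeom-style null ensemble of (G_norm, H_norm) path statistics is
    built by re-embedding surrogate matrices and re-running the path search;
    each of ``n_repeats`` ensemble members in turn plays the observed
    statistic against the others (leave-one-out), exactly as a null data
    set would, and the rejection rate at ``alpha`` is reported. The test
    statistic matches :func:`metconn.principal_path.joint_null_test`.
    """
    s = spawn_seeds(seed, 5)
    scheme = generate_parcel_scheme(n_per_hemisphere, seed=s[0])
    vox, truth = generate_voxel_metabolites(scheme, seed=s[1])
    metsim = _build_metsim(scheme, vox, 3, s[2])
    model = fit_distance_model(metsim, scheme)
    ens = sample_randgeom(model, scheme, variant="full", n=n_ensemble,
                          seed=s[3])
    g = scheme.graph(hemisphere="L")
    idx = scheme.index_of
    ax = {p: truth.planted_axis[idx[p]] for p in g.nodes}
    start = min(g.nodes, key=ax.get)
    end = max(g.nodes, key=ax.get)
    cfg = PathSearchConfig(M=M, seed=s[4])
    mode_seeds = spawn_seeds(s[4] + 1, n_ensemble)
    null_stats = []
    for i in range(n_ensemble):
        mode_i = reduce_mode(ens.matrices[i], region_ids=scheme.parcel_ids,
                             scheme=scheme, seed=mode_seeds[i],
                             max_iter=tsne_iter)
        try:
            res_i, _ = find_principal_path(mode_i, scheme, g, start, end,
                                           cfg)
        except ValueError:
            continue
        null_stats.append((res_i.G_norm, res_i.H_norm))
    null_arr = np.asarray(null_stats)
    n_eff = len(null_arr)
    repeats = min(n_repeats, n_eff)
    with np.errstate(divide="ignore"):
        costs = null_arr[:, 0] / null_arr[:, 1]
    costs[~np.isfinite(costs)] = np.inf
    rejections = 0
    ps = []
    for i in range(repeats):
        if statistic == "cost":
            p = empirical_pvalue(costs[i], np.delete(costs, i), tail="le")
        else:
            p = empirical_pvalue(null_arr[i], np.delete(null_arr, i, axis=0),
                                 tail="joint", tails=("le", "ge"))
        ps.append(p)
        rejections += p <= alpha
    return {"type1_rate": rejections / repeats, "n_repeats": repeats,
            "alpha": alpha, "pvalues": np.asarray(ps),
            "null_stats": null_arr,
            "stat_correlation": float(np.corrcoef(null_arr.T)[0, 1])
            if n_eff > 2 else np.nan}


def adjperm_test_calibration(seed: int, n_per_hemisphere: int = 30,
                             n_repeats: int = 200, n_perm: int = 99,
                             alpha: float = 0.05,
                             length_mm: float = 30.0) -> dict:
    """Type-I error of the AdjPerm correlation test on independent maps.

    Each replicate correlates two independently generated smooth spatial
    fields; the one-tailed AdjPerm p-value should be uniform, so the
    rejection rate at ``alpha`` estimates the empirical type-I error.
    """
    s = spawn_seeds(seed, 2)
    scheme = generate_parcel_scheme(n_per_hemisphere, seed=s[0])
    rng = np.random.default_rng(s[1])
    rejections = 0
    for rep in range(n_repeats):
        a = _smooth_field(scheme.centroids, length_mm, rng)
        b = _smooth_field(scheme.centroids, length_mm, rng)
        res = adjperm_correlation_test(
            a, b, scheme, n_perm=n_perm,
            seed=int(rng.integers(2**31)), tail="ge")
        rejections += res["p"] <= alpha
    return {"type1_rate": rejections / n_repeats, "n_repeats": n_repeats,
            "alpha": alpha}


def distance_sign_separation(seed: int, n_per_hemisphere: int = 105,
                             K_pert: int = 10) -> dict:
    """Median inter-centroid distance of positive vs negative weights."""
    from .nulls import distance_density

    s = spawn_seeds(seed, 3)
    scheme = generate_parcel_scheme(n_per_hemisphere, seed=s[0])
    vox, _ = generate_voxel_metabolites(scheme, seed=s[1])
    metsim = _build_metsim(scheme, vox, K_pert, s[2])
    dd = distance_density(metsim, scheme)
    pos = dd["positive"]["median_distance_mm"]
    neg = dd["negative"]["median_distance_mm"]
    return {"median_positive_mm": pos, "median_negative_mm": neg,
            "gap_mm": neg - pos, "n": len(scheme),
            "lognormal_mode_positive_mm":
                dd["positive"]["lognormal"]["mode_mm"],
            "lognormal_mode_negative_mm":
                dd["negative"]["lognormal"]["mode_mm"]}


def loo_kpert_comparison(seed: int, n_per_hemisphere: int = 105,
                         K_low: int = 1, K_high: int = 50) -> dict:
    """Leave-one-metabolite-out stability at two perturbation depths."""
    s = spawn_seeds(seed, 3)
    scheme = generate_parcel_scheme(n_per_hemisphere, seed=s[0])
    vox, _ = generate_voxel_metabolites(scheme, seed=s[1])
    low = leave_one_metabolite_out(vox, scheme, K_pert=K_low, seed=s[2],
                                   min_voxels=1)
    high = leave_one_metabolite_out(vox, scheme, K_pert=K_high, seed=s[2],
                                    min_voxels=1)
    gains = {m: high[m] - low[m] for m in low}
    return {"r_low": low, "r_high": high, "gains": gains,
            "min_gain": min(gains.values()), "n": len(scheme)}


def best_randgeom_vs_self(seed: int, n_per_hemisphere: int = 105,
                          n_surrogates: int = 1000, K_pert: int = 10) -> dict:
    """Best-of-ensemble RandGeom correlation vs between-subject structure.

    A second synthetic subject shares the planted axis but has fresh noise
    fields; its MetSiM correlation with the first subject's measures the
    reproducible structure that distance-only surrogates should fail to
    reach.
    """
    s = spawn_seeds(seed, 6)
    scheme = generate_parcel_scheme(n_per_hemisphere, seed=s[0])
    vox_a, _ = generate_voxel_metabolites(scheme, seed=s[1])
    vox_b, _ = generate_voxel_metabolites(scheme, seed=s[2])
    met_a = _build_metsim(scheme, vox_a, K_pert, s[3])
    met_b = _build_metsim(scheme, vox_b, K_pert, s[4])
    edges_a = upper_tri(met_a.W)
    self_r = float(np.corrcoef(edges_a, upper_tri(met_b.W))[0, 1])
    model = fit_distance_model(met_a, scheme)
    ens = sample_randgeom(model, scheme, variant="full", n=n_surrogates,
                          seed=s[5])
    iu = np.triu_indices(len(scheme), k=1)
    surr_edges = ens.matrices[:, iu[0], iu[1]]
    ea = edges_a - edges_a.mean()
    se = surr_edges - surr_edges.mean(axis=1, keepdims=True)
    rs = se @ ea / (np.linalg.norm(se, axis=1) * np.linalg.norm(ea))
    return {"best_surrogate_r": float(np.max(rs)),
            "between_subject_r": self_r,
            "surrogate_rs": rs, "n": len(scheme),
            "n_surrogates": n_surrogates}


def isomap_stability(seed: int, n_per_hemisphere: int = 105,
                     K_pert: int = 10, neighbor_sizes=(3, 5, 8, 12, 16, 20)
                     ) -> dict:
    """First-component variance fraction across neighbourhood sizes.

    Neighbourhood sizes whose k-NN graph is disconnected (possible when the
    row profiles form well-separated clusters) are skipped; the stability
    summary covers the connected range.
    """
    s = spawn_seeds(seed, 3)
    scheme = generate_parcel_scheme(n_per_hemisphere, seed=s[0])
    vox, _ = generate_voxel_metabolites(scheme, seed=s[1])
    metsim = _build_metsim(scheme, vox, K_pert, s[2])
    usable, skipped = [], []
    for k in neighbor_sizes:
        try:
            isomap_variance_profile(metsim.W, neighbor_sizes=(k,))
            usable.append(k)
        except ValueError:
            skipped.append(k)
    if not usable:
        raise ValueError("no connected neighbourhood size")
    prof = isomap_variance_profile(metsim.W, neighbor_sizes=tuple(usable))
    frac = prof["component_1"].to_numpy()
    return {"first_fraction_mean": float(frac.mean()),
            "first_fraction_range": float(frac.max() - frac.min()),
            "profile": prof, "n": len(scheme),
            "neighbor_sizes": usable, "skipped": skipped}


def perturbation_variance_check(seed: int, n_draws: int = 10_000,
                                sigma2: float = 0.25,
                                multiplier: float = 3.0) -> dict:
    """Monte-Carlo sample variance of the perturbation draws vs closed form."""
    from .synthetic import VoxelMetaboliteData

    vox = VoxelMetaboliteData(
        parcel_ids=np.array([1]),
        signals={1: np.full((1, 5), 10.0)},
        variances={1: np.full((1, 5), sigma2)})
    reps = perturb_voxels(vox, K_pert=n_draws + 1,
                          variance_multiplier=multiplier, seed=seed)
    draws = np.array([r[1][0, 0] for r in reps[1:]])
    ratio = float(np.var(draws) / (multiplier * sigma2))
    return {"variance_ratio": ratio, "n": n_draws,
            "expected": multiplier * sigma2,
            "observed": float(np.var(draws))}
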