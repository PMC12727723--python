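"""End-to-end orchestration: synthetic data to network statistics.

``run_full`` executes the whole analysis sequence — generate (or ingest)
parcellated voxel data, filter regions, perturb, build profiles and the
MetSiM, reduce to the MS mode, characterize distance structure, fit spatial
null models, extract per-hemisphere principal paths, and compute network
metrics and cross-modal comparisons — and returns a results bundle with a
reproducibility manifest (config echo, seeds, content hashes).
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass
from pathlib import Path

import networkx as nx
import numpy as np

from . import __version__
from ._utils import spawn_seeds, upper_tri
from .embedding import cluster_mode_map, reconstruct_filtered, reduce_mode
from .graph_metrics import binarize, gini, nmi_score, overlap_score, rich_club
from .nulls import distance_density, fit_distance_model, sample_randgeom
from .principal_path import PathSearchConfig, find_principal_path
from .profiles import (compute_metsim, compute_profiles, filter_regions,
                       perturb_voxels, similarity_from_profiles)
from .synthetic import (generate_label_and_expression_maps,
                        generate_parcel_scheme, generate_voxel_metabolites)


@dataclass
class RunConfig:
    """Fully serializable configuration of a pipeline run."""

    seed: int = 7
    n_per_hemisphere: int = 16
    K_pert: int = 10
    min_voxels: int = 8
    variance_multiplier: float = 3.0
    pca_dims: int = 50
    perplexity: float = 30.0
    early_exaggeration: float = 12.0
    n_randgeom: int = 50
    edge_densities: tuple = (0.02, 0.10, 0.18, 0.40)
    rich_club_k: int = 2
    path_M: int = 200
    path_kappa: float = 3.0
    path_len_slack: int = 4     # max_len = shortest path + slack
    k_classes: int = 4
    n_genes: int = 100
    label_coupling: float = 0.8


def _hash(arr) -> str:
    return hashlib.sha256(np.ascontiguousarray(arr).tobytes()).hexdigest()[:16]


def _cortical_endpoints(scheme, axis, hemi: str) -> tuple[int, int]:
    mask = (scheme.hemisphere == hemi) & (scheme.superregion == "cortex")
    ids = scheme.parcel_ids[mask]
    ax = axis[mask]
    return int(ids[np.argmin(ax)]), int(ids[np.argmax(ax)])


def run_full(config: RunConfig, outdir: str | Path | None = None) -> dict:
    """Run the complete synthetic-to-results workflow.

    Returns a dict with the intermediate objects, summary statistics, and a
    ``manifest`` recording the configuration, per-stage seeds, wall times
    and content hashes of the key arrays. Deterministic given the config.
    """
    t0 = time.time()
    seeds = spawn_seeds(config.seed, 8)
    stage_log = []

    def log_stage(name, start):
        stage_log.append({"stage": name,
                          "wall_s": round(time.time() - start, 3)})

    t = time.time()
    scheme = generate_parcel_scheme(config.n_per_hemisphere, seed=seeds[0])
    vox, truth = generate_voxel_metabolites(scheme, seed=seeds[1])
    log_stage("synthetic", t)

    t = time.time()
    retained = filter_regions(vox, scheme, min_voxels=config.min_voxels)
    reps = perturb_voxels(vox, config.K_pert,
                          config.variance_multiplier, seed=seeds[2])
    profiles = compute_profiles(reps, scheme, retained)
    metsim = compute_metsim(profiles)
    log_stage("metsim", t)

    t = time.time()
    mode = reduce_mode(metsim.W, pca_dims=config.pca_dims,
                       perplexity=config.perplexity,
                       early_exaggeration=config.early_exaggeration,
                       seed=seeds[3], region_ids=metsim.region_ids,
                       scheme=scheme)
    filtered = reconstruct_filtered(mode)
    log_stage("mode", t)

    t = time.time()
    model = fit_distance_model(metsim, scheme)
    surrogates = sample_randgeom(model, scheme, variant="full",
                                 n=config.n_randgeom, seed=seeds[4])
    density = distance_density(metsim, scheme)
    obs_edges = upper_tri(metsim.W)
    null_rs = [float(np.corrcoef(upper_tri(m), obs_edges)[0, 1])
               for m in surrogates.matrices]
    log_stage("nulls", t)

    t = time.time()
    axis = truth.planted_axis
    path_cfg_base = dict(M=config.path_M, seed=seeds[5],
                         kappa=config.path_kappa)
    paths = {}
    mode_by_id = dict(zip(mode.region_ids, mode.mu))
    for hemi in ("L", "R"):
        g = scheme.graph(hemisphere=hemi, superregions=("cortex",))
        g = g.subgraph([p for p in g.nodes if p in mode_by_id]).copy()
        start, end = _cortical_endpoints(scheme, axis, hemi)
        if start not in g or end not in g or not nx.has_path(g, start, end):
            continue
        max_len = nx.shortest_path_length(g, start, end) + config.path_len_slack
        cfg = PathSearchConfig(max_len=max_len, **path_cfg_base)
        result, table = find_principal_path(mode, scheme, g, start, end, cfg)
        paths[hemi] = {"result": result, "n_candidates": len(table)}
    log_stage("paths", t)

    t = time.time()
    graph_stats = {}
    for rho in config.edge_densities:
        try:
            bg = binarize(metsim.W, rho, node_ids=metsim.region_ids)
        except ValueError:
            continue
        graph_stats[rho] = {"phi": rich_club(bg, config.rich_club_k),
                            "density": bg.edge_density}
    log_stage("graph_metrics", t)

    t = time.time()
    labels, expression = generate_label_and_expression_maps(
        scheme, config.k_classes, config.n_genes, config.label_coupling,
        seed=seeds[6])
    coexpr = similarity_from_profiles(expression.T, method="pearson",
                                      region_ids=scheme.parcel_ids)
    clusters = cluster_mode_map(mode, config.k_classes, seed=seeds[7])
    idx = scheme.index_of
    keep = np.asarray([idx[int(r)] for r in mode.region_ids])
    score, _ = overlap_score(labels[keep], clusters)
    nmi = nmi_score(labels[keep], clusters)
    log_stage("cross_modal", t)

    manifest = {
        "package_version": __version__,
        "config": asdict(config),
        "stage_seeds": seeds,
        "stages": stage_log,
        "hashes": {
            "centroids": _hash(scheme.centroids),
            "metsim": _hash(metsim.W),
            "mode": _hash(mode.mu),
        },
        "n_regions_retained": int(len(retained)),
        "total_wall_s": round(time.time() - t0, 3),
    }
    results = {
        "scheme": scheme, "voxdata": vox, "truth": truth,
        "profiles": profiles, "metsim": metsim, "mode": mode,
        "filtered": filtered, "distance_model": model,
        "randgeom": surrogates, "randgeom_correlations": null_rs,
        "distance_density": density, "paths": paths,
        "rich_club": graph_stats,
        "gini_parcel_sizes": gini(scheme.n_voxels),
        "labels": labels, "coexpression": coexpr,
        "mode_clusters": clusters,
        "overlap_score": score, "nmi": nmi,
        "manifest": manifest,
    }
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        scheme.to_tsv(outdir / "scheme.tsv", outdir / "adjacency.tsv")
        metsim.to_csv(outdir / "metsim.csv")
        mode.to_tsv(outdir / "mode.tsv")
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2)
    return results
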