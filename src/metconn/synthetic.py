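"""Synthetic parcellated MRSI data with planted structure.

The generator emulates the statistical features the analysis pipeline
assumes of real spectroscopic-imaging derivatives:

* a bilaterally symmetric parcel scheme (~210 parcels at default scale):
  cortical parcels on a deformed ellipsoidal shell per hemisphere, plus
  interior subcortical, cerebellar and brainstem clusters, so that "nearby
  but non-adjacent" configurations (e.g. cerebellum vs. occipital shell)
  exist;
* five metabolite fields (tNAA, tCr, Glx, Cho, Ins) that combine a planted
  monotone caudal-to-rostral axis, a cortical/subcortical contrast with a
  tNAA/Cho reversal, a spatially autocorrelated random field, and
  heteroscedastic voxel noise with CRLB-style per-voxel variances;
* a distance-decaying structural-connectivity backbone (streamline counts,
  lengths, node volumes);
* categorical label maps and gene-expression profiles coupled to the
  planted axis, for cross-modal comparison operators.

All randomness flows from a single integer seed through
``numpy.random.SeedSequence`` spawning, so regeneration is bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy.sparse.csgraph import minimum_spanning_tree
from scipy.spatial.distance import cdist

from .scheme import ParcelScheme

#: Canonical metabolite order used by every profile-valued matrix.
METABOLITES = ("tNAA", "tCr", "Glx", "Cho", "Ins")


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class GeometryConfig:
    """Geometry of the synthetic parcel scheme (all lengths in mm)."""

    shell_semiaxes: tuple = (42.0, 80.0, 58.0)  # x (hemi width), y, z
    shell_jitter: float = 0.04                  # radial jitter, fraction
    midline_gap: float = 4.0                    # cortical shell offset from x=0
    cortex_fraction: float = 0.72
    subcortex_fraction: float = 0.15
    cerebellum_fraction: float = 0.08           # remainder -> brainstem
    subcortex_center: tuple = (14.0, -8.0, 2.0)
    subcortex_sd: tuple = (5.0, 9.0, 7.0)
    cerebellum_center: tuple = (16.0, -62.0, -38.0)
    cerebellum_sd: tuple = (7.0, 7.0, 6.0)
    brainstem_center: tuple = (4.0, -28.0, -28.0)
    brainstem_sd: tuple = (1.5, 4.0, 6.0)
    adjacency_factor: float = 2.2               # x median NN distance
    voxel_count_median: float = 30.0
    voxel_count_sigma: float = 0.35             # lognormal sigma (Gini ~ 0.2)


@dataclass
class TruthConfig:
    """Planted metabolic structure.

    All five metabolites are driven by a single latent score — the planted
    axis — combining the caudal-to-rostral centroid coordinate with a
    ``noncortical_shift`` that displaces subcortical, cerebellar and
    brainstem parcels along the same score. Because the metabolite slopes
    have opposite signs for tNAA and Cho, this one-dimensional family
    carries both the monotone spatial gradient and the cortical/subcortical
    tNAA/Cho reversal, mirroring how the two phenomena coincide in real
    metabolite maps. ``voxel_cv`` is the within-parcel voxel noise and
    ``crlb_cv`` sets per-voxel variance estimates proportional to the
    signal.
    """

    base: dict = field(default_factory=lambda: {
        "tNAA": 10.0, "tCr": 8.0, "Glx": 9.0, "Cho": 3.0, "Ins": 5.0})
    axis_slope: dict = field(default_factory=lambda: {
        "tNAA": -0.50, "tCr": -0.15, "Glx": -0.30, "Cho": 0.50, "Ins": 0.25})
    noncortical_shift: float = 0.5  # latent-score offset of non-cortex
    field_scale: float = 0.02       # spatially correlated field, fraction
    field_length_mm: float = 25.0   # Gaussian smoothing length scale
    voxel_cv: float = 0.05          # voxel-to-voxel noise, fraction of mean
    crlb_cv: float = 0.08           # sqrt(sigma2)/Y reported per voxel


@dataclass
class SCConfig:
    """Distance-decaying streamline-count generator."""

    intensity: float = 80.0        # Poisson rate at zero distance
    decay_per_mm: float = 0.06
    adjacent_rate: float = 40.0    # extra rate on gray-matter-adjacent pairs
    length_jitter: float = 0.05    # positive jitter on streamline lengths
    voxel_volume_mm3: float = 125.0  # 5 mm isotropic voxels


# ---------------------------------------------------------------------------
# data containers
# ---------------------------------------------------------------------------

@dataclass
class VoxelMetaboliteData:
    """Per-parcel bags of voxel metabolite signals and variance estimates.

    ``signals[pid]`` and ``variances[pid]`` are ``(n_voxels, 5)`` arrays in
    the canonical metabolite order; voxel positions are not materialized.
    """

    parcel_ids: np.ndarray
    signals: dict
    variances: dict
    metabolites: tuple = METABOLITES

    def validate(self, scheme: ParcelScheme | None = None) -> None:
        for pid in self.parcel_ids:
            y = self.signals[int(pid)]
            s2 = self.variances[int(pid)]
            if y.shape != s2.shape or y.shape[1] != len(self.metabolites):
                raise ValueError(f"shape mismatch in parcel {pid}")
            if np.any(s2 < 0):
                raise ValueError(f"negative variance in parcel {pid}")
        if scheme is not None:
            for pid, nv in zip(scheme.parcel_ids, scheme.n_voxels):
                if self.signals[int(pid)].shape[0] != nv:
                    raise ValueError(f"voxel count mismatch in parcel {pid}")

    def voxel_counts(self) -> dict:
        return {int(p): self.signals[int(p)].shape[0] for p in self.parcel_ids}


@dataclass
class SyntheticTruth:
    """Ground truth planted by the generator, for parameter-recovery tests."""

    planted_axis: np.ndarray      # scalar per parcel, caudal (0) -> rostral (1)
    planted_class: np.ndarray     # categorical per parcel
    generator_params: dict


@dataclass
class StructuralInputs:
    """Raw structural-connectivity ingredients (before the weight formula)."""

    parcel_ids: np.ndarray
    ns: np.ndarray        # symmetric integer streamline counts
    lengths: np.ndarray   # mean streamline length per pair, mm
    volumes: np.ndarray   # node volumes, mm^3
    rates: np.ndarray     # expected counts (generator diagnostic)


# ---------------------------------------------------------------------------
# parcel scheme
# ---------------------------------------------------------------------------

def _allocate_counts(n: int, geo: GeometryConfig) -> dict:
    n_c = max(2, int(round(geo.cortex_fraction * n)))
    n_s = max(1, int(round(geo.subcortex_fraction * n)))
    n_cb = int(round(geo.cerebellum_fraction * n))
    n_bs = n - n_c - n_s - n_cb
    while n_bs < 0:  # tiny schemes: shrink optional groups first
        if n_cb > 0:
            n_cb -= 1
        elif n_s > 1:
            n_s -= 1
        else:
            n_c -= 1
        n_bs = n - n_c - n_s - n_cb
    return {"cortex": n_c, "subcortex": n_s, "cerebellum": n_cb,
            "brainstem": n_bs}


def _cortical_lobe(y: float, z: float) -> str:
    if y < -40:
        return "occipital"
    if y < 10:
        return "temporal" if z < 0 else "parietal"
    return "frontal"


def generate_parcel_scheme(n_per_hemisphere: int,
                           geometry: GeometryConfig | None = None,
                           seed: int = 0) -> ParcelScheme:
    """Generate a mirror-symmetric synthetic parcel scheme.

    Right-hemisphere parcels are sampled (cortex on a jittered ellipsoidal
    shell, subcortex/cerebellum/brainstem as interior Gaussian clusters) and
    mirrored about the x=0 plane to produce the left hemisphere, so every
    parcel has a homotopic partner. Gray-matter adjacency connects parcels
    within ``adjacency_factor`` times the median nearest-neighbour distance;
    per-hemisphere minimum-spanning-tree edges are added so each hemisphere
    graph is guaranteed connected.
    """
    if n_per_hemisphere < 4:
        raise ValueError("need at least 4 parcels per hemisphere")
    geo = geometry or GeometryConfig()
    rng = np.random.default_rng(seed)
    counts = _allocate_counts(n_per_hemisphere, geo)

    pts, supers = [], []
    # cortex: shell points with x > 0
    v = rng.normal(size=(counts["cortex"], 3))
    v[:, 0] = np.abs(v[:, 0]) + 1e-9
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    radii = 1.0 + geo.shell_jitter * rng.normal(size=(counts["cortex"], 1))
    shell = v * np.asarray(geo.shell_semiaxes) * radii
    shell[:, 0] += geo.midline_gap
    pts.append(shell)
    supers += ["cortex"] * counts["cortex"]
    # interior clusters
    for name, center, sd in (
            ("subcortex", geo.subcortex_center, geo.subcortex_sd),
            ("cerebellum", geo.cerebellum_center, geo.cerebellum_sd),
            ("brainstem", geo.brainstem_center, geo.brainstem_sd)):
        k = counts[name]
        if k == 0:
            continue
        c = np.asarray(center) + np.asarray(sd) * rng.normal(size=(k, 3))
        c[:, 0] = np.maximum(c[:, 0], 0.5)  # stay in the right hemisphere
        pts.append(c)
        supers += [name] * k
    right = np.vstack(pts)
    supers = np.asarray(supers, dtype=object)

    left = right.copy()
    left[:, 0] *= -1.0
    centroids = np.vstack([left, right])
    n = n_per_hemisphere
    hemisphere = np.asarray(["L"] * n + ["R"] * n, dtype=object)
    superregion = np.concatenate([supers, supers])
    lobe = np.asarray(
        [_cortical_lobe(p[1], p[2]) if s == "cortex" else str(s)
         for p, s in zip(centroids, superregion)], dtype=object)

    parcel_ids = np.arange(1, 2 * n + 1)
    homotopic = {}
    for i in range(n):
        homotopic[int(parcel_ids[i])] = int(parcel_ids[i + n])
        homotopic[int(parcel_ids[i + n])] = int(parcel_ids[i])
    names = tuple(f"{s[:4]}_{h}_{i:03d}"
                  for i, (s, h) in enumerate(zip(superregion, hemisphere), 1))

    nvox_r = np.maximum(1, np.round(rng.lognormal(
        np.log(geo.voxel_count_median), geo.voxel_count_sigma, size=n))
    ).astype(int)
    nvox_l = np.maximum(1, np.round(rng.lognormal(
        np.log(geo.voxel_count_median), geo.voxel_count_sigma, size=n))
    ).astype(int)
    n_voxels = np.concatenate([nvox_l, nvox_r])

    # adjacency: distance threshold plus per-hemisphere MST for connectivity
    D = cdist(centroids, centroids)
    np.fill_diagonal(D, np.inf)
    nn = D.min(axis=1)
    thresh = geo.adjacency_factor * np.median(nn)
    edges = set()
    for i in range(2 * n):
        for j in range(i + 1, 2 * n):
            if D[i, j] <= thresh:
                edges.add((int(parcel_ids[i]), int(parcel_ids[j])))
    for block in (slice(0, n), slice(n, 2 * n)):
        sub = D[block, block].copy()
        sub[~np.isfinite(sub)] = 0.0
        mst = minimum_spanning_tree(sub).tocoo()
        offset = block.start
        for a, b in zip(mst.row, mst.col):
            i, j = sorted((int(parcel_ids[a + offset]),
                           int(parcel_ids[b + offset])))
            edges.add((i, j))

    scheme = ParcelScheme(
        parcel_ids=parcel_ids, names=names, hemisphere=hemisphere,
        superregion=superregion, lobe=lobe, centroids=centroids,
        n_voxels=n_voxels, adjacency=frozenset(edges), homotopic=homotopic)
    for hemi in ("L", "R"):
        g = scheme.graph(hemisphere=hemi)
        if not nx.is_connected(g):
            raise RuntimeError(
                f"hemisphere {hemi} adjacency graph disconnected "
                f"({nx.number_connected_components(g)} components); "
                "increase adjacency_factor")
    return scheme


# ---------------------------------------------------------------------------
# metabolite fields
# ---------------------------------------------------------------------------

def planted_axis_from_scheme(scheme: ParcelScheme) -> np.ndarray:
    """The caudal-to-rostral axis: min-max normalized y centroid coordinate."""
    y = scheme.centroids[:, 1]
    span = y.max() - y.min()
    if span == 0:
        return np.zeros_like(y)
    return (y - y.min()) / span


def _smooth_field(centroids: np.ndarray, length_mm: float,
                  rng: np.random.Generator) -> np.ndarray:
    """Gaussian-kernel-smoothed iid field, standardized to unit variance."""
    eps = rng.normal(size=len(centroids))
    D = cdist(centroids, centroids)
    K = np.exp(-D**2 / (2 * length_mm**2))
    f = K @ eps / K.sum(axis=1)
    sd = f.std()
    return f / sd if sd > 0 else f


def generate_voxel_metabolites(scheme: ParcelScheme,
                               truth_cfg: TruthConfig | None = None,
                               seed: int = 0
                               ) -> tuple[VoxelMetaboliteData, SyntheticTruth]:
    """Generate voxel-level metabolite signals with planted structure.

    Each parcel's mean signal per metabolite is a smooth function of the
    planted caudal-to-rostral axis plus a superregion contrast and a
    spatially correlated random field; voxel signals add independent
    Gaussian noise (``voxel_cv``), and per-voxel variance estimates are set
    proportional to the signal (``crlb_cv``).
    """
    cfg = truth_cfg or TruthConfig()
    if cfg.voxel_cv < 0 or cfg.crlb_cv < 0 or cfg.field_scale < 0:
        raise ValueError("noise scales must be nonnegative")
    rng = np.random.default_rng(seed)
    noncortical = ~(scheme.superregion == "cortex")
    score = planted_axis_from_scheme(scheme) \
        + cfg.noncortical_shift * noncortical
    span = np.ptp(score)
    axis = (score - score.min()) / span if span > 0 else np.zeros_like(score)

    parcel_means = np.zeros((len(scheme), len(METABOLITES)))
    for mi, m in enumerate(METABOLITES):
        fld = _smooth_field(scheme.centroids, cfg.field_length_mm, rng)
        rel = (1.0 + cfg.axis_slope[m] * (axis - 0.5)
               + cfg.field_scale * fld)
        parcel_means[:, mi] = np.maximum(cfg.base[m] * rel, 0.05 * cfg.base[m])

    signals, variances = {}, {}
    for i, pid in enumerate(scheme.parcel_ids):
        nv = int(scheme.n_voxels[i])
        noise = rng.normal(size=(nv, len(METABOLITES)))
        y = parcel_means[i] * (1.0 + cfg.voxel_cv * noise)
        y = np.maximum(y, 1e-9)
        signals[int(pid)] = y
        variances[int(pid)] = (cfg.crlb_cv * y) ** 2

    vox = VoxelMetaboliteData(parcel_ids=scheme.parcel_ids.copy(),
                              signals=signals, variances=variances)
    vox.validate(scheme)
    truth = SyntheticTruth(
        planted_axis=axis,
        planted_class=scheme.superregion.copy(),
        generator_params={**asdict(cfg), "seed": seed})
    return vox, truth


# ---------------------------------------------------------------------------
# structural connectivity
# ---------------------------------------------------------------------------

def generate_structural_connectivity(scheme: ParcelScheme,
                                     cfg: SCConfig | None = None,
                                     seed: int = 0) -> StructuralInputs:
    """Distance-decaying streamline counts, lengths and node volumes.

    Expected counts follow ``intensity * exp(-decay_per_mm * d)`` with an
    extra ``adjacent_rate`` on gray-matter-adjacent pairs; realized counts
    are Poisson draws, symmetric by construction. Lengths are centroid
    distances with positive multiplicative jitter; volumes scale with voxel
    counts.
    """
    cfg = cfg or SCConfig()
    if cfg.intensity < 0 or cfg.adjacent_rate < 0 or cfg.decay_per_mm < 0:
        raise ValueError("rates must be nonnegative")
    rng = np.random.default_rng(seed)
    n = len(scheme)
    D = scheme.distance_matrix()
    A = scheme.adjacency_matrix()
    with np.errstate(invalid="ignore"):
        decay = np.exp(-cfg.decay_per_mm * D)
    decay[~np.isfinite(decay)] = 0.0
    rates = cfg.intensity * decay + cfg.adjacent_rate * A
    np.fill_diagonal(rates, 0.0)

    ns = np.zeros((n, n), dtype=int)
    iu = np.triu_indices(n, k=1)
    ns[iu] = rng.poisson(rates[iu])
    ns = ns + ns.T

    lengths = D * (1.0 + np.abs(cfg.length_jitter * rng.normal(size=(n, n))))
    lengths = (lengths + lengths.T) / 2.0
    np.fill_diagonal(lengths, 0.0)
    volumes = scheme.n_voxels.astype(float) * cfg.voxel_volume_mm3
    return StructuralInputs(parcel_ids=scheme.parcel_ids.copy(), ns=ns,
                            lengths=lengths, volumes=volumes, rates=rates)


# ---------------------------------------------------------------------------
# labels and expression
# ---------------------------------------------------------------------------

def generate_label_and_expression_maps(scheme: ParcelScheme,
                                       k_classes: int,
                                       n_genes: int,
                                       coupling: float,
                                       seed: int = 0,
                                       axis: np.ndarray | None = None
                                       ) -> tuple[np.ndarray, np.ndarray]:
    """Synthetic categorical labels and gene-expression profiles.

    Labels are quantile bands of the planted axis with a ``1 - coupling``
    uniform flip rate; expression profiles are linear mixtures of the axis
    (weight ``coupling``) and independent Gaussian noise, one row per gene.
    """
    n = len(scheme)
    if not (2 <= k_classes <= n):
        raise ValueError("k_classes must be in [2, n parcels]")
    if not (0.0 <= coupling <= 1.0):
        raise ValueError("coupling must be in [0, 1]")
    rng = np.random.default_rng(seed)
    if axis is None:
        axis = planted_axis_from_scheme(scheme)

    order = np.argsort(axis, kind="stable")
    ranks = np.empty(n, dtype=int)
    ranks[order] = np.arange(n)
    labels = np.minimum((ranks * k_classes) // n, k_classes - 1).astype(int)
    flip = rng.random(n) >= coupling
    labels[flip] = rng.integers(0, k_classes, size=int(flip.sum()))

    axis_z = (axis - axis.mean()) / (axis.std() or 1.0)
    w = rng.normal(size=(n_genes, 1))
    noise = rng.normal(size=(n_genes, n))
    expression = (coupling * w * axis_z[None, :]
                  + np.sqrt(max(1.0 - coupling**2, 0.0)) * noise)
    return labels, expression


# ---------------------------------------------------------------------------
# voxel-data I/O (long-format TSV)
# ---------------------------------------------------------------------------

def voxels_to_tsv(vox: VoxelMetaboliteData, path) -> None:
    rows = []
    for pid in vox.parcel_ids:
        y = vox.signals[int(pid)]
        s2 = vox.variances[int(pid)]
        for vi in range(y.shape[0]):
            for mi, m in enumerate(vox.metabolites):
                rows.append((int(pid), vi, m, y[vi, mi], s2[vi, mi]))
    pd.DataFrame(rows, columns=["parcel_id", "voxel_index", "metabolite",
                                "Y", "sigma2"]).to_csv(path, sep="\t",
                                                       index=False)


def voxels_from_tsv(path) -> VoxelMetaboliteData:
    df = pd.read_csv(Path(path), sep="\t")
    signals, variances = {}, {}
    parcel_ids = np.asarray(sorted(df["parcel_id"].unique()))
    m_index = {m: i for i, m in enumerate(METABOLITES)}
    for pid, grp in df.groupby("parcel_id"):
        nv = int(grp["voxel_index"].max()) + 1
        y = np.zeros((nv, len(METABOLITES)))
        s2 = np.zeros((nv, len(METABOLITES)))
        for _, r in grp.iterrows():
            y[int(r["voxel_index"]), m_index[r["metabolite"]]] = r["Y"]
            s2[int(r["voxel_index"]), m_index[r["metabolite"]]] = r["sigma2"]
        signals[int(pid)] = y
        variances[int(pid)] = s2
    return VoxelMetaboliteData(parcel_ids=parcel_ids, signals=signals,
                               variances=variances)
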