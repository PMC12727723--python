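"""Metabolic profiles and the metabolic similarity matrix (MetSiM).

The pipeline estimates a 5-metabolite profile per brain region (parcel
median of voxel signals, z-scored across regions), propagates quantification
uncertainty by Monte-Carlo perturbation of voxel signals with their
CRLB-derived variances, and correlates regional profiles with Spearman rank
correlation to obtain a symmetric region-by-region similarity matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from ._utils import fisher_aggregate, fisher_z, spawn_seeds, spearman_matrix, upper_tri
from .scheme import ParcelScheme
from .synthetic import METABOLITES, VoxelMetaboliteData

#: Perturbation draws use variance = DEFAULT_VARIANCE_MULTIPLIER * sigma2.
DEFAULT_VARIANCE_MULTIPLIER = 3.0


@dataclass
class MetabolicProfileSet:
    """Regions x (metabolites x perturbations) z-scored profile matrix.

    Columns are metabolite-major: column ``m * K_pert + k`` holds replicate
    ``k`` of metabolite ``m``. Within each column, values are z-scored across
    the retained regions.
    """

    region_ids: np.ndarray
    Z: np.ndarray
    K_pert: int
    metabolites: tuple = METABOLITES

    def columns_for(self, metabolite: str) -> np.ndarray:
        m = self.metabolites.index(metabolite)
        return np.arange(m * self.K_pert, (m + 1) * self.K_pert)

    def drop_metabolite(self, metabolite: str) -> "MetabolicProfileSet":
        keep = np.setdiff1d(np.arange(self.Z.shape[1]),
                            self.columns_for(metabolite))
        rest = tuple(m for m in self.metabolites if m != metabolite)
        return MetabolicProfileSet(region_ids=self.region_ids,
                                   Z=self.Z[:, keep], K_pert=self.K_pert,
                                   metabolites=rest)


@dataclass
class MetSiM:
    """Symmetric region x region similarity matrix with unit diagonal."""

    region_ids: np.ndarray
    W: np.ndarray

    def validate(self) -> None:
        W = self.W
        if W.shape[0] != W.shape[1] or W.shape[0] != len(self.region_ids):
            raise ValueError("W must be square and match region ids")
        if not np.allclose(W, W.T, atol=1e-10):
            raise ValueError("W must be symmetric")
        if not np.allclose(np.diag(W), 1.0, atol=1e-10):
            raise ValueError("diagonal must be 1")
        if np.nanmax(np.abs(W)) > 1 + 1e-10:
            raise ValueError("entries must lie in [-1, 1]")

    def to_csv(self, path) -> None:
        pd.DataFrame(self.W, index=self.region_ids,
                     columns=self.region_ids).to_csv(path)

    @classmethod
    def from_csv(cls, path) -> "MetSiM":
        df = pd.read_csv(path, index_col=0)
        return cls(region_ids=df.index.to_numpy(), W=df.to_numpy(dtype=float))


# ---------------------------------------------------------------------------
# region filtering
# ---------------------------------------------------------------------------

def filter_regions(voxdata: VoxelMetaboliteData,
                   scheme: ParcelScheme,
                   min_voxels: int = 8,
                   max_missing_fraction: float = 0.7,
                   coverage_per_subject: pd.DataFrame | None = None
                   ) -> np.ndarray:
    """Retain regions with enough voxels and adequate cohort coverage.

    A region is kept when it contains at least ``min_voxels`` voxels and,
    when a cohort coverage table is given (subjects x regions, truthy =
    covered), is missing in at most ``max_missing_fraction`` of subjects.
    """
    if min_voxels < 1 or not (0 <= max_missing_fraction <= 1):
        raise ValueError("thresholds out of range")
    counts = voxdata.voxel_counts()
    retained = [int(p) for p in scheme.parcel_ids
                if counts.get(int(p), 0) >= min_voxels]
    if coverage_per_subject is not None:
        cov = coverage_per_subject
        n_subj = cov.shape[0]
        retained = [p for p in retained
                    if p not in cov.columns
                    or (n_subj - cov[p].astype(bool).sum()) / n_subj
                    <= max_missing_fraction]
    if not retained:
        raise ValueError("no regions survive the filter")
    return np.asarray(retained)


# ---------------------------------------------------------------------------
# Monte-Carlo perturbation
# ---------------------------------------------------------------------------

def perturb_voxels(voxdata: VoxelMetaboliteData,
                   K_pert: int,
                   variance_multiplier: float = DEFAULT_VARIANCE_MULTIPLIER,
                   seed: int = 0) -> list[dict]:
    """Draw ``K_pert`` voxel-signal replicates for uncertainty propagation.

    Replicate 0 is the unperturbed data; replicates 1..K_pert-1 resample each
    voxel signal from ``Normal(Y, variance_multiplier * sigma2)``
    independently per voxel and metabolite.

    Returns a list of ``K_pert`` dicts mapping parcel id -> (n_voxels, 5)
    signal arrays.
    """
    if K_pert < 1:
        raise ValueError("K_pert must be >= 1")
    if variance_multiplier < 0:
        raise ValueError("variance multiplier must be nonnegative")
    replicates = [{int(p): voxdata.signals[int(p)].copy()
                   for p in voxdata.parcel_ids}]
    seeds = spawn_seeds(seed, max(K_pert - 1, 1))
    for k in range(1, K_pert):
        rng = np.random.default_rng(seeds[k - 1])
        rep = {}
        for p in voxdata.parcel_ids:
            y = voxdata.signals[int(p)]
            sd = np.sqrt(variance_multiplier * voxdata.variances[int(p)])
            rep[int(p)] = rng.normal(y, sd)
        replicates.append(rep)
    return replicates


# ---------------------------------------------------------------------------
# profiles and similarity
# ---------------------------------------------------------------------------

def compute_profiles(replicates: list[dict],
                     scheme: ParcelScheme,
                     retained_ids: np.ndarray) -> MetabolicProfileSet:
    """Parcel medians z-scored across regions, per replicate and metabolite.

    The even-voxel-count median is the mean of the two central order
    statistics. Columns are concatenated metabolite-major, replicate-minor.
    """
    retained = np.asarray(retained_ids)
    K = len(replicates)
    n = len(retained)
    n_met = len(METABOLITES)
    Z = np.empty((n, n_met * K))
    for k, rep in enumerate(replicates):
        med = np.stack([np.median(rep[int(p)], axis=0) for p in retained])
        for m in range(n_met):
            col = med[:, m]
            sd = col.std()
            if sd == 0:
                raise ValueError(
                    f"degenerate z-score: metabolite {METABOLITES[m]} "
                    f"replicate {k} constant across regions")
            Z[:, m * K + k] = (col - col.mean()) / sd
    return MetabolicProfileSet(region_ids=retained, Z=Z, K_pert=K)


def compute_metsim(profiles: MetabolicProfileSet,
                   replicate_mode: str = "concatenate") -> MetSiM:
    """Pairwise Spearman correlations between regional metabolic profiles.

    ``replicate_mode="concatenate"`` (default) correlates the full
    5*K_pert-column profile vectors, so the perturbation replicates enlarge
    the rank-correlation sample size; ``"average"`` instead computes one
    Spearman matrix per replicate and averages them.
    """
    Z = profiles.Z
    if Z.shape[1] < 3:
        raise ValueError("Spearman correlation needs at least 3 columns")
    for i, rid in enumerate(profiles.region_ids):
        if np.ptp(Z[i]) == 0:
            raise ValueError(f"constant profile for region {rid}: "
                             "rank correlation undefined")
    if replicate_mode == "concatenate":
        W = spearman_matrix(Z)
    elif replicate_mode == "average":
        K = profiles.K_pert
        n_met = len(profiles.metabolites)
        mats = []
        for k in range(K):
            cols = np.arange(n_met) * K + k
            mats.append(spearman_matrix(Z[:, cols]))
        W = np.mean(mats, axis=0)
    else:
        raise ValueError(f"unknown replicate_mode {replicate_mode!r}")
    W = np.clip((W + W.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(W, 1.0)
    out = MetSiM(region_ids=np.asarray(profiles.region_ids), W=W)
    out.validate()
    return out


def similarity_from_profiles(X: np.ndarray, method: str = "pearson",
                             region_ids: np.ndarray | None = None) -> MetSiM:
    """Generic profile-similarity engine (rows = regions, columns = features).

    Reused for gene co-expression (Pearson) and cytoarchitectonic profile
    similarity; ``method="spearman"`` reproduces the MetSiM construction.
    """
    X = np.asarray(X, dtype=float)
    if X.shape[1] < 2:
        raise ValueError("need at least 2 columns")
    for i in range(X.shape[0]):
        if np.ptp(X[i]) == 0:
            raise ValueError(f"constant profile in row {i}")
    if method == "pearson":
        W = np.corrcoef(X)
    elif method == "spearman":
        W = spearman_matrix(X)
    else:
        raise ValueError(f"unknown method {method!r}")
    W = np.clip((W + W.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(W, 1.0)
    ids = region_ids if region_ids is not None else np.arange(X.shape[0])
    return MetSiM(region_ids=np.asarray(ids), W=W)


def group_average_metsim(matrices: list[MetSiM]) -> MetSiM:
    """Element-wise mean of individual MetSiMs over an identical region set."""
    if not matrices:
        raise ValueError("empty list")
    ref = matrices[0].region_ids
    for m in matrices[1:]:
        if not np.array_equal(m.region_ids, ref):
            raise ValueError("region sets/ordering differ between subjects")
    W = np.mean([m.W for m in matrices], axis=0)
    np.fill_diagonal(W, 1.0)
    return MetSiM(region_ids=np.asarray(ref), W=W)


# ---------------------------------------------------------------------------
# stability statistics
# ---------------------------------------------------------------------------

def edgewise_consistency(individual: list[MetSiM], reference: MetSiM,
                         alpha: float = 0.05) -> pd.DataFrame:
    """Per-subject edge-wise agreement with a reference MetSiM.

    For each subject the upper-triangle edges are Pearson-correlated with
    the reference; correlations are aggregated across subjects through the
    Fisher z-transform and p-values are Benjamini-Hochberg adjusted. Returns
    a tidy frame with one row per subject plus an ``aggregate`` row.
    """
    if len(individual) < 2:
        raise ValueError("need at least 2 subjects")
    ref_edges = upper_tri(reference.W)
    if np.ptp(ref_edges) == 0:
        raise ValueError("constant reference edge vector")
    rows = []
    for s, m in enumerate(individual):
        edges = upper_tri(m.W)
        if np.ptp(edges) == 0:
            raise ValueError(f"constant edge vector for subject {s}")
        r, p = stats.pearsonr(edges, ref_edges)
        rows.append({"subject": s, "r": r, "z": float(fisher_z(r)), "p": p})
    df = pd.DataFrame(rows)
    rejected, p_adj, _, _ = multipletests(df["p"], alpha=alpha,
                                          method="fdr_bh")
    df["p_adj"] = p_adj
    df["significant"] = rejected
    agg = pd.DataFrame([{"subject": "aggregate",
                         "r": fisher_aggregate(df["r"]),
                         "z": float(np.mean(df["z"])),
                         "p": np.nan, "p_adj": np.nan,
                         "significant": bool(rejected.all())}])
    return pd.concat([df, agg], ignore_index=True)


def leave_one_metabolite_out(voxdata: VoxelMetaboliteData,
                             scheme: ParcelScheme,
                             K_pert: int,
                             seed: int = 0,
                             retained_ids: np.ndarray | None = None,
                             variance_multiplier: float = DEFAULT_VARIANCE_MULTIPLIER,
                             min_voxels: int = 8) -> dict:
    """Influence of each metabolite on the MetSiM.

    Rebuilds the similarity matrix from the remaining four metabolites (the
    perturbation draws are shared with the full matrix, so the comparison
    isolates the removed metabolite) and reports the edge-wise Pearson
    correlation with the 5-metabolite MetSiM.
    """
    if retained_ids is None:
        retained_ids = filter_regions(voxdata, scheme, min_voxels=min_voxels)
    reps = perturb_voxels(voxdata, K_pert, variance_multiplier, seed)
    profiles = compute_profiles(reps, scheme, retained_ids)
    full = compute_metsim(profiles)
    full_edges = upper_tri(full.W)
    out = {}
    for m in METABOLITES:
        reduced = compute_metsim(profiles.drop_metabolite(m))
        r, _ = stats.pearsonr(upper_tri(reduced.W), full_edges)
        out[m] = float(r)
    return out


def aggregate_leave_one_out(per_subject: list[dict]) -> dict:
    """Fisher-aggregate per-metabolite leave-one-out correlations."""
    out = {}
    for m in METABOLITES:
        out[m] = fisher_aggregate([d[m] for d in per_subject])
    return out
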