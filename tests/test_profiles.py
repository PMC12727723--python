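"""Profiles, perturbation, and MetSiM construction."""

import numpy as np
import pytest
from scipy import stats

import metconn as mc
from metconn._utils import upper_tri
from metconn.profiles import MetabolicProfileSet, MetSiM
from metconn.synthetic import METABOLITES, VoxelMetaboliteData


def _make_vox(counts, value=1.0):
    """Uniform-signal voxel data with given per-parcel voxel counts."""
    ids = np.arange(1, len(counts) + 1)
    signals = {int(p): np.full((c, 5), value) for p, c in zip(ids, counts)}
    variances = {int(p): np.zeros((c, 5)) for p, c in zip(ids, counts)}
    return VoxelMetaboliteData(parcel_ids=ids, signals=signals,
                               variances=variances)


class TestFilterRegions:
    def test_seven_voxels_excluded_at_default_threshold(self, small_scheme):
        counts = [7] + [20] * (len(small_scheme) - 1)
        vox = _make_vox(counts)
        vox.parcel_ids = small_scheme.parcel_ids
        vox.signals = {int(p): np.full((c, 5), 1.0)
                       for p, c in zip(small_scheme.parcel_ids, counts)}
        vox.variances = {int(p): np.zeros((c, 5))
                         for p, c in zip(small_scheme.parcel_ids, counts)}
        retained = mc.filter_regions(vox, small_scheme, min_voxels=8)
        assert int(small_scheme.parcel_ids[0]) not in retained
        assert len(retained) == len(small_scheme) - 1

    def test_vacuous_filter_retains_all(self, small_scheme, medium_data):
        vox, _ = mc.generate_voxel_metabolites(small_scheme, seed=1)
        retained = mc.filter_regions(vox, small_scheme, min_voxels=1)
        assert len(retained) == len(small_scheme)

    def test_cohort_coverage_threshold(self, small_scheme):
        import pandas as pd
        vox, _ = mc.generate_voxel_metabolites(small_scheme, seed=2)
        bad = int(small_scheme.parcel_ids[0])
        cov = pd.DataFrame(
            True, index=range(10), columns=small_scheme.parcel_ids)
        cov.loc[0:7, bad] = False   # missing in 8/10 > 0.7
        retained = mc.filter_regions(vox, small_scheme, min_voxels=1,
                                     max_missing_fraction=0.7,
                                     coverage_per_subject=cov)
        assert bad not in retained

    def test_empty_retained_set_errors(self, small_scheme):
        vox, _ = mc.generate_voxel_metabolites(small_scheme, seed=3)
        with pytest.raises(ValueError):
            mc.filter_regions(vox, small_scheme, min_voxels=10**6)


class TestPerturbVoxels:
    def test_zero_variance_gives_identical_replicates(self):
        vox = _make_vox([5, 5], value=2.0)
        reps = mc.perturb_voxels(vox, K_pert=4, seed=1)
        for rep in reps[1:]:
            for p in vox.parcel_ids:
                assert np.array_equal(rep[int(p)], vox.signals[int(p)])

    def test_kpert_one_is_identity(self, small_scheme):
        vox, _ = mc.generate_voxel_metabolites(small_scheme, seed=4)
        reps = mc.perturb_voxels(vox, K_pert=1, seed=5)
        assert len(reps) == 1
        for p in vox.parcel_ids:
            assert np.array_equal(reps[0][int(p)], vox.signals[int(p)])

    def test_monte_carlo_variance_matches_three_sigma2(self):
        # one voxel, many replicates: sample variance ~ multiplier * sigma2
        ids = np.array([1])
        vox = VoxelMetaboliteData(
            parcel_ids=ids, signals={1: np.full((1, 5), 10.0)},
            variances={1: np.full((1, 5), 0.25)})
        reps = mc.perturb_voxels(vox, K_pert=10_001, seed=6)
        draws = np.stack([r[1][0, 0] for r in reps[1:]])
        assert np.var(draws) == pytest.approx(3 * 0.25, rel=0.05)

    def test_negative_multiplier_rejected(self):
        vox = _make_vox([3])
        with pytest.raises(ValueError):
            mc.perturb_voxels(vox, 2, variance_multiplier=-1.0)


class TestComputeProfiles:
    def test_median_before_zscore(self, small_scheme):
        vox, _ = mc.generate_voxel_metabolites(small_scheme, seed=7)
        p1 = int(small_scheme.parcel_ids[0])
        vox.signals[p1][:, :] = 1.0
        vox.signals[p1][:3, 0] = [1.0, 2.0, 100.0]
        vox.signals[p1][3:, 0] = 2.0
        med = np.median(vox.signals[p1], axis=0)
        assert med[0] == 2.0

    def test_two_regions_give_plus_minus_one(self):
        rng = np.random.default_rng(8)
        ids = np.array([1, 2])
        vox = VoxelMetaboliteData(
            parcel_ids=ids,
            signals={1: rng.uniform(1, 2, (4, 5)),
                     2: rng.uniform(3, 4, (4, 5))},
            variances={1: np.zeros((4, 5)), 2: np.zeros((4, 5))})
        reps = mc.perturb_voxels(vox, 1)
        prof = mc.compute_profiles(reps, None, ids)
        assert np.allclose(np.abs(prof.Z), 1.0)

    def test_columns_standardized(self, medium_scheme, medium_data):
        vox, _ = medium_data
        reps = mc.perturb_voxels(vox, 3, seed=9)
        prof = mc.compute_profiles(
            reps, medium_scheme, mc.filter_regions(vox, medium_scheme, 1))
        assert np.allclose(prof.Z.mean(axis=0), 0.0, atol=1e-8)
        assert np.allclose(prof.Z.std(axis=0), 1.0, atol=1e-8)

    def test_constant_column_errors(self):
        vox = _make_vox([3, 3, 3])  # identical parcels -> zero variance
        reps = mc.perturb_voxels(vox, 1)
        with pytest.raises(ValueError, match="degenerate"):
            mc.compute_profiles(reps, None, vox.parcel_ids)


class TestComputeMetsim:
    def test_identical_rows_correlate_perfectly(self):
        base = np.array([0.3, -1.2, 0.5, 1.1, -0.7])
        Z = np.stack([base, base, base * 2 + 1])
        prof = MetabolicProfileSet(region_ids=np.arange(3), Z=Z, K_pert=1)
        W = mc.compute_metsim(prof).W
        assert W[0, 1] == pytest.approx(1.0)
        assert W[0, 2] == pytest.approx(1.0)  # rank-identical

    def test_reversed_ranks_give_minus_one(self):
        a = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        prof = MetabolicProfileSet(region_ids=np.arange(2),
                                   Z=np.stack([a, a[::-1]]), K_pert=1)
        assert mc.compute_metsim(prof).W[0, 1] == pytest.approx(-1.0)

    def test_hand_example_matches_rank_then_pearson_oracle(self, rng):
        Z = rng.normal(size=(3, 5))
        prof = MetabolicProfileSet(region_ids=np.arange(3), Z=Z, K_pert=1)
        W = mc.compute_metsim(prof).W
        for i in range(3):
            for j in range(i + 1, 3):
                ri = stats.rankdata(Z[i])
                rj = stats.rankdata(Z[j])
                expected = stats.pearsonr(ri, rj).statistic
                assert W[i, j] == pytest.approx(expected, abs=1e-12)

    def test_permutation_equivariance(self, medium_metsim, rng):
        # permuting region order permutes rows/columns identically
        n = len(medium_metsim.region_ids)
        perm = rng.permutation(n)
        Z = rng.normal(size=(n, 8))
        prof = MetabolicProfileSet(region_ids=np.arange(n), Z=Z, K_pert=1)
        W = mc.compute_metsim(prof).W
        prof_p = MetabolicProfileSet(region_ids=np.arange(n), Z=Z[perm],
                                     K_pert=1)
        Wp = mc.compute_metsim(prof_p).W
        assert np.allclose(Wp, W[np.ix_(perm, perm)])

    def test_structural_invariants(self, medium_metsim):
        W = medium_metsim.W
        assert np.allclose(W, W.T)
        assert np.allclose(np.diag(W), 1.0)
        assert np.all(np.abs(W) <= 1.0)

    def test_constant_row_names_region(self):
        Z = np.vstack([np.ones(5), np.arange(5.0)])
        prof = MetabolicProfileSet(region_ids=np.array([101, 102]), Z=Z,
                                   K_pert=1)
        with pytest.raises(ValueError, match="101"):
            mc.compute_metsim(prof)

    def test_average_mode_agrees_on_noise_free_replicates(self, medium_scheme,
                                                          medium_data):
        vox, _ = medium_data
        reps = mc.perturb_voxels(vox, 3, variance_multiplier=0.0, seed=1)
        prof = mc.compute_profiles(
            reps, medium_scheme, mc.filter_regions(vox, medium_scheme, 1))
        a = mc.compute_metsim(prof, replicate_mode="concatenate").W
        b = mc.compute_metsim(prof, replicate_mode="average").W
        assert np.allclose(a, b, atol=1e-12)


class TestSimilarityFromProfiles:
    def test_spearman_delegates_to_metsim(self, rng):
        Z = rng.normal(size=(4, 6))
        prof = MetabolicProfileSet(region_ids=np.arange(4), Z=Z, K_pert=1)
        assert np.allclose(mc.similarity_from_profiles(Z, "spearman").W,
                           mc.compute_metsim(prof).W)

    def test_pearson_textbook_three_points(self):
        X = np.array([[1.0, 2.0, 3.0], [2.0, 4.0, 6.0], [3.0, 2.0, 1.0]])
        W = mc.similarity_from_profiles(X, "pearson").W
        assert W[0, 1] == pytest.approx(1.0)
        assert W[0, 2] == pytest.approx(-1.0)


class TestGroupAverage:
    def test_single_matrix_identity(self, medium_metsim):
        avg = mc.group_average_metsim([medium_metsim])
        assert np.allclose(avg.W, medium_metsim.W)

    def test_opposite_offdiagonals_cancel(self, medium_metsim):
        W = medium_metsim.W
        neg = MetSiM(region_ids=medium_metsim.region_ids, W=-W.copy())
        np.fill_diagonal(neg.W, 1.0)
        avg = mc.group_average_metsim([medium_metsim, neg])
        off = ~np.eye(len(W), dtype=bool)
        assert np.allclose(avg.W[off], 0.0)

    def test_region_mismatch_errors(self, medium_metsim):
        other = MetSiM(region_ids=medium_metsim.region_ids + 1,
                       W=medium_metsim.W.copy())
        with pytest.raises(ValueError):
            mc.group_average_metsim([medium_metsim, other])


class TestEdgewiseConsistency:
    def test_identical_subjects_aggregate_to_one(self, medium_metsim):
        df = mc.edgewise_consistency([medium_metsim] * 3, medium_metsim)
        agg = df[df["subject"] == "aggregate"].iloc[0]
        assert agg["r"] == pytest.approx(1.0, abs=1e-9)

    def test_fisher_z_closed_form(self):
        from metconn._utils import fisher_z
        assert float(fisher_z(0.5)) == pytest.approx(np.arctanh(0.5))
        assert float(fisher_z(0.5)) == pytest.approx(0.5493, abs=1e-4)

    def test_bh_step_up_rejects_all_four(self):
        # p = (.01,.02,.03,.04) at q=.05: every p_(i) <= i/4 * .05
        from statsmodels.stats.multitest import multipletests
        rej, _, _, _ = multipletests([0.01, 0.02, 0.03, 0.04], alpha=0.05,
                                     method="fdr_bh")
        assert rej.all()


class TestLeaveOneMetaboliteOut:
    def test_redundant_metabolite_leaves_metsim_unchanged(self):
        # 4-region toy: the removed metabolite (col 0) exactly duplicates
        # another, and every region pair is perfectly rank-concordant or
        # rank-discordant, so the Spearman matrix is invariant to removal
        Z = np.array([[1.0, 1.0, 2.0, 3.0, 4.0],
                      [10.0, 10.0, 20.0, 30.0, 40.0],
                      [2.0, 2.0, 4.0, 6.0, 8.0],
                      [4.0, 4.0, 3.0, 2.0, 1.0]])
        prof = MetabolicProfileSet(region_ids=np.arange(1, 5), Z=Z, K_pert=1)
        full = mc.compute_metsim(prof).W
        reduced = mc.compute_metsim(prof.drop_metabolite("tNAA")).W
        assert np.allclose(full, reduced, atol=1e-12)
        assert full[0, 3] == pytest.approx(-1.0)

    def test_returns_correlation_per_metabolite(self, medium_scheme,
                                                medium_data):
        vox, _ = medium_data
        out = mc.leave_one_metabolite_out(vox, medium_scheme, K_pert=3,
                                          seed=5, min_voxels=1)
        assert set(out) == set(METABOLITES)
        assert all(-1.0 <= v <= 1.0 for v in out.values())
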