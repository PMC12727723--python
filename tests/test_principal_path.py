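"""Gradient field, path statistics, enumeration, and the path search."""

import itertools
import math

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import metconn as mc
from metconn.embedding import ModeMap
from metconn.principal_path import (GradientField, PathSearchConfig,
                                    _is_plausible, rice_bins)
from metconn.scheme import ParcelScheme


def _chain_scheme(mu_vals, spacing=1.0):
    """Collinear parcels 1..n with mode values mu_vals."""
    n = len(mu_vals)
    ids = np.arange(1, n + 1)
    centroids = np.zeros((n, 3))
    centroids[:, 1] = np.arange(n) * spacing
    adjacency = frozenset((int(i), int(i + 1)) for i in ids[:-1])
    scheme = ParcelScheme(
        parcel_ids=ids, names=tuple(f"p{i}" for i in ids),
        hemisphere=np.asarray(["R"] * n, dtype=object),
        superregion=np.asarray(["cortex"] * n, dtype=object),
        lobe=np.asarray(["frontal"] * n, dtype=object),
        centroids=centroids, n_voxels=np.full(n, 10),
        adjacency=adjacency, homotopic={})
    mode = ModeMap(region_ids=ids, mu=np.asarray(mu_vals, dtype=float))
    return scheme, mode


class TestMsGradient:
    def test_flat_field_zero_vector(self):
        scheme, mode = _chain_scheme([0.5, 0.5, 0.5])
        fld = mc.ms_gradient(mode, scheme)
        assert fld.magnitude(1, 2) == 0.0
        assert np.allclose(fld.vector(1, 2), 0.0)

    def test_direct_substitution(self):
        scheme, mode = _chain_scheme([0.0, 1.0], spacing=2.0)
        fld = mc.ms_gradient(mode, scheme)
        assert fld.magnitude(1, 2) == pytest.approx(0.5)  # per mm

    def test_antisymmetry_on_random_fields(self, rng):
        mu = rng.uniform(size=6)
        scheme, mode = _chain_scheme(mu)
        fld = mc.ms_gradient(mode, scheme)
        for i, j in scheme.adjacency:
            # the scalar derivative flips sign; the vector (sign times
            # direction, both of which flip) is reversal-invariant
            assert fld.signed(i, j) == pytest.approx(-fld.signed(j, i))
            assert np.allclose(fld.vector(i, j), fld.vector(j, i))
            assert fld.magnitude(i, j) >= 0

    def test_coincident_centroids_error(self):
        scheme, mode = _chain_scheme([0.0, 1.0])
        scheme = ParcelScheme(
            parcel_ids=scheme.parcel_ids, names=scheme.names,
            hemisphere=scheme.hemisphere, superregion=scheme.superregion,
            lobe=scheme.lobe, centroids=np.zeros((2, 3)),
            n_voxels=scheme.n_voxels, adjacency=scheme.adjacency)
        with pytest.raises(ValueError, match="coincident"):
            mc.ms_gradient(mode, scheme)


class TestPathGradient:
    def test_flat_path_zero(self):
        scheme, mode = _chain_scheme([0.3, 0.3, 0.3])
        fld = mc.ms_gradient(mode, scheme)
        g_mu, g_norm = mc.path_gradient((1, 2, 3), fld)
        assert g_mu == 0.0 and g_norm == 0.0

    def test_hand_evaluation_three_collinear_nodes(self):
        # 1 mm spacing, mu = (0, 0.5, 1): each edge gradient 0.5/mm
        scheme, mode = _chain_scheme([0.0, 0.5, 1.0])
        fld = mc.ms_gradient(mode, scheme)
        g_mu, _ = mc.path_gradient((1, 2, 3), fld)
        assert g_mu == pytest.approx(0.5)

    def test_monotone_linear_sequence_below_random_max(self):
        scheme, mode = _chain_scheme(np.linspace(0, 1, 8))
        fld = mc.ms_gradient(mode, scheme)
        _, g_norm = mc.path_gradient(tuple(range(1, 9)), fld,
                                     PathSearchConfig(M=1000, seed=0))
        assert 0 < g_norm <= 1.0

    def test_affine_invariance_with_rescaled_range(self):
        scheme, mode = _chain_scheme([0.1, 0.7, 0.4, 0.9])
        fld = mc.ms_gradient(mode, scheme)
        cfg = PathSearchConfig(M=500, seed=1, mu_range=(0.1, 0.9))
        g_mu, g_norm = mc.path_gradient((1, 2, 3, 4), fld, cfg)
        scheme2, mode2 = _chain_scheme(2 * np.array([0.1, 0.7, 0.4, 0.9]) + 5)
        fld2 = mc.ms_gradient(mode2, scheme2)
        cfg2 = PathSearchConfig(M=500, seed=1, mu_range=(5.2, 6.8))
        g_mu2, g_norm2 = mc.path_gradient((1, 2, 3, 4), fld2, cfg2)
        assert g_mu2 == pytest.approx(2 * g_mu)       # scales with mu
        assert g_norm2 == pytest.approx(g_norm, rel=1e-9)  # normalizer too

    def test_single_node_path_rejected(self):
        scheme, mode = _chain_scheme([0.0, 1.0])
        fld = mc.ms_gradient(mode, scheme)
        with pytest.raises(ValueError):
            mc.path_gradient((1,), fld)


class TestPathEntropy:
    def test_rice_rule_210_nodes(self):
        assert rice_bins(210) == 12

    def test_single_bin_occupancy_zero_entropy(self):
        scheme, mode = _chain_scheme([0.5, 0.5, 0.5, 0.5])
        # global range is degenerate -> entropy 0 by convention
        h, _ = mc.path_entropy((1, 2, 3, 4), mode)
        assert h == 0.0

    def test_concentrated_values_low_entropy(self):
        mu = np.array([0.01, 0.02, 0.01, 0.02, 0.015, 1.0])
        scheme, mode = _chain_scheme(mu)
        h, _ = mc.path_entropy((1, 2, 3, 4, 5), mode,
                               PathSearchConfig(mu_range=(0.0, 1.0)))
        assert h == 0.0  # all five values in the first bin

    def test_uniform_occupancy_maximal_entropy(self):
        # Rice rule for 4 nodes: ceil(2 * 4^(1/3)) = 4 bins; one value each
        scheme, mode = _chain_scheme([0.1, 0.35, 0.6, 0.85])
        h, n_bins = mc.path_entropy((1, 2, 3, 4), mode,
                                    PathSearchConfig(mu_range=(0.0, 1.0)))
        assert n_bins == 4
        assert h == pytest.approx(1.0)


class TestPathCost:
    def test_zero_gradient_zero_cost(self):
        assert mc.path_cost(0.0, 0.8) == 0.0

    def test_reported_hemisphere_statistics_ratio(self):
        assert mc.path_cost(0.08, 0.79) == pytest.approx(0.1013, abs=2e-4)

    def test_infinite_at_zero_entropy(self):
        assert math.isinf(mc.path_cost(0.5, 0.0))


class TestEnumeratePaths:
    def test_four_cycle_two_paths(self):
        g = nx.cycle_graph([1, 2, 3, 4])  # edges 1-2, 2-3, 3-4, 4-1
        paths = list(mc.enumerate_paths(g, 1, 3))
        assert sorted(paths) == [(1, 2, 3), (1, 4, 3)]

    def test_k4_five_paths(self):
        g = nx.complete_graph([1, 2, 3, 4])
        assert len(list(mc.enumerate_paths(g, 1, 3))) == 5

    def test_max_len_nonadjacent_empty(self):
        g = nx.path_graph([1, 2, 3])
        assert list(mc.enumerate_paths(g, 1, 3, max_len=1)) == []

    def test_deterministic_order(self):
        g = nx.complete_graph([3, 1, 4, 2])
        a = list(mc.enumerate_paths(g, 1, 4))
        b = list(mc.enumerate_paths(g, 1, 4))
        assert a == b

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_matches_networkx_oracle_on_random_graphs(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 9))
        g = nx.gnp_random_graph(n, 0.5, seed=int(rng.integers(1 << 30)))
        nodes = sorted(g.nodes)
        start, end = nodes[0], nodes[-1]
        ours = sorted(mc.enumerate_paths(g, start, end))
        oracle = sorted(tuple(p) for p in
                        nx.all_simple_paths(g, start, end))
        assert ours == oracle


class TestFindPrincipalPath:
    def test_chain_graph_unique_path_optimal(self):
        scheme, mode = _chain_scheme(np.linspace(0, 1, 6))
        g = scheme.graph()
        res, table = mc.find_principal_path(mode, scheme, g, 1, 6,
                                            PathSearchConfig(M=200, seed=2))
        assert res.gamma == (1, 2, 3, 4, 5, 6)
        assert len(table) == 1

    def test_high_gradient_shortcut_not_taken(self):
        # chain 1..5 with an added shortcut 1-5 whose single step jumps the
        # whole mode range: its mean gradient is much higher
        scheme, mode = _chain_scheme(np.linspace(0, 1, 5))
        edges = set(scheme.adjacency) | {(1, 5)}
        scheme = ParcelScheme(
            parcel_ids=scheme.parcel_ids, names=scheme.names,
            hemisphere=scheme.hemisphere, superregion=scheme.superregion,
            lobe=scheme.lobe, centroids=scheme.centroids,
            n_voxels=scheme.n_voxels, adjacency=frozenset(edges))
        g = scheme.graph()
        res, table = mc.find_principal_path(mode, scheme, g, 1, 5,
                                            PathSearchConfig(M=500, seed=3))
        assert res.gamma == (1, 2, 3, 4, 5)
        assert len(table) == 2

    def test_reversal_symmetry(self):
        scheme, mode = _chain_scheme([0.2, 0.9, 0.4, 0.6, 0.1])
        fld = mc.ms_gradient(mode, scheme)
        cfg = PathSearchConfig(M=500, seed=4)
        gamma = (1, 2, 3, 4, 5)
        g_mu_f, _ = mc.path_gradient(gamma, fld, cfg)
        g_mu_b, _ = mc.path_gradient(gamma[::-1], fld, cfg)
        assert g_mu_f == pytest.approx(g_mu_b)
        h_f, _ = mc.path_entropy(gamma, mode, cfg)
        h_b, _ = mc.path_entropy(gamma[::-1], mode, cfg)
        assert h_f == pytest.approx(h_b)

    def test_argmin_invariant_to_enumeration_order(self):
        rng = np.random.default_rng(5)
        n = 7
        g = nx.gnp_random_graph(n, 0.6, seed=11)
        g = nx.relabel_nodes(g, {i: i + 1 for i in range(n)})
        ids = np.arange(1, n + 1)
        centroids = rng.normal(scale=10, size=(n, 3))
        scheme = ParcelScheme(
            parcel_ids=ids, names=tuple(map(str, ids)),
            hemisphere=np.asarray(["R"] * n, dtype=object),
            superregion=np.asarray(["cortex"] * n, dtype=object),
            lobe=np.asarray(["frontal"] * n, dtype=object),
            centroids=centroids, n_voxels=np.full(n, 5),
            adjacency=frozenset(tuple(sorted(e)) for e in g.edges),
            homotopic={})
        mode = ModeMap(region_ids=ids, mu=rng.uniform(size=n))
        cfg = PathSearchConfig(M=300, seed=6, kappa=10.0)
        res1, _ = mc.find_principal_path(mode, scheme, g, 1, n, cfg)
        # relabelled copy with reversed insertion order enumerates differently
        g2 = nx.Graph()
        g2.add_nodes_from(sorted(g.nodes, reverse=True))
        g2.add_edges_from(sorted(g.edges, reverse=True))
        res2, _ = mc.find_principal_path(mode, scheme, g2, 1, n, cfg)
        assert res1.gamma == res2.gamma

    def test_detour_filter_rejects_meandering_path(self):
        # zig-zag: arc length 3.5 mm, straight endpoint distance 0.5 mm
        scheme, mode = _chain_scheme([0.0, 0.2, 0.4, 0.6, 0.8])
        centroids = np.zeros((5, 3))
        centroids[:, 1] = [0.0, 1.0, 2.0, 1.0, 0.5]
        scheme = ParcelScheme(
            parcel_ids=scheme.parcel_ids, names=scheme.names,
            hemisphere=scheme.hemisphere, superregion=scheme.superregion,
            lobe=scheme.lobe, centroids=centroids,
            n_voxels=scheme.n_voxels, adjacency=scheme.adjacency)
        fld = mc.ms_gradient(mode, scheme)
        gamma = (1, 2, 3, 4, 5)
        assert not _is_plausible(gamma, fld, kappa=3.0)
        assert _is_plausible(gamma, fld, kappa=8.0)

    def test_all_paths_filtered_raises_with_diagnostics(self):
        scheme, mode = _chain_scheme(np.linspace(0, 1, 8))
        g = scheme.graph()
        with pytest.raises(ValueError, match="filtered"):
            mc.find_principal_path(mode, scheme, g, 1, 8,
                                   PathSearchConfig(kappa=0.5))

    def test_planted_gradient_recovery(self):
        scheme = mc.generate_parcel_scheme(14, seed=5)
        _, truth = mc.generate_voxel_metabolites(scheme, seed=6)
        mode = ModeMap(region_ids=scheme.parcel_ids, mu=truth.planted_axis)
        g = scheme.graph(hemisphere="R", superregions=("cortex",))
        idx = scheme.index_of
        ax = {p: truth.planted_axis[idx[p]] for p in g.nodes}
        start = min(g.nodes, key=ax.get)
        end = max(g.nodes, key=ax.get)
        res, _ = mc.find_principal_path(mode, scheme, g, start, end,
                                        PathSearchConfig(M=500, seed=7))
        path_ax = [ax[p] for p in res.gamma]
        rho = stats.spearmanr(np.arange(len(path_ax)), path_ax).statistic
        assert rho >= 0.95


class TestJointNullTest:
    def test_dominating_path_extreme_pvalue(self):
        obs = mc.PathResult(gamma=(1, 2), L=1, G_mu=0.0, G_norm=0.0,
                            H_norm=1.0, cost=0.0, N_bins=3,
                            endpoints=(1, 2))
        null = np.column_stack([np.random.default_rng(0).uniform(0.1, 1, 999),
                                np.random.default_rng(1).uniform(0, 0.9, 999)])
        p = mc.empirical_pvalue((obs.G_norm, obs.H_norm), null,
                                tail="joint", tails=("le", "ge"))
        assert p == pytest.approx(1 / 1000)

    def test_end_to_end_on_small_scheme(self, small_scheme):
        vox, truth = mc.generate_voxel_metabolites(small_scheme, seed=8)
        reps = mc.perturb_voxels(vox, 3, seed=9)
        prof = mc.compute_profiles(
            reps, small_scheme, mc.filter_regions(vox, small_scheme, 1))
        metsim = mc.compute_metsim(prof)
        mode = ModeMap(region_ids=small_scheme.parcel_ids,
                       mu=truth.planted_axis)
        g = small_scheme.graph(hemisphere="L")
        idx = small_scheme.index_of
        ax = {p: truth.planted_axis[idx[p]] for p in g.nodes}
        start, end = min(g.nodes, key=ax.get), max(g.nodes, key=ax.get)
        cfg = PathSearchConfig(M=100, seed=10)
        res, _ = mc.find_principal_path(mode, small_scheme, g, start, end,
                                        cfg)
        out = mc.joint_null_test(res, metsim, small_scheme, g, n_null=19,
                                 seed=11, path_cfg=cfg,
                                 mode_kwargs={"max_iter": 300})
        assert 0 < out["p"] <= 1.0
        assert out["null_stats"].shape == (19, 2)
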