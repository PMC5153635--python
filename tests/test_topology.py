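import numpy as np
import pytest

from docnet import topology
from docnet.errors import UndefinedMetricError
from docnet.graphs import ThresholdedGraph, density_grid, threshold_by_density
from docnet.connectivity import ConnectivityMatrix

from oracles import (
    betweenness_brute,
    clustering_brute,
    degree_brute,
    path_length_brute,
    random_small_graph,
    strength_brute,
)


def _graph(w, density=0.5):
    w = np.asarray(w, dtype=float)
    return ThresholdedGraph(weights=w, density=density)


def _triangle(weight=0.5):
    w = np.full((3, 3), weight)
    np.fill_diagonal(w, 0.0)
    return _graph(w)


def _path3():
    w = np.zeros((3, 3))
    w[0, 1] = w[1, 0] = 1.0
    w[1, 2] = w[2, 1] = 1.0
    return _graph(w)


class TestNodalMetrics:
    def test_uniform_triangle(self):
        nm = topology.nodal_metrics(_triangle(0.5))
        assert np.allclose(nm.strength, 1.0)
        assert np.array_equal(nm.degree, [2, 2, 2])
        assert np.allclose(nm.betweenness, 0.0)

    def test_path_midpoint_betweenness(self):
        nm = topology.nodal_metrics(_path3())
        assert nm.betweenness[1] == pytest.approx(1.0)
        assert nm.betweenness[0] == nm.betweenness[2] == 0.0

    def test_tiny_graph_rejected(self):
        with pytest.raises(UndefinedMetricError):
            topology.nodal_metrics(_graph(np.zeros((2, 2))))

    @pytest.mark.parametrize("trial", range(25))
    def test_matches_bruteforce_oracle(self, trial):
        rng = np.random.default_rng(900 + trial)
        w = random_small_graph(rng)
        nm = topology.nodal_metrics(_graph(w))
        assert np.allclose(nm.strength, strength_brute(w), atol=1e-12)
        assert np.array_equal(nm.degree, degree_brute(w))
        assert np.allclose(nm.betweenness, betweenness_brute(w), atol=1e-8)

    def test_handshake_identity(self, rng):
        w = random_small_graph(rng, 7)
        nm = topology.nodal_metrics(_graph(w))
        assert nm.strength.sum() == pytest.approx(2 * np.triu(w, 1).sum())

    def test_strength_scales_degree_does_not(self, rng):
        w = random_small_graph(rng, 6)
        a = topology.nodal_metrics(_graph(w))
        b = topology.nodal_metrics(_graph(3.0 * w))
        assert np.allclose(b.strength, 3.0 * a.strength)
        assert np.array_equal(b.degree, a.degree)


class TestNetworkMean:
    def test_uniform_and_singleton(self, small_parc):
        vals = np.full(small_parc.n_nodes, 2.5)
        assert topology.network_mean(vals, small_parc, "FPN") == pytest.approx(2.5)

    def test_matches_direct_mean(self, small_parc, rng):
        vals = rng.standard_normal(small_parc.n_nodes)
        idx = small_parc.nodes_of("DMN")
        assert topology.network_mean(vals, small_parc, "DMN") == pytest.approx(
            vals[idx].mean(), abs=1e-12
        )

    def test_unknown_network_raises(self, small_parc):
        with pytest.raises(KeyError):
            topology.network_mean(np.zeros(small_parc.n_nodes), small_parc, "NOPE")


class TestGlobalMetrics:
    def test_complete_unit_graph(self):
        w = np.ones((4, 4)) - np.eye(4)
        c, el = topology.global_metrics(_graph(w))
        assert c == pytest.approx(1.0)
        assert el == pytest.approx(1.0)

    def test_path_graph_no_triangles(self):
        c, _ = topology.global_metrics(_path3())
        assert c == 0.0

    def test_empty_graph_rejected(self):
        with pytest.raises(UndefinedMetricError):
            topology.global_metrics(_graph(np.zeros((4, 4))))

    @pytest.mark.parametrize("trial", range(15))
    def test_matches_bruteforce_oracle(self, trial):
        rng = np.random.default_rng(300 + trial)
        w = random_small_graph(rng)
        if not np.any(w):
            return
        c, el = topology.global_metrics(_graph(w))
        assert c == pytest.approx(clustering_brute(w), abs=1e-10)
        assert el == pytest.approx(path_length_brute(w), abs=1e-8)


class TestRewireNull:
    def _modular_graph(self, rng, k=50):
        labels = np.repeat(np.arange(5), k // 5)
        p = np.where(labels[:, None] == labels[None, :], 0.6, 0.05)
        w = np.triu(rng.random((k, k)) < p, 1) * rng.uniform(0.3, 1.0, (k, k))
        w = np.triu(w, 1)
        return _graph(w + w.T)

    def test_degree_sequence_preserved(self, rng):
        g = self._modular_graph(rng)
        for null in topology.rewire_null(g, n_nulls=5, seed=1):
            assert np.array_equal(np.sort(null.degree()), np.sort(g.degree()))
            assert np.array_equal(null.degree(), g.degree())

    def test_edge_count_and_weight_multiset_preserved(self, rng):
        g = self._modular_graph(rng)
        for null in topology.rewire_null(g, n_nulls=3, seed=2):
            assert null.n_edges == g.n_edges
            assert np.allclose(
                np.sort(null.edge_list()[2]), np.sort(g.edge_list()[2])
            )

    def test_rewiring_destroys_clustering(self, rng):
        g = self._modular_graph(rng)
        c_real, _ = topology.global_metrics(g)
        c_null = np.mean(
            [topology.global_metrics(n)[0]
             for n in topology.rewire_null(g, n_nulls=20, seed=3)]
        )
        assert c_null < c_real

    def test_deterministic_for_seed(self, rng):
        g = self._modular_graph(rng)
        a = topology.rewire_null(g, n_nulls=2, seed=9)
        b = topology.rewire_null(g, n_nulls=2, seed=9)
        for x, y in zip(a, b):
            assert np.array_equal(x.weights, y.weights)


class TestNormalize:
    def test_real_equal_to_null_mean(self, rng):
        v = rng.random(5)
        assert np.allclose(topology.normalize(v, [v, v, v]), 1.0)

    def test_division_oracle(self, rng):
        real = rng.random(6)
        nulls = [rng.random(6) for _ in range(4)]
        out = topology.normalize(real, nulls)
        assert np.allclose(out, real / np.mean(nulls, axis=0))

    def test_zero_null_mean_sentinels(self):
        out = topology.normalize(np.array([0.0, 2.0]),
                                 [np.array([0.0, 0.0])] * 3)
        assert out[0] == 1.0
        assert np.isnan(out[1])

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            topology.normalize(np.zeros(3), [np.zeros(4)])


class TestSmallWorldness:
    def test_self_comparison_is_unity(self, rng):
        w = random_small_graph(rng, 6)
        g = _graph(w)
        assert topology.small_worldness(g, [g, g]) == pytest.approx(1.0)

    def test_ring_lattice_is_small_world_vs_nulls(self):
        k, neigh = 60, 3
        w = np.zeros((k, k))
        for i in range(k):
            for d in range(1, neigh + 1):
                j = (i + d) % k
                w[i, j] = w[j, i] = 1.0
        g = _graph(w)
        nulls = topology.rewire_null(g, n_nulls=20, seed=4)
        assert topology.small_worldness(g, nulls) > 1.0


class TestAucOverDensities:
    def test_constant_profile(self):
        grid = density_grid()
        assert topology.auc_over_densities(
            np.full(len(grid), 2.0), grid.densities
        ) == pytest.approx(0.6)

    def test_linear_profile_closed_form(self):
        grid = density_grid()
        auc = topology.auc_over_densities(grid.densities, grid.densities)
        assert auc == pytest.approx((0.325**2 - 0.025**2) / 2.0)

    def test_orientation_invariance(self, rng):
        grid = density_grid()
        v = rng.random(len(grid))
        fwd = topology.auc_over_densities(v, grid.densities)
        rev = topology.auc_over_densities(v[::-1], grid.densities[::-1])
        assert fwd == pytest.approx(rev)

    def test_single_density_rejected(self):
        with pytest.raises(ValueError):
            topology.auc_over_densities([1.0], [0.1])


class TestSubjectTopology:
    def test_profile_shapes_and_network_consistency(self, tiny_cohort, rng):
        from docnet import connectivity as conn

        parc, subjects = tiny_cohort
        c = conn.subject_connectivity(subjects[0])
        grid = density_grid(0.1, 0.3, 0.1)
        prof = topology.subject_topology(
            c, grid, parc=parc, n_nulls=5, seed=0,
            metrics=("strength", "degree"),
        )
        k = parc.n_nodes
        assert prof.raw["strength"].shape == (3, k)
        assert set(prof.network_auc["strength"]) == set(parc.networks)
        # network AUC equals the mean of its nodes' AUCs
        for net in parc.networks:
            idx = parc.nodes_of(net)
            assert prof.network_auc["strength"][net] == pytest.approx(
                prof.nodal_auc["strength"][idx].mean(), abs=1e-12
            )
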