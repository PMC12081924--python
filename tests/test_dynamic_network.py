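import numpy as np
import pytest

from scrden import ValidationError
from scrden.dynamic_network import (StageNetwork, dynamics_along_path,
                                    node_cluster_coefficient, node_diversity,
                                    stage_network, threshold_network)
from scrden.ensemble_cluster import ClusterAssignment
from scrden.rank_network import EdgeProfileMatrix
from scrden.trajectory import TrajectoryModel

from _oracles import (cluster_coeff_oracle, diversity_oracle,
                      stage_weight_oracle)


def profile_fixture(edges, values, n_cells):
    return EdgeProfileMatrix(edges, np.asarray(values, dtype=float),
                             [f"c{j}" for j in range(n_cells)],
                             normalization="minmax")


def model_fixture(labels, cluster_T, start=1):
    labels = np.asarray(labels, dtype=int)
    cells = [f"c{i}" for i in range(len(labels))]
    centroids = {cl: np.zeros(2) for cl in cluster_T}
    D = {cl: float(t) for cl, t in cluster_T.items()}
    return (ClusterAssignment(cells, labels),
            TrajectoryModel(start, centroids, D, dict(cluster_T),
                            cells, labels))


class TestStageNetwork:
    def test_constant_profile_gives_its_mean(self):
        prof = profile_fixture([("a", "b")], [[0.6] * 4], 4)
        labels, model = model_fixture([1, 1, 2, 2], {1: 0.0, 2: 1.0})
        net = stage_network(prof, labels, model, ["a", "b"], pt=0.0)
        assert net.weights[0, 1] == pytest.approx(0.6)
        np.testing.assert_allclose(net.weights, net.weights.T)

    def test_single_cell_stage_equals_that_cell(self):
        prof = profile_fixture([("a", "b")], [[0.1, 0.9, 0.4]], 3)
        labels, model = model_fixture([1, 2, 2], {1: 0.0, 2: 1.0})
        net = stage_network(prof, labels, model, ["a", "b"], pt=0.0)
        assert net.weights[0, 1] == pytest.approx(0.1)

    def test_three_gene_fixture_matches_group_mean_oracle(self, rng):
        edges = [("a", "b"), ("a", "c"), ("b", "c")]
        values = rng.random((3, 5))
        prof = profile_fixture(edges, values, 5)
        labels, model = model_fixture([1, 1, 1, 2, 2], {1: 0.0, 2: 1.0})
        net = stage_network(prof, labels, model, ["a", "b", "c"], pt=0.0)
        mask = [True, True, True, False, False]
        expected = stage_weight_oracle(values, edges, net.genes, mask)
        np.testing.assert_allclose(net.weights, expected, atol=1e-12)

    def test_pairs_outside_edge_universe_absent(self):
        prof = profile_fixture([("a", "b")], [[0.5, 0.5]], 2)
        labels, model = model_fixture([1, 1], {1: 0.0})
        net = stage_network(prof, labels, model, ["a", "b", "z"], pt=0.0)
        assert not net.present[net.genes.index("a"), net.genes.index("z")]

    def test_unknown_stage_errors(self):
        prof = profile_fixture([("a", "b")], [[0.5, 0.5]], 2)
        labels, model = model_fixture([1, 1], {1: 0.0})
        with pytest.raises(ValidationError):
            stage_network(prof, labels, model, ["a", "b"], pt=0.7)


class TestThreshold:
    def _net(self, weights):
        weights = np.asarray(weights, dtype=float)
        genes = [f"g{i}" for i in range(weights.shape[0])]
        present = weights > 0
        return StageNetwork(0.0, genes, weights, present)

    def test_below_threshold_removed_exact_survives(self):
        net = self._net([[0, 0.19, 0.2], [0.19, 0, 0.5], [0.2, 0.5, 0]])
        out = threshold_network(net, 0.2)
        assert out.weights[0, 1] == 0.0
        assert out.weights[0, 2] == pytest.approx(0.2)
        assert out.weights[1, 2] == pytest.approx(0.5)

    def test_zero_threshold_is_identity(self, rng):
        w = rng.random((4, 4))
        w = (w + w.T) / 2
        np.fill_diagonal(w, 0.0)
        net = self._net(w)
        out = threshold_network(net, 0.0)
        np.testing.assert_array_equal(out.weights, net.weights)

    def test_random_instance_matches_elementwise_oracle(self, rng):
        w = rng.random((6, 6))
        w = (w + w.T) / 2
        np.fill_diagonal(w, 0.0)
        net = self._net(w)
        out = threshold_network(net, 0.3)
        np.testing.assert_array_equal(out.weights,
                                      np.where(w >= 0.3, w, 0.0) * (w > 0))


class TestTopology:
    def _net(self, weights):
        weights = np.asarray(weights, dtype=float)
        genes = [f"g{i}" for i in range(weights.shape[0])]
        return StageNetwork(0.0, genes, weights, weights > 0)

    def test_equal_weights_diversity_one(self):
        w = np.zeros((4, 4))
        w[0, 1:] = w[1:, 0] = 0.3
        div = node_diversity(self._net(w))
        assert div["g0"] == pytest.approx(1.0)

    def test_degree_one_diversity_zero(self):
        w = np.zeros((2, 2))
        w[0, 1] = w[1, 0] = 0.9
        assert node_diversity(self._net(w)).tolist() == [0.0, 0.0]

    def test_hand_arithmetic_example(self):
        w = np.zeros((4, 4))
        for j, wt in ((1, 0.6), (2, 0.2), (3, 0.2)):
            w[0, j] = w[j, 0] = wt
        p = np.array([0.6, 0.2, 0.2])
        expected = -(p * np.log(p)).sum() / np.log(3)
        assert node_diversity(self._net(w))["g0"] == pytest.approx(expected)

    def test_triangle_and_star(self):
        tri = np.array([[0, 1, 1], [1, 0, 1], [1, 1, 0]], dtype=float)
        co = node_cluster_coefficient(self._net(tri))
        assert co.tolist() == [1.0, 1.0, 1.0]
        star = np.zeros((4, 4))
        star[0, 1:] = star[1:, 0] = 1.0
        assert node_cluster_coefficient(self._net(star))["g0"] == 0.0

    def test_random_graph_matches_brute_force(self, rng):
        w = (rng.random((6, 6)) < 0.5).astype(float) * rng.random((6, 6))
        w = np.triu(w, 1)
        w = w + w.T
        net = self._net(w)
        np.testing.assert_allclose(node_diversity(net).to_numpy(),
                                   diversity_oracle(w, w > 0), atol=1e-10)
        np.testing.assert_allclose(
            node_cluster_coefficient(net).to_numpy(),
            cluster_coeff_oracle(w > 0), atol=1e-10)

    def test_statistics_bounded_in_unit_interval(self, rng):
        for _ in range(5):
            w = np.triu((rng.random((8, 8)) < 0.4) * rng.random((8, 8)), 1)
            w = w + w.T
            net = self._net(w)
            div = node_diversity(net)
            co = node_cluster_coefficient(net)
            assert ((div >= 0) & (div <= 1 + 1e-12)).all()
            assert ((co >= 0) & (co <= 1)).all()


class TestDynamicsAlongPath:
    def test_single_stage_path(self):
        prof = profile_fixture([("a", "b")], [[0.5, 0.6]], 2)
        labels, model = model_fixture([1, 1], {1: 0.0})
        nets, summary = dynamics_along_path(prof, labels, model,
                                            ["a", "b"], [1], threshold=0.0)
        assert len(nets) == 1 and len(summary) == 1

    def test_identical_populations_identical_networks(self, rng):
        values = np.tile(rng.random((3, 1)), (1, 4))
        prof = profile_fixture([("a", "b"), ("a", "c"), ("b", "c")],
                               values, 4)
        labels, model = model_fixture([1, 1, 2, 2], {1: 0.0, 2: 1.0})
        nets, _ = dynamics_along_path(prof, labels, model,
                                      ["a", "b", "c"], [1, 2], threshold=0.0)
        np.testing.assert_allclose(nets[0].weights, nets[1].weights)

    def test_switching_module_strengthens_along_path(self):
        # profile of the (a, b) pair ramps up over three stages
        values = np.array([[0.1, 0.1, 0.5, 0.5, 0.9, 0.9],
                           [0.3, 0.3, 0.3, 0.3, 0.3, 0.3]])
        prof = profile_fixture([("a", "b"), ("a", "c")], values, 6)
        labels, model = model_fixture([1, 1, 2, 2, 3, 3],
                                      {1: 0.0, 2: 0.5, 3: 1.0})
        nets, summary = dynamics_along_path(
            prof, labels, model, ["a", "b", "c"], [1, 2, 3], threshold=0.0)
        ia, ib = nets[0].genes.index("a"), nets[0].genes.index("b")
        first, last = nets[0].weights[ia, ib], nets[-1].weights[ia, ib]
        assert last > first
        assert summary.pseudotime.is_monotonic_increasing
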