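"""Expected influence, bridge decomposition, and nodewise predictability."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import symptomnet as sn
from tests.conftest import make_ordinal_battery, net_from_weights, uniform_design


def three_node_net():
    W = np.zeros((3, 3))
    W[0, 1] = W[1, 0] = 0.5
    W[0, 2] = W[2, 0] = -0.2
    return net_from_weights(W)


def random_net(seed, p=6):
    rng = np.random.default_rng(seed)
    W = rng.uniform(-0.3, 0.5, size=(p, p))
    W = (W + W.T) / 2
    np.fill_diagonal(W, 0.0)
    return net_from_weights(W)


class TestExpectedInfluence:
    def test_signed_row_sums(self):
        assert np.allclose(
            sn.expected_influence(three_node_net()), [0.3, 0.5, -0.2]
        )

    def test_empty_network_all_zero(self):
        assert np.allclose(sn.expected_influence(net_from_weights(np.zeros((4, 4)))), 0)


class TestStandardize:
    def test_simple_example(self):
        assert np.allclose(sn.standardize([1, 2, 3]), [-1, 0, 1])

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            sn.standardize([2.0, 2.0, 2.0])

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_output_has_mean_zero_unit_sd(self, seed):
        x = np.random.default_rng(seed).normal(size=8)
        z = sn.standardize(x)
        assert abs(z.mean()) < 1e-12
        assert z.std(ddof=1) == pytest.approx(1.0, abs=1e-12)


class TestBridgeExpectedInfluence:
    def test_single_community_gives_zero_bridge(self):
        net = random_net(0)
        bridge, _ = sn.bridge_expected_influence(
            net, sn.Partition(np.ones(net.p, dtype=int))
        )
        assert np.allclose(bridge, 0.0)

    def test_all_edges_cross_when_node_isolated_in_community(self):
        net = three_node_net()
        part = sn.Partition(np.array([1, 2, 2]))
        bridge, _ = sn.bridge_expected_influence(net, part)
        assert np.allclose(bridge, [0.3, 0.5, -0.2])

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_additivity_identity_two_communities(self, seed):
        # EI = bridge EI + within-community EI, exactly, per node
        net = random_net(seed)
        rng = np.random.default_rng(seed)
        assignment = rng.integers(1, 3, size=net.p)
        assignment[:2] = [1, 2]  # both communities nonempty
        part = sn.Partition(np.sort(assignment))
        bridge, decomp = sn.bridge_expected_influence(net, part)
        own_cols = [f"community_{c}" for c in part.assignment]
        within = np.array(
            [decomp.loc[lab, col] for lab, col in zip(net.node_labels, own_cols)]
        )
        assert np.allclose(bridge + within, sn.expected_influence(net), atol=1e-14)

    def test_invariant_to_community_relabeling(self):
        net = random_net(4)
        a = sn.Partition(np.array([1, 1, 2, 2, 3, 3]))
        b = sn.Partition(np.array([2, 2, 3, 3, 1, 1]))  # same blocks, new ids
        bridge_a, _ = sn.bridge_expected_influence(net, a)
        bridge_b, _ = sn.bridge_expected_influence(net, b)
        assert np.allclose(bridge_a, bridge_b)

    def test_node_permutation_consistency(self):
        net = random_net(5)
        perm = np.array([3, 1, 4, 0, 5, 2])
        W2 = net.weights[np.ix_(perm, perm)]
        assignment = np.array([1, 1, 1, 2, 2, 2])
        part = sn.Partition(assignment)
        part2 = sn.Partition(assignment[perm])
        b1, _ = sn.bridge_expected_influence(net, part)
        b2, _ = sn.bridge_expected_influence(net_from_weights(W2), part2)
        assert np.allclose(b1[perm], b2)

    def test_partition_must_cover_nodes(self):
        with pytest.raises(ValueError):
            sn.bridge_expected_influence(random_net(6), sn.Partition(np.array([1, 2])))


class TestPredictability:
    def test_independent_item_near_zero(self):
        design = uniform_design(3, 5000)
        rm = sn.sample_responses(sn.random_ggm(3, 0.0), design, seed=0)
        W = np.zeros((3, 3))
        W[0, 1] = W[1, 0] = 0.2  # claim neighbors despite independence
        W[0, 2] = W[2, 0] = 0.2
        pred = sn.node_predictability(rm, net_from_weights(W))
        assert pred[0] <= 0.02

    def test_duplicated_neighbor_is_fully_predictive(self):
        rng = np.random.default_rng(1)
        col = rng.integers(1, 5, size=2000)
        rm = sn.ResponseMatrix(
            values=np.column_stack([col, col]), battery=make_ordinal_battery(2)
        )
        W = np.zeros((2, 2))
        W[0, 1] = W[1, 0] = 0.9
        pred = sn.node_predictability(rm, net_from_weights(W))
        assert np.all(pred >= 0.98)

    def test_known_linear_r_squared_recovered(self):
        # y = x + e with Var(e) = Var(x): true R^2 = 0.5
        rng = np.random.default_rng(11)
        n = 5000
        x = rng.integers(0, 10, size=n)
        y = np.rint(x + rng.normal(scale=np.sqrt(99 / 12), size=n)).astype(int)
        from symptomnet.scales import ItemDefinition, ScaleBattery

        items = (
            ItemDefinition("X", "predictor", tuple(range(0, 10)), "DEP"),
            ItemDefinition("Y", "response", tuple(range(y.min(), y.max() + 1)), "DEP"),
        )
        bat = ScaleBattery(items=items, dep_cutoff=10)
        rm = sn.ResponseMatrix(values=np.column_stack([x, y]), battery=bat)
        W = np.zeros((2, 2))
        W[0, 1] = W[1, 0] = 0.5
        pred = sn.node_predictability(rm, net_from_weights(W))
        assert pred[1] == pytest.approx(0.5, abs=0.05)

    def test_isolated_node_scores_zero(self):
        design = uniform_design(3, 300)
        rm = sn.sample_responses(sn.random_ggm(3, 1.0, seed=2), design, seed=2)
        pred = sn.node_predictability(rm, net_from_weights(np.zeros((3, 3))))
        assert np.all(pred == 0.0)

    def test_binary_item_uses_normalized_accuracy(self):
        rng = np.random.default_rng(3)
        z = rng.standard_normal(4000)
        x = (z > 0).astype(int)
        y = (z + rng.normal(scale=0.5, size=4000) > 0).astype(int)
        from symptomnet.scales import ItemDefinition, ScaleBattery

        items = (
            ItemDefinition("B1", "a", (0, 1), "PTSD"),
            ItemDefinition("B2", "b", (0, 1), "PTSD"),
        )
        bat = ScaleBattery(items=items, ptsd_cutoff=1)
        rm = sn.ResponseMatrix(values=np.column_stack([x, y]), battery=bat)
        W = np.zeros((2, 2))
        W[0, 1] = W[1, 0] = 0.5
        pred = sn.node_predictability(rm, net_from_weights(W))
        assert 0.2 < pred[0] <= 1.0  # informative but imperfect neighbor

    def test_noise_neighbors_do_not_inflate(self):
        design = uniform_design(5, 5000)
        truth = sn.random_ggm(5, 0.0)
        rm = sn.sample_responses(truth, design, seed=4)
        rng = np.random.default_rng(4)
        signal = rm.values[:, 1]
        values = rm.values.copy()
        values[:, 0] = signal  # item 0 duplicates item 1; rest are noise
        rm = sn.ResponseMatrix(values=values, battery=rm.battery)
        W_small = np.zeros((5, 5))
        W_small[0, 1] = W_small[1, 0] = 0.9
        W_big = W_small.copy()
        for j in (2, 3, 4):
            W_big[0, j] = W_big[j, 0] = 0.1
        p_small = sn.node_predictability(rm, net_from_weights(W_small))[0]
        p_big = sn.node_predictability(rm, net_from_weights(W_big))[0]
        assert p_big <= p_small + 0.02


class TestCentralityTable:
    def test_table_assembles_all_indices(self, fast_config):
        design = uniform_design(6, 800)
        rm = sn.sample_responses(sn.random_ggm(6, 0.5, seed=6), design, seed=6)
        net = sn.estimate_network(rm, fast_config)
        part = sn.Partition(np.array([1, 1, 1, 2, 2, 2]), node_labels=net.node_labels)
        table = sn.centrality_table(net, theoretical=part, rm=rm).frame
        assert {"ei_raw", "ei_z", "predictability", "bridge_ei_theoretical"} <= set(
            table.columns
        )
        assert abs(table["ei_z"].mean()) < 1e-12
        assert table["predictability"].between(0, 1).all()
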