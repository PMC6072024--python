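import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from neulite.netbuild import (Network, create_network,
                              distance_tapered_probability)
from neulite.streams import TAG_EDGE, pair_stream


def const_rule(n):
    def rule(source, target):
        return n
    return rule


def two_group_net():
    net = create_network("demo")
    net.add_nodes(3, per_node_props={"positions": np.zeros((3, 3))},
                  pop_name="exc", model_type="biophysical",
                  model_template="passive_cable",
                  dynamics_params="p.json", morphology_file="m.swc")
    net.add_nodes(2, per_node_props={"positions": np.zeros((2, 3))},
                  pop_name="inh", model_type="intfire",
                  model_template="lif", dynamics_params="l.json")
    return net


class TestCreateNetwork:
    def test_empty_container(self):
        net = create_network("V1")
        assert (net.name, net.n_nodes, net.n_edges) == ("V1", 0, 0)
        assert net.node_types == {} and net.edge_types == {}

    def test_names_need_not_be_unique(self):
        assert create_network("LGN") is not create_network("LGN")

    @pytest.mark.parametrize("bad", ["", None, 3])
    def test_invalid_name(self, bad):
        with pytest.raises(ValueError):
            create_network(bad)


class TestAddNodes:
    def test_counts_and_contiguous_gids(self):
        net = create_network("n")
        net.add_nodes(3, pop_name="a")
        net.add_nodes(2, pop_name="b")
        assert net.n_nodes == 5
        assert [n.node_id for n in net.nodes()] == [0, 1, 2, 3, 4]
        assert len(net.node_types) == 2
        assert [n.node_type_id for n in net.nodes()] == [0, 0, 0, 1, 1]

    def test_each_call_creates_one_type_with_shared_props(self):
        net = create_network("n")
        ntid = net.add_nodes(80, model_type="biophysical",
                             morphology_file="m.swc",
                             dynamics_params="d.json",
                             model_template="passive_cable",
                             per_node_props={
                                 "positions": np.random.default_rng(0)
                                 .random((80, 3))})
        assert net.n_nodes == 80
        assert [n.node_id for n in net.nodes()][-1] == 79
        assert net.node_types[ntid]["morphology_file"] == "m.swc"
        # positions are per-instance, not in the type table
        assert "x" not in net.node_types[ntid]

    def test_per_node_array_length_mismatch(self):
        net = create_network("n")
        with pytest.raises(ValueError, match="shape"):
            net.add_nodes(4, per_node_props={"w": np.zeros(5)})

    @pytest.mark.parametrize("n", [0, -1])
    def test_nonpositive_count_rejected(self, n):
        with pytest.raises(ValueError):
            create_network("n").add_nodes(n, pop_name="x")

    def test_reserved_key_rejected(self):
        with pytest.raises(ValueError, match="reserved"):
            create_network("n").add_nodes(2, node_id="oops")

    def test_type_instance_collision_rejected(self):
        net = create_network("n")
        with pytest.raises(ValueError):
            net.add_nodes(2, w=1.0, per_node_props={"w": np.zeros(2)})

    def test_bad_model_type_rejected(self):
        with pytest.raises(ValueError, match="model_type"):
            create_network("n").add_nodes(2, model_type="hodgkin")

    @given(st.lists(st.integers(min_value=1, max_value=30), min_size=1,
                    max_size=6))
    @settings(max_examples=30, deadline=None)
    def test_gids_always_contiguous(self, sizes):
        net = create_network("n")
        for i, n in enumerate(sizes):
            net.add_nodes(n, pop_name=f"g{i}")
        assert net.n_nodes == sum(sizes)
        assert [v.node_id for v in net.nodes()] == list(range(sum(sizes)))


class TestQueryNodes:
    def test_true_matches_all(self):
        net = two_group_net()
        assert len(net.query_nodes(None)) == 5

    def test_equality_query(self):
        net = two_group_net()
        got = net.query_nodes({"pop_name": "exc"})
        assert [n.node_id for n in got] == [0, 1, 2]

    def test_missing_property_is_non_match(self):
        # only biophysical nodes carry morphology_file
        net = two_group_net()
        got = net.query_nodes(lambda n: n["morphology_file"] == "m.swc")
        assert [n.node_id for n in got] == [0, 1, 2]

    def test_instance_and_type_props_share_namespace(self):
        net = two_group_net()
        node = net.node(0)
        assert node["pop_name"] == "exc"       # type level
        assert node["x"] == 0.0                # instance level
        assert node.get("nope") is None


class TestAddEdges:
    def test_registers_without_enumeration(self):
        net = two_group_net()
        etid = net.add_edges(source={"pop_name": "inh"},
                             target={"pop_name": "exc"},
                             connection_rule=const_rule(1),
                             dynamics_params="g.json", syn_weight=1e-3,
                             delay=1.0)
        assert etid in net.edge_types
        assert net.n_edges == 0

    def test_two_calls_two_ids(self):
        net = two_group_net()
        a = net.add_edges(connection_rule=const_rule(1))
        b = net.add_edges(connection_rule=const_rule(1))
        assert a != b

    def test_unknown_weight_function_fails_fast(self):
        net = two_group_net()
        with pytest.raises(ValueError, match="weight_function"):
            net.add_edges(connection_rule=const_rule(1),
                          weight_function="no_such_fn")

    @pytest.mark.parametrize("dr", [[500, 400], [-1, 10], [5]])
    def test_malformed_distance_range(self, dr):
        net = two_group_net()
        with pytest.raises(ValueError, match="distance_range"):
            net.add_edges(connection_rule=const_rule(1), distance_range=dr)

    def test_negative_delay_rejected(self):
        with pytest.raises(ValueError, match="delay"):
            two_group_net().add_edges(connection_rule=const_rule(1),
                                      delay=-1.0)


class TestBuildEdges:
    def test_constant_rule_full_cross_product(self):
        net = two_group_net()
        net.add_edges(source={"pop_name": "exc"},
                      target={"pop_name": "inh"},
                      connection_rule=const_rule(1))
        assert net.build_edges(seed=0) == 6    # 3 sources x 2 targets

    def test_zero_rule_and_empty_query(self):
        net = two_group_net()
        net.add_edges(connection_rule=const_rule(0))
        net.add_edges(source={"pop_name": "ghost"}, target=None,
                      connection_rule=const_rule(5))
        assert net.build_edges(seed=0) == 0

    @pytest.mark.parametrize("bad,exc", [(1.5, TypeError),
                                         (-1, ValueError)])
    def test_bad_nsyns_names_pair(self, bad, exc):
        net = two_group_net()
        net.add_edges(connection_rule=lambda s, t: bad)
        with pytest.raises(exc, match="edge type 0"):
            net.build_edges(seed=0)

    def test_seed_determinism(self, two_pop_net):
        from neulite.fixtures import two_pop_spec
        again = two_pop_spec(n_exc=12, n_inh=4, seed=7)
        for col in two_pop_net.edge_table:
            np.testing.assert_array_equal(two_pop_net.edge_table[col],
                                          again.edge_table[col])
        other = two_pop_spec(n_exc=12, n_inh=4, seed=8)
        assert not all(
            np.array_equal(two_pop_net.edge_table[c], other.edge_table[c])
            for c in two_pop_net.edge_table)

    def test_incremental_rules_leave_earlier_edges_unchanged(self):
        def probabilistic(s, t, *, rng):
            return int(rng.random() < 0.5)

        net1 = two_group_net()
        net1.add_edges(connection_rule=probabilistic)
        net1.build_edges(seed=11)
        first = {c: v.copy() for c, v in net1.edge_table.items()}

        net2 = two_group_net()
        net2.add_edges(connection_rule=probabilistic)
        net2.add_edges(connection_rule=probabilistic)
        net2.build_edges(seed=11)
        mask = net2.edge_table["edge_type_id"] == 0
        for col in first:
            np.testing.assert_array_equal(first[col],
                                          net2.edge_table[col][mask])

    def test_referential_integrity_after_build(self, two_pop_net):
        assert two_pop_net.validate_integrity() == []


class TestDistanceTaperedRule:
    def _nodes(self, d):
        net = create_network("n")
        net.add_nodes(2, per_node_props={
            "positions": np.array([[0.0, 0.0, 0.0], [d, 0.0, 0.0]])})
        return net.node(0), net.node(1)

    def test_p_zero_never_connects(self):
        a, b = self._nodes(10.0)
        hits = sum(
            distance_tapered_probability(
                a, b, p0=0.0, sigma=50.0,
                rng=pair_stream(0, TAG_EDGE, 0, 0, i))
            for i in range(200))
        assert hits == 0

    def test_p_one_zero_distance_always_connects(self):
        a, b = self._nodes(0.0)
        draws = [distance_tapered_probability(
            a, b, p0=1.0, sigma=50.0, nsyns_range=(2, 2),
            rng=pair_stream(0, TAG_EDGE, 0, 0, i)) for i in range(200)]
        assert all(d == 2 for d in draws)

    def test_monte_carlo_rate_matches_closed_form(self):
        # p = 0.5 exp(-1/2) at d = sigma
        a, b = self._nodes(100.0)
        n = 10_000
        hits = sum(
            distance_tapered_probability(
                a, b, p0=0.5, sigma=100.0,
                rng=pair_stream(42, TAG_EDGE, 0, 0, i)) > 0
            for i in range(n))
        p = 0.5 * np.exp(-0.5)
        sd = np.sqrt(n * p * (1 - p))
        assert abs(hits - n * p) < 3 * sd

    def test_missing_position_is_error(self):
        net = create_network("n")
        net.add_nodes(2, pop_name="nopos")
        with pytest.raises(ValueError, match="position"):
            distance_tapered_probability(
                net.node(0), net.node(1), p0=0.5, sigma=10.0,
                rng=pair_stream(0, TAG_EDGE, 0, 0, 1))

    @pytest.mark.parametrize("kw", [{"p0": 1.5}, {"sigma": 0.0},
                                    {"nsyns_range": (0, 3)},
                                    {"nsyns_range": (4, 2)}])
    def test_parameter_validation(self, kw):
        a, b = self._nodes(10.0)
        args = {"p0": 0.5, "sigma": 10.0, **kw}
        with pytest.raises(ValueError):
            distance_tapered_probability(
                a, b, rng=pair_stream(0, TAG_EDGE, 0, 0, 1), **args)
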