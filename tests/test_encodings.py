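"""Genotypes, mutation operators and genotype->network development."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from evoplast.encodings import (
    CppnCycleError,
    DevelopmentError,
    DirectEncoding,
    GraphGenotype,
    HnnEncoding,
    MapEncoding,
    MutationRates,
    Substrate,
    cppn_eval,
    decode_labels,
    default_substrate,
    develop_hnn,
    polynomial_mutation,
)
from evoplast.encodings.base import EdgeGene, NodeGene
from evoplast.encodings.direct import make_cppn_encoding
from evoplast.encodings.map_based import MapDevelopmentConfig
from evoplast.regularity import network_automorphisms


def forced(**kw):
    """Mutation rates with everything off except the named operators."""
    return MutationRates(**{**dict(
        p_add_conn=0, p_del_conn=0, p_move_conn=0,
        p_add_neuron=0, p_del_neuron=0, p_weight=0, p_param=0), **kw})


class TestPolynomialMutation:
    @given(st.floats(0.01, 1.99), st.integers(0, 1000))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_stays_within_bounds(self, x, seed):
        rng = np.random.default_rng(seed)
        for _ in range(20):
            assert 0.0 <= polynomial_mutation(x, 0.0, 2.0, 15.0, rng) <= 2.0

    def test_symmetric_at_midpoint(self):
        rng = np.random.default_rng(3)
        draws = [polynomial_mutation(1.0, 0.0, 2.0, 15.0, rng) for _ in range(20_000)]
        se = np.std(draws) / math.sqrt(len(draws))
        assert abs(np.mean(draws) - 1.0) < 3 * se

    def test_large_index_shrinks_perturbation(self):
        rng = np.random.default_rng(4)
        small = np.mean([abs(polynomial_mutation(1.0, 0, 2, 10.0, rng) - 1) for _ in range(5000)])
        tiny = np.mean([abs(polynomial_mutation(1.0, 0, 2, 10_000.0, rng) - 1) for _ in range(5000)])
        assert tiny < small / 5

    def test_out_of_bounds_rejected(self, rng):
        with pytest.raises(ValueError):
            polynomial_mutation(3.0, 0.0, 2.0, 15.0, rng)


class TestDirectEncoding:
    def test_random_init_is_feed_forward_bipartite(self, rng):
        enc = DirectEncoding()
        g = enc.random_init(rng)
        assert g.n_nodes == 14 and g.n_edges == 40
        assert not g.hidden_ids()

    def test_same_seed_same_genotype(self):
        enc = DirectEncoding()
        a = enc.random_init(np.random.default_rng(9))
        b = enc.random_init(np.random.default_rng(9))
        assert a.to_dict() == b.to_dict()

    def test_generation_zero_has_no_plastic_weights(self, rng):
        enc = DirectEncoding()
        net = enc.develop(enc.random_init(rng))
        assert not net.plastic_mask().any()

    def test_zero_rates_is_identity(self, rng):
        enc = DirectEncoding(rates=MutationRates.zero())
        g = enc.random_init(rng)
        assert enc.mutate(g, rng).to_dict() == g.to_dict()

    def test_forced_add_neuron_splits_a_connection(self, rng):
        enc = DirectEncoding(rates=forced(p_add_neuron=1.0))
        g = enc.random_init(rng)
        n0, e0 = g.n_nodes, g.n_edges
        weights = {
            (e.source, e.target): tuple(e.genes) for e in g.edges.values()
        }
        g2 = enc.mutate(g, rng)
        assert g2.n_nodes == n0 + 1 and g2.n_edges == e0 + 1
        new = g2.hidden_ids()[0]
        halves = [e for e in g2.edges.values() if new in (e.source, e.target)]
        assert len(halves) == 2
        # both halves carry the split edge's genes (weight kept on both)
        src = [e.source for e in halves if e.target == new][0]
        tgt = [e.target for e in halves if e.source == new][0]
        assert tuple(halves[0].genes) == tuple(halves[1].genes) == weights[(src, tgt)]

    def test_forced_delete_neuron_removes_incident_edges(self, rng):
        enc = DirectEncoding(rates=forced(p_add_neuron=1.0))
        g = enc.random_init(rng)
        g = enc.mutate(g, rng)  # create one hidden node
        hid = g.hidden_ids()[0]
        degree = sum(1 for e in g.edges.values() if hid in (e.source, e.target))
        del_enc = DirectEncoding(rates=forced(p_del_neuron=1.0))
        g2 = del_enc.mutate(g, rng)
        assert g2.n_nodes == g.n_nodes - 1
        assert g2.n_edges == g.n_edges - degree

    def test_mutation_chain_preserves_invariants(self, rng):
        enc = DirectEncoding()
        g = enc.random_init(rng)
        io = set(g.node_ids("input")) | set(g.node_ids("output"))
        for _ in range(500):
            g = enc.mutate(g, rng)
            g.check_invariants()
        assert io <= set(g.node_ids())  # I/O roster never deleted

    def test_develop_maps_one_to_one(self, rng):
        enc = DirectEncoding()
        g = enc.random_init(rng)
        for _ in range(50):
            g = enc.mutate(g, rng)
        net = enc.develop(g)
        assert net.n_neurons == g.n_nodes
        assert len(net.connections) == g.n_edges

    def test_genotype_json_round_trip(self, rng, tmp_path):
        enc = DirectEncoding()
        g = enc.random_init(rng)
        path = tmp_path / "g.json"
        g.to_json(path)
        assert GraphGenotype.from_json(path).to_dict() == g.to_dict()


class TestMapEncoding:
    def test_decode_label_thresholds(self):
        node = decode_labels([0.0, 1.0, 0.49, 0.5], "node")
        assert node["is_map"] is False and node["inhibitory"] is True
        assert node["modulatory"] is False
        assert node["bias"] == pytest.approx(0.0)  # gene 0.5 -> middle of [-2, 2]
        edge = decode_labels([0.0, 0.0, 1.0], "edge")
        assert edge["weight"] == 0.0 and edge["connection_type"] == "one_to_all"
        assert decode_labels([1.0, 0.0, 0.0], "edge")["weight"] == pytest.approx(2.0)

    def test_decode_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            decode_labels([1.2, 0, 0], "edge")

    def _genotype_with_hidden(self, enc, conn_type, rng, kind_gene=0.0):
        """stimulus map -> hidden map -> output map with chosen scheme."""
        g = enc.random_init(rng)
        g.edges.clear()
        hid = g.fresh_id()
        g.add_node(NodeGene(hid, "hidden", np.array([1.0, 0.0, kind_gene, 0.5])))
        ct = 1.0 if conn_type == "one_to_all" else 0.0
        g.add_edge(EdgeGene(0, hid, np.array([0.8, 0.0, ct])))
        g.add_edge(EdgeGene(hid, 4, np.array([0.8, 0.0, ct])))
        return g, hid

    def test_one_to_one_between_equal_maps(self, rng):
        enc = MapEncoding()
        g, hid = self._genotype_with_hidden(enc, "one_to_one", rng)
        net = enc.develop(g)
        # 10 inputs + 4 hidden + 4 outputs; 4 + 4 paired connections
        assert net.n_neurons == 18
        assert len(net.connections) == 8
        pairs = {(c.source, c.target) for c in net.connections}
        assert (f"n0.2", f"n{hid}.2") in pairs  # k-th to k-th

    def test_one_to_all_between_maps(self, rng):
        enc = MapEncoding()
        g, _ = self._genotype_with_hidden(enc, "one_to_all", rng)
        net = enc.develop(g)
        assert len(net.connections) == 32
        mags = {c.magnitude for c in net.connections}
        assert len(mags) == 1  # uniform weight across the expansion

    def test_singleton_to_map_develops_as_fan(self, rng):
        enc = MapEncoding()
        g = enc.random_init(rng)
        g.edges.clear()
        g.add_edge(EdgeGene(1, 4, np.array([0.5, 0.0, 0.0])))  # reward -> output map
        net = enc.develop(g)
        assert len(net.connections) == 4  # one-to-one degenerates to one-to-all

    def test_neuron_count_law(self, rng):
        enc = MapEncoding(MapDevelopmentConfig(map_size=3))
        g = enc.random_init(rng)
        for _ in range(100):
            g = enc.mutate(g, rng)
        net = enc.develop(g)
        n_map = 3  # stimulus, feedback, output rosters are maps
        hidden_maps = sum(
            1 for h in g.hidden_ids()
            if decode_labels(g.nodes[h].genes, "node")["is_map"]
        )
        singles = 2 + (len(g.hidden_ids()) - hidden_maps)
        assert net.n_neurons == (n_map + hidden_maps) * 3 + singles

    def test_label_genes_stay_in_unit_interval(self, rng):
        enc = MapEncoding()
        g = enc.random_init(rng)
        for _ in range(300):
            g = enc.mutate(g, rng)
            g.check_invariants()
        net = enc.develop(g)  # development stays total on mutated genotypes
        assert net.n_inputs == 10 and net.n_outputs == 4

    def test_development_is_deterministic(self, rng):
        enc = MapEncoding()
        g = enc.random_init(rng)
        for _ in range(50):
            g = enc.mutate(g, rng)
        assert enc.develop(g).to_dict() == enc.develop(g).to_dict()

    def test_free_hidden_map_gives_map_factorial_automorphisms(self, rng):
        enc = MapEncoding()
        g, _ = self._genotype_with_hidden(enc, "one_to_all", rng)
        net = enc.develop(g)
        assert enc.has_free_hidden_map(g, net)
        assert network_automorphisms(net) % math.factorial(4) == 0

    def test_modulatory_hidden_map_creates_plastic_fan(self, rng):
        enc = MapEncoding()
        g, hid = self._genotype_with_hidden(enc, "one_to_all", rng, kind_gene=1.0)
        g.add_edge(EdgeGene(0, 4, np.array([0.8, 0.0, 1.0])))  # stim -> out, modulated
        net = enc.develop(g)
        kinds = {m.id: m.kind for m in net.neurons}
        assert kinds[f"n{hid}.0"] == "modulatory"
        assert net.plastic_mask().sum() == 16  # the 4x4 stim->out fan


class TestHnnEncoding:
    def test_cppn_linear_pass_through(self):
        enc = make_cppn_encoding(1, 1)
        g = GraphGenotype(enc.node_spec, enc.edge_spec)
        g.add_node(NodeGene(0, "input", np.array([0.0, 0.0, 3.0])))
        g.add_node(NodeGene(1, "output", np.array([0.0, 0.0, 3.0])))  # linear, bias 0
        g.add_edge(EdgeGene(0, 1, np.array([1.0, 0.0])))
        for x in (-1.5, 0.0, 0.7):
            assert cppn_eval(g, [x])[0] == pytest.approx(x)

    def test_cppn_gaussian_peaks_at_zero(self):
        enc = make_cppn_encoding(1, 1)
        g = GraphGenotype(enc.node_spec, enc.edge_spec)
        g.add_node(NodeGene(0, "input", np.array([0.0, 0.0, 3.0])))
        g.add_node(NodeGene(1, "output", np.array([0.0, 0.0, 2.0])))  # gaussian
        g.add_edge(EdgeGene(0, 1, np.array([1.0, 0.0])))
        assert cppn_eval(g, [0.0])[0] == pytest.approx(1.0)
        assert cppn_eval(g, [2.0])[0] == pytest.approx(math.exp(-4.0))

    def test_two_node_composition_matches_manual(self):
        # x -> sine(2x) -> sigmoid(0.5 - sine(2x))  (inhibitory second edge)
        enc = make_cppn_encoding(1, 1)
        g = GraphGenotype(enc.node_spec, enc.edge_spec)
        g.add_node(NodeGene(0, "input", np.array([0.0, 0.0, 3.0])))
        g.add_node(NodeGene(2, "hidden", np.array([0.0, 0.0, 0.0])))   # sine
        g.add_node(NodeGene(1, "output", np.array([0.5, 0.0, 1.0])))   # sigmoid, bias .5
        g.add_edge(EdgeGene(0, 2, np.array([2.0, 0.0])))
        g.add_edge(EdgeGene(2, 1, np.array([1.0, 1.0])))
        x = 0.8
        expected = 1.0 / (1.0 + math.exp(-(0.5 - math.sin(2 * x))))
        assert cppn_eval(g, [x])[0] == pytest.approx(expected)

    def test_cycle_raises(self, rng):
        enc = make_cppn_encoding(1, 1)
        g = GraphGenotype(enc.node_spec, enc.edge_spec)
        g.add_node(NodeGene(0, "input", np.array([0.0, 0.0, 3.0])))
        g.add_node(NodeGene(1, "output", np.array([0.0, 0.0, 3.0])))
        g.add_node(NodeGene(2, "hidden", np.array([0.0, 0.0, 3.0])))
        g.add_node(NodeGene(3, "hidden", np.array([0.0, 0.0, 3.0])))
        g.add_edge(EdgeGene(2, 3, np.array([1.0, 0.0])))
        g.add_edge(EdgeGene(3, 2, np.array([1.0, 0.0])))
        g.add_edge(EdgeGene(0, 1, np.array([1.0, 0.0])))
        with pytest.raises(CppnCycleError):
            cppn_eval(g, [0.0])

    def test_default_substrate_strict_nine(self):
        sub = default_substrate(9)
        assert sub.n == 18
        assert len({tuple(c) for c in sub.coords}) == 18

    def test_substrate_mirror_symmetry_and_determinism(self):
        sub = default_substrate(10)
        xs = sub.coords[:4, 0]
        assert xs[0] == -xs[3] and xs[1] == -xs[2]
        assert np.array_equal(sub.coords, default_substrate(10).coords)

    @staticmethod
    def _const_cppns(leo_value, weight_value=0.5, kind_value=1.0):
        """CPPNs with constant outputs, built from bias-only output nodes."""
        def build(n_in, outs):
            enc = make_cppn_encoding(n_in, 2)
            g = GraphGenotype(enc.node_spec, enc.edge_spec)
            for k in range(n_in):
                g.add_node(NodeGene(k, "input", np.array([0.0, 0.0, 3.0])))
            for k, val in enumerate(outs):
                g.add_node(NodeGene(n_in + k, "output", np.array([val, 0.0, 3.0])))
            return g
        return build(7, [leo_value, weight_value]), build(4, [0.0, kind_value])

    def test_constant_leo_below_threshold_gives_empty_net(self):
        conn, node = self._const_cppns(leo_value=0.2)
        net = develop_hnn(conn, node, default_substrate(10))
        assert len(net.connections) == 0

    def test_constant_leo_above_threshold_connects_all_allowed_pairs(self):
        conn, node = self._const_cppns(leo_value=0.9)
        net = develop_hnn(conn, node, default_substrate(10))
        # 10 inputs -> 9 hidden/output targets each, 5 hidden -> 9 each
        assert len(net.connections) == 10 * 9 + 5 * 9

    @pytest.mark.parametrize("kind_out,expected", [(0.39, "modulatory"), (0.41, "standard")])
    def test_modulatory_cutoff(self, kind_out, expected):
        conn, node = self._const_cppns(leo_value=0.9, kind_value=kind_out)
        net = develop_hnn(conn, node, default_substrate(10))
        kinds = {m.kind for m in net.neurons if m.role == "hidden"}
        assert kinds == {expected}
        assert all(m.kind == "standard" for m in net.neurons if m.role != "hidden")

    def test_development_determinism_and_weight_bounds(self):
        enc = HnnEncoding()
        developed = 0
        for seed in range(8):
            rng = np.random.default_rng(seed)
            g = enc.random_init(rng)
            for _ in range(30):
                g = enc.mutate(g, rng)
            try:
                a, b = enc.develop(g), enc.develop(g)
            except DevelopmentError:
                continue  # recurrent CPPN: rejected genotype, covered below
            developed += 1
            assert a.to_dict() == b.to_dict()
            assert all(0 <= c.magnitude <= a.params.w_max for c in a.connections)
        assert developed >= 3

    def test_x_symmetric_cppn_yields_symmetric_network(self):
        # conn CPPN depending only on |x1 - x2| (via gaussian of x1 - x2):
        # the substrate's x-mirror becomes a network automorphism
        enc = make_cppn_encoding(7, 2)
        g = GraphGenotype(enc.node_spec, enc.edge_spec)
        for k in range(7):
            g.add_node(NodeGene(k, "input", np.array([0.0, 0.0, 3.0])))
        # hidden gaussian over x1 - x2
        g.add_node(NodeGene(9, "hidden", np.array([0.0, 0.0, 2.0])))
        g.add_edge(EdgeGene(0, 9, np.array([1.0, 0.0])))   # + x1
        g.add_edge(EdgeGene(3, 9, np.array([1.0, 1.0])))   # - x2
        # LEO output: linear on the gaussian
        g.add_node(NodeGene(7, "output", np.array([0.0, 0.0, 3.0])))
        g.add_edge(EdgeGene(9, 7, np.array([0.8, 0.0])))
        # weight output: constant 0.5
        g.add_node(NodeGene(8, "output", np.array([0.5, 0.0, 3.0])))
        _, node = self._const_cppns(leo_value=0.0)
        net = develop_hnn(g, node, default_substrate(10))
        assert len(net.connections) > 0
        assert network_automorphisms(net) % 2 == 0

    def test_encoding_cycle_surfaces_as_development_error(self, rng):
        enc = HnnEncoding()
        g = enc.random_init(rng)
        # force a recurrent CPPN
        conn = g.conn
        h1, h2 = conn.fresh_id(), conn.fresh_id() + 1
        conn.add_node(NodeGene(h1, "hidden", np.array([0.0, 0.0, 3.0])))
        conn.add_node(NodeGene(h2, "hidden", np.array([0.0, 0.0, 3.0])))
        conn.add_edge(EdgeGene(h1, h2, np.array([1.0, 0.0])))
        conn.add_edge(EdgeGene(h2, h1, np.array([1.0, 0.0])))
        conn.add_edge(EdgeGene(0, h1, np.array([1.0, 0.0])))
        with pytest.raises(DevelopmentError):
            enc.develop(g)
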