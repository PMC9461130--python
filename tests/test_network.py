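import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mdgnet import network
from mdgnet.assoc import AssociationEdge

from conftest import brute_force_cycles, brute_force_mcc, canonical


def typed_net(nodes: dict, edges: list) -> network.TypedNetwork:
    net = network.TypedNetwork()
    for n, t in nodes.items():
        net.add_node(n, t)
    for a, b, prov in edges:
        net.add_edge(a, b, prov)
    return net


class TestTypedNetwork:
    def test_no_self_loops_or_dangling_edges(self):
        net = typed_net({"a": "gene", "b": "trait"}, [])
        with pytest.raises(ValueError):
            net.add_edge("a", "a", "ppi")
        with pytest.raises(KeyError):
            net.add_edge("a", "zzz", "ppi")

    def test_one_edge_per_pair_and_provenance(self):
        net = typed_net({"a": "gene", "b": "gene"}, [("a", "b", "ppi")])
        net.add_edge("b", "a", "ppi")       # duplicate (unordered)
        net.add_edge("a", "b", "coexpr")    # second provenance allowed
        assert len(net.edges) == 2

    def test_tf_gene_precedence_and_type_clash(self):
        net = typed_net({"x": "gene"}, [])
        net.add_node("x", "TF")
        assert net.nodes["x"] == "TF"
        with pytest.raises(ValueError):
            net.add_node("x", "trait")


class TestAssembleMdgn:
    TYPES = {"t": "trait", "m": "metabolite", "g": "gene", "r": "miRNA",
             "f": "TF"}

    def _assoc(self, a, b):
        return AssociationEdge(a, b, "trait-metabolite", 2.0, 0.01, "MCP+SCAD")

    def test_disjoint_layers_conserve_counts(self):
        grn_layer = typed_net({"f": "TF", "g": "gene"}, [("f", "g", "tfbs")])
        net, report = network.assemble_mdgn(
            [self._assoc("t", "m")], [("t", "g2")], [], grn_layer,
            {**self.TYPES, "g2": "gene"},
        )
        assert report["nodes"] == 5  # t, m, g2, f, g
        assert report["edges"] == 3

    def test_shared_gene_merges_into_single_node(self):
        grn_layer = typed_net({"f": "TF", "g": "gene"}, [("f", "g", "tfbs")])
        net, report = network.assemble_mdgn(
            [], [("t", "g")], [], grn_layer, self.TYPES)
        assert report["nodes"] == 3
        assert {e.provenance for e in net.edges} == {"qtl_link", "tfbs"}

    def test_type_collision_rejected(self):
        grn_layer = typed_net({"t": "gene"}, [])
        with pytest.raises(ValueError):
            network.assemble_mdgn([self._assoc("t", "m")], [], [], grn_layer,
                                  self.TYPES)


class TestCircuits:
    def test_triangle_single_cycle(self):
        net = typed_net({c: "gene" for c in "abc"},
                        [("a", "b", "ppi"), ("b", "c", "ppi"), ("a", "c", "ppi")])
        assert network.enumerate_circuits(net) == [("a", "b", "c")]

    def test_k4_has_seven_bounded_cycles(self):
        G = nx.complete_graph(4)
        cycles = network.enumerate_circuits(G, 3, 5)
        assert len(cycles) == 7
        assert sorted(len(c) for c in cycles) == [3, 3, 3, 3, 4, 4, 4]

    def test_tree_has_no_cycles(self):
        G = nx.random_labeled_tree(10, seed=1)
        assert network.enumerate_circuits(G) == []

    def test_matches_brute_force_on_random_graphs(self):
        rng = np.random.default_rng(60)
        for _ in range(100):
            n = int(rng.integers(4, 13))
            G = nx.gnp_random_graph(n, 0.35, seed=int(rng.integers(1e9)))
            got = set(network.enumerate_circuits(G, 3, 5))
            assert got == brute_force_cycles(G, 3, 5)

    def test_canonicalization_commutes_with_relabeling(self):
        rng = np.random.default_rng(61)
        G = nx.gnp_random_graph(9, 0.4, seed=7)
        perm = dict(zip(G.nodes, rng.permutation(list(G.nodes))))
        H = nx.relabel_nodes(G, perm)
        got_g = {tuple(perm[v] for v in c) for c in network.enumerate_circuits(G)}
        got_h = set(network.enumerate_circuits(H))
        assert {canonical(c) for c in got_g} == got_h


class TestClassification:
    def _net(self, types: dict) -> network.TypedNetwork:
        nodes = list(types)
        edges = [(nodes[i], nodes[(i + 1) % len(nodes)], "qtl_link")
                 for i in range(len(nodes))]
        return typed_net(types, edges)

    @pytest.mark.parametrize("types,dim", [
        ({"t": "trait", "g": "gene", "l": "lipid"}, "3D"),
        ({"t": "trait", "m": "metabolite", "g": "gene", "r": "miRNA"}, "4D"),
        ({"g1": "gene", "g2": "gene", "f": "TF"}, "other"),
        ({"t": "trait", "m": "metabolite", "f": "TF"}, "3D"),  # TF fills gene slot
    ])
    def test_dimension_rules(self, types, dim):
        net = self._net(types)
        cycles = network.enumerate_circuits(net)
        subs = network.classify_subnetworks(cycles, net)
        assert [s.dimension for s in subs] == [dim]

    def test_removing_mirnas_removes_all_4d(self):
        types = {"t": "trait", "m": "metabolite", "g": "gene", "r": "miRNA"}
        net = self._net(types)
        net.add_edge("t", "g", "qtl_link")
        subs = network.classify_subnetworks(network.enumerate_circuits(net), net)
        assert any(s.dimension == "4D" for s in subs)
        stripped = typed_net(
            {k: v for k, v in types.items() if v != "miRNA"},
            [(e.a, e.b, e.provenance) for e in net.edges
             if "r" not in (e.a, e.b)],
        )
        subs2 = network.classify_subnetworks(
            network.enumerate_circuits(stripped), stripped)
        assert not any(s.dimension == "4D" for s in subs2)

    def test_unknown_node_rejected(self):
        net = self._net({"a": "gene", "b": "gene", "c": "gene"})
        with pytest.raises(KeyError):
            network.classify_subnetworks([("a", "b", "zzz")], net)


class TestMCC:
    def test_triangle_each_node_scores_two(self):
        G = nx.complete_graph(3)
        assert set(network.mcc_scores(G).values()) == {2.0}

    def test_star_center_scores_degree(self):
        G = nx.star_graph(3)  # center 0, leaves 1..3
        scores = network.mcc_scores(G)
        assert scores[0] == 3.0 and scores[1] == 1.0

    def test_matches_brute_force_on_small_graphs(self):
        rng = np.random.default_rng(62)
        for _ in range(50):
            n = int(rng.integers(2, 9))
            G = nx.gnp_random_graph(n, 0.5, seed=int(rng.integers(1e9)))
            assert network.mcc_scores(G) == brute_force_mcc(G)

    def test_isolated_node_scores_zero(self):
        G = nx.Graph()
        G.add_node("x")
        assert network.mcc_scores(G) == {"x": 0.0}

    def test_hubs_top_decile_without_ties(self):
        # 20 nodes with distinct scores at the cut: a K4 where one member
        # carries 3 pendant leaves (MCC 9) and another one leaf (MCC 7)
        G = nx.Graph()
        for i in range(4):
            for j in range(i + 1, 4):
                G.add_edge(f"c{i}", f"c{j}")
        for k in range(3):
            G.add_edge("c0", f"leaf_a{k}")
        G.add_edge("c1", "leaf_b0")
        nx.add_path(G, [f"p{i}" for i in range(12)])
        assert len(G) == 20
        top = network.hubs(G, top_frac=0.10)
        assert top == ["c0", "c1"]


class TestReportAndExport:
    def _demo_net(self):
        return typed_net(
            {"t": "trait", "m": "metabolite", "g": "gene", "r": "miRNA",
             "iso": "lipid"},
            [("t", "m", "assoc"), ("m", "g", "qtl_link"), ("g", "t", "qtl_link"),
             ("r", "g", "mirna_target")],
        )

    def test_same_pathway_flag(self):
        net = self._demo_net()
        subs = network.classify_subnetworks(network.enumerate_circuits(net), net)
        rep = network.subnetwork_report(subs, net,
                                        {"g": ["gmx00020"], "m": ["gmx00020"]})
        assert rep["same_pathway"].tolist() == ["true"]
        rep_unknown = network.subnetwork_report(subs, net)
        assert rep_unknown["same_pathway"].tolist() == ["unknown"]

    @pytest.mark.parametrize("fmt", ["JSON", "GraphML", "SIF"])
    def test_round_trip(self, tmp_path, fmt):
        net = self._demo_net()
        path = tmp_path / f"net.{fmt.lower()}"
        network.export_network(net, path, fmt)
        assert network.import_network(path, fmt) == net

    def test_empty_network_exports(self, tmp_path):
        net = network.TypedNetwork()
        for fmt in ("JSON", "GraphML", "SIF"):
            path = tmp_path / f"empty.{fmt.lower()}"
            network.export_network(net, path, fmt)
            assert network.import_network(path, fmt) == net

    def test_k4_sif_has_six_interaction_lines(self, tmp_path):
        nodes = {f"g{i}": "gene" for i in range(4)}
        edges = [(f"g{i}", f"g{j}", "ppi") for i in range(4) for j in range(i + 1, 4)]
        net = typed_net(nodes, edges)
        network.export_network(net, tmp_path / "k4.sif", "SIF")
        lines = (tmp_path / "k4.sif").read_text().splitlines()
        assert len([l for l in lines if "\t" in l]) == 6

    def test_unsupported_format_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            network.export_network(self._demo_net(), tmp_path / "x", "XGMML")

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_random_typed_network_graphml_round_trip(self, seed):
        rng = np.random.default_rng(seed)
        types = ["trait", "metabolite", "lipid", "gene", "TF", "miRNA"]
        nodes = {f"n{i}": types[int(rng.integers(len(types)))] for i in range(8)}
        net = network.TypedNetwork()
        for n, t in nodes.items():
            net.add_node(n, t)
        provs = sorted(network.PROVENANCES)
        for _ in range(10):
            a, b = (str(v) for v in rng.choice(list(nodes), size=2, replace=False))
            net.add_edge(a, b, provs[int(rng.integers(len(provs)))],
                         weight=float(np.round(rng.uniform(0, 1), 3)))
        import pathlib
        import tempfile
        with tempfile.TemporaryDirectory() as d:
            p = pathlib.Path(d) / "net.graphml"
            network.export_network(net, p, "GraphML")
            assert network.import_network(p, "GraphML") == net
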