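"""Multi-dimensional genetic network assembly and circuit analysis.

The MDGN is a heterogeneous graph over node types {trait, metabolite, lipid,
gene, TF, miRNA} whose edges carry a provenance tag (assoc, qtl_link, coexpr,
ppi, tfbs, mirna_target).  *Circulating sub-networks* are simple cycles of the
undirected skeleton (regulatory edge direction is ignored): a cycle is 3D when
it contains at least one gene/TF, one trait and one metabolite-or-lipid and no
miRNA, and 4D when it additionally contains a miRNA.  Hub nodes are the top
decile of maximal clique centrality, MCC(v) = sum over maximal cliques C
containing v of (|C| - 1)! (degree for nodes whose neighborhood has no edge).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import pandas as pd

NODE_TYPES = {"trait", "metabolite", "lipid", "gene", "TF", "miRNA"}
PROVENANCES = {"assoc", "qtl_link", "coexpr", "ppi", "tfbs", "mirna_target"}


@dataclass(frozen=True)
class NetEdge:
    a: str
    b: str
    edge_type: str
    directed: bool
    weight: float
    provenance: str


class TypedNetwork:
    """Heterogeneous graph with typed nodes and provenance-tagged edges.

    No self-loops; at most one edge per (unordered node pair, provenance).
    """

    def __init__(self):
        self.nodes: dict[str, str] = {}
        self._edges: dict[tuple, NetEdge] = {}

    # -- construction -------------------------------------------------------
    def add_node(self, node: str, node_type: str) -> None:
        if node_type not in NODE_TYPES:
            raise ValueError(f"unknown node type {node_type!r}")
        existing = self.nodes.get(node)
        if existing is None:
            self.nodes[node] = node_type
        elif existing != node_type:
            # TF wins over gene (a TF is a gene); other clashes are errors
            if {existing, node_type} == {"gene", "TF"}:
                self.nodes[node] = "TF"
            else:
                raise ValueError(
                    f"node {node!r} typed both {existing!r} and {node_type!r}"
                )

    def add_edge(self, a: str, b: str, provenance: str, edge_type: str | None = None,
                 directed: bool = False, weight: float = 1.0) -> None:
        if a == b:
            raise ValueError(f"self-loop on {a!r}")
        for endpoint in (a, b):
            if endpoint not in self.nodes:
                raise KeyError(f"edge endpoint {endpoint!r} is not a node")
        if provenance not in PROVENANCES:
            raise ValueError(f"unknown provenance {provenance!r}")
        key = (tuple(sorted((a, b))), provenance)
        if key not in self._edges:
            self._edges[key] = NetEdge(
                a, b, edge_type or provenance, directed, float(weight), provenance
            )

    # -- access -------------------------------------------------------------
    @property
    def edges(self) -> list[NetEdge]:
        return [self._edges[k] for k in sorted(self._edges)]

    def node_type(self, node: str) -> str:
        return self.nodes[node]

    def skeleton(self) -> nx.Graph:
        """Undirected simple graph over all nodes (direction/multiplicity dropped)."""
        G = nx.Graph()
        for node, t in self.nodes.items():
            G.add_node(node, nodetype=t)
        for e in self.edges:
            G.add_edge(e.a, e.b)
        return G

    def counts(self) -> dict:
        by_type: dict[str, int] = {}
        for t in self.nodes.values():
            by_type[t] = by_type.get(t, 0) + 1
        by_prov: dict[str, int] = {}
        for e in self.edges:
            by_prov[e.provenance] = by_prov.get(e.provenance, 0) + 1
        return {"nodes": len(self.nodes), "edges": len(self._edges),
                "node_types": by_type, "edge_provenance": by_prov}

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, TypedNetwork)
            and self.nodes == other.nodes
            and self._edges == other._edges
        )


@dataclass
class SubNetwork:
    cycle: tuple
    node_types: tuple
    dimension: str     # "3D" | "4D" | "other"

    @property
    def size(self) -> int:
        return len(self.cycle)


# ---------------------------------------------------------------------------
# assembly
# ---------------------------------------------------------------------------

def assemble_mdgn(assoc_edges: list, trait_links: list, metab_links: list,
                  grn: TypedNetwork, node_types: dict) -> tuple[TypedNetwork, dict]:
    """Union of the three layers into one typed network.

    ``assoc_edges`` are AssociationEdge objects (first layer);
    ``trait_links``/``metab_links`` are (variable, feature_id) pairs from
    QTL/mQTL-window candidates (second layer, provenance qtl_link); ``grn``
    is the regulatory layer.  ``node_types`` maps every referenced id to its
    type.  Returns the network and an integration report of per-layer counts.
    """
    net = TypedNetwork()

    def ensure(node: str):
        if node not in net.nodes:
            t = node_types.get(node)
            if t is None:
                raise KeyError(f"no node type declared for {node!r}")
            net.add_node(node, t)

    n_assoc = 0
    for e in assoc_edges:
        ensure(e.node_a)
        ensure(e.node_b)
        net.add_edge(e.node_a, e.node_b, "assoc", edge_type=e.edge_class,
                     weight=abs(e.statistic))
        n_assoc += 1
    n_qtl = 0
    for variable, feature in list(trait_links) + list(metab_links):
        ensure(variable)
        ensure(feature)
        net.add_edge(variable, feature, "qtl_link")
        n_qtl += 1
    for node, t in grn.nodes.items():
        net.add_node(node, t)
    for e in grn.edges:
        net.add_edge(e.a, e.b, e.provenance, edge_type=e.edge_type,
                     directed=e.directed, weight=e.weight)
    report = {
        "assoc_edges": n_assoc,
        "qtl_links": n_qtl,
        "grn_edges": len(grn.edges),
        **net.counts(),
    }
    return net, report


# ---------------------------------------------------------------------------
# circuits
# ---------------------------------------------------------------------------

def canonical_cycle(cycle) -> tuple:
    """Lexicographically smallest rotation over both orientations."""
    nodes = list(cycle)
    n = len(nodes)
    best = None
    for seq in (nodes, nodes[::-1]):
        for shift in range(n):
            rot = tuple(seq[(shift + k) % n] for k in range(n))
            if best is None or rot < best:
                best = rot
    return best


def enumerate_circuits(net: TypedNetwork | nx.Graph, min_len: int = 3,
                       max_len: int = 5) -> list[tuple]:
    """All simple cycles of the undirected skeleton with length in
    [min_len, max_len], each in canonical form, sorted."""
    if min_len < 3 or max_len < min_len:
        raise ValueError("need max_len >= min_len >= 3")
    G = net.skeleton() if isinstance(net, TypedNetwork) else net
    out = {
        canonical_cycle(c)
        for c in nx.simple_cycles(G, length_bound=max_len)
        if len(c) >= min_len
    }
    return sorted(out, key=lambda c: (len(c), c))


def classify_subnetworks(cycles: list, net: TypedNetwork) -> list[SubNetwork]:
    """Label each cycle 3D / 4D / other from its node-type composition.

    3D: >= 1 gene-or-TF, >= 1 trait, >= 1 metabolite-or-lipid, no miRNA.
    4D: the 3D composition plus >= 1 miRNA.
    """
    subs = []
    for cycle in cycles:
        types = []
        for node in cycle:
            if node not in net.nodes:
                raise KeyError(f"cycle node {node!r} missing from the network")
            types.append(net.nodes[node])
        tset = set(types)
        has_gene = bool(tset & {"gene", "TF"})
        has_trait = "trait" in tset
        has_compound = bool(tset & {"metabolite", "lipid"})
        has_mirna = "miRNA" in tset
        if has_gene and has_trait and has_compound:
            dim = "4D" if has_mirna else "3D"
        else:
            dim = "other"
        subs.append(SubNetwork(tuple(cycle), tuple(types), dim))
    return subs


# ---------------------------------------------------------------------------
# hubs
# ---------------------------------------------------------------------------

def mcc_scores(net: TypedNetwork | nx.Graph) -> dict[str, float]:
    """Maximal clique centrality: sum over maximal cliques containing v of
    (|C|-1)!.  Every edge that is itself a maximal clique contributes 1, so a
    node whose neighborhood contains no edge scores its degree; isolated
    nodes score 0."""
    G = net.skeleton() if isinstance(net, TypedNetwork) else net
    scores = {v: 0.0 for v in G.nodes}
    for clique in nx.find_cliques(G):
        if len(clique) < 2:
            continue
        w = math.factorial(len(clique) - 1)
        for v in clique:
            scores[v] += w
    return scores


def hubs(net: TypedNetwork | nx.Graph, top_frac: float = 0.10) -> list[str]:
    """Nodes in the top ``top_frac`` of the MCC distribution, ties included,
    ordered by (score desc, id asc)."""
    scores = mcc_scores(net)
    if not scores:
        return []
    ordered = sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))
    k = max(1, int(round(top_frac * len(ordered))))
    cutoff = ordered[k - 1][1]
    return [v for v, s in ordered if s >= cutoff]


# ---------------------------------------------------------------------------
# reports and export
# ---------------------------------------------------------------------------

def subnetwork_report(subs: list, net: TypedNetwork,
                      pathway_map: dict | None = None) -> pd.DataFrame:
    """Tabulate sub-networks with a same-pathway flag.

    The flag is true when any gene/TF and any metabolite/lipid in the cycle
    share a pathway id; with no ``pathway_map`` it is "unknown".
    """
    edge_by_pair: dict = {}
    for e in net.edges:
        edge_by_pair.setdefault(tuple(sorted((e.a, e.b))), []).append(e.provenance)
    rows = []
    for sub in subs:
        if pathway_map is None:
            flag = "unknown"
        else:
            genes = [n for n, t in zip(sub.cycle, sub.node_types) if t in ("gene", "TF")]
            compounds = [n for n, t in zip(sub.cycle, sub.node_types)
                         if t in ("metabolite", "lipid")]
            shared = any(
                set(pathway_map.get(g, [])) & set(pathway_map.get(c, []))
                for g in genes for c in compounds
            )
            flag = str(shared).lower()
        provs = []
        n = len(sub.cycle)
        for i in range(n):
            pair = tuple(sorted((sub.cycle[i], sub.cycle[(i + 1) % n])))
            provs.append("+".join(sorted(edge_by_pair.get(pair, []))))
        rows.append(
            {
                "dimension": sub.dimension,
                "size": sub.size,
                "nodes": ",".join(sub.cycle),
                "node_types": ",".join(sub.node_types),
                "edge_provenance": ";".join(provs),
                "same_pathway": flag,
            }
        )
    return pd.DataFrame(
        rows, columns=["dimension", "size", "nodes", "node_types",
                       "edge_provenance", "same_pathway"]
    )


def export_network(net: TypedNetwork, path, fmt: str = "GraphML") -> None:
    """Write the network as SIF, GraphML or JSON (round-trip safe).

    SIF keeps the Cytoscape ``source<TAB>type<TAB>target`` layout; node types
    and edge attributes ride in a companion ``<path>.nodes.tsv`` /
    ``<path>.edges.tsv`` pair so the import reproduces the network exactly.
    """
    fmt = fmt.lower()
    path = Path(path)
    if fmt == "json":
        doc = {
            "nodes": self_nodes(net),
            "edges": [
                {"a": e.a, "b": e.b, "edge_type": e.edge_type,
                 "directed": e.directed, "weight": e.weight,
                 "provenance": e.provenance}
                for e in net.edges
            ],
        }
        path.write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")
    elif fmt == "graphml":
        G = nx.MultiGraph()
        for node, t in net.nodes.items():
            G.add_node(node, nodetype=t)
        for e in net.edges:
            # src/dst attributes preserve orientation of directed regulatory
            # edges through the undirected multigraph container
            G.add_edge(e.a, e.b, key=e.provenance, provenance=e.provenance,
                       edge_type=e.edge_type, directed=int(e.directed),
                       weight=float(e.weight), src=e.a, dst=e.b)
        nx.write_graphml(G, path)
    elif fmt == "sif":
        with open(path, "w") as fh:
            linked = set()
            for e in net.edges:
                fh.write(f"{e.a}\t{e.edge_type}\t{e.b}\n")
                linked.update((e.a, e.b))
            for node in sorted(set(net.nodes) - linked):
                fh.write(f"{node}\n")
        with open(f"{path}.nodes.tsv", "w") as fh:
            fh.write("node\tnodetype\n")
            for node in sorted(net.nodes):
                fh.write(f"{node}\t{net.nodes[node]}\n")
        with open(f"{path}.edges.tsv", "w") as fh:
            fh.write("node_a\tnode_b\tedge_type\tdirected\tweight\tprovenance\n")
            for e in net.edges:
                fh.write(
                    f"{e.a}\t{e.b}\t{e.edge_type}\t{int(e.directed)}\t"
                    f"{e.weight}\t{e.provenance}\n"
                )
    else:
        raise ValueError(f"unsupported format {fmt!r} (use SIF, GraphML or JSON)")


def self_nodes(net: TypedNetwork) -> dict:
    return {node: net.nodes[node] for node in sorted(net.nodes)}


def import_network(path, fmt: str = "GraphML") -> TypedNetwork:
    fmt = fmt.lower()
    path = Path(path)
    net = TypedNetwork()
    if fmt == "json":
        doc = json.loads(path.read_text())
        for node, t in doc["nodes"].items():
            net.add_node(node, t)
        for e in doc["edges"]:
            net.add_edge(e["a"], e["b"], e["provenance"], e["edge_type"],
                         bool(e["directed"]), e["weight"])
    elif fmt == "graphml":
        G = nx.read_graphml(path, force_multigraph=True)
        for node, data in G.nodes(data=True):
            net.add_node(node, data["nodetype"])
        for a, b, data in G.edges(data=True):
            net.add_edge(data.get("src", a), data.get("dst", b),
                         data["provenance"], data["edge_type"],
                         bool(int(data["directed"])), float(data["weight"]))
    elif fmt == "sif":
        nodes = pd.read_csv(f"{path}.nodes.tsv", sep="\t")
        for _, row in nodes.iterrows():
            net.add_node(row["node"], row["nodetype"])
        edges = pd.read_csv(f"{path}.edges.tsv", sep="\t")
        for _, row in edges.iterrows():
            net.add_edge(row["node_a"], row["node_b"], row["provenance"],
                         row["edge_type"], bool(row["directed"]),
                         float(row["weight"]))
    else:
        raise ValueError(f"unsupported format {fmt!r}")
    return net
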