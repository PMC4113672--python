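"""Assembly and topology of the miRNA-mediated interaction (MMI) network.

Nodes are mRNAs and lncRNAs; each edge is one (lncRNA, mRNA, miRNA)
triple stating that the miRNA mediates the sponge interaction between
the pair, so a pair sharing several miRNAs carries parallel edges
(a multigraph). An edge requires both a high sensitivity score and
dual seed support for its miRNA. Weights on the collapsed pair graph
count distinct mediating miRNAs. The plain correlation network —
one unlabeled edge per cognate pair — serves as the permissive
baseline the MMI network refines.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass

import networkx as nx
import pandas as pd

from .correlation import PairSet
from .seedmatch import SeedIndex, pair_has_support

logger = logging.getLogger(__name__)


class MMINetwork:
    """Bipartite lncRNA/mRNA multigraph with miRNA edge labels."""

    def __init__(self, graph: nx.MultiGraph | None = None) -> None:
        self.graph = graph if graph is not None else nx.MultiGraph()

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def nodes_with_biotype(self, biotype: str) -> set[str]:
        return {n for n, b in self.graph.nodes(data="biotype") if b == biotype}

    @property
    def lncrnas(self) -> set[str]:
        return self.nodes_with_biotype("lncRNA")

    @property
    def mrnas(self) -> set[str]:
        return self.nodes_with_biotype("mRNA")

    def edge_triples(self) -> list[tuple[str, str, str]]:
        """Sorted unique (lncrna, mrna, mirna) triples."""
        triples = []
        for u, v, mirna in self.graph.edges(keys=True):
            lnc, mrna = (u, v) if self.graph.nodes[u]["biotype"] == "lncRNA" else (v, u)
            triples.append((lnc, mrna, mirna))
        return sorted(triples)

    def mirnas_for_pair(self, lncrna: str, mrna: str) -> set[str]:
        if not self.graph.has_edge(lncrna, mrna):
            return set()
        return set(self.graph[lncrna][mrna])

    def to_edge_frame(self) -> pd.DataFrame:
        rows = []
        for lnc, mrna, mirna in self.edge_triples():
            data = self.graph.get_edge_data(lnc, mrna, key=mirna)
            rows.append((lnc, mrna, mirna, data.get("s"), data.get("r_xy")))
        return pd.DataFrame(rows, columns=["lncrna", "mrna", "mirna", "s", "r_xy"])


def build_mmi_network(
    selected_frame: pd.DataFrame,
    index: SeedIndex | None = None,
) -> MMINetwork:
    """Build the MMI network from selected triplets plus seed support.

    *selected_frame* must already contain only high-S triplets (columns
    mrna, lncrna, mirna and optionally s, r_xy). With a seed index,
    triplets whose pair lacks dual seed support for the miRNA are
    dropped; duplicates collapse onto a single keyed edge. Isolated
    nodes cannot arise (nodes exist only as edge endpoints).
    """
    net = MMINetwork()
    g = net.graph
    kept = 0
    for row in selected_frame.itertuples(index=False):
        if index is not None and not pair_has_support(
            row.mrna, row.lncrna, row.mirna, index
        ):
            continue
        g.add_node(row.lncrna, biotype="lncRNA")
        g.add_node(row.mrna, biotype="mRNA")
        g.add_edge(
            row.lncrna,
            row.mrna,
            key=row.mirna,
            mirna=row.mirna,
            s=float(getattr(row, "s", float("nan"))),
            r_xy=float(getattr(row, "r_xy", float("nan"))),
        )
        kept += 1
    if net.n_edges == 0:
        logger.warning("build_mmi_network: empty network")
    logger.info(
        "build_mmi_network: %d nodes (%d lncRNA / %d mRNA), %d edges",
        net.n_nodes,
        len(net.lncrnas),
        len(net.mrnas),
        net.n_edges,
    )
    return net


def collapse_weights(net: MMINetwork) -> pd.DataFrame:
    """Weighted pair graph: weight = number of distinct mediating miRNAs.

    The weights sum to the edge count of the parent multigraph.
    """
    rows = [
        (lnc, mrna, len(net.mirnas_for_pair(lnc, mrna)))
        for lnc, mrna in {(l, m) for l, m, _ in net.edge_triples()}
    ]
    frame = pd.DataFrame(rows, columns=["lncrna", "mrna", "weight"])
    return frame.sort_values(
        ["weight", "lncrna", "mrna"], ascending=[False, True, True]
    ).reset_index(drop=True)


@dataclass
class ComponentInfo:
    nodes: set[str]
    n_nodes: int
    n_edges: int
    dominant_mirna: str | None
    dominant_share: float
    dominant_tie: bool


def connected_components(net: MMINetwork) -> list[ComponentInfo]:
    """Maximal connected subgraphs, largest first.

    Connectivity is unweighted and undirected. Each component reports
    its modal edge label (the dominant mediating miRNA); ties are
    broken lexicographically and flagged.
    """
    infos = []
    for nodes in nx.connected_components(net.graph):
        sub = net.graph.subgraph(nodes)
        labels = Counter(key for _, _, key in sub.edges(keys=True))
        dominant, share, tie = None, 0.0, False
        if labels:
            top = max(labels.values())
            winners = sorted(m for m, c in labels.items() if c == top)
            dominant = winners[0]
            tie = len(winners) > 1
            share = 100.0 * top / sub.number_of_edges()
        infos.append(
            ComponentInfo(
                set(nodes), len(nodes), sub.number_of_edges(), dominant, share, tie
            )
        )
    infos.sort(key=lambda c: (-c.n_nodes, -c.n_edges, min(c.nodes)))
    return infos


def components_frame(components) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (i + 1, c.n_nodes, c.n_edges, c.dominant_mirna, c.dominant_share, c.dominant_tie)
            for i, c in enumerate(components)
        ],
        columns=[
            "component",
            "n_nodes",
            "n_edges",
            "dominant_mirna",
            "dominant_share_pct",
            "dominant_tie",
        ],
    )


def rank_hubs(
    net: MMINetwork,
    biotype_filter: str | None = None,
    families: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Rank nodes by incident edge count (multi-edges counted).

    Returns one row per node with the multigraph degree, the number of
    distinct partners, and the top mediating miRNA family with its share
    of the node's edges. *families* maps miRNA id -> family label
    (e.g. the seed); by default each miRNA is its own family. Ties in
    degree are broken lexicographically by node id.
    """
    rows = []
    for node, biotype in net.graph.nodes(data="biotype"):
        if biotype_filter is not None and biotype != biotype_filter:
            continue
        edge_degree = net.graph.degree(node)
        partners = set(net.graph[node])
        labels = Counter(
            families.get(key, key) if families else key
            for _, _, key in net.graph.edges(node, keys=True)
        )
        top = max(labels.values())
        winners = sorted(f for f, c in labels.items() if c == top)
        rows.append(
            (
                node,
                biotype,
                edge_degree,
                len(partners),
                winners[0],
                100.0 * top / edge_degree,
            )
        )
    frame = pd.DataFrame(
        rows,
        columns=[
            "node",
            "biotype",
            "edge_degree",
            "n_partners",
            "top_family",
            "top_family_share_pct",
        ],
    )
    return frame.sort_values(
        ["edge_degree", "node"], ascending=[False, True]
    ).reset_index(drop=True)


def relationship_profile(net: MMINetwork, lncrna_id: str) -> dict[str, int]:
    """Classify a lncRNA's partner relationships.

    Per partner mRNA: *many-to-one* when the pair shares more than one
    miRNA; for single-miRNA partners, *one-to-many* when that miRNA also
    links this lncRNA to other mRNAs, else *one-to-one*. The counts sum
    to the node's distinct partner count.
    """
    if lncrna_id not in net.graph:
        raise KeyError(f"node {lncrna_id!r} not in network")
    mirna_reach = Counter(key for _, _, key in net.graph.edges(lncrna_id, keys=True))
    counts = {"many_to_one": 0, "one_to_many": 0, "one_to_one": 0}
    for partner in net.graph[lncrna_id]:
        shared = net.graph[lncrna_id][partner]
        if len(shared) > 1:
            counts["many_to_one"] += 1
        else:
            (mirna,) = shared
            if mirna_reach[mirna] > 1:
                counts["one_to_many"] += 1
            else:
                counts["one_to_one"] += 1
    return counts


def mediation_stats(net: MMINetwork, family) -> tuple[float, float, float]:
    """Share of the network mediated by a miRNA family.

    Returns percentages of (edges labeled by a family member, lncRNA
    nodes incident to such an edge, mRNA nodes incident to such an
    edge). An empty network yields zeros.
    """
    family = set(family)
    if not family:
        raise ValueError("family must be non-empty")
    if net.n_edges == 0:
        return (0.0, 0.0, 0.0)
    triples = net.edge_triples()
    hit = [(l, m) for l, m, mirna in triples if mirna in family]
    edge_share = 100.0 * len(hit) / len(triples)
    lnc_hit = {l for l, _ in hit}
    mrna_hit = {m for _, m in hit}
    lnc_share = 100.0 * len(lnc_hit) / len(net.lncrnas)
    mrna_share = 100.0 * len(mrna_hit) / len(net.mrnas)
    return (edge_share, lnc_share, mrna_share)


def build_correlation_network(pairs: PairSet) -> nx.Graph:
    """Simple graph with one unlabeled edge per selected cognate pair."""
    g = nx.Graph()
    for mrna, lncrna, r in pairs.frame[["mrna", "lncrna", "r"]].itertuples(index=False):
        g.add_node(lncrna, biotype="lncRNA")
        g.add_node(mrna, biotype="mRNA")
        g.add_edge(lncrna, mrna, r=float(r))
    return g


def write_edge_list(net: MMINetwork, path) -> None:
    """Three-column export: node1 (lncRNA), node2 (mRNA), interaction (miRNA)."""
    frame = net.to_edge_frame()[["lncrna", "mrna", "mirna"]]
    frame.columns = ["node1", "node2", "interaction"]
    frame.to_csv(path, sep="\t", index=False)


def write_gml(net: MMINetwork, path) -> None:
    nx.write_gml(net.graph, str(path))
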