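import numpy as np
import pandas as pd
import pytest

from spongenet.correlation import PairSet
from spongenet.io import SequenceSet
from spongenet.network import (
    build_correlation_network,
    build_mmi_network,
    collapse_weights,
    components_frame,
    connected_components,
    mediation_stats,
    rank_hubs,
    relationship_profile,
    write_edge_list,
    write_gml,
)
from spongenet.seedmatch import build_seed_index, extract_seed


def _selection(rows):
    return pd.DataFrame(rows, columns=["mrna", "lncrna", "mirna", "s", "r_xy"])


def _net(rows):
    return build_mmi_network(_selection(rows))


@pytest.fixture()
def two_community_net():
    # community 1: l1 linked to m1..m3 via mirA (and m1 also via mirB)
    # community 2: l2 - m4 via mirC
    return _net(
        [
            ("m1", "l1", "mirA", 0.5, 0.8),
            ("m1", "l1", "mirB", 0.4, 0.8),
            ("m2", "l1", "mirA", 0.5, 0.7),
            ("m3", "l1", "mirA", 0.6, 0.9),
            ("m4", "l2", "mirC", 0.7, 0.85),
        ]
    )


class TestBuildNetwork:
    def test_multigraph_semantics_one_pair_two_edges(self):
        net = _net(
            [("m1", "l1", "mirA", 0.5, 0.8), ("m1", "l1", "mirB", 0.4, 0.8)]
        )
        assert net.n_nodes == 2
        assert net.n_edges == 2
        assert net.mirnas_for_pair("l1", "m1") == {"mirA", "mirB"}

    def test_duplicate_triplets_collapse(self):
        net = _net(
            [("m1", "l1", "mirA", 0.5, 0.8), ("m1", "l1", "mirA", 0.5, 0.8)]
        )
        assert net.n_edges == 1

    def test_seed_support_is_required_alongside_s(self):
        seed = extract_seed("mirA", "UAACACUGUCU")
        utrs = SequenceSet({"m1": "GGG" + seed.site + "GGG", "m2": "G" * 12}, "utr3")
        lncs = SequenceSet({"l1": "CC" + seed.site + "CC"}, "lnc_transcript")
        index = build_seed_index([seed], utrs, lncs)
        sel = _selection(
            [("m1", "l1", "mirA", 0.4, 0.8), ("m2", "l1", "mirA", 0.9, 0.9)]
        )
        net = build_mmi_network(sel, index)
        assert net.edge_triples() == [("l1", "m1", "mirA")]

    def test_no_isolated_nodes_and_bipartite_typing(self, two_community_net):
        g = two_community_net.graph
        assert all(g.degree(n) > 0 for n in g)
        for u, v in g.edges():
            assert {g.nodes[u]["biotype"], g.nodes[v]["biotype"]} == {"lncRNA", "mRNA"}

    def test_empty_selection_warns_not_raises(self, caplog):
        with caplog.at_level("WARNING"):
            net = _net([])
        assert net.n_edges == 0


class TestWeights:
    def test_pair_weight_counts_distinct_mirnas(self, two_community_net):
        weights = collapse_weights(two_community_net)
        w = weights.set_index(["lncrna", "mrna"])["weight"]
        assert w[("l1", "m1")] == 2
        assert w[("l1", "m2")] == 1

    def test_weights_sum_to_edge_count(self, two_community_net):
        assert collapse_weights(two_community_net)["weight"].sum() == 5

    def test_all_singleton_weights_means_pairs_equal_edges(self):
        net = _net([("m1", "l1", "mirA", 0.5, 0.8), ("m2", "l2", "mirB", 0.5, 0.8)])
        weights = collapse_weights(net)
        assert (weights["weight"] == 1).all()
        assert len(weights) == net.n_edges


class TestComponents:
    def test_two_planted_communities(self, two_community_net):
        comps = connected_components(two_community_net)
        assert len(comps) == 2
        assert comps[0].n_nodes == 4 and comps[0].n_edges == 4
        assert comps[1].n_nodes == 2 and comps[1].n_edges == 1

    def test_dominant_mirna_is_modal_edge_label(self, two_community_net):
        comps = connected_components(two_community_net)
        assert comps[0].dominant_mirna == "mirA"
        assert comps[0].dominant_share == pytest.approx(75.0)
        assert not comps[0].dominant_tie

    def test_component_nodes_partition_node_set(self, two_community_net):
        comps = connected_components(two_community_net)
        union = set().union(*(c.nodes for c in comps))
        assert union == set(two_community_net.graph)
        assert sum(c.n_nodes for c in comps) == two_community_net.n_nodes

    def test_single_edge_component(self):
        comps = connected_components(_net([("m1", "l1", "mirA", 0.5, 0.8)]))
        assert len(comps) == 1 and comps[0].n_nodes == 2 and comps[0].n_edges == 1

    def test_tie_flagged_and_broken_lexicographically(self):
        net = _net(
            [("m1", "l1", "mirB", 0.5, 0.8), ("m2", "l1", "mirA", 0.5, 0.8)]
        )
        (comp,) = connected_components(net)
        assert comp.dominant_mirna == "mirA"
        assert comp.dominant_tie

    def test_components_frame_layout(self, two_community_net):
        frame = components_frame(connected_components(two_community_net))
        assert list(frame["component"]) == [1, 2]


class TestHubs:
    def test_edge_degree_counts_multiedges(self):
        rows = [
            (f"m{i}", "l1", mir, 0.5, 0.8)
            for i in range(1, 4)
            for mir in ("mirA", "mirB")
        ]
        hubs = rank_hubs(_net(rows))
        top = hubs.iloc[0]
        assert top["node"] == "l1"
        assert top["edge_degree"] == 6
        assert top["n_partners"] == 3

    def test_single_edge_degrees(self):
        hubs = rank_hubs(_net([("m1", "l1", "mirA", 0.5, 0.8)]))
        assert set(hubs["edge_degree"]) == {1}

    def test_biotype_filter(self, two_community_net):
        hubs = rank_hubs(two_community_net, biotype_filter="lncRNA")
        assert set(hubs["biotype"]) == {"lncRNA"}

    def test_family_mapping_aggregates_shares(self):
        net = _net(
            [
                ("m1", "l1", "mirA", 0.5, 0.8),
                ("m2", "l1", "mirB", 0.5, 0.8),
                ("m3", "l1", "mirC", 0.5, 0.8),
            ]
        )
        hubs = rank_hubs(net, families={"mirA": "fam1", "mirB": "fam1", "mirC": "fam2"})
        top = hubs[hubs["node"] == "l1"].iloc[0]
        assert top["top_family"] == "fam1"
        assert top["top_family_share_pct"] == pytest.approx(200 / 3)

    def test_planted_hub_ranks_first(self):
        rows = [("m0", "lbg", "mirZ", 0.5, 0.8)]
        rows += [(f"m{i}", "lhub", "mirA", 0.5, 0.8) for i in range(1, 11)]
        hubs = rank_hubs(_net(rows), biotype_filter="lncRNA")
        assert hubs.iloc[0]["node"] == "lhub"


class TestRelationships:
    def test_many_to_one_one_to_many_one_to_one(self):
        rows = [
            # partner mA shares 3 miRNAs -> many-to-one
            ("mA", "l1", "mir1", 0.5, 0.8),
            ("mA", "l1", "mir2", 0.5, 0.8),
            ("mA", "l1", "mir3", 0.5, 0.8),
            # mir4 links l1 to 4 mRNAs -> those partners one-to-many
            ("mB", "l1", "mir4", 0.5, 0.8),
            ("mC", "l1", "mir4", 0.5, 0.8),
            ("mD", "l1", "mir4", 0.5, 0.8),
            ("mE", "l1", "mir4", 0.5, 0.8),
            # unique miRNA, single mRNA -> one-to-one
            ("mF", "l1", "mir5", 0.5, 0.8),
        ]
        counts = relationship_profile(_net(rows), "l1")
        assert counts == {"many_to_one": 1, "one_to_many": 4, "one_to_one": 1}

    def test_counts_sum_to_distinct_partner_count(self, two_community_net):
        counts = relationship_profile(two_community_net, "l1")
        assert sum(counts.values()) == 3

    def test_unknown_node_rejected(self, two_community_net):
        with pytest.raises(KeyError):
            relationship_profile(two_community_net, "nope")


class TestMediation:
    def test_edge_share_is_ratio(self):
        rows = [(f"m{i}", "l1", "mirA", 0.5, 0.8) for i in range(7)]
        rows += [(f"m{i}", "l1", "mirB", 0.5, 0.8) for i in range(7, 10)]
        edge, lnc, mrna = mediation_stats(_net(rows), {"mirA"})
        assert edge == pytest.approx(70.0)

    def test_absent_family_gives_zero(self, two_community_net):
        assert mediation_stats(two_community_net, {"mirZ"}) == (0.0, 0.0, 0.0)

    def test_exhaustive_family_gives_hundreds(self, two_community_net):
        assert mediation_stats(two_community_net, {"mirA", "mirB", "mirC"}) == (
            100.0,
            100.0,
            100.0,
        )


class TestCorrelationNetwork:
    def _pairs(self, rows):
        return PairSet(pd.DataFrame(rows, columns=["mrna", "lncrna", "r"]), 0.7, 99.0)

    def test_shared_lncrna_makes_a_star(self):
        g = build_correlation_network(
            self._pairs([("m1", "l1", 0.8), ("m2", "l1", 0.9), ("m3", "l1", 0.75)])
        )
        assert g.number_of_nodes() == 4 and g.number_of_edges() == 3
        assert g.degree("l1") == 3

    def test_empty_pairset(self):
        g = build_correlation_network(self._pairs([]))
        assert g.number_of_nodes() == 0

    def test_mmi_network_is_subgraph_of_correlation_network(self):
        pairs = self._pairs([("m1", "l1", 0.8), ("m2", "l1", 0.9), ("m3", "l2", 0.75)])
        corr_net = build_correlation_network(pairs)
        mmi = _net([("m1", "l1", "mirA", 0.5, 0.8)])  # subset of the pairs
        assert set(mmi.graph.nodes) <= set(corr_net.nodes)
        for lnc, mrna, _ in mmi.edge_triples():
            assert corr_net.has_edge(lnc, mrna)


class TestMonotoneShrinkage:
    def test_stricter_s_threshold_never_adds_edges(self):
        rng = np.random.default_rng(13)
        rows = [
            (f"m{i}", f"l{i % 4}", f"mir{i % 3}", float(s), 0.8)
            for i, s in enumerate(rng.uniform(0, 1, 30))
        ]
        frame = _selection(rows)
        edge_sets = []
        for threshold in (0.2, 0.5, 0.8):
            net = build_mmi_network(frame[frame["s"] > threshold])
            edge_sets.append(set(net.edge_triples()))
        assert edge_sets[2] <= edge_sets[1] <= edge_sets[0]


def test_exports_are_readable(tmp_path, two_community_net):
    edge_path = tmp_path / "edges.tsv"
    write_edge_list(two_community_net, edge_path)
    back = pd.read_csv(edge_path, sep="\t")
    assert list(back.columns) == ["node1", "node2", "interaction"]
    assert len(back) == two_community_net.n_edges
    write_gml(two_community_net, tmp_path / "net.gml")
    assert (tmp_path / "net.gml").stat().st_size > 0
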