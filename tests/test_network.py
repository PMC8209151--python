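"""Association-network assembly, masking and persistence."""

import numpy as np
import pytest

from mdlink import (
    EdgeRecord,
    HeteroNetwork,
    LabeledPairSet,
    NodeRef,
    adjacency_row,
    assemble_network,
    load_edge_list,
    remove_md_edges,
)
from mdlink.network import NetworkError


def _edge(a, b, ta="miRNA", tb="disease", assoc="miRNA-disease"):
    return EdgeRecord(NodeRef(ta, a), NodeRef(tb, b), assoc)


class TestLoadEdgeList:
    def test_reads_two_rows(self, tmp_path):
        p = tmp_path / "e.tsv"
        p.write_text("# header\nm1\td1\nm2\td2\n")
        edges = load_edge_list(p, "miRNA-disease")
        assert len(edges) == 2
        assert edges[0].source.node_type == "disease"  # canonical sort order
        assert {e.assoc_type for e in edges} == {"miRNA-disease"}

    def test_duplicate_pair_collapses(self, tmp_path):
        p = tmp_path / "e.tsv"
        p.write_text("m1\td1\nm1\td1\n")
        assert len(load_edge_list(p, "miRNA-disease")) == 1

    def test_malformed_row_names_line(self, tmp_path):
        p = tmp_path / "e.tsv"
        p.write_text("m1\td1\nm1\n")
        with pytest.raises(NetworkError, match=":2"):
            load_edge_list(p, "miRNA-disease")

    def test_missing_file(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            load_edge_list(tmp_path / "nope.tsv", "miRNA-disease")

    def test_unknown_assoc_type(self, tmp_path):
        p = tmp_path / "e.tsv"
        p.write_text("a\tb\n")
        with pytest.raises(NetworkError):
            load_edge_list(p, "miRNA-gene")


class TestAssemble:
    def test_node_union_and_degree(self):
        net = assemble_network(
            [_edge("m1", "d1"), _edge("m1", "p1", tb="protein", assoc="miRNA-protein")]
        )
        assert len(net.nodes) == 3
        assert net.degree(NodeRef("miRNA", "m1")) == 2

    def test_symmetry_and_edge_count(self, small_fixture):
        s = small_fixture.network.adjacency
        assert np.array_equal(s, s.T)
        assert s.sum() == 2 * small_fixture.network.n_edges()

    def test_degree_sum_matches_edge_list(self, small_fixture):
        # independent oracle: count unique undirected pairs across edge lists
        n_unique = sum(len(set(v)) for v in small_fixture.edge_lists.values())
        assert small_fixture.network.adjacency.sum() == 2 * n_unique

    def test_empty_edges_rejected(self):
        with pytest.raises(NetworkError):
            assemble_network([])

    def test_self_loop_rejected(self):
        with pytest.raises(NetworkError):
            EdgeRecord(
                NodeRef("protein", "p1"), NodeRef("protein", "p1"),
                "protein-protein",
            )
            _ = assemble_network(
                [EdgeRecord(NodeRef("protein", "p1"), NodeRef("protein", "p1"),
                            "protein-protein")]
            )


class TestRemoveMdEdges:
    def test_removes_both_orientations(self, small_fixture):
        net = small_fixture.network
        m, d = small_fixture.positives.positives()[0]
        out = remove_md_edges(net, [(m, d)])
        i, j = out.index_of(NodeRef("miRNA", m)), out.index_of(NodeRef("disease", d))
        assert out.adjacency[i, j] == 0 and out.adjacency[j, i] == 0
        assert out.degree(NodeRef("miRNA", m)) == net.degree(NodeRef("miRNA", m)) - 1

    def test_input_not_mutated_and_empty_identity(self, small_fixture):
        net = small_fixture.network
        before = net.adjacency.copy()
        out = remove_md_edges(net, [])
        assert np.array_equal(out.adjacency, before)
        remove_md_edges(net, small_fixture.positives.positives())
        assert np.array_equal(net.adjacency, before)

    def test_mass_removal_count(self, small_fixture):
        net = small_fixture.network
        pos = small_fixture.positives.positives()
        out = remove_md_edges(net, pos)
        assert net.adjacency.sum() - out.adjacency.sum() == 2 * len(pos)

    def test_only_md_block_touched(self, small_fixture):
        net = small_fixture.network
        out = remove_md_edges(net, small_fixture.positives.positives())
        keep = [
            i for i, n in enumerate(net.nodes)
            if n.node_type not in ("miRNA", "disease")
        ]
        assert np.array_equal(
            net.adjacency[np.ix_(keep, keep)], out.adjacency[np.ix_(keep, keep)]
        )

    def test_absent_pair_logged_not_fatal(self, small_fixture, caplog):
        out = remove_md_edges(small_fixture.network, [("zzz", "yyy")])
        assert np.array_equal(out.adjacency, small_fixture.network.adjacency)


class TestAdjacencyRow:
    def test_row_matches_edge_membership(self, small_fixture):
        net = small_fixture.network
        node = net.nodes_of_type("miRNA")[3]
        row = adjacency_row(net, node)
        assert len(row) == len(net.nodes)
        # oracle: scan all edge lists for this node's partners
        partners = set()
        for assoc, pairs in small_fixture.edge_lists.items():
            from mdlink.network import ASSOC_TYPES
            ta, tb = ASSOC_TYPES[assoc]
            for a, b in pairs:
                if (ta, a) == (node.node_type, node.node_id):
                    partners.add(NodeRef(tb, b))
                if (tb, b) == (node.node_type, node.node_id):
                    partners.add(NodeRef(ta, a))
        expected = np.zeros(len(net.nodes))
        for p in partners:
            expected[net.index_of(p)] = 1
        assert np.array_equal(row, expected)

    def test_unknown_node(self, small_fixture):
        with pytest.raises(NetworkError):
            adjacency_row(small_fixture.network, NodeRef("miRNA", "nope"))


def test_serialization_round_trip(tmp_path, small_fixture):
    net = small_fixture.network
    net.to_files(tmp_path / "nodes.tsv", tmp_path / "edges.tsv")
    back = HeteroNetwork.from_files(tmp_path / "nodes.tsv", tmp_path / "edges.tsv")
    assert back.nodes == net.nodes
    assert np.array_equal(back.adjacency, net.adjacency)


def test_labeled_pair_set_round_trip(tmp_path, small_fixture):
    pos = small_fixture.positives
    pos.to_file(tmp_path / "pairs.tsv")
    back = LabeledPairSet.from_file(tmp_path / "pairs.tsv")
    assert back.pairs == pos.pairs


def test_labeled_pair_set_rejects_duplicates():
    with pytest.raises(NetworkError):
        LabeledPairSet((("m1", "d1", 1), ("m1", "d1", 0)))
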