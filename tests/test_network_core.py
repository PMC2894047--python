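import networkx as nx
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dgnet.network import (
    GeneSet,
    Network,
    NetworkFormatError,
    clustering_coefficient,
    degree,
    induced_subgraph,
    largest_connected_component,
    map_gene_set,
    read_gene_set,
    read_network,
    shortest_path_lengths,
    write_edge_list,
    write_graphml,
)

TRIANGLE = Network.from_edges([("A", "B"), ("B", "C"), ("C", "A")])


class TestNormalization:
    def test_self_loops_and_duplicates_dropped(self):
        net = Network.from_edges([("A", "B"), ("B", "C"), ("C", "A"), ("A", "A"), ("a", "b")])
        assert net.n_nodes == 3 and net.n_edges == 3
        assert net.n_self_loops_dropped == 1
        assert net.n_duplicates_dropped == 1
        net.validate()

    def test_single_edge(self):
        net = Network.from_edges([("A", "B")])
        assert net.n_nodes == 2 and net.n_edges == 1
        assert degree(net, "A") == 1

    def test_case_insensitive_identifiers(self):
        net = Network.from_edges([("grin1", "Dlg4")])
        assert net.nodes == {"GRIN1", "DLG4"}


class TestReaders:
    def test_edge_list(self, tmp_path):
        p = tmp_path / "net.tsv"
        p.write_text("# comment\nA B\nB C\nC A\nA A\na b\n")
        net = read_network(p)
        assert net.n_nodes == 3 and net.n_edges == 3

    def test_edge_list_malformed_line_names_lineno(self, tmp_path):
        p = tmp_path / "net.tsv"
        p.write_text("A B\nJUSTONE\n")
        with pytest.raises(NetworkFormatError, match=":2"):
            read_network(p)

    def test_empty_file_rejected(self, tmp_path):
        p = tmp_path / "net.tsv"
        p.write_text("")
        with pytest.raises(NetworkFormatError, match="empty"):
            read_network(p)

    def test_sif(self, tmp_path):
        p = tmp_path / "net.sif"
        p.write_text("A pp B C\nD pp A\nLONER\n")
        net = read_network(p)
        assert net.nodes == {"A", "B", "C", "D", "LONER"}
        assert net.n_edges == 3
        assert degree(net, "LONER") == 0

    def test_graphml_roundtrip(self, tmp_path):
        p = tmp_path / "net.graphml"
        write_graphml(TRIANGLE, p, node_attrs={"deg": {"A": 2}})
        back = read_network(p)
        assert back.nodes == TRIANGLE.nodes
        assert back.sorted_edges() == TRIANGLE.sorted_edges()

    def test_edge_list_roundtrip_deterministic(self, tmp_path):
        p1, p2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
        write_edge_list(TRIANGLE, p1)
        write_edge_list(read_network(p1), p2)
        assert p1.read_text() == p2.read_text()

    def test_gene_set_file(self, tmp_path):
        p = tmp_path / "genes.txt"
        p.write_text("# header\ngrin1\nDLG4\nGRIN1\n")
        gs = read_gene_set(p)
        assert gs.members == frozenset({"GRIN1", "DLG4"})


class TestMapGeneSet:
    net = Network.from_edges([("A", "B"), ("B", "C")])

    @pytest.mark.parametrize(
        "members, expected_mapped, expected_unmapped",
        [
            ({"A", "C", "Z"}, {"A", "C"}, 1),
            ({"X", "Y"}, set(), 2),
            ({"A", "B", "C"}, {"A", "B", "C"}, 0),
        ],
    )
    def test_mapping(self, members, expected_mapped, expected_unmapped):
        mapped, n_unmapped = map_gene_set(self.net, GeneSet.from_iterable("s", members))
        assert mapped.members == frozenset(expected_mapped)
        assert n_unmapped == expected_unmapped


class TestElementaryOps:
    def test_degree(self):
        star = Network.from_edges([("HUB", leaf) for leaf in "ABCDE"])
        assert degree(TRIANGLE, "A") == 2
        assert degree(star, "HUB") == 5
        iso = Network.from_edges([("A", "B")], nodes=["Z"])
        assert degree(iso, "Z") == 0
        with pytest.raises(KeyError):
            degree(TRIANGLE, "NOPE")

    def test_shortest_path_lengths(self):
        path = Network.from_edges([("A", "B"), ("B", "C")])
        assert shortest_path_lengths(path, "A") == {"A": 0, "B": 1, "C": 2}
        two = Network.from_edges([("A", "B"), ("C", "D")])
        assert set(shortest_path_lengths(two, "A")) == {"A", "B"}
        k4 = Network.from_edges([(u, v) for u in "ABCD" for v in "ABCD" if u < v])
        d = shortest_path_lengths(k4, "A")
        assert all(d[v] == 1 for v in "BCD")

    def test_clustering_coefficient(self):
        assert clustering_coefficient(TRIANGLE, "A") == 1.0
        star = Network.from_edges([("HUB", leaf) for leaf in "ABC"])
        assert clustering_coefficient(star, "HUB") == 0.0
        # node A with neighbors B, C, D and only B-C present: 1 of 3 pairs
        net = Network.from_edges([("A", "B"), ("A", "C"), ("A", "D"), ("B", "C")])
        assert clustering_coefficient(net, "A") == pytest.approx(2 / 6)

    def test_induced_subgraph(self):
        sub = induced_subgraph(TRIANGLE, {"A", "B"})
        assert sub.n_nodes == 2 and sub.n_edges == 1
        assert induced_subgraph(TRIANGLE, TRIANGLE.nodes).sorted_edges() == TRIANGLE.sorted_edges()
        assert induced_subgraph(TRIANGLE, set()).n_nodes == 0

    def test_largest_connected_component(self):
        net = Network.from_edges([("A", "B"), ("B", "C"), ("C", "A"), ("X", "Y")])
        assert largest_connected_component(net).nodes == {"A", "B", "C"}
        assert largest_connected_component(TRIANGLE).nodes == TRIANGLE.nodes
        tied = Network.from_edges([("A", "B"), ("C", "D")])
        assert largest_connected_component(tied).nodes == {"A", "B"}
        with pytest.raises(ValueError):
            largest_connected_component(Network.from_edges([]))


edge_lists = st.lists(
    st.tuples(st.integers(0, 15), st.integers(0, 15)), min_size=1, max_size=40
)


class TestProperties:
    @given(edges=edge_lists)
    @settings(max_examples=60, deadline=None)
    def test_normalization_invariants(self, edges):
        net = Network.from_edges(edges)
        net.validate()

    @given(edges=edge_lists)
    @settings(max_examples=40, deadline=None)
    def test_shortest_paths_symmetric(self, edges):
        net = Network.from_edges(edges)
        for u in net.sorted_nodes()[:5]:
            du = shortest_path_lengths(net, u)
            for v, d in du.items():
                assert shortest_path_lengths(net, v)[u] == d

    @given(edges=edge_lists, keep=st.sets(st.integers(0, 15)))
    @settings(max_examples=40, deadline=None)
    def test_induced_subgraph_idempotent(self, edges, keep):
        net = Network.from_edges(edges)
        keep = {str(k) for k in keep}
        once = induced_subgraph(net, keep)
        twice = induced_subgraph(once, keep)
        assert once.nodes == twice.nodes
        assert once.sorted_edges() == twice.sorted_edges()
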