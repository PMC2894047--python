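import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dgnet.network import GeneSet, Network
from dgnet.pathways import (
    PathwayCollection,
    bh_fdr,
    crosstalk_all_pairs,
    crosstalk_graph,
    fisher_exact_2x2,
    pathway_enrichment,
    pathway_link_set,
    read_gmt,
    write_gmt,
)

from oracles import fisher_greater_enumeration, fisher_two_sided_enumeration

TRIANGLE = Network.from_edges([("A", "B"), ("B", "C"), ("C", "A")])


class TestGmtIO:
    def test_roundtrip(self, tmp_path):
        pc = PathwayCollection(
            {"PW1": frozenset({"A", "B", "C"}), "PW2": frozenset({"B", "D"})},
            source="toy",
        )
        path = tmp_path / "sets.gmt"
        write_gmt(pc, path)
        back = read_gmt(path)
        assert back.pathways == pc.pathways

    def test_short_line_rejected(self, tmp_path):
        p = tmp_path / "bad.gmt"
        p.write_text("NAME\tdescription-without-genes\n")
        with pytest.raises(ValueError):
            read_gmt(p)

    def test_empty_pathway_rejected(self):
        with pytest.raises(ValueError):
            PathwayCollection({"EMPTY": frozenset()})


class TestFisherExact:
    def test_small_table_against_enumeration(self):
        assert fisher_exact_2x2(2, 0, 0, 2, "greater") == pytest.approx(1 / 6)
        assert fisher_greater_enumeration(2, 0, 0, 2) == pytest.approx(1 / 6)

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact_2x2(0, 0, 0, 0)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact_2x2(-1, 2, 3, 4)

    def test_symmetric_table_shows_no_association(self):
        assert fisher_exact_2x2(5, 5, 5, 5, "greater") > 0.5

    @pytest.mark.parametrize(
        "table",
        [(3, 1, 2, 6), (0, 4, 4, 0), (2, 2, 2, 2), (7, 0, 3, 5), (1, 9, 9, 1)],
    )
    def test_both_alternatives_match_enumeration(self, table):
        a, b, c, d = table
        assert fisher_exact_2x2(a, b, c, d, "greater") == pytest.approx(
            fisher_greater_enumeration(a, b, c, d)
        )
        assert fisher_exact_2x2(a, b, c, d, "two-sided") == pytest.approx(
            fisher_two_sided_enumeration(a, b, c, d)
        )


class TestBhFdr:
    def test_hand_worked_example(self):
        assert bh_fdr([0.01, 0.02, 0.03, 0.5]) == pytest.approx([0.04, 0.04, 0.04, 0.5])

    def test_single_value(self):
        assert bh_fdr([1.0]) == [1.0]

    def test_equal_values_unchanged(self):
        assert bh_fdr([0.2, 0.2, 0.2]) == pytest.approx([0.2, 0.2, 0.2])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    @settings(max_examples=100, deadline=None)
    def test_adjusted_at_least_raw_and_monotone(self, ps):
        qs = bh_fdr(ps)
        assert all(q >= p - 1e-12 for p, q in zip(ps, qs))
        order = np.argsort(ps)
        sorted_qs = [qs[i] for i in order]
        assert all(a <= b + 1e-12 for a, b in zip(sorted_qs, sorted_qs[1:]))


class TestEnrichment:
    def test_planted_pathway_passes_filter(self):
        genes = [f"G{i}" for i in range(100)]
        pc = PathwayCollection({"HIT": frozenset(genes[:6]), "OTHER": frozenset(genes[50:80])})
        disease = GeneSet.from_iterable("disease", genes[:6])
        background = GeneSet.from_iterable("bg", genes)
        results = {r.pathway: r for r in pathway_enrichment(pc, disease, background)}
        hit = results["HIT"]
        assert hit.overlap_count == 6 and hit.passes_filter
        assert hit.p_value < 1e-6
        assert hit.score == pytest.approx(-math.log10(hit.p_value))

    def test_disjoint_pathway_fails_filter(self):
        genes = [f"G{i}" for i in range(50)]
        pc = PathwayCollection({"PW": frozenset(genes[20:30])})
        results = pathway_enrichment(
            pc,
            GeneSet.from_iterable("disease", genes[:10]),
            GeneSet.from_iterable("bg", genes),
        )
        assert results[0].overlap_count == 0 and not results[0].passes_filter

    def test_large_overlap_with_weak_p_fails_filter(self):
        # overlap > 5 but the pathway is so large the overlap is expected
        genes = [f"G{i}" for i in range(40)]
        pc = PathwayCollection({"BIG": frozenset(genes)})
        disease = GeneSet.from_iterable("disease", genes[:8])
        results = pathway_enrichment(pc, disease, GeneSet.from_iterable("bg", genes))
        assert results[0].overlap_count == 8
        assert not results[0].passes_filter  # p = 1: score 0

    def test_unmapped_disease_rejected(self):
        pc = PathwayCollection({"PW": frozenset({"A"})})
        with pytest.raises(ValueError):
            pathway_enrichment(
                pc,
                GeneSet.from_iterable("disease", {"ZZZ"}),
                GeneSet.from_iterable("bg", {"A", "B"}),
            )


class TestLinkSet:
    def test_partial_pathway(self):
        assert pathway_link_set(TRIANGLE, {"A", "B"}) == {("A", "B")}

    def test_full_triangle(self):
        assert len(pathway_link_set(TRIANGLE, {"A", "B", "C"})) == 3

    def test_no_internal_edges(self):
        net = Network.from_edges([("A", "B"), ("C", "D")])
        assert pathway_link_set(net, {"A", "C"}) == set()


def _chain_network(n):
    return Network.from_edges([(f"G{i}", f"G{i+1}") for i in range(n - 1)])


class TestCrosstalk:
    def test_pair_count_matches_combinations(self):
        net = _chain_network(200)
        rng = np.random.default_rng(0)
        pc = PathwayCollection(
            {
                f"PW{i:02d}": frozenset(f"G{j}" for j in rng.choice(200, 10, replace=False))
                for i in range(24)
            }
        )
        results = crosstalk_all_pairs(pc, net)
        assert len(results) == 276  # C(24, 2)

    def test_identical_pathways_are_extreme(self):
        net = _chain_network(100)
        shared = frozenset(f"G{i}" for i in range(0, 30))
        pc = PathwayCollection(
            {
                "TWIN-A": shared,
                "TWIN-B": shared,
                "OTHER-1": frozenset(f"G{i}" for i in range(40, 70)),
                "OTHER-2": frozenset(f"G{i}" for i in range(70, 99)),
            }
        )
        results = crosstalk_all_pairs(pc, net)
        by_pair = {(r.pathway_a, r.pathway_b): r for r in results}
        twin = by_pair[("TWIN-A", "TWIN-B")]
        assert twin.n_common_nodes == 30 and twin.total_nodes == 60
        assert twin.p_nodes == min(r.p_nodes for r in results)
        assert twin.significant

    def test_disjoint_pair_not_significant(self):
        net = _chain_network(100)
        pc = PathwayCollection(
            {
                "A": frozenset(f"G{i}" for i in range(0, 20)),
                "B": frozenset(f"G{i}" for i in range(15, 35)),  # overlaps A
                "C": frozenset(f"G{i}" for i in range(60, 80)),  # disjoint from all
            }
        )
        results = crosstalk_all_pairs(pc, net)
        by_pair = {(r.pathway_a, r.pathway_b): r for r in results}
        assert not by_pair[("A", "C")].significant
        assert by_pair[("A", "C")].p_nodes >= by_pair[("A", "B")].p_nodes

    def test_fewer_than_three_rejected(self):
        pc = PathwayCollection({"A": frozenset({"G1"}), "B": frozenset({"G2"})})
        with pytest.raises(ValueError):
            crosstalk_all_pairs(pc, _chain_network(10))

    def test_crosstalk_graph_edges(self):
        net = _chain_network(100)
        shared = frozenset(f"G{i}" for i in range(0, 30))
        pc = PathwayCollection(
            {
                "TWIN-A": shared,
                "TWIN-B": shared,
                "OTHER-1": frozenset(f"G{i}" for i in range(40, 70)),
                "OTHER-2": frozenset(f"G{i}" for i in range(70, 99)),
            }
        )
        results = crosstalk_all_pairs(pc, net)
        g = crosstalk_graph(results, enrichment_scores={"TWIN-A": 3.0})
        assert g.n_nodes == 4
        assert set(g.sorted_edges()) == {
            (r.pathway_a, r.pathway_b) for r in results if r.significant
        }
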