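"""Attended-category estimation and degree-of-attention computation."""

import math

import numpy as np
import pytest

from ontosearch import (
    ArticleRecord,
    Concept,
    ConceptGraph,
    QuerySpec,
    attended_category,
    build_attention_map,
    category_correction,
    category_count,
    lowest_common_superordinates,
    pairwise_attention,
)
from conftest import make_g0
from oracles import brute_pair_attention, parents_of, random_dag

ALPHA = 1.7


def record(article_id, concepts):
    return ArticleRecord(article_id, frozenset(concepts))


class TestCategoryCount:
    def test_counts_by_category(self, mixed_graph):
        T = {"GO:0000002", "GO:0000003", "IPR000001"}
        assert category_count(mixed_graph, T, "molecular_function") == 2
        assert category_count(mixed_graph, T, "family") == 1

    def test_empty_set(self, mixed_graph):
        from ontosearch import CATEGORIES

        assert all(category_count(mixed_graph, set(), C) == 0 for C in CATEGORIES)

    def test_partition_property(self, mixed_graph):
        from ontosearch import CATEGORIES

        T = set(mixed_graph.nodes)
        assert sum(category_count(mixed_graph, T, C) for C in CATEGORIES) == len(T)


def make_tally_graph():
    """Isolated concepts tuned so the graph-wide InterPro tally is
    family=10, domain=10 (total 20): the InterPro correction branch becomes
    cross_pairs * 10/20."""
    concepts = (
        [Concept(f"GO:000000{i}", "molecular_function") for i in range(1, 7)]
        + [Concept("GO:0000010", "biological_process")]
        + [Concept(f"IPR00001{i:02d}", "family") for i in range(10)]
        + [Concept(f"IPR00002{i:02d}", "domain") for i in range(10)]
    )
    return ConceptGraph(concepts, [])


class TestCategoryCorrection:
    def test_go_branch_is_pair_count(self):
        graph = make_tally_graph()
        Tp = {"GO:0000001", "GO:0000002"}
        Ta = {"GO:0000003", "GO:0000004", "GO:0000005"}
        assert category_correction(graph, Tp, Ta, "molecular_function") == 6.0

    def test_interpro_branch_apportions_cross_pairs(self):
        graph = make_tally_graph()
        # 2 MF + 1 family vs 2 MF + 1 domain: 4 same-GO pairs of 9 total,
        # 5 cross pairs; family share 10/20 -> 2.5
        Tp = {"GO:0000001", "GO:0000002", "IPR0000100"}
        Ta = {"GO:0000003", "GO:0000004", "IPR0000200"}
        assert category_correction(graph, Tp, Ta, "family") == pytest.approx(2.5)
        assert category_correction(graph, Tp, Ta, "domain") == pytest.approx(2.5)

    def test_zero_counts_give_zero_correction(self):
        graph = make_tally_graph()
        Tp = {"GO:0000001"}
        Ta = {"GO:0000010"}  # BP: no MF pair
        assert category_correction(graph, Tp, Ta, "molecular_function") == 0.0

    def test_inapplicable_without_interpro_concepts(self, g0):
        assert category_correction(g0, {"C"}, {"D"}, "family") is None

    def test_empty_sets_are_an_error(self, g0):
        with pytest.raises(ValueError):
            category_correction(g0, set(), {"D"}, "molecular_function")


class TestAttendedCategory:
    def test_same_category_pairs_select_their_category(self, mixed_graph):
        Tp = {"GO:0000002", "GO:0000004"}
        Ta = {"GO:0000003", "GO:0000002"}
        # all four pairwise apexes are molecular_function concepts
        for tp in Tp:
            for ta in Ta:
                for pair in lowest_common_superordinates(mixed_graph, tp, ta):
                    assert mixed_graph.category(pair.lca) == "molecular_function"
        assert attended_category(mixed_graph, Tp, Ta) == "molecular_function"

    def test_no_common_superordinate_gives_none(self, mixed_graph):
        # MF component vs BP component: disjoint ancestries
        assert attended_category(mixed_graph, {"GO:0000004"}, {"GO:0000011"}) is None

    def test_interpro_apex_can_win(self, mixed_graph):
        # family-family pair meets at a family concept; rev favors it
        assert (
            attended_category(mixed_graph, {"IPR000002"}, {"IPR000001"}) == "family"
        )


class TestPairwiseAttention:
    def test_worked_pair_values(self, g0):
        (pair,) = lowest_common_superordinates(g0, "C", "D")
        att = pairwise_attention(g0, "C", "D", pair, ALPHA)
        assert att["C"] == pytest.approx(0.3864, abs=1e-4)
        assert att["D"] == pytest.approx(0.3864, abs=1e-4)
        assert att["A"] == pytest.approx(0.2273, abs=1e-4)

    def test_self_pair_degenerates_to_one(self, g0):
        (pair,) = lowest_common_superordinates(g0, "C", "C")
        assert pairwise_attention(g0, "C", "C", pair, ALPHA) == {"C": 1.0}

    def test_sums_to_one_on_random_graphs(self):
        rng = np.random.default_rng(7)
        for _ in range(15):
            nodes, edges = random_dag(rng, max_nodes=20)
            graph = ConceptGraph([Concept(i, c) for i, c in nodes], edges)
            ids = sorted(graph.nodes)
            for _ in range(5):
                t1, t2 = (ids[int(i)] for i in rng.integers(len(ids), size=2))
                for pair in lowest_common_superordinates(graph, t1, t2):
                    att = pairwise_attention(graph, t1, t2, pair, ALPHA)
                    assert sum(att.values()) == pytest.approx(1.0)
                    assert set(att) == set(pair.node_union())

    def test_matches_brute_force_evaluation(self, g0):
        (pair,) = lowest_common_superordinates(g0, "C", "D")
        expected = brute_pair_attention(parents_of(
            [("A", "R"), ("B", "R"), ("C", "A"), ("D", "A"), ("D", "B"), ("E", "C")]
        ), "C", "D", ALPHA)
        got = pairwise_attention(g0, "C", "D", pair, ALPHA)
        assert got == pytest.approx(expected)

    def test_alpha_at_most_one_is_an_error(self, g0):
        (pair,) = lowest_common_superordinates(g0, "C", "D")
        with pytest.raises(ValueError):
            pairwise_attention(g0, "C", "D", pair, 1.0)


class TestBuildAttentionMap:
    def test_worked_single_pair_query(self, g0):
        query = QuerySpec(record("P", {"C"}), record("A1", {"D"}), "all_pairs")
        att = build_attention_map(g0, query, ALPHA)
        assert att.values == pytest.approx(
            {"C": 1.0, "D": 1.0, "A": 0.5882}, abs=1e-4
        )

    def test_mode_none_is_empty(self, g0):
        att = build_attention_map(g0, QuerySpec(record("P", {"C"}), mode="none"))
        assert len(att) == 0 and att.get("C") == 0.0

    def test_category_mode_without_estimate_is_empty(self, mixed_graph):
        # primary and additional in disconnected components: no apex at all
        query = QuerySpec(
            record("P", {"GO:0000004"}), record("A1", {"GO:0000011"}), "category"
        )
        att = build_attention_map(mixed_graph, query)
        assert len(att) == 0 and att.attended_category is None

    def test_missing_additional_article_is_an_error(self, g0):
        with pytest.raises(ValueError):
            QuerySpec(record("P", {"C"}), mode="all_pairs")

    def test_nonzero_map_peaks_at_exactly_one(self, mixed_graph):
        query = QuerySpec(
            record("P", {"GO:0000004", "IPR000002"}),
            record("A1", {"GO:0000003", "IPR000001"}),
            "all_pairs",
        )
        att = build_attention_map(mixed_graph, query)
        assert max(att.values.values()) == 1.0
        assert all(0.0 < v <= 1.0 for v in att.values.values())

    def test_off_path_concepts_keep_zero_attention(self, mixed_graph):
        query = QuerySpec(
            record("P", {"GO:0000004"}), record("A1", {"GO:0000003"}), "all_pairs"
        )
        att = build_attention_map(mixed_graph, query)
        allowed = set()
        for pair in lowest_common_superordinates(
            mixed_graph, "GO:0000004", "GO:0000003"
        ):
            allowed |= pair.node_union()
        assert set(att.values) <= allowed
        assert att.get("GO:0000011") == 0.0

    def test_attention_decays_with_distance_along_side_path(self):
        # chain T4 -> T3 -> T2 -> T1 -> T0; query pair (T4, T2), apex T2
        concepts = [Concept(f"T{i}", "molecular_function") for i in range(5)]
        edges = [(f"T{i}", f"T{i-1}") for i in range(1, 5)]
        graph = ConceptGraph(concepts, edges)
        query = QuerySpec(record("P", {"T4"}), record("A1", {"T2"}), "all_pairs")
        att = build_attention_map(graph, query)
        assert att.get("T4") > att.get("T3") > 0.0

    def test_attention_tsv_export(self, g0):
        import io

        from ontosearch.attention import write_attention_tsv

        query = QuerySpec(record("P", {"C"}), record("A1", {"D"}), "all_pairs")
        out = io.StringIO()
        write_attention_tsv(build_attention_map(g0, query), out)
        lines = out.getvalue().strip().splitlines()
        assert lines[0].startswith("A\t0.588")
        assert len(lines) == 3

    def test_category_mode_matches_all_pairs_when_apexes_agree(self, g0):
        # G0 is single-category: every apex lies in the attended category
        primary = record("P", {"C", "E"})
        additional = record("A1", {"D"})
        att_all = build_attention_map(
            g0, QuerySpec(primary, additional, "all_pairs")
        )
        att_cat = build_attention_map(
            g0, QuerySpec(primary, additional, "category")
        )
        assert att_cat.values == pytest.approx(att_all.values)
        assert att_cat.attended_category == "molecular_function"
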