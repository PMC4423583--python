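"""Citation-based relevance sets, average precision, and mode comparison.

Relevance judgements are derived from citations rather than expert labels:
an article that cites both query articles is treated as evidence that
whatever else it cites is related to the query.  The positives for a query
(primary, additional) are therefore the union of the reference lists of all
co-citing articles, intersected with the search corpus and stripped of the
query articles themselves; every other corpus article is a negative.

Ranking quality is summarized by average precision per query and mean
average precision (MAP) across queries.  ``compare_modes`` runs the three
attention configurations — no additional article, all path pairs, and
attended-category-restricted — over a query list and reports per-mode MAPs
with Wilcoxon signed-rank p-values on the paired per-query APs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

from scipy import stats

from .attention import MODES, QuerySpec
from .corpus_io import ArticleRecord, CitationGraph
from .ontology_graph import ConceptGraph
from .similarity import SimilarityParams, rank_corpus

logger = logging.getLogger("ontosearch")


@dataclass(frozen=True)
class RelevanceSet:
    """Positive/negative partition of a corpus for one query pair."""

    positives: frozenset[str]
    negatives: frozenset[str]
    query: tuple[str, str]

    @property
    def has_positives(self) -> bool:
        return bool(self.positives)


def build_relevance_set(
    citations: CitationGraph,
    corpus_ids,
    primary: str,
    additional: str,
) -> RelevanceSet:
    """Positives: corpus articles cited by any co-citer of both query
    articles, excluding the query articles; negatives: the rest."""
    if primary == additional:
        raise ValueError("primary and additional must differ")
    corpus_ids = frozenset(corpus_ids)
    cited_union: set[str] = set()
    for cited_set in citations.edges.values():
        if primary in cited_set and additional in cited_set:
            cited_union |= cited_set
    positives = (cited_union & corpus_ids) - {primary, additional}
    negatives = corpus_ids - positives - {primary, additional}
    return RelevanceSet(frozenset(positives), frozenset(negatives), (primary, additional))


def average_precision(ranking: Sequence[str], relevance: RelevanceSet) -> float:
    """AP of a ranked id list, normalized by the total number of positives
    (positives missing from the ranking contribute zero)."""
    if not relevance.positives:
        raise ValueError("average precision is undefined with no positives")
    if len(set(ranking)) != len(ranking):
        raise ValueError("ranking contains duplicate ids")
    hits = 0
    total = 0.0
    for rank, article_id in enumerate(ranking, start=1):
        if article_id in relevance.positives:
            hits += 1
            total += hits / rank
    return total / len(relevance.positives)


def mean_average_precision(per_query_ap: Sequence[float]) -> float:
    if not per_query_ap:
        raise ValueError("MAP of an empty query list is undefined")
    return float(sum(per_query_ap)) / len(per_query_ap)


@dataclass
class ModeComparison:
    """Per-mode MAP and per-query AP tables for one corpus and query list."""

    map_by_mode: dict[str, float]
    ap_by_mode: dict[str, dict[tuple[str, str], float]]
    skipped_queries: int
    wilcoxon_p: dict[tuple[str, str], Optional[float]] = field(default_factory=dict)


def _wilcoxon_p(x: Sequence[float], y: Sequence[float]) -> Optional[float]:
    """Two-sided signed-rank p-value, or None when undefined (all ties /
    single pair)."""
    diffs = [a - b for a, b in zip(x, y)]
    if len(diffs) < 2 or all(d == 0 for d in diffs):
        return None
    try:
        return float(stats.wilcoxon(x, y).pvalue)
    except ValueError:
        return None


def compare_modes(
    graph: ConceptGraph,
    corpus: Sequence[ArticleRecord],
    citations: CitationGraph,
    queries: Sequence[tuple[str, str]],
    params: Optional[SimilarityParams] = None,
    modes: Sequence[str] = MODES,
) -> ModeComparison:
    """Rank and score every query under each attention mode.

    Queries whose citation-derived positives are empty cannot be scored and
    are skipped (their count is reported); an entirely skipped query list is
    an error.  The corpus seen by the ranking is exactly the corpus scored
    by AP.
    """
    params = params or SimilarityParams()
    by_id = {article.id: article for article in corpus}
    corpus_ids = frozenset(by_id)
    ap_by_mode: dict[str, dict[tuple[str, str], float]] = {m: {} for m in modes}
    skipped = 0
    for primary_id, additional_id in queries:
        for qid in (primary_id, additional_id):
            if qid not in by_id:
                raise ValueError(f"query article {qid!r} is not in the corpus")
        relevance = build_relevance_set(citations, corpus_ids, primary_id, additional_id)
        if not relevance.has_positives:
            skipped += 1
            continue
        for mode in modes:
            query = QuerySpec(
                primary=by_id[primary_id],
                additional=None if mode == "none" else by_id[additional_id],
                mode=mode,
            )
            ranking = rank_corpus(graph, query, corpus, params)
            ap = average_precision([aid for aid, _ in ranking], relevance)
            ap_by_mode[mode][(primary_id, additional_id)] = ap
    if skipped:
        logger.warning("skipped %d queries with no citation-derived positives", skipped)
    if all(not table for table in ap_by_mode.values()):
        raise ValueError("every query was skipped: no citation-derived positives")
    map_by_mode = {
        mode: mean_average_precision(list(table.values()))
        for mode, table in ap_by_mode.items()
    }
    report = ModeComparison(map_by_mode, ap_by_mode, skipped)
    mode_list = list(modes)
    for i, m1 in enumerate(mode_list):
        for m2 in mode_list[i + 1 :]:
            shared = sorted(set(ap_by_mode[m1]) & set(ap_by_mode[m2]))
            report.wilcoxon_p[(m1, m2)] = _wilcoxon_p(
                [ap_by_mode[m1][q] for q in shared],
                [ap_by_mode[m2][q] for q in shared],
            )
    return report
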