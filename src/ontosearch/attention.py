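"""Query-intention modelling: attended category and degree of attention.

A query is a pair of articles — the one being read (primary, concept set
T_p) and a related one the user has also looked at (additional, T_a).  The
intention behind the query is assumed to live in what the two articles have
in common, which the hierarchy makes concrete: the lowest common
superordinate concepts of all concept pairs (tp, ta) in T_p x T_a.

Two estimates are derived from those apex concepts:

* the *attended category* — which of the seven concept categories carries
  the intention, chosen by tallying apex categories with a correction
  (``rev``) for the structural bias of the integrated graph (apexes of
  cross-category pairs are always InterPro concepts, and InterPro category
  sizes are heavily skewed);
* a per-concept *degree of attention* in (0, 1] — concepts on the
  shortest-related path pairs receive weight decaying as ``alpha**-d`` with
  the hop distance d to the nearest query concept, normalized per pair so
  short (specific) pairs concentrate more attention than long (vague) ones,
  summed over all pairs, then rescaled so the maximum is exactly 1.

Concepts off every shortest-related path pair have attention 0.  Attention
later enters concept similarity as a per-node discount of the distance
penalty.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Optional

from .corpus_io import ArticleRecord
from .ontology_graph import (
    CATEGORIES,
    GO_CATEGORIES,
    IPR_CATEGORIES,
    ConceptGraph,
    PathPair,
    lowest_common_superordinates,
)

#: Attention modes: no additional article / all path pairs contribute /
#: only pairs whose apex falls in the estimated attended category.
MODES = ("none", "all_pairs", "category")


@dataclass(frozen=True)
class QuerySpec:
    """A two-article query and the attention mode to run it under."""

    primary: ArticleRecord
    additional: Optional[ArticleRecord] = None
    mode: str = "none"

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"unknown mode {self.mode!r}; expected one of {MODES}")
        if self.mode == "none" and self.additional is not None:
            raise ValueError("mode 'none' takes no additional article")
        if self.mode != "none" and self.additional is None:
            raise ValueError(f"mode {self.mode!r} requires an additional article")


@dataclass(frozen=True)
class CategoryTally:
    """Per-category concept counts n(T, C) and correction values rev."""

    counts: dict[str, int]
    rev: dict[str, Optional[float]]


@dataclass(frozen=True)
class AttentionMap:
    """concept id -> degree of attention in (0, 1]; absent concepts are 0."""

    values: dict[str, float]
    attended_category: Optional[str] = None
    query: Optional[QuerySpec] = None

    def get(self, concept_id: str) -> float:
        return self.values.get(concept_id, 0.0)

    def __len__(self) -> int:
        return len(self.values)


def category_count(graph: ConceptGraph, T, C: str) -> int:
    """n(T, C): how many members of concept set T belong to category C."""
    if C not in CATEGORIES:
        raise ValueError(f"unknown category {C!r}")
    return sum(1 for t in T if graph.category(t) == C)


def category_correction(graph: ConceptGraph, Tp, Ta, C: str) -> Optional[float]:
    """The bias correction rev^C for attended-category selection.

    GO categories: the number of same-category (tp, ta) pairs,
    n(Tp,C) * n(Ta,C).  InterPro categories: the cross-category pair count
    |Tp||Ta| - sum_C' n(Tp,C') n(Ta,C') apportioned by the category's share
    of all InterPro concepts in the graph.  Returns None when the graph has
    no InterPro concepts at all (the share is undefined).
    """
    if not Tp or not Ta:
        raise ValueError("Tp and Ta must be nonempty")
    if C in GO_CATEGORIES:
        return float(category_count(graph, Tp, C) * category_count(graph, Ta, C))
    tally = graph.category_tally()
    total_ipr = sum(tally.get(c, 0) for c in IPR_CATEGORIES)
    if total_ipr == 0:
        return None
    same_go_pairs = sum(
        category_count(graph, Tp, c) * category_count(graph, Ta, c)
        for c in GO_CATEGORIES
    )
    cross_pairs = len(Tp) * len(Ta) - same_go_pairs
    return cross_pairs * tally.get(C, 0) / total_ipr


def _lca_category_tally(graph: ConceptGraph, Tp, Ta) -> Counter:
    """Multiset tally of apex categories over all (tp, ta) pairs; each
    co-minimal apex of each pair contributes once."""
    tally: Counter = Counter()
    for tp in sorted(Tp):
        for ta in sorted(Ta):
            for pair in lowest_common_superordinates(graph, tp, ta):
                tally[graph.category(pair.lca)] += 1
    return tally


def attended_category(graph: ConceptGraph, Tp, Ta) -> Optional[str]:
    """The category whose corrected apex count n(T_lca, C)/rev^C is largest.

    Categories with rev^C of 0 (or undefined) are ineligible; ties go to
    the earlier category in the fixed order (the three GO categories first,
    then the four InterPro ones).  None when no pair has a common
    superordinate concept or no category is eligible.
    """
    tally = _lca_category_tally(graph, Tp, Ta)
    if not tally:
        return None
    best: Optional[str] = None
    best_score = float("-inf")
    for C in CATEGORIES:
        rev = category_correction(graph, Tp, Ta, C)
        if rev is None or rev <= 0:
            continue
        score = tally.get(C, 0) / rev
        if score > best_score:
            best, best_score = C, score
    return best


def pairwise_attention(
    graph: ConceptGraph, tp: str, ta: str, pair: PathPair, alpha: float
) -> dict[str, float]:
    """Normalized attention of one shortest-related path pair.

    Raw weights decay as ``alpha**-d`` with the shortest upward hop count d
    from the query concept on whose side path the node lies; the apex,
    reached from both sides, takes the average of the two decays.  Should a
    node sit on both side paths (possible in a DAG) the primary side wins.
    The weights are normalized over the pair's node union, so each pair
    carries total attention mass 1.
    """
    if alpha <= 1:
        raise ValueError("alpha must be > 1")
    d_tp = graph.upward_distances(tp)
    d_ta = graph.upward_distances(ta)
    raw: dict[str, float] = {}
    raw[pair.lca] = 0.5 * (
        alpha ** -d_tp[pair.lca] + alpha ** -d_ta[pair.lca]
    )
    for t in pair.left_path[1:]:
        raw[t] = alpha ** -d_tp[t]
    for t in pair.right_path[1:]:
        if t not in raw:
            raw[t] = alpha ** -d_ta[t]
    total = sum(raw.values())
    return {t: v / total for t, v in raw.items()}


def build_attention_map(
    graph: ConceptGraph, query: QuerySpec, alpha: float = 1.7
) -> AttentionMap:
    """Accumulate pairwise attention over the whole query and rescale.

    mode ``none``: empty map (every concept keeps attention 0, similarity
    reduces to the pure distance decay).  mode ``all_pairs``: every
    co-minimal path pair of every (tp, ta) contributes.  mode ``category``:
    only pairs whose apex lies in the estimated attended category
    contribute; if no category can be estimated the map is empty.  The
    accumulated totals are divided by their maximum, so a nonempty map has
    maximum exactly 1.
    """
    if query.mode == "none":
        return AttentionMap({}, None, query)
    Tp = query.primary.concepts
    Ta = query.additional.concepts
    target: Optional[str] = None
    if query.mode == "category":
        target = attended_category(graph, Tp, Ta)
        if target is None:
            return AttentionMap({}, None, query)
    accumulated: dict[str, float] = defaultdict(float)
    for tp in sorted(Tp):
        for ta in sorted(Ta):
            for pair in lowest_common_superordinates(graph, tp, ta):
                if target is not None and graph.category(pair.lca) != target:
                    continue
                for t, v in pairwise_attention(graph, tp, ta, pair, alpha).items():
                    accumulated[t] += v
    if not accumulated:
        return AttentionMap({}, target, query)
    peak = max(accumulated.values())
    return AttentionMap(
        {t: v / peak for t, v in accumulated.items()}, target, query
    )


def write_attention_tsv(attention: AttentionMap, tsv) -> None:
    """Two-column export (concept id, attention) for inspection."""
    import pandas as pd

    rows = sorted(attention.values.items())
    pd.DataFrame(rows).to_csv(tsv, sep="\t", header=False, index=False)
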