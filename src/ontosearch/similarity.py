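"""Concept and article similarity, and corpus ranking.

Two concepts are similar when few concepts separate them from their lowest
common superordinate concept.  With the deterministic shortest-related path
pair of (t1, t2) and its node union U:

    Sim_concept(t1, t2) = 1 / prod_{t in U} alpha**(1 - att(t))

and 0 when no common superordinate concept exists.  With all attention 0
this is alpha**-|U|, a pure exponential decay in the separation; attending
to a node on the path (att -> 1) removes its factor from the penalty, so
intention raises the similarity of concept pairs that meet near attended
concepts.

The decay constant alpha is calibrated so that concepts separated by 8 path
nodes — half the maximum root-to-leaf depth of GO — are about 1% similar,
giving the default alpha = 1.7.

Article similarity is the asymmetric best-match sum

    Sim_concepts(T1, T2) = sum_{t1 in T1} max_{t2 in T2} Sim_concept(t1, t2)

with T1 the query (primary) article and T2 the search target; ranking a
corpus scores every target against the query under one attention map.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

from .attention import AttentionMap, QuerySpec, build_attention_map
from .corpus_io import ArticleRecord
from .ontology_graph import ConceptGraph, lowest_common_superordinates


@dataclass(frozen=True)
class SimilarityParams:
    """Tunables of the similarity model; alpha is the per-node decay."""

    alpha: float = 1.7

    def __post_init__(self) -> None:
        if not self.alpha > 1:
            raise ValueError("alpha must be > 1")


def calibrate_alpha(
    target_similarity: float = 0.01, path_nodes: int = 8, decimals: int = 1
) -> float:
    """Largest alpha (rounded down to ``decimals``) with
    ``alpha**-path_nodes >= target_similarity``.

    The defaults encode the GO depth argument: 8 nodes is half the maximum
    depth from a GO root to a terminal, and such concepts should retain
    about 1% similarity.  Returns 1.7 under the defaults.
    """
    if not 0 < target_similarity < 1:
        raise ValueError("target_similarity must be in (0, 1)")
    step = 10.0**-decimals
    alpha = target_similarity ** (-1.0 / path_nodes)
    alpha = math.floor(round(alpha / step, 9)) * step
    # guard against floating-point edge cases at the boundary
    while alpha**-path_nodes < target_similarity:
        alpha -= step
    return round(alpha, decimals)


def concept_similarity(
    graph: ConceptGraph,
    t1: str,
    t2: str,
    attention: Optional[AttentionMap] = None,
    params: Optional[SimilarityParams] = None,
) -> float:
    """Sim_concept(t1, t2) over the deterministic first shortest-related
    path pair; 0 when the concepts share no superordinate concept."""
    params = params or SimilarityParams()
    pairs = lowest_common_superordinates(graph, t1, t2)
    if not pairs:
        return 0.0
    union = pairs[0].node_union()
    if attention is None:
        exponent = float(len(union))
    else:
        exponent = sum(1.0 - attention.get(t) for t in union)
    return params.alpha**-exponent


def article_similarity(
    graph: ConceptGraph,
    T1,
    T2,
    attention: Optional[AttentionMap] = None,
    params: Optional[SimilarityParams] = None,
    _cache: Optional[dict] = None,
) -> float:
    """Best-match sum of T2 against T1 (asymmetric; T1 is the query side)."""
    params = params or SimilarityParams()
    total = 0.0
    for t1 in sorted(T1):
        best = 0.0
        for t2 in sorted(T2):
            if _cache is not None:
                key = (t1, t2)
                sim = _cache.get(key)
                if sim is None:
                    sim = concept_similarity(graph, t1, t2, attention, params)
                    _cache[key] = sim
            else:
                sim = concept_similarity(graph, t1, t2, attention, params)
            if sim > best:
                best = sim
        total += best
    return total


def rank_corpus(
    graph: ConceptGraph,
    query: QuerySpec,
    corpus: Sequence[ArticleRecord],
    params: Optional[SimilarityParams] = None,
) -> list[tuple[str, float]]:
    """Score every corpus article against the query and sort.

    The attention map is built once from the query; both query articles are
    excluded from the ranking.  Sort is by descending score, ties broken by
    ascending article id, so rankings are fully deterministic.
    """
    params = params or SimilarityParams()
    attention = build_attention_map(graph, query, params.alpha)
    excluded = {query.primary.id}
    if query.additional is not None:
        excluded.add(query.additional.id)
    cache: dict = {}
    scored = [
        (
            article.id,
            article_similarity(
                graph, query.primary.concepts, article.concepts,
                attention, params, _cache=cache,
            ),
        )
        for article in corpus
        if article.id not in excluded
    ]
    scored.sort(key=lambda item: (-item[1], item[0]))
    return scored
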