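"""Seeded generators for concept graphs and retrieval benchmarks.

Everything downstream — parsing aside — can be exercised without any
ontology download: ``generate_concept_graph`` builds an integrated-style
DAG (three singly-rooted GO components, four InterPro forests, InterPro->GO
cross-links) and ``generate_benchmark`` plants an intention signal in a
corpus over it.

The planted benchmark mirrors the premise of the retrieval method: an
article touches several facets, and only the facet shared with the
additional article carries the query intention.  Each query is built around
a "focus" concept of the planted category plus two "distractor" concepts
with descendant pools disjoint from the focus pool.  The primary article
mixes focus-pool concepts with its own distractor facet; the additional
article mixes focus-pool concepts with a different distractor facet, so the
two query articles agree only on the focus.  The articles relevant to the
query draw a fraction ``signal_strength`` of their concepts from the focus
pool; an equal number of *confounder* articles draw the same fraction from
the primary's distractor pool (they resemble the primary through the
unattended facet and are never relevant); remaining background articles
draw uniformly.  Synthetic co-citing articles cite the query pair plus
exactly the planted relevant set, so the citation-derived relevance
protocol recovers the plant by construction.  At ``signal_strength`` 0 all
target articles are drawn from the same uniform distribution and ranking
can only achieve chance-level precision.

All generators are pure functions of their spec (seed included): reruns are
identical, and each generator draws from its own namespaced random stream
so adding one never perturbs another.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .corpus_io import (
    ArticleRecord,
    CitationGraph,
    write_article_concepts,
    write_citation_graph,
)
from .ontology_graph import (
    DEFAULT_EXCLUDED_ROOTS,
    GO_CATEGORIES,
    IPR_CATEGORIES,
    Concept,
    ConceptGraph,
    write_graph_tsv,
)

# stream namespaces, one per generator
_NS_GRAPH = 101
_NS_BENCH = 202

#: Every 5th InterPro entry of a category starts a new tree; the resulting
#: forest roots are the only anchors available for cross-links.
_IPR_ROOT_STRIDE = 5


@dataclass(frozen=True)
class GraphSpec:
    """Shape of a synthetic integrated concept graph.

    Category node counts exclude the three GO roots, which are always added
    (with the real GO root accessions) and registered as excluded roots.
    """

    nodes_per_go_category: tuple[int, int, int] = (30, 30, 30)
    nodes_per_ipr_category: tuple[int, int, int, int] = (25, 15, 10, 10)
    extra_parent_probability: float = 0.15
    crosslink_count: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n < 0 for n in self.nodes_per_go_category + self.nodes_per_ipr_category):
            raise ValueError("node counts must be >= 0")
        if not 0 <= self.extra_parent_probability <= 1:
            raise ValueError("extra_parent_probability must be in [0, 1]")


@dataclass(frozen=True)
class BenchmarkSpec:
    """Shape of a planted-intention retrieval benchmark.

    ``n_articles`` counts the search-target corpus (planted-relevant,
    confounder, and background articles); the query articles and co-citing
    articles are extra.  ``signal_strength`` is the fraction of a relevant
    article's concepts drawn from the query pair's focus-concept
    descendants — and, symmetrically, of a confounder article's concepts
    drawn from the primary article's distractor pool.
    """

    n_articles: int = 200
    concepts_per_article: int = 6
    n_queries: int = 3
    planted_category: str = "molecular_function"
    signal_strength: float = 0.7
    n_cociting: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_queries < 1:
            raise ValueError("n_queries must be >= 1")
        if not 0 <= self.signal_strength <= 1:
            raise ValueError("signal_strength must be in [0, 1]")
        if self.concepts_per_article < 1:
            raise ValueError("concepts_per_article must be >= 1")

    @property
    def n_relevant_per_query(self) -> int:
        """Planted-relevant articles per query: 5% of the corpus, min 3."""
        return max(3, round(0.05 * self.n_articles))


_GO_ROOT_BY_CATEGORY = dict(
    zip(GO_CATEGORIES, ("GO:0008150", "GO:0003674", "GO:0005575"))
)


def generate_concept_graph(spec: GraphSpec) -> ConceptGraph:
    """Build a seeded integrated-style concept DAG.

    Each GO category is one component rooted at its (excluded) root; every
    other node takes one uniform primary parent among the earlier nodes of
    its component and, with ``extra_parent_probability``, one extra parent,
    so the graph is acyclic by construction.  InterPro categories are
    forests; ``crosslink_count`` of their tree roots become children of
    uniformly chosen non-root GO nodes.
    """
    rng = np.random.default_rng([_NS_GRAPH, spec.seed])
    concepts: list[Concept] = []
    edges: list[tuple[str, str]] = []
    go_nonroot: list[str] = []
    serial = 0

    for category, count in zip(GO_CATEGORIES, spec.nodes_per_go_category):
        root = _GO_ROOT_BY_CATEGORY[category]
        concepts.append(Concept(root, category))
        component = [root]
        for _ in range(count):
            serial += 1
            node = f"GO:{serial:07d}"
            concepts.append(Concept(node, category))
            parent = component[rng.integers(len(component))]
            edges.append((node, parent))
            if len(component) > 1 and rng.random() < spec.extra_parent_probability:
                extra = component[rng.integers(len(component))]
                if extra != parent:
                    edges.append((node, extra))
            component.append(node)
            go_nonroot.append(node)

    ipr_roots: list[str] = []
    ipr_serial = 0
    for category, count in zip(IPR_CATEGORIES, spec.nodes_per_ipr_category):
        component: list[str] = []
        for i in range(count):
            ipr_serial += 1
            node = f"IPR{ipr_serial:06d}"
            concepts.append(Concept(node, category))
            if i % _IPR_ROOT_STRIDE == 0:
                ipr_roots.append(node)
            else:
                parent = component[rng.integers(len(component))]
                edges.append((node, parent))
                if len(component) > 1 and rng.random() < spec.extra_parent_probability:
                    extra = component[rng.integers(len(component))]
                    if extra != parent:
                        edges.append((node, extra))
            component.append(node)

    if spec.crosslink_count > len(ipr_roots):
        raise ValueError(
            f"crosslink_count {spec.crosslink_count} exceeds the "
            f"{len(ipr_roots)} available InterPro roots"
        )
    if spec.crosslink_count:
        anchors = go_nonroot or [
            _GO_ROOT_BY_CATEGORY[c]
            for c, n in zip(GO_CATEGORIES, spec.nodes_per_go_category)
        ]
        chosen = rng.choice(len(ipr_roots), size=spec.crosslink_count, replace=False)
        for idx in sorted(chosen):
            edges.append((ipr_roots[idx], anchors[rng.integers(len(anchors))]))

    roots_present = frozenset(_GO_ROOT_BY_CATEGORY.values())
    return ConceptGraph(concepts, edges, roots_present)


def _sample_concepts(
    rng: np.random.Generator,
    k: int,
    pool: Sequence[str],
    background: Sequence[str],
    n_from_pool: int,
) -> frozenset[str]:
    """k distinct concepts: n_from_pool from the focus pool, rest uniform
    background (redrawing collisions until distinct)."""
    chosen: set[str] = set()
    n_from_pool = min(n_from_pool, len(pool), k)
    while len(chosen) < n_from_pool:
        chosen.add(pool[rng.integers(len(pool))])
    while len(chosen) < k:
        chosen.add(background[rng.integers(len(background))])
    return frozenset(chosen)


def generate_benchmark(
    graph: ConceptGraph, spec: BenchmarkSpec
) -> tuple[list[ArticleRecord], CitationGraph, list[tuple[str, str]]]:
    """Plant an intention-retrieval benchmark on ``graph``.

    Returns (articles, citations, queries).  ``articles`` holds the query
    articles followed by the search-target corpus; ``queries`` lists
    (primary id, additional id) pairs.  The co-citing articles exist only
    in the citation graph: each cites its query pair and the query's whole
    planted relevant set, so ``build_relevance_set`` recovers exactly the
    planted relevant articles.
    """
    rng = np.random.default_rng([_NS_BENCH, spec.seed])
    k = spec.concepts_per_article
    background = sorted(graph.nodes - graph.excluded_roots)
    min_pool = max(4, k)
    foci = [
        t
        for t in sorted(graph.nodes)
        if graph.category(t) == spec.planted_category
        and t not in graph.excluded_roots
        and len(graph.descendant_set(t) - graph.excluded_roots) >= min_pool
    ]
    if not foci:
        raise ValueError(
            f"graph has no {spec.planted_category!r} concept with >= "
            f"{min_pool} descendants to serve as a focus"
        )
    anchors = [
        t
        for t in sorted(graph.nodes)
        if t not in graph.excluded_roots
        and len(graph.descendant_set(t) - graph.excluded_roots) >= min_pool
    ]

    articles: list[ArticleRecord] = []
    citations = CitationGraph()
    queries: list[tuple[str, str]] = []
    n_relevant = spec.n_relevant_per_query
    n_background = spec.n_articles - 2 * spec.n_queries * n_relevant
    if n_background < 0:
        raise ValueError(
            "n_articles too small for the planted relevant and confounder sets"
        )

    serial_target = 0
    serial_citer = 0
    for qi in range(spec.n_queries):
        focus = foci[rng.integers(len(foci))]
        focus_pool = sorted(graph.descendant_set(focus) - graph.excluded_roots)
        # two distractor facets with pools disjoint from the focus pool:
        # the primary and additional articles agree only on the focus
        distractors = []
        candidates = [
            t
            for t in anchors
            if not (graph.descendant_set(t) & set(focus_pool))
        ]
        while len(distractors) < 2 and candidates:
            pick = candidates[rng.integers(len(candidates))]
            candidates = [
                t
                for t in candidates
                if t != pick and not (graph.descendant_set(t) & graph.descendant_set(pick))
            ]
            distractors.append(pick)
        pools = [
            sorted(graph.descendant_set(d) - graph.excluded_roots)
            for d in distractors
        ]
        distractor_p = pools[0] if pools else background
        distractor_a = pools[1] if len(pools) > 1 else background

        n_focus = (k + 1) // 2
        primary_concepts = _sample_concepts(rng, k, focus_pool, distractor_p, n_focus)
        additional_concepts = _sample_concepts(rng, k, focus_pool, distractor_a, n_focus)
        primary = ArticleRecord(f"1{qi:06d}", primary_concepts)
        additional = ArticleRecord(f"2{qi:06d}", additional_concepts)
        articles += [primary, additional]
        queries.append((primary.id, additional.id))

        n_signal = round(spec.signal_strength * k)
        relevant_ids = []
        for _ in range(n_relevant):
            serial_target += 1
            record = ArticleRecord(
                f"3{serial_target:06d}",
                _sample_concepts(rng, k, focus_pool, background, n_signal),
            )
            articles.append(record)
            relevant_ids.append(record.id)
        # confounders: resemble the primary through its distractor facet
        for _ in range(n_relevant):
            serial_target += 1
            articles.append(
                ArticleRecord(
                    f"3{serial_target:06d}",
                    _sample_concepts(rng, k, distractor_p, background, n_signal),
                )
            )
        for _ in range(spec.n_cociting):
            serial_citer += 1
            citer = f"9{serial_citer:06d}"
            for cited in [primary.id, additional.id] + relevant_ids:
                citations.add(citer, cited)

    for _ in range(n_background):
        serial_target += 1
        articles.append(
            ArticleRecord(
                f"3{serial_target:06d}",
                _sample_concepts(rng, k, [], background, 0),
            )
        )
    return articles, citations, queries


def write_benchmark(
    out_dir: str,
    graph: ConceptGraph,
    articles: Sequence[ArticleRecord],
    citations: CitationGraph,
    queries: Sequence[tuple[str, str]],
) -> None:
    """Write a complete benchmark directory in the package's TSV dialects."""
    os.makedirs(out_dir, exist_ok=True)
    write_graph_tsv(
        graph,
        os.path.join(out_dir, "concept_nodes.tsv"),
        os.path.join(out_dir, "concept_edges.tsv"),
    )
    write_article_concepts(articles, os.path.join(out_dir, "article_concepts.tsv"))
    write_citation_graph(citations, os.path.join(out_dir, "citations.tsv"))
    import pandas as pd

    pd.DataFrame(list(queries)).to_csv(
        os.path.join(out_dir, "queries.tsv"), sep="\t", header=False, index=False
    )


def planted_mode_maps(
    graph_spec: Optional[GraphSpec] = None,
    bench_spec: Optional[BenchmarkSpec] = None,
    params=None,
):
    """Generate a planted benchmark and compare attention modes on it.

    Convenience wrapper: one call returns the
    :class:`~ontosearch.evaluation.ModeComparison` for a fully synthetic
    run, as used by the directional MAP checks and the CLI.
    """
    from .evaluation import compare_modes

    graph_spec = graph_spec or GraphSpec()
    bench_spec = bench_spec or BenchmarkSpec()
    graph = generate_concept_graph(graph_spec)
    articles, citations, queries = generate_benchmark(graph, bench_spec)
    return compare_modes(graph, articles, citations, queries, params)
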