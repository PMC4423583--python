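"""Article corpora: concept assignments, keywords, citations.

An article stands in for the MEDLINE -> PDB -> SIFTS -> GO/InterPro
annotation chain as a flat set of concept identifiers.  All inputs are
plain headerless TSV:

* article-concepts: ``article-id <TAB> concept-id`` (one pair per row)
* keywords:         ``article-id <TAB> keyword``
* years:            ``article-id <TAB> year``
* citations:        ``citing-id <TAB> cited-id``

Article and concept identifiers are opaque strings; nothing here touches
the network.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import pandas as pd

from .ontology_graph import ConceptGraph, _Stream

logger = logging.getLogger("ontosearch")


class CorpusError(ValueError):
    """A corpus input violates its contract."""


@dataclass(frozen=True)
class ArticleRecord:
    """An article as a set of concepts, with optional keywords and year."""

    id: str
    concepts: frozenset[str]
    keywords: frozenset[str] = frozenset()
    year: Optional[int] = None

    def __post_init__(self) -> None:
        if not self.id:
            raise CorpusError("article id must be nonempty")
        object.__setattr__(self, "concepts", frozenset(self.concepts))
        object.__setattr__(self, "keywords", frozenset(self.keywords))


@dataclass
class CitationGraph:
    """citing-article -> set of cited-article ids; self-citations rejected."""

    edges: dict[str, set[str]] = field(default_factory=dict)

    def cites(self, citing: str, cited: str) -> bool:
        return cited in self.edges.get(citing, ())

    def add(self, citing: str, cited: str) -> None:
        if citing == cited:
            raise CorpusError(f"self-citation: {citing!r}")
        self.edges.setdefault(citing, set()).add(cited)


def _read_pairs(stream: _Stream, names: Sequence[str]) -> pd.DataFrame:
    from .ontology_graph import _as_handle

    try:
        return pd.read_csv(
            _as_handle(stream), sep="\t", header=None, names=list(names), dtype=str
        )
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=list(names), dtype=str)


def load_article_concepts(
    tsv: _Stream,
    graph: ConceptGraph,
    strict: bool = False,
    keywords_tsv: Optional[_Stream] = None,
    years_tsv: Optional[_Stream] = None,
) -> list[ArticleRecord]:
    """Load a corpus from an article-concepts TSV, validated against ``graph``.

    Rows naming concepts absent from the graph are an error under
    ``strict``; otherwise they are dropped and the total dropped count is
    logged.  Optional companion TSVs attach keywords and publication years.
    """
    rows = _read_pairs(tsv, ["article", "concept"])
    keywords: dict[str, set[str]] = {}
    if keywords_tsv is not None:
        for r in _read_pairs(keywords_tsv, ["article", "keyword"]).itertuples():
            keywords.setdefault(r.article, set()).add(r.keyword)
    years: dict[str, int] = {}
    if years_tsv is not None:
        for r in _read_pairs(years_tsv, ["article", "year"]).itertuples():
            year = int(r.year)
            if r.article in years and years[r.article] != year:
                raise CorpusError(
                    f"article {r.article!r}: contradictory years "
                    f"{years[r.article]} and {year}"
                )
            years[r.article] = year

    concepts_by_article: dict[str, set[str]] = {}
    dropped = 0
    for i, r in enumerate(rows.itertuples(), start=1):
        if r.concept not in graph:
            if strict:
                raise CorpusError(
                    f"row {i}: article {r.article!r} names unknown concept "
                    f"{r.concept!r}"
                )
            dropped += 1
            continue
        concepts_by_article.setdefault(r.article, set()).add(r.concept)
    if dropped:
        logger.warning("dropped %d rows naming unknown concepts", dropped)
    return [
        ArticleRecord(
            article,
            frozenset(cs),
            frozenset(keywords.get(article, ())),
            years.get(article),
        )
        for article, cs in sorted(concepts_by_article.items())
    ]


def write_article_concepts(records: Iterable[ArticleRecord], tsv: _Stream) -> None:
    rows = sorted(
        (record.id, concept) for record in records for concept in record.concepts
    )
    pd.DataFrame(rows).to_csv(tsv, sep="\t", header=False, index=False)


def write_keywords(records: Iterable[ArticleRecord], tsv: _Stream) -> None:
    rows = sorted(
        (record.id, kw) for record in records for kw in record.keywords
    )
    pd.DataFrame(rows).to_csv(tsv, sep="\t", header=False, index=False)


def load_citation_graph(tsv: _Stream) -> CitationGraph:
    """Adjacency map citing -> cited; a self-citation row is an error."""
    graph = CitationGraph()
    for r in _read_pairs(tsv, ["citing", "cited"]).itertuples():
        graph.add(r.citing, r.cited)
    return graph


def write_citation_graph(citations: CitationGraph, tsv: _Stream) -> None:
    rows = sorted(
        (citing, cited)
        for citing, cited_set in citations.edges.items()
        for cited in cited_set
    )
    pd.DataFrame(rows).to_csv(tsv, sep="\t", header=False, index=False)


def keyword_prefilter(
    query, corpus: Sequence[ArticleRecord], min_overlap: int = 0
) -> list[ArticleRecord]:
    """Pre-search filter: keep articles sharing at least ``min_overlap``
    keywords with the query articles' combined keywords.

    Fail-open: with ``min_overlap`` 0 or a keyword-less query the corpus is
    returned unchanged — the filter exists to cut computation, never to
    exclude on missing data.
    """
    if min_overlap < 0:
        raise ValueError("min_overlap must be >= 0")
    query_keywords = set(query.primary.keywords)
    if query.additional is not None:
        query_keywords |= query.additional.keywords
    if min_overlap == 0 or not query_keywords:
        return list(corpus)
    return [
        article
        for article in corpus
        if len(query_keywords & article.keywords) >= min_overlap
    ]
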