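"""Integrated GO + InterPro concept hierarchy.

The concept space is a single directed acyclic graph built from the three
Gene Ontology namespaces (biological_process, molecular_function,
cellular_component), the four InterPro entry types (family, domain, repeat,
site), and the curated interpro2go cross-references, which add one
child->parent link from each mapped InterPro entry to its GO term.

Edges are stored child -> parent throughout: "superordinate" means ancestor,
and walking an edge forward moves towards more general concepts.  The three
GO namespace roots are recorded as *excluded roots*: they subsume everything
and are never eligible as a lowest common superordinate concept.

Path conventions: ancestor sets include the concept itself; a path is an
ordered node list from the ancestor down to the descendant, inclusive of
both ends; a path-pair cost is the total node count of its two paths (the
shared apex counted once per path).
"""

from __future__ import annotations

import io
import os
import re
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence, TextIO, Union

import networkx as nx
import obonet
import pandas as pd

GO_CATEGORIES: tuple[str, ...] = (
    "biological_process",
    "molecular_function",
    "cellular_component",
)
IPR_CATEGORIES: tuple[str, ...] = ("family", "domain", "repeat", "site")
CATEGORIES: tuple[str, ...] = GO_CATEGORIES + IPR_CATEGORIES

#: The three GO namespace roots, excluded from ancestor sets by default.
DEFAULT_EXCLUDED_ROOTS: frozenset[str] = frozenset(
    {"GO:0008150", "GO:0003674", "GO:0005575"}
)


class ParseError(ValueError):
    """A concept-hierarchy input file violates its dialect."""


class GraphError(ValueError):
    """A structural violation: unknown node, cycle, unreachable ancestor."""


@dataclass(frozen=True)
class Concept:
    """One node of the hierarchy: a GO term or an InterPro entry."""

    id: str
    category: str
    name: Optional[str] = None

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(
                f"concept {self.id!r}: unknown category {self.category!r}; "
                f"expected one of {CATEGORIES}"
            )


@dataclass(frozen=True)
class CrossLink:
    """An interpro2go mapping row: InterPro entry -> GO term."""

    interpro_id: str
    go_id: str


@dataclass(frozen=True)
class PathPair:
    """A lowest common superordinate concept with its two downward paths.

    ``left_path`` runs from the apex (``lca``) down to the first query
    concept, ``right_path`` down to the second; both include their
    endpoints.  ``cost`` is ``len(left_path) + len(right_path)``.
    """

    lca: str
    left_path: tuple[str, ...]
    right_path: tuple[str, ...]
    cost: int

    def node_union(self) -> frozenset[str]:
        return frozenset(self.left_path) | frozenset(self.right_path)


class ConceptGraph:
    """The integrated concept DAG with category labels and excluded roots.

    Thin wrapper around a :class:`networkx.DiGraph` whose edges point
    child -> parent, with per-node lazy caches for upward BFS distances
    (the workhorse of every ancestor / shortest-path query).
    """

    def __init__(
        self,
        concepts: Iterable[Concept],
        edges: Iterable[tuple[str, str]],
        excluded_roots: Iterable[str] = (),
    ) -> None:
        self._concepts: dict[str, Concept] = {}
        for c in concepts:
            if c.id in self._concepts:
                raise GraphError(f"duplicate concept id {c.id!r}")
            self._concepts[c.id] = c
        dag = nx.DiGraph()
        dag.add_nodes_from(self._concepts)
        for child, parent in edges:
            for endpoint in (child, parent):
                if endpoint not in self._concepts:
                    raise GraphError(
                        f"edge ({child!r}, {parent!r}) references unknown "
                        f"concept {endpoint!r}"
                    )
            dag.add_edge(child, parent)
        if not nx.is_directed_acyclic_graph(dag):
            cycle = nx.find_cycle(dag)
            raise GraphError(f"edge {cycle[0][:2]} participates in a cycle")
        roots = frozenset(excluded_roots)
        unknown = roots - self._concepts.keys()
        if unknown:
            raise GraphError(f"excluded roots not in graph: {sorted(unknown)}")
        self._dag = dag
        self.excluded_roots = roots
        self._updist: dict[str, dict[str, int]] = {}
        self._category_tally: Optional[Counter] = None

    # -- basic views ---------------------------------------------------

    @property
    def nodes(self) -> frozenset[str]:
        return frozenset(self._dag.nodes)

    @property
    def edges(self) -> frozenset[tuple[str, str]]:
        return frozenset(self._dag.edges)

    def __contains__(self, concept_id: str) -> bool:
        return concept_id in self._concepts

    def __len__(self) -> int:
        return len(self._concepts)

    def concept(self, concept_id: str) -> Concept:
        try:
            return self._concepts[concept_id]
        except KeyError:
            raise GraphError(f"unknown concept {concept_id!r}") from None

    def category(self, concept_id: str) -> str:
        return self.concept(concept_id).category

    def category_tally(self) -> Counter:
        """n(T_ALL, C) for every category C, cached."""
        if self._category_tally is None:
            self._category_tally = Counter(
                c.category for c in self._concepts.values()
            )
        return self._category_tally

    def children(self, concept_id: str) -> list[str]:
        self.concept(concept_id)
        return sorted(self._dag.predecessors(concept_id))

    def parents(self, concept_id: str) -> list[str]:
        self.concept(concept_id)
        return sorted(self._dag.successors(concept_id))

    # -- traversal -----------------------------------------------------

    def upward_distances(self, concept_id: str) -> dict[str, int]:
        """Shortest edge counts from ``concept_id`` to each of its ancestors
        (self included at distance 0).  Cached per node."""
        self.concept(concept_id)
        cached = self._updist.get(concept_id)
        if cached is None:
            cached = nx.single_source_shortest_path_length(self._dag, concept_id)
            self._updist[concept_id] = cached
        return cached

    def descendant_set(self, concept_id: str) -> frozenset[str]:
        """All concepts reachable downward from ``concept_id``, self included."""
        self.concept(concept_id)
        return frozenset(nx.ancestors(self._dag, concept_id)) | {concept_id}


# ---------------------------------------------------------------------
# Parsers
# ---------------------------------------------------------------------

_Stream = Union[str, os.PathLike, TextIO]


def _as_handle(stream: _Stream) -> TextIO:
    """Accept raw text, a path, or an open handle; return a readable handle."""
    if hasattr(stream, "read"):
        return stream  # type: ignore[return-value]
    if isinstance(stream, os.PathLike) or (
        isinstance(stream, str) and "\n" not in stream and os.path.exists(stream)
    ):
        return open(stream, "r", encoding="utf-8")
    return io.StringIO(str(stream))


def parse_obo(obo_text: _Stream) -> tuple[list[Concept], list[tuple[str, str]]]:
    """Read GO terms and is_a links from OBO 1.2/1.4 text.

    Obsolete terms are dropped; relationship types other than ``is_a``
    (part_of, regulates, ...) are ignored.  Every emitted term must carry a
    namespace naming one of the three GO categories.
    """
    graph = obonet.read_obo(_as_handle(obo_text))
    concepts: list[Concept] = []
    for term_id, data in graph.nodes(data=True):
        namespace = data.get("namespace")
        if namespace is None:
            raise ParseError(f"term {term_id!r} has no namespace")
        if namespace not in GO_CATEGORIES:
            raise ParseError(
                f"term {term_id!r}: namespace {namespace!r} is not a GO category"
            )
        concepts.append(Concept(term_id, namespace, data.get("name")))
    edges = [
        (child, parent)
        for child, parent, key in graph.edges(keys=True)
        if key == "is_a"
    ]
    return concepts, edges


_IPR_LINE = re.compile(r"^((?:--)*)(IPR\d+)::(.*?)::([A-Za-z_ ]+?)\s*$")


def parse_interpro_hierarchy(
    tree_text: _Stream,
) -> tuple[list[Concept], list[tuple[str, str]]]:
    """Read the indentation-based InterPro parent-child tree dialect.

    One entry per line, ``--`` repeated per nesting level, fields separated
    by ``::``: accession, name, entry type (Family/Domain/Repeat/Site).
    Each entry is linked to its nearest shallower predecessor.
    """
    concepts: list[Concept] = []
    edges: list[tuple[str, str]] = []
    stack: list[str] = []  # stack[d] = last accession seen at depth d
    handle = _as_handle(tree_text)
    for lineno, raw in enumerate(handle, start=1):
        line = raw.rstrip("\n")
        if not line.strip():
            continue
        m = _IPR_LINE.match(line)
        if m is None:
            raise ParseError(f"line {lineno}: not an InterPro tree entry: {line!r}")
        depth = len(m.group(1)) // 2
        accession, name, entry_type = m.group(2), m.group(3), m.group(4)
        category = entry_type.strip().lower().replace(" ", "_")
        if category not in IPR_CATEGORIES:
            raise ParseError(
                f"line {lineno}: unknown InterPro entry type {entry_type!r}"
            )
        if depth > len(stack):
            raise ParseError(
                f"line {lineno}: nesting depth jumps from {len(stack) - 1} "
                f"to {depth}"
            )
        concepts.append(Concept(accession, category, name or None))
        if depth > 0:
            edges.append((accession, stack[depth - 1]))
        del stack[depth:]
        stack.append(accession)
    return concepts, edges


_I2G_LINE = re.compile(
    r"^InterPro:(\S+)\s+.*?>\s*GO:.*?;\s*(GO:\d+)\s*$"
)


def parse_interpro2go(map_text: _Stream) -> list[CrossLink]:
    """Read the public interpro2go mapping dialect.

    ``InterPro:<IPR> <entry name> > GO:<term name> ; GO:<id>``; lines
    starting with ``!`` are comments.
    """
    links: list[CrossLink] = []
    handle = _as_handle(map_text)
    for lineno, raw in enumerate(handle, start=1):
        line = raw.strip()
        if not line or line.startswith("!"):
            continue
        m = _I2G_LINE.match(line)
        if m is None:
            raise ParseError(
                f"line {lineno}: not an interpro2go mapping (missing '; GO:' "
                f"field?): {line!r}"
            )
        links.append(CrossLink(m.group(1), m.group(2)))
    return links


# ---------------------------------------------------------------------
# Integration
# ---------------------------------------------------------------------


def integrate_hierarchies(
    go_part: tuple[Sequence[Concept], Sequence[tuple[str, str]]],
    ipr_part: tuple[Sequence[Concept], Sequence[tuple[str, str]]],
    links: Sequence[CrossLink],
    excluded_roots: Iterable[str] = DEFAULT_EXCLUDED_ROOTS,
) -> ConceptGraph:
    """Fuse the GO and InterPro DAGs through interpro2go cross-references.

    Each cross-link contributes one child->parent edge interpro_id -> go_id,
    making the mapped InterPro entry a subordinate of its GO term.
    """
    go_concepts, go_edges = go_part
    ipr_concepts, ipr_edges = ipr_part
    go_ids = {c.id for c in go_concepts}
    ipr_ids = {c.id for c in ipr_concepts}
    overlap = go_ids & ipr_ids
    if overlap:
        raise GraphError(f"GO and InterPro id sets overlap: {sorted(overlap)[:5]}")
    for link in links:
        if link.interpro_id not in ipr_ids:
            raise GraphError(f"cross-link from unknown InterPro id {link.interpro_id!r}")
        if link.go_id not in go_ids:
            raise GraphError(f"cross-link to unknown GO id {link.go_id!r}")
    edges = set(go_edges) | set(ipr_edges)
    edges |= {(link.interpro_id, link.go_id) for link in links}
    roots = frozenset(excluded_roots) & (go_ids | ipr_ids)
    return ConceptGraph(
        list(go_concepts) + list(ipr_concepts), sorted(edges), roots
    )


# ---------------------------------------------------------------------
# Ancestor and path-pair queries
# ---------------------------------------------------------------------


def ancestor_set(graph: ConceptGraph, t: str) -> frozenset[str]:
    """S(t): every concept reachable upward from t, t included, minus the
    excluded roots."""
    return frozenset(graph.upward_distances(t)) - graph.excluded_roots


def shortest_path_nodes(graph: ConceptGraph, descendant: str, ancestor: str) -> list[str]:
    """Minimum-node path from ``ancestor`` down to ``descendant``, endpoints
    included.  Among equal-length paths the lexicographically smallest
    node-id sequence is returned, so results are reproducible."""
    dist = graph.upward_distances(descendant)
    graph.concept(ancestor)
    if ancestor not in dist:
        raise GraphError(
            f"{ancestor!r} is not an ancestor of {descendant!r}"
        )
    path = [ancestor]
    level = dist[ancestor]
    current = ancestor
    while level > 0:
        # children of `current` one BFS level closer to the descendant;
        # greedy smallest-id choice yields the lexicographic minimum path
        candidates = sorted(
            y for y in graph._dag.predecessors(current) if dist.get(y) == level - 1
        )
        current = candidates[0]
        path.append(current)
        level -= 1
    return path


def lowest_common_superordinates(graph: ConceptGraph, t1: str, t2: str) -> list[PathPair]:
    """All co-minimal lowest common superordinate concepts of (t1, t2) with
    their shortest-related path pairs.

    A candidate apex x ranges over S(t1) ∩ S(t2); the minimized quantity is
    the total node count of the two paths.  The list is sorted by apex id,
    so ``[0]`` is the deterministic representative pair.  Concepts with no
    common superordinate yield an empty list.
    """
    d1 = graph.upward_distances(t1)
    d2 = graph.upward_distances(t2)
    common = (d1.keys() & d2.keys()) - graph.excluded_roots
    if not common:
        return []
    best = min(d1[x] + d2[x] for x in common)
    pairs = []
    for x in sorted(x for x in common if d1[x] + d2[x] == best):
        pairs.append(
            PathPair(
                lca=x,
                left_path=tuple(shortest_path_nodes(graph, t1, x)),
                right_path=tuple(shortest_path_nodes(graph, t2, x)),
                cost=best + 2,
            )
        )
    return pairs


# ---------------------------------------------------------------------
# TSV fixture round-trip
# ---------------------------------------------------------------------


def write_graph_tsv(graph: ConceptGraph, nodes_path: _Stream, edges_path: _Stream) -> None:
    """Export as a node-category TSV (id, category, excluded-root flag) and a
    two-column child/parent edge TSV."""
    nodes = pd.DataFrame(
        sorted(
            (t, graph.category(t), int(t in graph.excluded_roots))
            for t in graph.nodes
        )
    )
    nodes.to_csv(nodes_path, sep="\t", header=False, index=False)
    edges = pd.DataFrame(sorted(graph.edges))
    edges.to_csv(edges_path, sep="\t", header=False, index=False)


def read_graph_tsv(nodes_path: _Stream, edges_path: _Stream) -> ConceptGraph:
    nodes = pd.read_csv(
        nodes_path, sep="\t", header=None,
        names=["id", "category", "excluded"], dtype={"id": str, "category": str},
    )
    concepts = [Concept(r.id, r.category) for r in nodes.itertuples()]
    roots = [r.id for r in nodes.itertuples() if int(r.excluded)]
    try:
        edges_df = pd.read_csv(
            edges_path, sep="\t", header=None, names=["child", "parent"], dtype=str
        )
        edges = list(edges_df.itertuples(index=False, name=None))
    except pd.errors.EmptyDataError:
        edges = []
    return ConceptGraph(concepts, edges, roots)
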