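"""Independent brute-force oracles used to cross-check the implementation.

Everything here works on a plain child->parent adjacency dict and exhaustive
path enumeration — no networkx, no shared code with the package's traversal
routines — so agreement between the two routes is meaningful.
"""

from __future__ import annotations

from typing import Iterable


def parents_of(edges: Iterable[tuple[str, str]]) -> dict[str, list[str]]:
    adjacency: dict[str, list[str]] = {}
    for child, parent in edges:
        adjacency.setdefault(child, []).append(parent)
    return adjacency


def all_upward_paths(parents: dict[str, list[str]], node: str) -> list[list[str]]:
    """Every upward path starting at ``node`` (node first), including the
    trivial one-node path; assumes acyclicity."""
    paths = [[node]]
    for parent in parents.get(node, ()):
        for tail in all_upward_paths(parents, parent):
            paths.append([node] + tail)
    return paths


def brute_ancestors(parents, node, excluded=frozenset()) -> set[str]:
    return {p[-1] for p in all_upward_paths(parents, node)} - set(excluded)


def brute_shortest_down_path(parents, descendant, ancestor) -> list[str]:
    """Min-node path from ancestor down to descendant; lexicographically
    smallest downward sequence among equals."""
    candidates = [
        list(reversed(p))
        for p in all_upward_paths(parents, descendant)
        if p[-1] == ancestor
    ]
    best = min(len(p) for p in candidates)
    return min(p for p in candidates if len(p) == best)


def brute_lcs(parents, t1, t2, excluded=frozenset()):
    """(min total node count, set of co-minimal apex ids), or (None, set())
    when the concepts share no common superordinate concept."""
    min_nodes_1 = {}
    for p in all_upward_paths(parents, t1):
        x = p[-1]
        min_nodes_1[x] = min(min_nodes_1.get(x, len(p)), len(p))
    min_nodes_2 = {}
    for p in all_upward_paths(parents, t2):
        x = p[-1]
        min_nodes_2[x] = min(min_nodes_2.get(x, len(p)), len(p))
    common = (min_nodes_1.keys() & min_nodes_2.keys()) - set(excluded)
    if not common:
        return None, set()
    cost = {x: min_nodes_1[x] + min_nodes_2[x] for x in common}
    best = min(cost.values())
    return best, {x for x, c in cost.items() if c == best}


def brute_concept_similarity(parents, t1, t2, att, alpha, excluded=frozenset()):
    """Direct evaluation of the decay similarity over the deterministic
    first shortest-related path pair, from enumerated paths only."""
    best, lcas = brute_lcs(parents, t1, t2, excluded)
    if not lcas:
        return 0.0
    apex = min(lcas)
    union = set(brute_shortest_down_path(parents, t1, apex)) | set(
        brute_shortest_down_path(parents, t2, apex)
    )
    product = 1.0
    for t in union:
        product *= alpha ** (1.0 - att.get(t, 0.0))
    return 1.0 / product


def brute_pair_attention(parents, tp, ta, alpha, excluded=frozenset()):
    """Direct evaluation of the per-pair normalized attention of the
    deterministic first shortest-related path pair."""
    best, lcas = brute_lcs(parents, tp, ta, excluded)
    apex = min(lcas)
    left = brute_shortest_down_path(parents, tp, apex)
    right = brute_shortest_down_path(parents, ta, apex)

    def updist(node, target):
        return len(brute_shortest_down_path(parents, node, target)) - 1

    raw = {apex: 0.5 * (alpha ** -updist(tp, apex) + alpha ** -updist(ta, apex))}
    for t in left[1:]:
        raw[t] = alpha ** -updist(tp, t)
    for t in right[1:]:
        raw.setdefault(t, alpha ** -updist(ta, t))
    total = sum(raw.values())
    return {t: v / total for t, v in raw.items()}


def random_dag(rng, max_nodes=30):
    """A random labelled DAG: (concepts-as-(id, category) list, edges).

    Ids are assigned in shuffled order so lexicographic order disagrees
    with topological order and tie-breaks are genuinely exercised.
    """
    from ontosearch.ontology_graph import CATEGORIES

    n = int(rng.integers(4, max_nodes + 1))
    labels = [f"N{i:02d}" for i in range(n)]
    order = rng.permutation(n)
    ids = [labels[order[i]] for i in range(n)]
    nodes = [(node, CATEGORIES[rng.integers(len(CATEGORIES))]) for node in ids]
    edges = []
    for i in range(1, n):
        r = rng.random()
        n_parents = 0 if r < 0.10 else (1 if r < 0.85 else 2)
        for parent in rng.choice(i, size=min(n_parents, i), replace=False):
            edges.append((ids[i], ids[int(parent)]))
    return nodes, edges
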