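# Methods

## The concept hierarchy

The working data structure is a single DAG whose nodes are GO terms (three
namespaces: biological_process, molecular_function, cellular_component) and
InterPro entries (four types: family, domain, repeat, site), seven
categories in all.  Edges point child → parent and carry only subsumption
meaning: GO `is_a` links, InterPro parent–child links, and one link per
interpro2go cross-reference making the mapped InterPro entry a child of its
GO term.  Obsolete GO terms and non-`is_a` GO relationships (`part_of`,
`regulates`, …) are excluded: the similarity model reads an edge as "one
step more general", which only subsumption supports.  The three GO roots
are kept in the graph but registered as *excluded roots*: they subsume
essentially everything, so they are removed from every ancestor set and can
never serve as a lowest common superordinate concept.

Ancestor sets include the concept itself.  This makes the apex of a
concept paired with itself the concept itself, so identical concepts are
maximally close — which the best-match article score needs to behave
sensibly.  A consequence of keeping the similarity formula literal is that
self-similarity is α⁻¹ rather than 1 (the one-node path pair still
contributes one penalty factor).  We keep the literal formula: the score is
only ever used comparatively, and a uniform per-concept ceiling does not
change any ranking.

## Path pairs and determinism

The lowest common superordinate concept of (t₁, t₂) minimizes the total
node count of the two downward paths; all co-minimal apexes are computed,
and wherever a single representative is needed the apex with the smallest
identifier is used, with each path chosen as the lexicographically smallest
minimum-length node sequence.  Ties are real in DAGs, so an arbitrary-but-
fixed choice is required for reproducible scores; lexicographic order is
the simplest stable one.  Path-pair costs count nodes (the similarity
exponent needs node products); `len_SP` counts edges (the attention decay
needs hop exponents); a path of n nodes has len_SP = n − 1.

## Attention

Raw per-node attention uses the *global* shortest hop distance from the
query concept (equivalently, the position along the chosen shortest path).
The apex weight is the symmetric average of the decay from both sides.
Per-pair normalization runs over the pair's node union, so every concept
pair injects total attention mass 1 regardless of its length — short,
specific pairs therefore concentrate more attention per node than long,
vague ones, which is the intended length correction.  When a pair has
several co-minimal apexes each path pair contributes its own normalized
term, and the attended-category tally counts one entry per (pair, apex):
categories that mediate many pairs should dominate the estimate.  If one
node lies on both side paths of a single pair (possible in a DAG), the
primary-side weight wins; the case is rare and the two weights differ only
when the two query concepts sit at different depths.

The attended category maximizes n(T_lca, C)/rev^C.  rev^C for a GO
category is the number of same-category concept pairs between the two
query articles; for an InterPro category it is the number of remaining
(cross-category) pairs apportioned by the category's share of all InterPro
concepts in the graph.  Categories with rev^C = 0 are ineligible (avoiding
0/0 when a category simply cannot produce apexes for this query); when the
graph contains no InterPro concepts the InterPro correction is undefined
and those categories are likewise ineligible.  Argmax ties break by a
fixed category order (GO's three, then InterPro's four).  When no category
is eligible or no concept pair has a common superordinate, attention
degrades to the empty map and scoring falls back to the attention-free
decay — the same behaviour as a query without an additional article.

## Similarity, ranking, and the decay constant

α must exceed 1 so that similarity falls with separation; the default 1.7
is the largest one-decimal value with α⁻⁸ ≥ 0.01, i.e. concepts separated
by 8 path nodes (half the maximum GO root-to-leaf depth) retain about 1%
similarity.  `calibrate_alpha` recomputes this analytically.  The article
score is a sum over the query article's concepts of the best match in the
target — deliberately asymmetric: the query side fixes the denominatorless
sum, so targets covering many of the query's concepts win even if they
contain much else besides.  Rankings sort by descending score with ties
broken by ascending article identifier.  GO and InterPro levels are not
depth-normalized against each other (no edge weights); the integrated
graph mixes granularities, a known limitation of the level-free path
model.

## Evaluation protocol

Positives for a query (primary, additional) are the corpus articles cited
by at least one article that cites *both* query articles, minus the query
articles themselves; everything else in the corpus is negative.  Average
precision normalizes by the total number of positives, so positives the
ranking never retrieves still count against it; MAP averages over queries.
Queries with no co-citers have no defined positives and are skipped with a
reported count rather than scored 0 — scoring them would measure the
citation graph, not the ranking.  Significance between modes is reported
as a Wilcoxon signed-rank p-value on the paired per-query APs via
scipy; when every pair is tied the statistic is undefined and None is
reported.  MAP is evaluated on exactly the corpus the ranking saw; if the
keyword prefilter is used, the filter settings belong in the run manifest.

The keyword prefilter is an exact-overlap threshold on the union of the
query articles' keywords, off by default and fail-open (no keywords, no
exclusion): it exists to cut computation on large corpora, not to change
the method.

## The synthetic generators

`generate_concept_graph` emulates the integrated hierarchy's gross shape:
three singly-rooted GO components (roots carry the real GO root accessions
and are the excluded roots), four InterPro forests (a new tree root every
fifth entry), uniform random primary parents plus optional extra parents
(default probability 0.15, giving mild DAG-ness), and 8 InterPro→GO
cross-links by default.  Default size is ~210 concepts (30 per GO
category, 25/15/10/10 for InterPro).  It does not imitate real GO depth or
branching distributions; it exists so every downstream stage is exercised
on structurally valid input.

`generate_benchmark` plants the premise the retrieval method rests on: an
article has several facets and only the shared one carries the intention.
Each query draws a *focus* concept of the planted category and two
*distractor* concepts with descendant pools disjoint from the focus pool;
the primary article mixes focus-pool concepts (half of its 6 concepts)
with its own distractor facet, the additional article with a different
one.  Relevant articles draw `signal_strength` of their concepts from the
focus pool (default 0.7, rest uniform); an equal number of *confounder*
articles draw the same fraction from the primary's distractor pool — they
resemble the primary through the facet the additional article does not
share, which is exactly what intention modelling must penalize; the
remaining background articles draw uniformly.  Co-citing articles (3 per
query) cite the query pair plus the full planted relevant set, so the
citation protocol recovers the plant exactly.  Default corpus: 200 target
articles, 3 queries, 10 relevant + 10 confounders per query.  At
signal_strength 0 all targets are exchangeable draws from the same uniform
distribution and MAP sits at chance level; passing benchmarks therefore
show that attention exploits planted facet structure, not that it helps on
any particular real corpus, whose concept assignments are sparser, deeper,
and far more skewed.

All generators are pure functions of their spec; random streams are
namespaced per generator, so adding a generator never shifts another's
output for the same seed.

## Problem sizes and numerics

The directional benchmark checks use 20 independent runs of the default
200-article corpus per condition, enough for the mode ordering and the
signal-strength monotonicity to be stable across seeds at these effect
sizes.  The exhaustive-enumeration cross-check of the path-pair search
uses 100 random DAGs of up to 30 nodes with ≥ 100 compared pairs.  All
similarity arithmetic is plain double-precision products of α powers; no
tolerance tighter than 10⁻⁴ is asserted on derived decimal values, and the
attention map's maximum is exactly 1.0 by construction (division of a
float by itself).  Degenerate inputs — empty concept sets, identical query
concepts, disconnected components, categories with zero correction — all
take defined branches (zero score, self-apex, empty pair list, ineligible
category) rather than raising.
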