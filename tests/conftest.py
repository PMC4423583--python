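import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the `oracles` helper module

from ontosearch import Concept, ConceptGraph

#: G0: the six-node worked fixture used throughout.
#: R is the apex; C and D meet at A; D also descends from B; E hangs off C.
G0_EDGES = [("A", "R"), ("B", "R"), ("C", "A"), ("D", "A"), ("D", "B"), ("E", "C")]


def make_g0(excluded_roots=(), category="molecular_function"):
    concepts = [Concept(x, category) for x in "RABCDE"]
    return ConceptGraph(concepts, G0_EDGES, excluded_roots)


@pytest.fixture
def g0():
    return make_g0()


@pytest.fixture
def mixed_graph():
    """A small integrated-style graph: one GO molecular_function tree, one
    biological_process pair, and an InterPro family chain cross-linked under
    the MF tree.  No excluded roots, so apexes stay visible."""
    concepts = [
        Concept("GO:0000001", "molecular_function"),
        Concept("GO:0000002", "molecular_function"),
        Concept("GO:0000003", "molecular_function"),
        Concept("GO:0000004", "molecular_function"),
        Concept("GO:0000010", "biological_process"),
        Concept("GO:0000011", "biological_process"),
        Concept("IPR000001", "family"),
        Concept("IPR000002", "family"),
        Concept("IPR000010", "domain"),
    ]
    edges = [
        ("GO:0000002", "GO:0000001"),
        ("GO:0000003", "GO:0000001"),
        ("GO:0000004", "GO:0000002"),
        ("GO:0000011", "GO:0000010"),
        ("IPR000001", "GO:0000003"),  # cross-link
        ("IPR000002", "IPR000001"),
        ("IPR000010", "GO:0000011"),  # cross-link
    ]
    return ConceptGraph(concepts, edges)
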