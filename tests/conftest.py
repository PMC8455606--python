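import numpy as np
import pytest

import cellont as co

TINY_OBO = """\
[Term]
id: CL:0000000
name: cell

[Term]
id: CL:0000542
name: lymphocyte
def: "A nucleated hematopoietic cell." []
is_a: CL:0000000

[Term]
id: CL:0000084
name: T cell
def: "A type of lymphocyte whose defining characteristic is the expression of a T cell receptor complex." []
is_a: CL:0000542

[Term]
id: CL:0000236
name: B cell
def: "A lymphocyte of B lineage." []
is_a: CL:0000542

[Term]
id: CL:9999999
name: dead cell
is_obsolete: true
"""


@pytest.fixture(scope="session")
def tiny_terms():
    return co.parse_obo(TINY_OBO)


@pytest.fixture(scope="session")
def tiny_graph(tiny_terms):
    return co.build_graph(tiny_terms)


@pytest.fixture(scope="session")
def two_node_graph():
    terms = [
        co.OntologyTerm("T:A", "root cell"),
        co.OntologyTerm("T:B", "child cell", parent_ids=["T:A"]),
    ]
    return co.build_graph(terms)


@pytest.fixture(scope="session")
def fixture_data():
    """Standard synthetic dataset (40-term tree, beta=0.5, 30 cells/term)."""
    return co.standard_fixture(seed=0)


def random_tree_graph(rng: np.random.Generator, n: int) -> co.OntologyGraph:
    """A random rooted tree with n nodes (test helper)."""
    terms = [co.OntologyTerm("N:0", "node 0")]
    for i in range(1, n):
        parent = int(rng.integers(0, i))
        terms.append(co.OntologyTerm(f"N:{i}", f"node {i}", parent_ids=[f"N:{parent}"]))
    return co.build_graph(terms)


def random_weighted_graph(rng: np.random.Generator, n: int, extra: int = 5) -> co.OntologyGraph:
    """Random tree plus extra weighted edges (test helper)."""
    graph = random_tree_graph(rng, n)
    weights = {}
    for _ in range(extra):
        a, b = rng.integers(0, n, size=2)
        if a != b:
            weights[(f"N:{min(a,b)}", f"N:{max(a,b)}")] = float(rng.uniform(0.1, 1.0))
    terms = [
        co.OntologyTerm(t.term_id, t.name, t.definition, list(t.parent_ids))
        for t in graph.terms
    ]
    for (a, b), _ in weights.items():
        ai, bi = int(a.split(":")[1]), int(b.split(":")[1])
        child, parent = (a, b) if ai > bi else (b, a)
        idx = int(child.split(":")[1])
        if parent not in terms[idx].parent_ids:
            terms[idx].parent_ids.append(parent)
    return co.build_graph(terms, edge_weights=weights)
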