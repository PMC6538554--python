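import numpy as np
import pytest

from mdsim.ontology import ICTable, OntologyGraph, Term


def make_graph(edges, domain="T", extra_terms=(), obsolete=()):
    """Build an OntologyGraph from (child, parent) pairs and loose term ids."""
    ids = sorted({x for e in edges for x in e} | set(extra_terms) | set(obsolete))
    terms = {
        i: Term(id=i, name=i, domain=domain, obsolete=i in obsolete) for i in ids
    }
    return OntologyGraph(terms, edges, name=domain)


def random_dag(rng, n_terms, domain="T"):
    """Random rooted DAG: term i attaches to 1-2 earlier terms."""
    ids = [f"{domain}:{i:03d}" for i in range(n_terms)]
    edges = []
    for i in range(1, n_terms):
        k = 1 + int(rng.random() < 0.3 and i > 1)
        for p in rng.choice(i, size=min(k, i), replace=False):
            edges.append((ids[i], ids[int(p)]))
    return make_graph(edges, domain=domain, extra_terms=ids)


def random_ic(rng, graph):
    """Random IC values, non-decreasing from parent to child, roots at 0.

    Monotonicity matches what any corpus-derived table satisfies, and it is
    what makes MICA(x, x) = x hold."""
    import networkx as nx

    ic = {}
    for t in reversed(list(nx.topological_sort(graph.graph))):  # parents first
        if t in graph.roots:
            ic[t] = 0.0
        else:
            parent_ic = max(
                (ic[p] for p in graph.graph.successors(t)), default=0.0
            )
            ic[t] = float(np.round(parent_ic + rng.uniform(0.0, 1.0), 6))
    ic_max = max(ic.values(), default=0.0)
    return ICTable(ic=ic, ic_max=ic_max, source="corpus")


@pytest.fixture
def chain_graph():
    # r <- a <- b
    return make_graph([("b", "a"), ("a", "r")])


@pytest.fixture
def diamond_graph():
    # r <- {a, b} <- c
    return make_graph([("c", "a"), ("c", "b"), ("a", "r"), ("b", "r")])
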