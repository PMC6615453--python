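import random

import pytest
from rdflib import Literal, URIRef
from rdflib.namespace import RDF, XSD

import xenograph as xg


@pytest.fixture(scope="session")
def vocab():
    return xg.Vocabulary()


@pytest.fixture(scope="session")
def schema():
    return xg.build_schema()


@pytest.fixture(scope="session")
def rules(schema):
    return xg.RuleSet.from_schema(schema)


@pytest.fixture()
def table1():
    return xg.table1_fixture()


def random_store(rng: random.Random, n_nodes: int = 12,
                 n_triples: int = 25) -> xg.TripleStore:
    """Random graph mixing URI objects, plain-string and decimal literals."""
    ns = "http://example.org/lab/"
    g = xg.TripleStore(ns)
    nodes = [URIRef(f"{ns}n{i}") for i in range(n_nodes)]
    preds = [URIRef(f"{ns}p{i}") for i in range(4)] + [RDF.type]
    for _ in range(n_triples):
        s = rng.choice(nodes)
        p = rng.choice(preds)
        kind = rng.random()
        if kind < 0.5:
            o = rng.choice(nodes)
        elif kind < 0.8:
            o = Literal(f"text {rng.randint(0, 99)} \"quoted\" \\slash")
        else:
            o = Literal(str(round(rng.uniform(-100, 100), 3)),
                        datatype=XSD.decimal)
        g.add((s, p, o))
    return g


def random_tree_edges(rng: random.Random, n_nodes: int,
                      dag: bool = False) -> list[tuple[URIRef, URIRef]]:
    """Random generates-topology: a tree, or a DAG with extra forward edges."""
    ns = "http://example.org/lab/"
    nodes = [URIRef(f"{ns}n{i}") for i in range(n_nodes)]
    edges = [(nodes[rng.randint(0, i - 1)], nodes[i])
             for i in range(1, n_nodes)]
    if dag:
        for _ in range(n_nodes // 3):
            i, j = sorted(rng.sample(range(n_nodes), 2))
            if (nodes[i], nodes[j]) not in edges:
                edges.append((nodes[i], nodes[j]))
    return edges


def reachability_closure(edges, predicate):
    """Brute-force oracle: all (a, predicate, b) with b reachable from a."""
    adj = {}
    for a, b in edges:
        adj.setdefault(a, set()).add(b)
    out = set()
    for a in adj:
        seen = set()
        stack = list(adj[a])
        while stack:
            x = stack.pop()
            if x in seen:
                continue
            seen.add(x)
            stack.extend(adj.get(x, ()))
        out.update((a, predicate, b) for b in seen)
    return out
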