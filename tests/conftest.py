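import random

import networkx as nx
import pytest

from molenrich.ontology import OntologyGraph, OntologyTerm, parse_obo
from molenrich.pruning import ResultGraph
from molenrich.stats import EnrichmentRow


CHAIN_OBO = """\
format-version: 1.2

[Term]
id: CHEBI:C0
name: top class

[Term]
id: CHEBI:C1
name: mid class
is_a: CHEBI:C0

[Term]
id: CHEBI:m1
name: molecule one
property_value: http://purl.obolibrary.org/obo/chebi/inchi "InChI=1S/CH4/h1H4" xsd:string
is_a: CHEBI:C1
"""

MIXED_OBO = """\
format-version: 1.2

[Term]
id: CHEBI:S0
name: chemical entity

[Term]
id: CHEBI:S1
name: organic acid
is_a: CHEBI:S0

[Term]
id: CHEBI:R0
name: role

[Term]
id: CHEBI:R1
name: antibiotic
is_a: CHEBI:R0

[Term]
id: CHEBI:m1
name: cef-like molecule
property_value: http://purl.obolibrary.org/obo/chebi/inchi "InChI=1S/C2H6O/c1-2-3/h3H" xsd:string
is_a: CHEBI:S1
relationship: has_role CHEBI:R1
"""


@pytest.fixture
def chain_graph() -> OntologyGraph:
    return parse_obo(CHAIN_OBO)


@pytest.fixture
def mixed_graph() -> OntologyGraph:
    return parse_obo(MIXED_OBO)


def build_graph(term_specs, edges) -> OntologyGraph:
    """term_specs: iterable of (id, name) or (id, name, inchi)."""
    g = OntologyGraph()
    for spec in term_specs:
        tid, name, *rest = spec
        g.terms[tid] = OntologyTerm(term_id=tid, name=name,
                                    inchi=rest[0] if rest else None)
    g.edges = set(edges)
    g.assign_branches()
    return g


def make_result_graph(edges, molecules=(), pvalues=None, extra_nodes=()) -> ResultGraph:
    """Result graph from child->parent edge pairs; pvalues: id -> p_adj."""
    g = nx.DiGraph()
    nodes = {n for e in edges for n in e} | set(extra_nodes)
    for n in sorted(nodes):
        g.add_node(n, name=n, is_molecule=n in set(molecules))
    for child, parent in edges:
        g.add_edge(child, parent, relation="is_a")
    stats = {}
    for node, p in (pvalues or {}).items():
        stats[node] = EnrichmentRow(class_id=node, name=node, k=1, n=1, K=1,
                                    N=1, p_success=1.0, p_raw=p, p_adj=p,
                                    fold=1.0, sample_pct=100.0)
    return ResultGraph(graph=g, node_stats=stats)


def random_dag(rng: random.Random, n_nodes: int, p_edge: float = 0.15):
    """Random DAG edge pairs (child -> parent points to lower index)."""
    edges = set()
    for i in range(1, n_nodes):
        for j in range(i):
            if rng.random() < p_edge:
                edges.add((f"n{i}", f"n{j}"))
    return edges
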