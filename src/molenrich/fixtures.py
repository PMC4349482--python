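"""Synthetic ontology and sample generators with known planted structure.

Generated ontologies mimic the shape the analysis cares about: a structural
class DAG rooted at "chemical entity", a role hierarchy rooted at "role",
InChI-bearing molecule leaves, a designated "planted class" that samples can
be enriched for, and guaranteed pruning targets (a linear chain, a diamond
and an isolated node).  Everything is reproducible from the seed, and the
OBO serialisation is byte-identical across runs.
"""

from __future__ import annotations

import random
from dataclasses import dataclass

from .ontology import (
    HAS_PART,
    HAS_ROLE,
    IS_A,
    OntologyGraph,
    OntologyTerm,
    build_annotation_index,
)
from .saddlesum import WeightedSample

STRUCTURAL_ROOT = "CHEBI:1"
ROLE_ROOT = "CHEBI:2"
PLANTED_CLASS_NAME = "planted class"

# fixed motif ids so every pruner has a guaranteed target
CHAIN_IDS = ("CHEBI:50", "CHEBI:51", "CHEBI:52")
DIAMOND_IDS = ("CHEBI:60", "CHEBI:61", "CHEBI:62", "CHEBI:63")
ISOLATED_ID = "CHEBI:70"


class FixtureError(ValueError):
    pass


@dataclass
class FixtureSpec:
    """Parameters of one synthetic ontology / sample pair.

    ``planted_effect`` is the enrichment odds for plain samples (1.0 = null)
    and the mean weight shift for weighted samples (0.0 = null, 1.0 pushes
    planted members to mean 0.9 vs background mean 0.1).
    """

    n_classes: int = 50
    n_molecules: int = 30
    max_parents: int = 2
    role_fraction: float = 0.2
    planted_class_size: int = 5
    planted_effect: float = 1.0
    sample_size: int = 15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_classes < 1 or self.n_molecules < 1:
            raise FixtureError("n_classes and n_molecules must be >= 1")
        if self.max_parents < 1:
            raise FixtureError("max_parents must be >= 1")
        if not 0.0 <= self.role_fraction < 1.0:
            raise FixtureError("role_fraction must be in [0, 1)")
        if not 1 <= self.planted_class_size <= self.n_molecules:
            raise FixtureError("planted_class_size must be in [1, n_molecules]")
        if self.sample_size < 1:
            raise FixtureError("sample_size must be >= 1")


def planted_class_id(graph: OntologyGraph) -> str:
    """The id of the designated planted class in a fixture ontology."""
    for tid, term in graph.terms.items():
        if term.name == PLANTED_CLASS_NAME:
            return tid
    raise FixtureError("graph has no planted class")


def _mol_inchi(j: int) -> str:
    return f"InChI=1S/C6H{j + 4}O{j % 7}/fixture-{j}"


def make_ontology(spec: FixtureSpec) -> tuple[OntologyGraph, str]:
    """Build a synthetic ontology; returns the graph and its OBO text."""
    rng = random.Random(spec.seed)
    g = OntologyGraph()

    def add_term(tid: str, name: str, inchi: str | None = None) -> None:
        g.terms[tid] = OntologyTerm(term_id=tid, name=name, inchi=inchi)

    add_term(STRUCTURAL_ROOT, "chemical entity")
    add_term(ROLE_ROOT, "role")

    # fixed motifs
    c0, c1, c2 = CHAIN_IDS
    add_term(c0, "chain top")
    add_term(c1, "chain middle")
    add_term(c2, "chain bottom")
    g.edges |= {(c0, STRUCTURAL_ROOT, IS_A), (c1, c0, IS_A), (c2, c1, IS_A)}
    d0, d1, d2, d3 = DIAMOND_IDS
    add_term(d0, "diamond top")
    add_term(d1, "diamond left")
    add_term(d2, "diamond right")
    add_term(d3, "diamond bottom")
    g.edges |= {
        (d0, STRUCTURAL_ROOT, IS_A),
        (d1, d0, IS_A),
        (d2, d0, IS_A),
        (d3, d1, IS_A),
        (d3, d2, IS_A),
    }
    add_term(ISOLATED_ID, "isolated class")

    n_role = int(round(spec.role_fraction * spec.n_classes))
    n_struct = max(1, spec.n_classes - n_role)

    # structural classes; parents drawn from earlier classes keeps it a DAG
    struct_ids: list[str] = []
    for i in range(n_struct):
        tid = f"CHEBI:{100 + i}"
        add_term(tid, f"structural class {i}")
        pool = [STRUCTURAL_ROOT] + struct_ids
        n_par = rng.randint(1, min(spec.max_parents, len(pool)))
        for parent in rng.sample(pool, n_par):
            g.edges.add((tid, parent, IS_A))
        struct_ids.append(tid)

    # dedicated leaf-level planted class: kept out of every parent pool so
    # its membership stays exactly its own molecules
    planted = "CHEBI:99"
    add_term(planted, PLANTED_CLASS_NAME)
    g.edges.add((planted, rng.choice([STRUCTURAL_ROOT] + struct_ids[:1]), IS_A))

    # a couple of has_part edges between structural classes (later -> earlier)
    if len(struct_ids) >= 4:
        for _ in range(2):
            child = rng.choice(struct_ids[2:])
            parent = rng.choice(struct_ids[: struct_ids.index(child)] or [STRUCTURAL_ROOT])
            g.edges.add((child, parent, HAS_PART))

    role_ids: list[str] = []
    for i in range(n_role):
        tid = f"CHEBI:{3000 + i}"
        add_term(tid, f"role class {i}")
        pool = [ROLE_ROOT] + role_ids
        for parent in rng.sample(pool, rng.randint(1, min(spec.max_parents, len(pool)))):
            g.edges.add((tid, parent, IS_A))
        role_ids.append(tid)

    # molecules: the first planted_class_size go under the planted class
    attach_pool = struct_ids or [STRUCTURAL_ROOT]
    for j in range(spec.n_molecules):
        tid = f"CHEBI:{5000 + j}"
        add_term(tid, f"molecule {j}", inchi=_mol_inchi(j))
        if j < spec.planted_class_size:
            g.edges.add((tid, planted, IS_A))
        else:
            n_par = rng.randint(1, min(2, spec.max_parents))
            for parent in rng.sample(attach_pool, min(n_par, len(attach_pool))):
                g.edges.add((tid, parent, IS_A))
        if role_ids and rng.random() < 0.5:
            g.edges.add((tid, rng.choice(role_ids), HAS_ROLE))

    g.assign_branches()
    return g, write_obo(g)


def write_obo(graph: OntologyGraph) -> str:
    """Serialise a graph in the OBO dialect understood by ``parse_obo``.

    Stanzas and edge lines are emitted in sorted order, so equal graphs
    produce byte-identical text.
    """

    def sort_key(tid: str) -> tuple:
        prefix, _, local = tid.partition(":")
        return (prefix, int(local)) if local.isdigit() else (prefix, local)

    parents: dict[str, list[tuple[str, str]]] = {t: [] for t in graph.terms}
    for child, parent, rel in sorted(graph.edges):
        parents[child].append((rel, parent))

    chunks = ["format-version: 1.2\nontology: fixture\n"]
    all_terms = dict(graph.terms)
    all_terms.update(graph.obsolete_terms)
    for tid in sorted(all_terms, key=sort_key):
        term = all_terms[tid]
        lines = ["[Term]", f"id: {tid}", f"name: {term.name}"]
        if term.inchi is not None:
            lines.append(
                "property_value: http://purl.obolibrary.org/obo/chebi/inchi "
                f'"{term.inchi}" xsd:string'
            )
        for rel, parent in sorted(parents.get(tid, [])):
            if rel == IS_A:
                lines.append(f"is_a: {parent}")
            else:
                lines.append(f"relationship: {rel} {parent}")
        if term.is_obsolete:
            lines.append("is_obsolete: true")
        chunks.append("\n".join(lines) + "\n")
    return "\n".join(chunks)


def make_sample(
    graph: OntologyGraph, spec: FixtureSpec, mode: str = "plain"
) -> WeightedSample:
    """Draw a sample enriched for the fixture's planted class.

    Plain: weighted sampling without replacement, planted members at odds
    ``planted_effect`` against 1.  Weighted: planted members get weights
    centred at 0.1 + 0.8 * planted_effect, background at 0.1 (sd 0.05,
    truncated to [0, 1]).
    """
    rng = random.Random(spec.seed + 1)
    index = build_annotation_index(graph)
    planted = planted_class_id(graph)
    members = index.molecules_of(planted)
    if len(members) < spec.planted_class_size:
        raise FixtureError(
            f"planted class has {len(members)} molecules, "
            f"need >= {spec.planted_class_size}"
        )
    molecules = sorted(index.molecule_ids)
    size = min(spec.sample_size, len(molecules))

    if mode == "plain":
        odds = {m: (spec.planted_effect if m in members else 1.0) for m in molecules}
        chosen: list[str] = []
        pool = list(molecules)
        for _ in range(size):
            total = sum(odds[m] for m in pool)
            r = rng.random() * total
            acc = 0.0
            for m in pool:
                acc += odds[m]
                if acc >= r:
                    chosen.append(m)
                    pool.remove(m)
                    break
        return WeightedSample(entries=[(m, None) for m in sorted(chosen)])

    if mode == "weighted":
        planted_in = sorted(members)[: spec.planted_class_size]
        others = [m for m in molecules if m not in set(planted_in)]
        rng.shuffle(others)
        chosen = (planted_in + others)[:size]
        high_mean = min(1.0, 0.1 + 0.8 * spec.planted_effect)
        entries = []
        for m in sorted(chosen):
            mean = high_mean if m in members else 0.1
            w = min(1.0, max(0.0, rng.gauss(mean, 0.05)))
            entries.append((m, w))
        return WeightedSample(entries=entries)

    raise FixtureError(f"unknown sample mode {mode!r}")
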