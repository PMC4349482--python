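"""OBO ontology handling: parsing, branch/relation restriction, annotation.

The ontology is modelled as a directed, typed multigraph whose edges point
from the more specific term to the more general one (child -> parent).
Fully specified small molecules are the terms that carry an InChI string;
everything else is a class.  Annotation (which molecules a class transitively
subsumes) is derived by walking ``is_a`` / ``has_part`` edges upward, plus a
single non-chained ``has_role`` hop out of each molecule.
"""

from __future__ import annotations

import io
import os
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, TextIO

IS_A = "is_a"
HAS_PART = "has_part"
HAS_ROLE = "has_role"
OTHER = "other"

#: Relation types kept under their own name; anything else becomes ``other``.
KNOWN_RELATIONS = frozenset({IS_A, HAS_PART, HAS_ROLE})

#: Default relation set used for annotation propagation.
DEFAULT_ANNOTATION_RELATIONS = frozenset({IS_A, HAS_PART, HAS_ROLE})

#: Relations used for the display/result graph.
DISPLAY_RELATIONS = frozenset({IS_A, HAS_PART})

BRANCH_STRUCTURAL = "structural"
BRANCH_ROLE = "role"
BRANCH_OTHER = "other"


class OntologyError(Exception):
    """Base class for ontology-layer failures."""


class ParseError(OntologyError):
    """Raised for malformed OBO input."""


class UnknownTermError(OntologyError, KeyError):
    """Raised when a term id is not present in the graph."""


class EmptyPopulationError(OntologyError):
    """Raised when an annotation index would have no molecule leaves."""


class ConfigurationError(OntologyError):
    """Raised for invalid restriction/denominator configuration."""


@dataclass
class OntologyTerm:
    """A single ontology term.

    A term is a *molecule* iff it carries an InChI string; the string itself
    is treated as an opaque marker, no chemistry is interpreted.
    """

    term_id: str
    name: str = ""
    inchi: str | None = None
    is_obsolete: bool = False
    branch: str = BRANCH_STRUCTURAL

    def __post_init__(self) -> None:
        if not self.term_id:
            raise ValueError("term_id must be non-empty")
        if self.inchi is not None and not self.inchi.startswith("InChI="):
            raise ValueError(
                f"term {self.term_id}: InChI string must start with 'InChI=': "
                f"{self.inchi!r}"
            )

    @property
    def is_molecule(self) -> bool:
        return self.inchi is not None


@dataclass
class ParseReport:
    """What happened while reading an OBO file."""

    n_terms: int = 0
    n_obsolete: int = 0
    dropped_edges: int = 0
    messages: list[str] = field(default_factory=list)


@dataclass
class OntologyGraph:
    """Typed directed ontology graph; edges are (child, parent, relation)."""

    terms: dict[str, OntologyTerm] = field(default_factory=dict)
    edges: set[tuple[str, str, str]] = field(default_factory=set)
    obsolete_terms: dict[str, OntologyTerm] = field(default_factory=dict)
    report: ParseReport | None = None

    _parent_adj: dict[str, list[tuple[str, str]]] | None = field(
        default=None, repr=False, compare=False
    )
    _child_adj: dict[str, list[tuple[str, str]]] | None = field(
        default=None, repr=False, compare=False
    )

    # -- adjacency -----------------------------------------------------

    def _invalidate(self) -> None:
        self._parent_adj = None
        self._child_adj = None

    def parent_adjacency(self) -> Mapping[str, list[tuple[str, str]]]:
        """Map child id -> list of (parent_id, relation)."""
        if self._parent_adj is None:
            adj: dict[str, list[tuple[str, str]]] = {t: [] for t in self.terms}
            for child, parent, rel in sorted(self.edges):
                adj[child].append((parent, rel))
            self._parent_adj = adj
        return self._parent_adj

    def child_adjacency(self) -> Mapping[str, list[tuple[str, str]]]:
        """Map parent id -> list of (child_id, relation)."""
        if self._child_adj is None:
            adj: dict[str, list[tuple[str, str]]] = {t: [] for t in self.terms}
            for child, parent, rel in sorted(self.edges):
                adj[parent].append((child, rel))
            self._child_adj = adj
        return self._child_adj

    def roots(self, relations: frozenset[str] = DISPLAY_RELATIONS) -> set[str]:
        """Terms with no outgoing hierarchical edge."""
        has_out = {c for c, _p, r in self.edges if r in relations}
        return set(self.terms) - has_out

    def molecule_ids(self) -> set[str]:
        return {t for t, term in self.terms.items() if term.is_molecule}

    def class_ids(self) -> set[str]:
        return {t for t, term in self.terms.items() if not term.is_molecule}

    # -- branch tagging ------------------------------------------------

    def assign_branches(
        self,
        role_root_names: Iterable[str] = ("role",),
        role_root_ids: Iterable[str] = (),
        excluded_subtrees: Iterable[str] = (),
    ) -> None:
        """Tag every term as structural, role or other (excluded).

        A term is role-branch iff it is a role root or an ``is_a`` descendant
        of one.  Terms under an excluded subtree root become ``other``.
        """
        name_set = {n.lower() for n in role_root_names}
        roots = {t for t, term in self.terms.items() if term.name.lower() in name_set}
        roots |= {t for t in role_root_ids if t in self.terms}
        role_set = self._is_a_downset(roots)
        other_set = self._is_a_downset(
            {t for t in excluded_subtrees if t in self.terms}
        )
        for tid, term in self.terms.items():
            if tid in other_set:
                term.branch = BRANCH_OTHER
            elif tid in role_set:
                term.branch = BRANCH_ROLE
            else:
                term.branch = BRANCH_STRUCTURAL

    def _is_a_downset(self, seed: set[str]) -> set[str]:
        """seed plus all is_a descendants (towards leaves)."""
        child_adj = self.child_adjacency()
        seen = set(seed)
        stack = list(seed)
        while stack:
            node = stack.pop()
            for child, rel in child_adj[node]:
                if rel == IS_A and child not in seen:
                    seen.add(child)
                    stack.append(child)
        return seen


# ---------------------------------------------------------------------------
# OBO parsing
# ---------------------------------------------------------------------------

_PROPERTY_VALUE_RE = re.compile(r'^(?P<key>\S+)\s+"(?P<value>[^"]*)"')


def _open_source(source: str | os.PathLike | TextIO) -> TextIO:
    if hasattr(source, "read"):
        return source  # type: ignore[return-value]
    if isinstance(source, str) and "\n" in source:
        return io.StringIO(source)
    return open(source, "r", encoding="utf-8")


def _strip_obo_comment(value: str) -> str:
    # trailing " ! human readable name" comments
    return value.split(" ! ")[0].strip()


def parse_obo(source: str | os.PathLike | TextIO) -> OntologyGraph:
    """Parse an OBO 1.2/1.4 flat file into an :class:`OntologyGraph`.

    ``source`` may be a path, an open text stream, or the file content
    itself (any string containing a newline).  Obsolete terms are parsed
    and kept in ``graph.obsolete_terms`` but excluded from the graph and
    from all edges.  Edges whose target id was never declared are dropped
    and counted in ``graph.report.dropped_edges``.
    """
    stream = _open_source(source)
    report = ParseReport()

    stanzas: list[dict] = []
    current: dict | None = None
    in_term = False

    for lineno, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n")
        stripped = line.strip()
        if stripped.startswith("["):
            if in_term and current is not None:
                stanzas.append(current)
            in_term = stripped == "[Term]"
            current = {"lineno": lineno, "id": None, "name": "", "inchi": None,
                       "obsolete": False, "edges": []} if in_term else None
            continue
        if not in_term or current is None or not stripped or stripped.startswith("!"):
            continue
        if ":" not in stripped:
            continue
        key, _, value = stripped.partition(":")
        key = key.strip()
        value = value.strip()
        if key == "id":
            current["id"] = _strip_obo_comment(value)
        elif key == "name":
            current["name"] = value
        elif key == "is_obsolete":
            current["obsolete"] = value.lower().startswith("true")
        elif key == "is_a":
            current["edges"].append((IS_A, _strip_obo_comment(value)))
        elif key == "relationship":
            parts = _strip_obo_comment(value).split()
            if len(parts) < 2:
                raise ParseError(f"line {lineno}: malformed relationship line: {line!r}")
            rel = parts[0] if parts[0] in KNOWN_RELATIONS else OTHER
            current["edges"].append((rel, parts[1]))
        elif key == "property_value":
            m = _PROPERTY_VALUE_RE.match(value)
            if m and m.group("key").lower().endswith("inchi"):
                current["inchi"] = m.group("value")
        elif key == "xref":
            xkey, sep, xval = value.partition(":")
            if sep and xkey.lower().endswith("inchi") and xval.startswith("InChI="):
                current["inchi"] = xval.strip()
    if in_term and current is not None:
        stanzas.append(current)

    graph = OntologyGraph(report=report)
    pending_edges: list[tuple[str, str, str]] = []
    for stanza in stanzas:
        tid = stanza["id"]
        if not tid:
            raise ParseError(
                f"[Term] stanza starting at line {stanza['lineno']} has no id"
            )
        term = OntologyTerm(
            term_id=tid,
            name=stanza["name"],
            inchi=stanza["inchi"],
            is_obsolete=stanza["obsolete"],
        )
        if term.is_obsolete:
            graph.obsolete_terms[tid] = term
            report.n_obsolete += 1
            continue
        if tid in graph.terms:
            raise ParseError(f"duplicate term id {tid!r}")
        graph.terms[tid] = term
        for rel, target in stanza["edges"]:
            pending_edges.append((tid, target, rel))

    for child, parent, rel in pending_edges:
        if parent in graph.terms and child in graph.terms:
            graph.edges.add((child, parent, rel))
        else:
            report.dropped_edges += 1
            report.messages.append(
                f"dropped edge {child} -{rel}-> {parent}: undeclared or obsolete target"
            )
    report.n_terms = len(graph.terms)
    graph.assign_branches()
    return graph


# ---------------------------------------------------------------------------
# Restriction operations
# ---------------------------------------------------------------------------


def _induced_subgraph(graph: OntologyGraph, keep: set[str]) -> OntologyGraph:
    sub = OntologyGraph(
        terms={t: graph.terms[t] for t in keep},
        edges={(c, p, r) for c, p, r in graph.edges if c in keep and p in keep},
        report=graph.report,
    )
    return sub


def restrict_branch(graph: OntologyGraph, branch: str) -> OntologyGraph:
    """Restrict the ontology to its structural or role branch.

    ``branch='all'`` is the identity.  For the role branch, molecule leaves
    attached via ``has_role`` are retained as annotation sources.
    """
    if branch == "all":
        return _induced_subgraph(graph, set(graph.terms))
    if branch == BRANCH_STRUCTURAL:
        keep = {t for t, term in graph.terms.items() if term.branch == BRANCH_STRUCTURAL}
        return _induced_subgraph(graph, keep)
    if branch == BRANCH_ROLE:
        role_classes = {t for t, term in graph.terms.items() if term.branch == BRANCH_ROLE}
        if not role_classes:
            raise ConfigurationError(
                "branch='role' requested but no role root found in the ontology"
            )
        molecules = {
            c
            for c, p, r in graph.edges
            if r == HAS_ROLE and p in role_classes and graph.terms[c].is_molecule
        }
        return _induced_subgraph(graph, role_classes | molecules)
    raise ConfigurationError(f"unknown branch {branch!r}")


def filter_relations(graph: OntologyGraph, allowed: Iterable[str]) -> OntologyGraph:
    """Drop all edges whose relation is not in ``allowed``; nodes unchanged."""
    allowed = frozenset(allowed)
    if not allowed:
        raise ConfigurationError("allowed relation set must be non-empty")
    return OntologyGraph(
        terms=dict(graph.terms),
        edges={(c, p, r) for c, p, r in graph.edges if r in allowed},
        report=graph.report,
    )


def ancestors(
    graph: OntologyGraph,
    term_id: str,
    relations: Iterable[str] = DEFAULT_ANNOTATION_RELATIONS,
) -> set[str]:
    """Transitive closure along child->parent edges of the given relations.

    Excludes ``term_id`` itself.
    """
    if term_id not in graph.terms:
        raise UnknownTermError(term_id)
    relations = frozenset(relations)
    adj = graph.parent_adjacency()
    seen: set[str] = set()
    stack = [term_id]
    while stack:
        node = stack.pop()
        for parent, rel in adj[node]:
            if rel in relations and parent not in seen:
                seen.add(parent)
                stack.append(parent)
    seen.discard(term_id)
    return seen


def annotation_ancestors(
    graph: OntologyGraph,
    term_id: str,
    relations: Iterable[str] = DEFAULT_ANNOTATION_RELATIONS,
) -> set[str]:
    """Ancestor closure used for annotation propagation.

    Like :func:`ancestors` but ``has_role`` edges are only followed out of
    the origin term itself (molecule -> role class), never chained further
    down the walk; the role hierarchy is then climbed via ``is_a``.
    """
    if term_id not in graph.terms:
        raise UnknownTermError(term_id)
    relations = frozenset(relations)
    adj = graph.parent_adjacency()
    seen: set[str] = set()
    stack = [term_id]
    while stack:
        node = stack.pop()
        for parent, rel in adj[node]:
            if rel not in relations:
                continue
            if rel == HAS_ROLE and node != term_id:
                continue
            if parent not in seen:
                seen.add(parent)
                stack.append(parent)
    seen.discard(term_id)
    return seen


@dataclass
class AnnotationIndex:
    """Transitive class -> molecule annotation sets plus population sizes."""

    class_to_molecules: dict[str, frozenset[str]]
    population_size_entities: int
    population_size_classes: int
    molecule_ids: frozenset[str]
    names: dict[str, str] = field(default_factory=dict)

    def molecules_of(self, class_id: str) -> frozenset[str]:
        return self.class_to_molecules.get(class_id, frozenset())


def build_annotation_index(
    graph: OntologyGraph,
    relations: Iterable[str] = DEFAULT_ANNOTATION_RELATIONS,
) -> AnnotationIndex:
    """Annotate every class with the molecules it transitively subsumes.

    ``N_e`` (entity population) counts distinct InChI-bearing leaves in the
    graph; ``N_c`` counts class terms.  Classes subsuming no molecule are
    simply absent from the map.
    """
    relations = frozenset(relations)
    molecules = sorted(graph.molecule_ids())
    if not molecules:
        raise EmptyPopulationError("ontology contains no InChI-bearing molecule leaves")
    class_to_mols: dict[str, set[str]] = {}
    is_mol = {t: graph.terms[t].is_molecule for t in graph.terms}
    for mol in molecules:
        for anc in annotation_ancestors(graph, mol, relations):
            if is_mol[anc]:
                continue  # molecule-above-molecule (e.g. has_part) is not a class
            class_to_mols.setdefault(anc, set()).add(mol)
    n_classes = sum(1 for v in is_mol.values() if not v)
    return AnnotationIndex(
        class_to_molecules={c: frozenset(s) for c, s in class_to_mols.items()},
        population_size_entities=len(molecules),
        population_size_classes=n_classes,
        molecule_ids=frozenset(molecules),
        names={t: term.name for t, term in graph.terms.items()},
    )
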