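"""Result-graph pruning: five reduction operators and the strategy engine.

The result graph keeps only ``is_a`` / ``has_part`` edges (child -> parent).
A strategy applies pruners in three phases: pre-loop (once), loop (repeated
until a full pass leaves the graph unchanged) and final (once).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping

import networkx as nx

from .ontology import DISPLAY_RELATIONS, IS_A, OntologyGraph
from .stats import EnrichmentRow


class PruningError(Exception):
    pass


@dataclass
class ResultGraph:
    """Pruned/prunable enrichment result graph.

    ``graph`` is a DiGraph with child->parent edges carrying a ``relation``
    attribute and nodes carrying ``name`` and ``is_molecule``.  When two
    typed edges connect the same pair, ``is_a`` wins (edges are treated as
    equivalent for pruning).  ``collapsed_paths`` maps a replacement edge to
    the ordered ids removed by the linear branch collapser.
    """

    graph: nx.DiGraph
    node_stats: dict[str, EnrichmentRow] = field(default_factory=dict)
    collapsed_paths: dict[tuple[str, str], list[str]] = field(default_factory=dict)

    @classmethod
    def from_ontology(
        cls,
        ontology: OntologyGraph,
        rows: Iterable[EnrichmentRow] = (),
        relations: frozenset[str] = DISPLAY_RELATIONS,
    ) -> "ResultGraph":
        g = nx.DiGraph()
        for tid in sorted(ontology.terms):
            term = ontology.terms[tid]
            g.add_node(tid, name=term.name, is_molecule=term.is_molecule)
        for child, parent, rel in sorted(ontology.edges):
            if rel not in relations:
                continue
            if g.has_edge(child, parent) and g[child][parent]["relation"] == IS_A:
                continue
            g.add_edge(child, parent, relation=rel)
        return cls(graph=g, node_stats={r.class_id: r for r in rows})

    def copy(self) -> "ResultGraph":
        return ResultGraph(
            graph=self.graph.copy(),
            node_stats=dict(self.node_stats),
            collapsed_paths={k: list(v) for k, v in self.collapsed_paths.items()},
        )

    def signature(self) -> tuple[frozenset, frozenset]:
        return frozenset(self.graph.nodes), frozenset(self.graph.edges)

    def _remove_nodes(self, nodes: Iterable[str]) -> None:
        nodes = set(nodes)
        self.graph.remove_nodes_from(nodes)
        self.node_stats = {k: v for k, v in self.node_stats.items() if k not in nodes}
        self.collapsed_paths = {
            (c, p): ids
            for (c, p), ids in self.collapsed_paths.items()
            if c not in nodes and p not in nodes
        }


# ---------------------------------------------------------------------------
# Pruners.  Each takes a ResultGraph and returns a new, pruned one.
# ---------------------------------------------------------------------------


def zero_degree_vertex_pruner(rg: ResultGraph) -> ResultGraph:
    """Remove nodes with neither incoming nor outgoing edges."""
    out = rg.copy()
    isolated = [n for n in out.graph if out.graph.degree(n) == 0]
    out._remove_nodes(isolated)
    return out


def root_children_pruner(rg: ResultGraph, levels: int = 3) -> ResultGraph:
    """Remove the top ``levels`` levels below (and including) the roots.

    Roots are nodes with no outgoing child->parent edge; a node is removed
    when its minimum distance from some root, measured towards the leaves,
    is < ``levels``.
    """
    if levels < 1:
        raise ValueError("levels must be >= 1")
    out = rg.copy()
    g = out.graph
    roots = [n for n in g if g.out_degree(n) == 0]
    if len(g) and not roots:
        raise PruningError("graph has no roots; cycle suspected")
    depth: dict[str, int] = {r: 0 for r in roots}
    frontier = list(roots)
    d = 0
    while frontier and d + 1 < levels:
        d += 1
        nxt = []
        for node in frontier:
            for child in g.predecessors(node):
                if child not in depth:
                    depth[child] = d
                    nxt.append(child)
        frontier = nxt
    out._remove_nodes([n for n, dd in depth.items() if dd < levels])
    return out


def molecule_leaves_pruner(rg: ResultGraph) -> ResultGraph:
    """Remove InChI-bearing nodes with no incoming edge (distinct molecules)."""
    out = rg.copy()
    g = out.graph
    doomed = [
        n for n in g if g.in_degree(n) == 0 and g.nodes[n].get("is_molecule", False)
    ]
    out._remove_nodes(doomed)
    return out


def high_pvalue_branch_pruner(
    rg: ResultGraph,
    alpha: float = 0.05,
    use: str = "p_adj",
    protect: Iterable[str] = (),
) -> ResultGraph:
    """Remove branches where every node in the down-set is insignificant.

    A node is retained iff it, or some descendant towards the leaves, has
    p <= alpha; nodes without statistics count as insignificant.  ``use``
    selects ``p_adj`` (default) or ``p_raw``.  ``protect`` may contain
    ``"molecules"`` and/or ``"roots"``: those nodes are never removed (used
    by the fragment preset, which keeps terminal molecule leaves and roots).
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    if use not in ("p_adj", "p_raw"):
        raise ValueError(f"unknown p-value field {use!r}")
    protect = set(protect)
    out = rg.copy()
    g = out.graph
    significant = {
        n
        for n, row in out.node_stats.items()
        if n in g and getattr(row, use) <= alpha
    }
    retained = set(significant)
    stack = list(significant)
    while stack:  # significant nodes keep all their ancestors
        node = stack.pop()
        for parent in g.successors(node):
            if parent not in retained:
                retained.add(parent)
                stack.append(parent)
    if "molecules" in protect:
        retained |= {n for n in g if g.nodes[n].get("is_molecule", False)}
    if "roots" in protect:
        retained |= {n for n in g if g.out_degree(n) == 0}
    out._remove_nodes(set(g.nodes) - retained)
    return out


def linear_branch_collapser(rg: ResultGraph) -> ResultGraph:
    """Collapse maximal stretches of in-degree-1/out-degree-1 nodes.

    Each stretch is removed and replaced by a single edge connecting its
    surrounding nodes; the removed ids are recorded on that edge (previously
    recorded stretches along the path are inlined in order).  No parallel
    edge is created: an existing edge absorbs the record.
    """
    out = rg.copy()
    g = out.graph
    interior = {n for n in g if g.in_degree(n) == 1 and g.out_degree(n) == 1}
    done: set[str] = set()
    for seed in sorted(interior):
        if seed in done:
            continue
        if not g.has_node(seed) or g.in_degree(seed) != 1 or g.out_degree(seed) != 1:
            continue  # degree changed earlier in this pass
        chain = [seed]
        head = seed
        while True:
            prev = next(iter(g.predecessors(head)))
            if prev in interior and prev not in done and prev not in chain:
                chain.insert(0, prev)
                head = prev
            else:
                break
        tail = seed
        while True:
            nxt = next(iter(g.successors(tail)))
            if nxt in interior and nxt not in done and nxt not in chain:
                chain.append(nxt)
                tail = nxt
            else:
                break
        done.update(chain)
        pred = next(iter(g.predecessors(chain[0])))
        succ = next(iter(g.successors(chain[-1])))
        path_edges = (
            [(pred, chain[0])]
            + list(zip(chain, chain[1:]))
            + [(chain[-1], succ)]
        )
        removed = []
        for i, (c, p) in enumerate(path_edges):
            removed.extend(out.collapsed_paths.pop((c, p), []))
            if p != succ:
                removed.append(p)
        relation = g[chain[-1]][succ]["relation"]
        out._remove_nodes(chain)
        if g.has_edge(pred, succ):
            out.collapsed_paths.setdefault((pred, succ), []).extend(removed)
        else:
            g.add_edge(pred, succ, relation=relation)
            out.collapsed_paths[(pred, succ)] = removed
    return out


# ---------------------------------------------------------------------------
# Strategy engine
# ---------------------------------------------------------------------------

PrunerSpec = tuple[str, dict]

PRUNERS: Mapping[str, Callable[..., ResultGraph]] = {
    "zero_degree_vertex": zero_degree_vertex_pruner,
    "root_children": root_children_pruner,
    "molecule_leaves": molecule_leaves_pruner,
    "high_p_branch": high_pvalue_branch_pruner,
    "linear_branch_collapser": linear_branch_collapser,
}


@dataclass
class PruningStrategy:
    """Ordered pruner lists for the pre-loop, loop and final phases."""

    pre_loop: list[PrunerSpec] = field(default_factory=list)
    loop: list[PrunerSpec] = field(default_factory=list)
    final: list[PrunerSpec] = field(default_factory=list)

    def validate(self) -> None:
        for phase in (self.pre_loop, self.loop, self.final):
            for name, _params in phase:
                if name not in PRUNERS:
                    raise PruningError(f"unknown pruner {name!r}")


def plain_default(alpha: float = 0.05) -> PruningStrategy:
    return PruningStrategy(
        pre_loop=[
            ("high_p_branch", {"alpha": alpha}),
            ("linear_branch_collapser", {}),
            ("root_children", {"levels": 3}),
        ],
        loop=[
            ("molecule_leaves", {}),
            ("high_p_branch", {"alpha": alpha}),
            ("linear_branch_collapser", {}),
            ("zero_degree_vertex", {}),
        ],
        final=[],
    )


def weighted_default(alpha: float = 0.05) -> PruningStrategy:
    strat = plain_default(alpha)
    strat.final = [("zero_degree_vertex", {})]
    return strat


def fragment_default(alpha: float = 0.05) -> PruningStrategy:
    # terminal molecule leaves and root vertices are never removed
    hp = ("high_p_branch", {"alpha": alpha, "protect": ("molecules", "roots")})
    return PruningStrategy(
        pre_loop=[hp, ("linear_branch_collapser", {})],
        loop=[hp, ("linear_branch_collapser", {})],
        final=[],
    )


STRATEGY_PRESETS: Mapping[str, Callable[[float], PruningStrategy]] = {
    "plain_default": plain_default,
    "weighted_default": weighted_default,
    "fragment_default": fragment_default,
}


def _apply_one(rg: ResultGraph, spec: PrunerSpec) -> ResultGraph:
    name, params = spec
    return PRUNERS[name](rg, **params)


def apply_strategy(
    rg: ResultGraph, strategy: PruningStrategy
) -> tuple[ResultGraph, list[tuple[str, str, int]]]:
    """Run the three strategy phases; returns (graph, log).

    The log holds one ``(phase, pruner, nodes_removed)`` entry per pruner
    application.  The loop phase exits when a full pass changes neither the
    node nor the edge set and is guarded at 10 * |V| passes.
    """
    strategy.validate()
    log: list[tuple[str, str, int]] = []

    def run(rg: ResultGraph, spec: PrunerSpec, phase: str) -> ResultGraph:
        before = rg.graph.number_of_nodes()
        out = _apply_one(rg, spec)
        log.append((phase, spec[0], before - out.graph.number_of_nodes()))
        return out

    for spec in strategy.pre_loop:
        rg = run(rg, spec, "pre_loop")
    max_passes = 10 * max(1, rg.graph.number_of_nodes())
    passes = 0
    while strategy.loop:
        before = rg.signature()
        for spec in strategy.loop:
            rg = run(rg, spec, "loop")
        passes += 1
        if rg.signature() == before:
            break
        if passes > max_passes:
            raise PruningError("pruning loop failed to reach a fixpoint")
    for spec in strategy.final:
        rg = run(rg, spec, "final")
    return rg, log
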