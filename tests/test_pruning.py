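import random

import pytest

from conftest import make_result_graph, random_dag
from oracles import reachable_pairs

from molenrich.pruning import (
    PruningError,
    PruningStrategy,
    apply_strategy,
    fragment_default,
    high_pvalue_branch_pruner,
    linear_branch_collapser,
    molecule_leaves_pruner,
    plain_default,
    root_children_pruner,
    weighted_default,
    zero_degree_vertex_pruner,
)


class TestZeroDegreeVertexPruner:
    def test_single_isolated_node(self):
        rg = make_result_graph([], extra_nodes=["lonely"])
        assert zero_degree_vertex_pruner(rg).graph.number_of_nodes() == 0

    def test_connected_chain_unchanged(self):
        rg = make_result_graph([("a", "b"), ("b", "c")])
        out = zero_degree_vertex_pruner(rg)
        assert set(out.graph.nodes) == {"a", "b", "c"}

    def test_mixed(self):
        rg = make_result_graph(
            [("a", "b"), ("c", "d")], extra_nodes=["x", "y"]
        )
        out = zero_degree_vertex_pruner(rg)
        assert set(out.graph.nodes) == {"a", "b", "c", "d"}


class TestRootChildrenPruner:
    def test_levels_one_removes_roots_only(self):
        rg = make_result_graph([("b", "a"), ("c", "b")])  # a is the root
        out = root_children_pruner(rg, levels=1)
        assert set(out.graph.nodes) == {"b", "c"}

    def test_three_levels_chain(self):
        # chain R <- A <- B <- m  (edges child->parent)
        rg = make_result_graph([("A", "R"), ("B", "A"), ("m", "B")])
        out = root_children_pruner(rg, levels=3)
        assert set(out.graph.nodes) == {"m"}
        assert out.graph.degree("m") == 0

    def test_levels_beyond_depth_empties_graph(self):
        rg = make_result_graph([("b", "a")])
        assert root_children_pruner(rg, levels=10).graph.number_of_nodes() == 0

    def test_min_distance_over_all_roots(self):
        # d is depth 1 from root r2 even though depth 3 from r1
        rg = make_result_graph(
            [("a", "r1"), ("b", "a"), ("d", "b"), ("d", "r2")]
        )
        out = root_children_pruner(rg, levels=2)
        assert "d" not in out.graph

    def test_invalid_levels(self):
        with pytest.raises(ValueError):
            root_children_pruner(make_result_graph([("a", "b")]), levels=0)


class TestMoleculeLeavesPruner:
    def test_leaf_molecule_removed_class_kept(self):
        rg = make_result_graph([("mol", "cls")], molecules=["mol"])
        out = molecule_leaves_pruner(rg)
        assert set(out.graph.nodes) == {"cls"}

    def test_molecule_with_incoming_edge_retained(self):
        # a molecule with has_part children has in-degree > 0
        rg = make_result_graph([("part", "mol"), ("mol", "cls")], molecules=["mol"])
        out = molecule_leaves_pruner(rg)
        assert "mol" in out.graph

    def test_class_leaf_retained(self):
        rg = make_result_graph(
            [(f"m{i}", "c1") for i in range(3)] + [("c1", "c2")],
            molecules=[f"m{i}" for i in range(3)],
        )
        out = molecule_leaves_pruner(rg)
        assert set(out.graph.nodes) == {"c1", "c2"}


class TestHighPvalueBranchPruner:
    def test_all_insignificant_empties_graph(self):
        rg = make_result_graph(
            [("a", "b"), ("b", "c")], pvalues={"a": 1.0, "b": 1.0, "c": 1.0}
        )
        assert high_pvalue_branch_pruner(rg, 0.05).graph.number_of_nodes() == 0

    def test_significant_leaf_keeps_ancestors(self):
        rg = make_result_graph(
            [("leaf", "mid"), ("mid", "root"), ("other", "root")],
            pvalues={"leaf": 0.01, "mid": 0.9, "root": 0.9, "other": 0.9},
        )
        out = high_pvalue_branch_pruner(rg, 0.05)
        assert set(out.graph.nodes) == {"leaf", "mid", "root"}

    def test_insignificant_subtree_off_significant_spine(self):
        spine = [("s2", "s1"), ("s1", "s0")]
        hangers = [("h1", "s1"), ("h2", "h1"), ("h3", "h1"), ("h4", "h3")]
        pv = {"s0": 0.9, "s1": 0.9, "s2": 0.01}
        pv.update({h: 0.5 for h in ("h1", "h2", "h3", "h4")})
        out = high_pvalue_branch_pruner(make_result_graph(spine + hangers, pvalues=pv), 0.05)
        assert set(out.graph.nodes) == {"s0", "s1", "s2"}

    def test_nodes_without_stats_count_as_high_p(self):
        rg = make_result_graph([("a", "b")])  # no stats at all
        assert high_pvalue_branch_pruner(rg, 0.05).graph.number_of_nodes() == 0

    def test_protect_molecules_and_roots(self):
        rg = make_result_graph(
            [("mol", "cls"), ("cls", "root")],
            molecules=["mol"],
            pvalues={"cls": 0.9, "root": 0.9},
        )
        out = high_pvalue_branch_pruner(rg, 0.05, protect=("molecules", "roots"))
        assert set(out.graph.nodes) == {"mol", "root"}

    @pytest.mark.parametrize("seed", range(15))
    def test_safety_property(self, seed):
        rng = random.Random(seed)
        edges = random_dag(rng, rng.randint(5, 40))
        nodes = {n for e in edges for n in e}
        pv = {n: rng.random() for n in nodes}
        rg = make_result_graph(edges, pvalues=pv)
        out = high_pvalue_branch_pruner(rg, 0.05)
        kept = set(out.graph.nodes)
        # never removes a significant node
        assert {n for n in nodes if pv[n] <= 0.05} <= kept
        # nor any ancestor of one (ancestors = reachable along child->parent)
        pairs = reachable_pairs(edges, nodes)
        for n in nodes:
            if pv[n] <= 0.05:
                assert {v for (u, v) in pairs if u == n} <= kept


class TestLinearBranchCollapser:
    def test_minimal_stretch(self):
        rg = make_result_graph([("a", "x"), ("x", "b")])
        out = linear_branch_collapser(rg)
        assert set(out.graph.nodes) == {"a", "b"}
        assert out.graph.has_edge("a", "b")
        assert out.collapsed_paths[("a", "b")] == ["x"]

    def test_diamond_without_degree11_interior_unchanged(self):
        # two leaves feed both sides, so no node has in-degree 1 and
        # out-degree 1 and nothing may collapse
        edges = [("m", "A"), ("m", "B"), ("m2", "A"), ("m2", "B"),
                 ("A", "T"), ("B", "T")]
        out = linear_branch_collapser(make_result_graph(edges))
        assert set(out.graph.edges) == set(edges)
        assert out.collapsed_paths == {}

    def test_five_interior_nodes_collapse_to_one_edge(self):
        chain = ["a", "x1", "x2", "x3", "x4", "x5", "b"]
        edges = list(zip(chain, chain[1:]))
        out = linear_branch_collapser(make_result_graph(edges))
        assert set(out.graph.nodes) == {"a", "b"}
        assert out.collapsed_paths[("a", "b")] == ["x1", "x2", "x3", "x4", "x5"]

    def test_no_parallel_duplicate_edges(self):
        # a->x->b stretch plus a direct a->b edge: record merges, one edge
        out = linear_branch_collapser(
            make_result_graph([("a", "x"), ("x", "b"), ("a", "b")])
        )
        assert out.graph.number_of_edges() == 1
        assert out.collapsed_paths[("a", "b")] == ["x"]

    def test_repeat_collapse_inlines_previous_record(self):
        chain = ["a", "x", "b", "y", "c"]
        rg = make_result_graph(list(zip(chain, chain[1:])))
        once = linear_branch_collapser(rg)
        assert set(once.graph.nodes) == {"a", "c"}
        assert once.collapsed_paths[("a", "c")] == ["x", "b", "y"]

    @pytest.mark.parametrize("seed", range(15))
    def test_reachability_preserved(self, seed):
        rng = random.Random(100 + seed)
        edges = random_dag(rng, rng.randint(5, 60), p_edge=0.1)
        nodes = {n for e in edges for n in e}
        rg = make_result_graph(edges)
        out = linear_branch_collapser(rg)
        kept = set(out.graph.nodes)
        before = {
            (u, v) for (u, v) in reachable_pairs(edges, nodes)
            if u in kept and v in kept
        }
        after = reachable_pairs(set(out.graph.edges), kept)
        assert before == after


class TestApplyStrategy:
    def test_empty_strategy_is_identity(self):
        rg = make_result_graph([("a", "b"), ("c", "b")], extra_nodes=["z"])
        out, log = apply_strategy(rg, PruningStrategy())
        assert out.signature() == rg.signature()
        assert log == []

    def test_plain_default_on_all_insignificant_graph_empties(self):
        edges = [("m1", "c1"), ("c1", "c0"), ("m2", "c1")]
        rg = make_result_graph(edges, molecules=["m1", "m2"],
                               pvalues={"c0": 0.9, "c1": 0.9})
        out, _ = apply_strategy(rg, plain_default(0.05))
        assert out.graph.number_of_nodes() == 0

    def test_loop_output_is_fixpoint(self):
        rng = random.Random(77)
        edges = random_dag(rng, 40)
        nodes = {n for e in edges for n in e}
        pv = {n: rng.random() for n in nodes}
        mols = {n for n in nodes if rng.random() < 0.3}
        rg = make_result_graph(edges, molecules=mols, pvalues=pv)
        strat = plain_default(0.2)
        out, _ = apply_strategy(rg, strat)
        again, _ = apply_strategy(out, PruningStrategy(loop=strat.loop))
        assert again.signature() == out.signature()

    def test_unknown_pruner_rejected(self):
        with pytest.raises(PruningError):
            apply_strategy(
                make_result_graph([("a", "b")]),
                PruningStrategy(loop=[("bogus", {})]),
            )

    def test_log_records_removals(self):
        rg = make_result_graph([], extra_nodes=["only"])
        _, log = apply_strategy(
            rg, PruningStrategy(pre_loop=[("zero_degree_vertex", {})])
        )
        assert log == [("pre_loop", "zero_degree_vertex", 1)]

    @pytest.mark.parametrize("seed", range(10))
    def test_termination_on_random_dags(self, seed):
        rng = random.Random(999 + seed)
        edges = random_dag(rng, rng.randint(3, 50))
        nodes = {n for e in edges for n in e}
        pv = {n: rng.random() for n in nodes if rng.random() < 0.8}
        mols = {n for n in nodes if rng.random() < 0.2}
        rg = make_result_graph(edges, molecules=mols, pvalues=pv)
        for strat in (plain_default(0.1), weighted_default(0.1), fragment_default(0.1)):
            out, _ = apply_strategy(rg, strat)  # must not raise
            assert out.graph.number_of_nodes() <= rg.graph.number_of_nodes()

    def test_fragment_keeps_molecule_leaves_and_roots(self):
        edges = [("mol1", "c1"), ("mol2", "c2"), ("c1", "root"), ("c2", "root")]
        rg = make_result_graph(edges, molecules=["mol1", "mol2"],
                               pvalues={"c1": 0.01, "c2": 0.99, "root": 0.99})
        out, _ = apply_strategy(rg, fragment_default(0.05))
        assert {"mol1", "mol2", "root"} <= set(out.graph.nodes)
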