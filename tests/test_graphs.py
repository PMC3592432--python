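"""Topology pipeline: loops, cycles, moralization, triangulation, trees."""

import itertools

import networkx as nx
import numpy as np
import pytest

from clipper import graphs
from clipper.datasets import ExpressionDataset


def dag(*edges):
    g = nx.DiGraph()
    g.add_edges_from(edges)
    return g


def random_dataset(genes, n=12, seed=0):
    rng = np.random.default_rng(seed)
    values = rng.normal(size=(len(genes), n))
    labels = np.array([0] * (n // 2) + [1] * (n - n // 2))
    return ExpressionDataset(values, list(genes), [f"s{i}" for i in range(n)], labels)


class TestSelfLoops:
    def test_removes_only_self_loops(self):
        g = dag(("a", "a"), ("a", "b"))
        out = graphs.remove_self_loops(g)
        assert set(out.edges) == {("a", "b")}

    def test_identity_without_loops(self):
        g = dag(("a", "b"), ("b", "c"))
        assert set(graphs.remove_self_loops(g).edges) == set(g.edges)

    def test_all_loops_leaves_edgeless_graph(self):
        g = dag(("a", "a"), ("b", "b"))
        out = graphs.remove_self_loops(g)
        assert set(out.nodes) == {"a", "b"} and out.number_of_edges() == 0


class TestBreakCycles:
    def test_weakest_edge_of_forced_cycle_removed(self):
        # a->b->c->a; profiles crafted so |cor|(c,a) is clearly the smallest
        data = random_dataset(["a", "b", "c"], n=10, seed=1)
        data.values[1] = data.values[0] + 0.01 * data.values[1]  # b ~ a
        data.values[2] = np.concatenate([data.values[2][:5], -data.values[2][:5]])
        cors = {
            e: abs(np.corrcoef(data.row(e[0]), data.row(e[1]))[0, 1])
            for e in [("a", "b"), ("b", "c"), ("c", "a")]
        }
        weakest = min(cors, key=cors.get)
        g = dag(("a", "b"), ("b", "c"), ("c", "a"))
        out = graphs.break_cycles(g, data)
        assert nx.is_directed_acyclic_graph(out)
        assert set(g.edges) - set(out.edges) == {weakest}

    def test_acyclic_input_unchanged(self):
        data = random_dataset(["a", "b", "c"])
        g = dag(("a", "b"), ("b", "c"))
        assert set(graphs.break_cycles(g, data).edges) == set(g.edges)

    def test_two_disjoint_two_cycles(self):
        # Both edges of a 2-cycle share endpoints (equal |cor|); exactly one
        # edge per cycle must go, the lexicographic tie-break picking it.
        # Brute force: every single-edge removal per cycle yields a DAG.
        data = random_dataset(["a", "b", "c", "d"])
        g = dag(("a", "b"), ("b", "a"), ("c", "d"), ("d", "c"))
        for combo in itertools.product([("a", "b"), ("b", "a")], [("c", "d"), ("d", "c")]):
            h = g.copy()
            h.remove_edges_from(combo)
            assert nx.is_directed_acyclic_graph(h)
        out = graphs.break_cycles(g, data)
        removed = set(g.edges) - set(out.edges)
        assert nx.is_directed_acyclic_graph(out)
        assert removed == {("a", "b"), ("c", "d")}

    def test_zero_variance_cycle_fails(self):
        data = random_dataset(["a", "b"])
        data.values[:] = 1.0
        with pytest.raises(ValueError, match="zero-variance"):
            graphs.break_cycles(dag(("a", "b"), ("b", "a")), data)

    def test_output_always_acyclic_on_random_digraphs(self):
        for rep in range(200):
            rng = np.random.default_rng(rep)
            n = int(rng.integers(4, 10))
            genes = [f"g{i}" for i in range(n)]
            g = nx.DiGraph()
            g.add_nodes_from(genes)
            for u, v in itertools.permutations(genes, 2):
                if rng.random() < 0.25:
                    g.add_edge(u, v)
            data = random_dataset(genes, n=10, seed=rep + 1)
            out = graphs.break_cycles(g, data)
            assert nx.is_directed_acyclic_graph(out)


class TestMoralize:
    def test_v_structure_marries_parents(self):
        out = graphs.moralize(dag(("a", "c"), ("b", "c")))
        assert set(map(frozenset, out.edges)) == {
            frozenset("ac"), frozenset("bc"), frozenset("ab")
        }

    def test_chain_unchanged(self):
        out = graphs.moralize(dag(("a", "b"), ("b", "c")))
        assert set(map(frozenset, out.edges)) == {frozenset("ab"), frozenset("bc")}

    def test_three_parents_become_complete(self):
        out = graphs.moralize(dag(("a", "d"), ("b", "d"), ("c", "d")))
        assert out.number_of_edges() == 6  # complete on 4 nodes

    def test_cyclic_input_rejected(self):
        with pytest.raises(ValueError, match="acyclic"):
            graphs.moralize(dag(("a", "b"), ("b", "a")))

    def test_edges_are_input_union_marriages(self):
        for rep in range(30):
            rng = np.random.default_rng(rep)
            n = 8
            order = [f"g{i}" for i in range(n)]
            g = nx.DiGraph()
            g.add_nodes_from(order)
            for i, j in itertools.combinations(range(n), 2):
                if rng.random() < 0.3:
                    g.add_edge(order[i], order[j])
            marriages = set()
            for v in g.nodes:
                for u, w in itertools.combinations(sorted(g.predecessors(v)), 2):
                    marriages.add(frozenset((u, w)))
            expected = {frozenset(e) for e in g.edges} | marriages
            out = graphs.moralize(g)
            assert {frozenset(e) for e in out.edges} == expected


class TestTriangulate:
    def test_four_cycle_gets_exactly_one_chord(self):
        mg = nx.cycle_graph(["a", "b", "c", "d"])
        out = graphs.triangulate(mg)
        assert len(out.graph["fill_edges"]) == 1
        assert nx.is_chordal(out)

    def test_chordal_graph_untouched(self):
        mg = nx.complete_graph(["a", "b", "c"])
        out = graphs.triangulate(mg)
        assert out.graph["fill_edges"] == []
        assert set(map(frozenset, out.edges)) == set(map(frozenset, mg.edges))

    def test_six_cycle_chordal_by_independent_check(self):
        out = graphs.triangulate(nx.cycle_graph([f"n{i}" for i in range(6)]))
        assert nx.is_chordal(out)  # networkx MCS-based chordality oracle

    def test_random_graphs_become_chordal_and_keep_edges(self):
        for rep in range(50):
            g = nx.gnp_random_graph(12, 0.25, seed=rep)
            g = nx.relabel_nodes(g, {i: f"g{i:02d}" for i in g.nodes})
            out = graphs.triangulate(g)
            assert nx.is_chordal(out)
            assert set(map(frozenset, g.edges)) <= set(map(frozenset, out.edges))

    def test_mcs_gives_perfect_elimination_ordering(self):
        # simpliciality of each vertex's later neighbours in reverse MCS order
        g = graphs.triangulate(nx.gnp_random_graph(15, 0.3, seed=3))
        order = graphs.mcs_order(g)
        pos = {v: i for i, v in enumerate(order)}
        for v in order:
            earlier = [u for u in g[v] if pos[u] < pos[v]]
            for a, b in itertools.combinations(earlier, 2):
                assert g.has_edge(a, b)


class TestCliquesAndTree:
    def test_triangle_single_clique(self):
        assert graphs.find_cliques(nx.complete_graph("abc")) == [("a", "b", "c")]

    def test_path_two_cliques(self):
        cg = nx.path_graph("abc")
        assert graphs.find_cliques(cg) == [("a", "b"), ("b", "c")]

    def test_chorded_square(self):
        cg = nx.cycle_graph("abcd")
        cg.add_edge("a", "c")
        assert graphs.find_cliques(cg) == [("a", "b", "c"), ("a", "c", "d")]

    def test_two_clique_separator(self):
        cg = nx.path_graph("abc")
        jt = graphs.build_junction_tree(graphs.find_cliques(cg), cg)
        (edge,) = jt.tree.edges
        assert jt.separator(*edge) == frozenset({"b"})

    def test_complete_graph_single_clique_tree(self):
        cg = nx.complete_graph("abcde")
        jt = graphs.build_junction_tree(graphs.find_cliques(cg), cg)
        assert len(jt.cliques) == 1 and jt.tree.number_of_edges() == 0
        assert jt.leaves() == [jt.root]

    def test_disconnected_cliques_rejected(self):
        cg = nx.Graph([("a", "b"), ("c", "d")])
        with pytest.raises(ValueError, match="disconnected"):
            graphs.build_junction_tree(graphs.find_cliques(cg), cg)

    def test_running_intersection_on_random_graphs(self):
        # random moralized/triangulated graphs, per connected component
        checked = 0
        for rep in range(200):
            g = nx.gnp_random_graph(20, 0.2, seed=rep, directed=True)
            g = nx.relabel_nodes(g, {i: f"g{i:02d}" for i in g.nodes})
            d = nx.DiGraph((u, v) for u, v in g.edges if u < v)  # force DAG
            d.add_nodes_from(g.nodes)
            moral = graphs.moralize(d)
            for comp in nx.connected_components(moral):
                if len(comp) < 2:
                    continue
                sub = moral.subgraph(comp).copy()
                cg, jt = graphs.junction_tree_from_graph(sub)
                assert jt.check_running_intersection()
                assert jt.tree.number_of_edges() == len(jt.cliques) - 1
                # coverage: cliques cover nodes and edges
                assert jt.genes() == set(sub.nodes)
                cl_sets = [set(c) for c in jt.cliques]
                for e in cg.edges:
                    assert any(set(e) <= c for c in cl_sets)
                checked += 1
        assert checked > 100
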