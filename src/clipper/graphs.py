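"""Pathway topology pipeline: directed gene network -> rooted junction tree.

A pathway arrives as a directed, possibly cyclic gene-gene graph. The
decomposition used by the two-sample graphical Gaussian machinery needs an
undirected decomposable (chordal) graph, obtained through the classical
sequence: self-loop removal, data-driven cycle breaking, moralization,
triangulation, maximal-clique identification and junction-tree construction.
All tie-breaks are lexicographic on gene identifiers so a run is a pure
function of its inputs.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "JunctionTree",
    "remove_self_loops",
    "break_cycles",
    "moralize",
    "triangulate",
    "find_cliques",
    "mcs_order",
    "build_junction_tree",
    "junction_tree_from_graph",
    "is_chordal",
]


def _ordered_copy(g: nx.DiGraph) -> nx.DiGraph:
    """Rebuild with sorted node/edge insertion so traversals are deterministic."""
    h = nx.DiGraph()
    h.add_nodes_from(sorted(g.nodes))
    h.add_edges_from(sorted(g.edges))
    return h


def remove_self_loops(g: nx.DiGraph) -> nx.DiGraph:
    """Drop every edge (v, v); all other edges are preserved."""
    h = _ordered_copy(g)
    loops = list(nx.selfloop_edges(h))
    h.remove_edges_from(loops)
    if loops:
        logger.info("removed %d self-loop(s)", len(loops))
    return h


def break_cycles(g: nx.DiGraph, data) -> nx.DiGraph:
    """Delete directed cycles by dropping each cycle's weakest edge.

    Within the currently detected cycle the edge whose endpoint expression
    profiles have minimum absolute Pearson correlation (computed on all
    samples pooled) is removed; detection repeats until the graph is acyclic.
    Only edges lying on some directed cycle are ever removed.

    Parameters
    ----------
    g : directed graph without self-loops
    data : ExpressionDataset covering every node of ``g``
    """
    if any(u == v for u, v in g.edges):
        raise ValueError("remove self-loops before breaking cycles")
    h = _ordered_copy(g)
    corr_cache: dict[tuple[str, str], float] = {}

    def abs_corr(u: str, v: str) -> float:
        key = (u, v) if u <= v else (v, u)
        if key not in corr_cache:
            x, y = data.row(u), data.row(v)
            if np.std(x) == 0.0 or np.std(y) == 0.0:
                corr_cache[key] = np.nan
            else:
                corr_cache[key] = abs(float(np.corrcoef(x, y)[0, 1]))
        return corr_cache[key]

    while True:
        try:
            cycle = nx.find_cycle(h, source=sorted(h.nodes))
        except nx.NetworkXNoCycle:
            break
        scored = [((u, v), abs_corr(u, v)) for u, v, *_ in cycle]
        finite = [(e, c) for e, c in scored if not np.isnan(c)]
        if not finite:
            genes = sorted({n for e, _ in scored for n in e})
            raise ValueError(
                "cannot break cycle: all correlations undefined "
                f"(zero-variance genes among {genes})"
            )
        edge = min(finite, key=lambda ec: (ec[1], ec[0]))[0]
        h.remove_edge(*edge)
        logger.info("cycle broken: removed edge %s -> %s", *edge)
    return h


def moralize(dag: nx.DiGraph) -> nx.Graph:
    """Marry the parents of every node, then drop edge directions."""
    if not nx.is_directed_acyclic_graph(dag):
        raise ValueError("moralization requires an acyclic directed graph")
    m = nx.moral_graph(dag)
    m.remove_edges_from(nx.selfloop_edges(m))
    out = nx.Graph()
    out.add_nodes_from(sorted(m.nodes))
    out.add_edges_from(sorted(tuple(sorted(e)) for e in m.edges))
    return out


def triangulate(mg: nx.Graph) -> nx.Graph:
    """Greedy minimum-fill triangulation with lexicographic tie-breaking.

    Returns a chordal supergraph; the added edges are recorded in
    ``graph['fill_edges']``. Min-fill keeps cliques small, which matters
    because the largest clique bounds the sample size needed for estimation.
    """
    work = nx.Graph()
    work.add_nodes_from(sorted(mg.nodes))
    work.add_edges_from(sorted(tuple(sorted(e)) for e in mg.edges))
    out = work.copy()
    fill: list[tuple[str, str]] = []
    remaining = set(work.nodes)

    while remaining:
        best = None
        for v in sorted(remaining):
            nb = sorted(n for n in work[v] if n in remaining)
            deficiency = [
                (a, b)
                for a, b in itertools.combinations(nb, 2)
                if not work.has_edge(a, b)
            ]
            cand = (len(deficiency), v, deficiency)
            if best is None or cand[:2] < best[:2]:
                best = cand
        _, v, deficiency = best
        for a, b in deficiency:
            work.add_edge(a, b)
            out.add_edge(a, b)
            fill.append((a, b))
        remaining.discard(v)
        work.remove_node(v)

    out.graph["fill_edges"] = fill
    return out


def is_chordal(g: nx.Graph) -> bool:
    return nx.is_chordal(g)


def find_cliques(cg: nx.Graph) -> list[tuple[str, ...]]:
    """Maximal cliques as sorted gene tuples, lexicographically ordered."""
    return sorted(tuple(sorted(c)) for c in nx.find_cliques(cg))


def mcs_order(cg: nx.Graph) -> list[str]:
    """Maximum cardinality search ordering.

    Starts from the lexicographically smallest node; among nodes with equal
    numbered-neighbour counts the lexicographically smallest is chosen. For a
    chordal graph the reverse ordering is a perfect elimination ordering.
    """
    order: list[str] = []
    numbered: set[str] = set()
    count = {v: 0 for v in cg.nodes}
    while len(order) < cg.number_of_nodes():
        v = min((n for n in cg.nodes if n not in numbered), key=lambda n: (-count[n], n))
        order.append(v)
        numbered.add(v)
        for w in cg[v]:
            if w not in numbered:
                count[w] += 1
    return order


@dataclass
class JunctionTree:
    """Tree of maximal cliques with separator-labelled edges and a root.

    ``tree`` has the clique indices (into ``cliques``) as nodes; each edge
    carries the separator (clique intersection) in attribute ``separator``.
    """

    cliques: list[tuple[str, ...]]
    tree: nx.Graph
    root: int

    def leaves(self) -> list[int]:
        if len(self.cliques) == 1:
            return [self.root]
        return sorted(
            i for i in self.tree.nodes if i != self.root and self.tree.degree(i) == 1
        )

    def separator(self, i: int, j: int) -> frozenset:
        return self.tree.edges[i, j]["separator"]

    def genes(self) -> frozenset:
        return frozenset(g for c in self.cliques for g in c)

    def path_between(self, i: int, j: int) -> list[int]:
        return nx.shortest_path(self.tree, i, j)

    def check_running_intersection(self) -> bool:
        """Explicit pairwise check of the running intersection property."""
        for i, j in itertools.combinations(range(len(self.cliques)), 2):
            inter = set(self.cliques[i]) & set(self.cliques[j])
            for k in self.path_between(i, j):
                if not inter <= set(self.cliques[k]):
                    return False
        return True


def build_junction_tree(
    cliques: list[tuple[str, ...]], cg: nx.Graph
) -> JunctionTree:
    """Maximum-weight spanning tree on clique intersections, rooted by MCS.

    Kruskal on separator cardinality (lexicographic tie-break) guarantees the
    running intersection property when ``cliques`` are the maximal cliques of
    a chordal graph. Raises if the clique-intersection structure is
    disconnected: disconnected pathway components are junction *forests* and
    must be decomposed per connected component upstream.
    """
    cliques = sorted(tuple(sorted(c)) for c in cliques)
    nc = len(cliques)
    tree = nx.Graph()
    tree.add_nodes_from(range(nc))
    if nc > 1:
        candidates = []
        for i, j in itertools.combinations(range(nc), 2):
            sep = frozenset(cliques[i]) & frozenset(cliques[j])
            if sep:
                candidates.append((-len(sep), cliques[i], cliques[j], i, j, sep))
        parent = list(range(nc))

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for _, _, _, i, j, sep in sorted(candidates):
            ri, rj = find(i), find(j)
            if ri != rj:
                parent[ri] = rj
                tree.add_edge(i, j, separator=sep)
        if tree.number_of_edges() != nc - 1:
            raise ValueError(
                "clique-intersection structure is disconnected; build one "
                "junction tree per connected pathway component"
            )

    # Root: the clique reached first along the MCS ordering of the graph.
    order_pos = {v: k for k, v in enumerate(mcs_order(cg))}
    root = min(
        range(nc), key=lambda i: (min(order_pos[g] for g in cliques[i]), cliques[i])
    )
    return JunctionTree(cliques=cliques, tree=tree, root=root)


def junction_tree_from_graph(mg: nx.Graph) -> tuple[nx.Graph, JunctionTree]:
    """Triangulate an undirected graph and build its junction tree.

    Returns the chordal graph and the tree. The graph must be connected.
    """
    cg = triangulate(mg)
    return cg, build_junction_tree(find_cliques(cg), cg)
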