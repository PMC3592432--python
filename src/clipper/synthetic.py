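"""Synthetic two-class graphical Gaussian data and simulation studies.

The generator instantiates the two-model setup the tests target: both
classes multivariate normal with concentration matrices constrained to a
shared graph. Null scenarios draw the two classes from the same model and
drive the type-I-error study; alternative scenarios perturb means and
partial correlations inside chosen cliques for power and path-recovery
checks.

Defaults: a 12-gene chordal pathway whose junction tree is a chain of 5
cliques (sizes 4, 4, 3, 3, 3) and n1 = n2 = 20 samples per class — small
enough to simulate in bulk, large enough for multi-clique signal paths.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from . import graphs, inference, paths
from .datasets import ExpressionDataset

__all__ = [
    "Scenario",
    "default_pathway_graph",
    "default_junction_tree",
    "random_ggm",
    "sample_scenario",
    "null_study",
    "alt_study",
    "NullStudyResult",
    "AltStudyResult",
    "toy_junction_tree",
    "toy_weights",
]

# Maximal cliques of the default 12-gene pathway; consecutive cliques
# overlap, so the junction tree is a chain rooted (by MCS) at the first.
_DEFAULT_CLIQUES = [
    ("g01", "g02", "g03", "g04"),
    ("g03", "g04", "g05", "g06"),
    ("g06", "g07", "g08"),
    ("g08", "g09", "g10"),
    ("g10", "g11", "g12"),
]


def default_pathway_graph() -> nx.Graph:
    """The 12-node chordal graph used by the simulation studies."""
    g = nx.Graph()
    for c in _DEFAULT_CLIQUES:
        g.add_nodes_from(c)
        g.add_edges_from((a, b) for i, a in enumerate(c) for b in c[i + 1 :])
    return g


def default_junction_tree() -> tuple[nx.Graph, graphs.JunctionTree]:
    g = default_pathway_graph()
    return graphs.junction_tree_from_graph(g)


def random_ggm(
    graph: nx.Graph,
    seed,
    conditioning: float = 0.1,
    strength: tuple[float, float] = (0.1, 0.4),
) -> np.ndarray:
    """Random concentration matrix with exact zeros off the graph.

    Edge entries get random magnitudes in ``strength`` with random signs;
    the diagonal is set to the absolute row sum plus ``conditioning``, so
    the matrix is strictly diagonally dominant and (by Gershgorin) its
    minimum eigenvalue is at least ``conditioning``.
    """
    rng = np.random.default_rng(seed)
    nodes = sorted(graph.nodes)
    index = {v: i for i, v in enumerate(nodes)}
    P = len(nodes)
    K = np.zeros((P, P))
    for u, v in sorted(tuple(sorted(e)) for e in graph.edges):
        val = rng.uniform(*strength) * rng.choice([-1.0, 1.0])
        K[index[u], index[v]] = K[index[v], index[u]] = val
    for i in range(P):
        K[i, i] = np.sum(np.abs(K[i])) - np.abs(K[i, i]) + conditioning
        if K[i, i] == conditioning:  # isolated node
            K[i, i] = 1.0
    return K


@dataclass
class Scenario:
    """Two graphical Gaussian models on a shared graph, plus sample sizes."""

    graph: nx.Graph
    mu1: np.ndarray
    mu2: np.ndarray
    K1: np.ndarray
    K2: np.ndarray
    n1: int
    n2: int
    seed: int

    def __post_init__(self):
        P = len(self.graph.nodes)
        for name, K in (("K1", self.K1), ("K2", self.K2)):
            if K.shape != (P, P):
                raise ValueError(f"{name} has wrong dimensions")
            if not np.allclose(K, K.T):
                raise ValueError(f"{name} must be symmetric")
            if np.min(np.linalg.eigvalsh(K)) <= 0:
                raise ValueError(f"{name} must be positive definite")
        adj = nx.to_numpy_array(self.graph, nodelist=sorted(self.graph.nodes))
        off = (adj == 0) & ~np.eye(P, dtype=bool)
        for name, K in (("K1", self.K1), ("K2", self.K2)):
            if np.any(K[off] != 0):
                raise ValueError(f"{name} has non-zero entries off the graph")


def sample_scenario(sc: Scenario) -> ExpressionDataset:
    """Draw n1 samples from N(mu1, K1^-1) and n2 from N(mu2, K2^-1)."""
    rng = np.random.default_rng(sc.seed)
    nodes = sorted(sc.graph.nodes)
    X1 = rng.multivariate_normal(
        sc.mu1, np.linalg.inv(sc.K1), size=sc.n1, method="cholesky"
    )
    X2 = rng.multivariate_normal(
        sc.mu2, np.linalg.inv(sc.K2), size=sc.n2, method="cholesky"
    )
    values = np.vstack([X1, X2]).T  # genes x samples
    labels = np.concatenate([np.zeros(sc.n1, int), np.ones(sc.n2, int)])
    sample_ids = [f"s{i + 1:03d}" for i in range(sc.n1 + sc.n2)]
    return ExpressionDataset(values, nodes, sample_ids, labels, ("c1", "c2"))


def _spawn_seeds(seed: int, runs: int) -> list[tuple[int, int]]:
    """Per-run (model/data seed, permutation seed) pairs below 2**31."""
    ss = np.random.SeedSequence(seed)
    out = []
    for child in ss.spawn(runs):
        a, b = child.generate_state(2)
        out.append((int(a % (2**31)), int(b % (2**31))))
    return out


@dataclass
class NullStudyResult:
    alpha: float
    B: int
    runs: int
    p_concentration: np.ndarray
    p_mean_homo: np.ndarray
    p_mean_hetero: np.ndarray
    p_mean_selected: np.ndarray
    p_cliques: np.ndarray  # runs x n_cliques
    top_lengths: np.ndarray

    def rejection_pct(self) -> dict[str, float]:
        a = self.alpha
        return {
            "concentration": 100.0 * float(np.mean(self.p_concentration < a)),
            "mean_homo": 100.0 * float(np.mean(self.p_mean_homo < a)),
            "mean_hetero": 100.0 * float(np.mean(self.p_mean_hetero < a)),
            "mean": 100.0 * float(np.mean(self.p_mean_selected < a)),
            "cliques": 100.0 * float(np.mean(self.p_cliques < a)),
        }

    def pct_top_longer_than_one(self) -> float:
        return 100.0 * float(np.mean(self.top_lengths > 1))


def null_study(
    runs: int = 1000,
    alpha: float = 0.05,
    B: int = 500,
    seed: int = 0,
    n1: int = 20,
    n2: int = 20,
    graph: nx.Graph | None = None,
    tol: float = 1e-8,
    max_iter: int = 5000,
) -> NullStudyResult:
    """Type-I-error study: both classes from the same model, fresh per run.

    Each run draws a new random concentration matrix on ``graph``, samples
    both classes from it, runs all step-1 tests (whole pathway and cliques)
    and the full step-2 mining, and records p-values and the length of the
    top relevant sub-path (0 when no sub-path exists).
    """
    if graph is None:
        graph = default_pathway_graph()
    cg, jt = graphs.junction_tree_from_graph(graph)
    nc = len(jt.cliques)
    P = len(graph.nodes)
    res = NullStudyResult(
        alpha=alpha,
        B=B,
        runs=runs,
        p_concentration=np.empty(runs),
        p_mean_homo=np.empty(runs),
        p_mean_hetero=np.empty(runs),
        p_mean_selected=np.empty(runs),
        p_cliques=np.empty((runs, nc)),
        top_lengths=np.zeros(runs, dtype=int),
    )
    for r, (model_seed, perm_seed) in enumerate(_spawn_seeds(seed, runs)):
        K = random_ggm(graph, model_seed)
        sc = Scenario(graph, np.zeros(P), np.zeros(P), K, K, n1, n2, model_seed + 1)
        data = sample_scenario(sc)
        ts = inference.pathway_tests(
            data, cg, B=B, seed=perm_seed, cliques=jt.cliques, tol=tol, max_iter=max_iter
        )
        res.p_concentration[r] = ts.concentration.p_value
        res.p_mean_homo[r] = ts.mean_homo.p_value
        res.p_mean_hetero[r] = ts.mean_hetero.p_value
        res.p_mean_selected[r] = ts.mean(alpha).p_value
        res.p_cliques[r] = [t.p_value for t in ts.clique_concentration]
        weights = [w.w for w in ts.clique_weights(alpha)]
        top = paths.mine(jt, weights, alpha=alpha).top()
        res.top_lengths[r] = 0 if top is None else top.length
    return res


@dataclass
class AltStudyResult:
    runs: int
    target_cliques: tuple[int, ...]
    recovered: np.ndarray  # bool per run: top sub-path overlaps the targets
    jaccard: np.ndarray

    def recovery_rate(self) -> float:
        return float(np.mean(self.recovered))


def perturbed_scenario(
    graph: nx.Graph,
    jt: graphs.JunctionTree,
    target_cliques: tuple[int, ...],
    model_seed: int,
    n1: int = 50,
    n2: int = 50,
    mean_shift_sd: float = 5.0,
    flip_partial_correlations: bool = True,
) -> Scenario:
    """Localized alternative: inside the target cliques, class 2 gets its
    edge partial correlations sign-flipped and its means shifted by
    ``mean_shift_sd`` marginal standard deviations."""
    nodes = sorted(graph.nodes)
    index = {v: i for i, v in enumerate(nodes)}
    K1 = random_ggm(graph, model_seed)
    K2 = K1.copy()
    target_genes: set[str] = set()
    for c in target_cliques:
        target_genes |= set(jt.cliques[c])
    if flip_partial_correlations:
        for u, v in graph.edges:
            if u in target_genes and v in target_genes:
                K2[index[u], index[v]] *= -1.0
                K2[index[v], index[u]] *= -1.0
    sd = np.sqrt(np.diag(np.linalg.inv(K1)))
    mu2 = np.zeros(len(nodes))
    for g in target_genes:
        mu2[index[g]] = mean_shift_sd * sd[index[g]]
    return Scenario(graph, np.zeros(len(nodes)), mu2, K1, K2, n1, n2, model_seed + 1)


def alt_study(
    runs: int = 100,
    target_cliques: tuple[int, ...] = (1, 2),
    alpha: float = 0.05,
    B: int = 500,
    seed: int = 0,
    n1: int = 50,
    n2: int = 50,
    mean_shift_sd: float = 5.0,
    flip_partial_correlations: bool = True,
    graph: nx.Graph | None = None,
) -> AltStudyResult:
    """Recovery study: does the selected sub-path hit the perturbed cliques?

    Per run the top representative sub-path is compared with the target
    clique set; overlap (any shared clique) and the Jaccard index of the
    clique sets are recorded.
    """
    if graph is None:
        graph = default_pathway_graph()
    cg, jt = graphs.junction_tree_from_graph(graph)
    res = AltStudyResult(
        runs=runs,
        target_cliques=tuple(target_cliques),
        recovered=np.zeros(runs, dtype=bool),
        jaccard=np.zeros(runs),
    )
    for r, (model_seed, perm_seed) in enumerate(_spawn_seeds(seed, runs)):
        sc = perturbed_scenario(
            graph,
            jt,
            tuple(target_cliques),
            model_seed,
            n1=n1,
            n2=n2,
            mean_shift_sd=mean_shift_sd,
            flip_partial_correlations=flip_partial_correlations,
        )
        data = sample_scenario(sc)
        ts = inference.pathway_tests(data, cg, B=B, seed=perm_seed, cliques=jt.cliques)
        weights = [w.w for w in ts.clique_weights(alpha)]
        top = paths.mine(jt, weights, alpha=alpha).top()
        if top is not None:
            hit = set(top.clique_ids) & set(target_cliques)
            union = set(top.clique_ids) | set(target_cliques)
            res.recovered[r] = bool(hit)
            res.jaccard[r] = len(hit) / len(union)
    return res


# ---------------------------------------------------------------------------
# Hand-built 12-clique demonstration tree: root c1, leaves c8, c10, c12.
# ---------------------------------------------------------------------------


def toy_junction_tree() -> graphs.JunctionTree:
    """A 12-clique junction tree with root c1 and leaves c8, c10 and c12.

    The backbone is a chain c1-...-c8 with side branches c3-c9-c10 and
    c5-c11-c12, so exactly three root-to-leaf paths exist. Built directly
    (not from a graph) to exercise the miner on a known topology.
    """
    chain = [(f"t{i:02d}", f"t{i + 1:02d}") for i in range(1, 9)]  # c1..c8
    cliques = list(chain)
    cliques.append(("t03", "u01"))  # c9, hangs off c3 = (t03, t04)
    cliques.append(("u01", "u02"))  # c10
    cliques.append(("t05", "v01"))  # c11, hangs off c5 = (t05, t06)
    cliques.append(("v01", "v02"))  # c12
    tree = nx.Graph()
    tree.add_nodes_from(range(12))
    for i in range(7):
        tree.add_edge(i, i + 1, separator=frozenset(cliques[i]) & frozenset(cliques[i + 1]))
    tree.add_edge(2, 8, separator=frozenset({"t03"}))
    tree.add_edge(8, 9, separator=frozenset({"u01"}))
    tree.add_edge(4, 10, separator=frozenset({"t05"}))
    tree.add_edge(10, 11, separator=frozenset({"v01"}))
    return graphs.JunctionTree(cliques=[tuple(sorted(c)) for c in cliques], tree=tree, root=0)


def toy_weights() -> list[float]:
    """Clique weights giving the demonstration meaningful pattern.

    Along the backbone path c1..c8 the pattern is M M n M n n M M
    (M = meaningful at alpha = 0.05), which decomposes into four candidate
    sub-paths: {c1,c2}, {c4}, {c7,c8} and the bridged {c1,c2,c3,c4}. The
    side branches each end in one meaningful leaf clique.
    """
    w = [0.01, 0.02, 0.30, 0.01, 0.50, 0.60, 0.02, 0.01, 0.40, 0.03, 0.70, 0.04]
    return w
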