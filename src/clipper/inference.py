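"""Step 1: permutation tests on whole pathways and on single cliques.

Two families of hypotheses are tested between the two phenotype classes,
both under graphical Gaussian models sharing one undirected graph G:

* equality of concentration matrices ("homoschedasticity", K1 = K2) — a
  -2 log likelihood-ratio statistic comparing class-specific IPS fits with a
  pooled fit;
* equality of mean vectors — either a likelihood-ratio statistic with a
  common graph-constrained concentration (homoschedastic variant) or a
  Behrens-Fisher-type quadratic form of the mean difference in the metric
  (Sigma1/n1 + Sigma2/n2)^-1 (heteroschedastic variant).

Shrinkage precludes the asymptotic chi-square calibration, so every p-value
is a permutation p-value with the add-one rule, p = (1 + #{perm >= obs}) /
(B + 1); the shrinkage intensity is re-estimated within every permutation
and the same seeded permutation stream calibrates all statistics.

Per-clique tests reuse the concentration statistic on the clique's sub-data
with a complete graph (no IPS needed); a single-gene clique degenerates to a
two-sample variance LRT through the same formula.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
from statsmodels.stats.multitest import multipletests

from . import graphs
from ._kernels import (
    CONC,
    MEAN_HETERO,
    MEAN_HOMO,
    N_GLOBAL,
    _permutation_pvalues,
    cliques_to_arrays,
)
from .datasets import ExpressionDataset

__all__ = [
    "TestResult",
    "CliqueWeight",
    "PathwaySummary",
    "PathwayTestSet",
    "pathway_tests",
    "concentration_test",
    "mean_test",
    "clique_tests",
    "bonferroni",
]


@dataclass
class TestResult:
    statistic: float
    p_value: float
    n_perm: int
    kind: str  # concentration | mean_homo | mean_hetero


@dataclass
class CliqueWeight:
    clique_id: int
    genes: tuple[str, ...]
    w: float
    meaningful: bool


@dataclass
class PathwaySummary:
    pathway_id: str
    mean_p: float
    concentration_p: float
    mean_p_adj: float
    concentration_p_adj: float
    mean_variant: str
    clique_weights: list[CliqueWeight]


@dataclass
class PathwayTestSet:
    """Everything step 1 computes for one pathway component in one pass."""

    concentration: TestResult
    mean_homo: TestResult
    mean_hetero: TestResult
    clique_concentration: list[TestResult]
    clique_mean: list[TestResult]
    cliques: list[tuple[str, ...]]
    n_nonconverged: int

    def mean(self, alpha: float = 0.05) -> TestResult:
        """Variant-selected mean test: heteroschedastic when the pathway's
        concentration test rejects at ``alpha``, homoschedastic otherwise."""
        if self.concentration.p_value < alpha:
            return self.mean_hetero
        return self.mean_homo

    def clique_weights(
        self, alpha: float = 0.05, source: str = "concentration"
    ) -> list[CliqueWeight]:
        tests = (
            self.clique_concentration if source == "concentration" else self.clique_mean
        )
        return [
            CliqueWeight(
                clique_id=i,
                genes=self.cliques[i],
                w=t.p_value,
                meaningful=t.p_value < alpha,
            )
            for i, t in enumerate(tests)
        ]


def _prepare(data: ExpressionDataset, g: nx.Graph, cliques=None):
    if cliques is None:
        cg = g if nx.is_chordal(g) else graphs.triangulate(g)
        cliques = graphs.find_cliques(cg)
    genes = sorted(g.nodes)
    missing = [v for v in genes if not data.has_gene(v)]
    if missing:
        raise ValueError(f"graph genes missing from dataset: {', '.join(missing)}")
    sub = data.subset(genes)
    var = sub.values.var(axis=1)
    if np.any(var == 0.0):
        bad = [genes[i] for i in np.where(var == 0.0)[0]]
        raise ValueError(f"zero-variance gene(s): {', '.join(bad)}")
    node_index = {v: i for i, v in enumerate(genes)}
    cl_idx, cl_len = cliques_to_arrays(cliques, node_index)
    return sub, cliques, cl_idx, cl_len


def pathway_tests(
    data: ExpressionDataset,
    g: nx.Graph,
    B: int = 1000,
    seed: int = 0,
    cliques: list[tuple[str, ...]] | None = None,
    tol: float = 1e-8,
    max_iter: int = 5000,
    max_nonconvergence: float = 0.01,
) -> PathwayTestSet:
    """Run every step-1 test for one pathway with a shared permutation stream.

    Parameters
    ----------
    data : two-class expression data covering all graph nodes
    g : undirected conditional-independence graph (moralized pathway);
        triangulated internally when not chordal
    B : permutation count (p-values have granularity 1/(B+1))
    seed : seed for the permutation stream
    cliques : optionally the junction-tree cliques (recomputed otherwise)
    max_nonconvergence : abort when more than this fraction of IPS fits
        fails to converge
    """
    if data.n1 < 3 or data.n2 < 3:
        raise ValueError("both classes need at least 3 samples")
    sub, cliques, cl_idx, cl_len = _prepare(data, g, cliques)
    obs, counts, nonconv = _permutation_pvalues(
        sub.X, sub.labels, B, int(seed) % (2**31), cl_idx, cl_len, tol, max_iter
    )
    total_fits = 4 * (B + 1)
    if nonconv > max_nonconvergence * total_fits:
        raise RuntimeError(
            f"IPS failed to converge in {nonconv}/{total_fits} fits; "
            "increase max_iter or loosen tol"
        )
    pvals = (1.0 + counts) / (B + 1.0)

    def res(k: int, kind: str) -> TestResult:
        return TestResult(float(obs[k]), float(pvals[k]), B, kind)

    nc = len(cliques)
    return PathwayTestSet(
        concentration=res(CONC, "concentration"),
        mean_homo=res(MEAN_HOMO, "mean_homo"),
        mean_hetero=res(MEAN_HETERO, "mean_hetero"),
        clique_concentration=[
            res(N_GLOBAL + i, "concentration") for i in range(nc)
        ],
        clique_mean=[res(N_GLOBAL + nc + i, "mean_hetero") for i in range(nc)],
        cliques=cliques,
        n_nonconverged=int(nonconv),
    )


def concentration_test(
    data: ExpressionDataset, g: nx.Graph, B: int = 1000, seed: int = 0, **kw
) -> TestResult:
    """Permutation LRT of equal concentration matrices on graph ``g``."""
    return pathway_tests(data, g, B=B, seed=seed, **kw).concentration


def mean_test(
    data: ExpressionDataset,
    g: nx.Graph,
    homoschedastic: bool = True,
    B: int = 1000,
    seed: int = 0,
    **kw,
) -> TestResult:
    """Permutation test of equal mean vectors on graph ``g``."""
    ts = pathway_tests(data, g, B=B, seed=seed, **kw)
    return ts.mean_homo if homoschedastic else ts.mean_hetero


def clique_tests(
    data: ExpressionDataset,
    jt: graphs.JunctionTree,
    B: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
    source: str = "concentration",
    **kw,
) -> list[CliqueWeight]:
    """Per-clique weights: the clique-level test p-values, flagged at alpha."""
    g = nx.Graph()
    for c in jt.cliques:
        g.add_nodes_from(c)
        g.add_edges_from(
            (a, b) for i, a in enumerate(c) for b in c[i + 1 :]
        )
    ts = pathway_tests(data, g, B=B, seed=seed, cliques=jt.cliques, **kw)
    return ts.clique_weights(alpha=alpha, source=source)


def bonferroni(pvals) -> list[float]:
    """Bonferroni adjustment min(1, p * k) across k tests."""
    p = np.asarray(list(pvals), dtype=float)
    if p.size == 0:
        return []
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    adj = multipletests(p, method="bonferroni")[1]
    return [float(x) for x in adj]
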