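"""End-to-end orchestration and the scikit-learn estimator surface.

`run_clipper` drives the full two-step analysis over one or many pathways
and writes the report tables; :class:`ClipperAnalysis` packages the same
analysis for a single pathway as a feature-selecting transformer usable in
sklearn pipelines (the selected features are the genes of the reported
signal sub-paths).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from . import graphs, inference, paths
from .datasets import ExpressionDataset

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "ComponentResult", "ClipperRun", "analyze_pathway", "run_clipper", "ClipperAnalysis"]


@dataclass
class RunConfig:
    """User-settable constants of the two-step analysis."""

    alpha: float = 0.05
    t: float = 0.2
    B: int = 1000
    seed: int = 0
    tol: float = 1e-8
    max_iter: int = 5000
    weight_source: str = "concentration"  # or "mean"
    gating: str = "both"  # both | always | never

    def __post_init__(self):
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if not 0.0 < self.t < 1.0:
            raise ValueError("t must lie in (0, 1)")
        if self.B < 19:
            raise ValueError("need at least 19 permutations")
        if self.weight_source not in ("concentration", "mean"):
            raise ValueError("weight_source must be 'concentration' or 'mean'")
        if self.gating not in ("both", "always", "never"):
            raise ValueError("gating must be 'both', 'always' or 'never'")


@dataclass
class ComponentResult:
    """One connected pathway component, fully analyzed."""

    pathway_id: str
    component: int
    moral: nx.Graph
    chordal: nx.Graph
    junction_tree: graphs.JunctionTree
    tests: inference.PathwayTestSet
    report: paths.ClipperReport | None = None  # None when gated out

    @property
    def component_id(self) -> str:
        return f"{self.pathway_id}#{self.component}"


@dataclass
class ClipperRun:
    config: RunConfig
    components: list[ComponentResult]
    summaries: list[inference.PathwaySummary] = field(default_factory=list)


def prepare_topology(
    g: nx.DiGraph, data: ExpressionDataset
) -> list[tuple[nx.Graph, nx.Graph, graphs.JunctionTree]]:
    """Directed pathway graph -> per-component (moral, chordal, tree).

    Self-loops are removed, cycles broken against the expression data, the
    DAG moralized, and each connected component (>= 2 genes) triangulated
    and decomposed; single-gene components are logged and skipped.
    """
    dag = graphs.break_cycles(graphs.remove_self_loops(g), data)
    moral = graphs.moralize(dag)
    out = []
    for comp in sorted(nx.connected_components(moral), key=lambda c: sorted(c)):
        if len(comp) < 2:
            logger.info("skipping single-gene component: %s", sorted(comp))
            continue
        sub = moral.subgraph(comp).copy()
        cg, jt = graphs.junction_tree_from_graph(sub)
        out.append((sub, cg, jt))
    return out


def analyze_pathway(
    pathway_id: str,
    g: nx.DiGraph,
    data: ExpressionDataset,
    config: RunConfig,
    seed: int | None = None,
) -> list[ComponentResult]:
    """Step 1 on every connected component of one pathway (no gating yet)."""
    seed = config.seed if seed is None else seed
    results = []
    for k, (moral, cg, jt) in enumerate(prepare_topology(g, data)):
        sub = data.subset(sorted(moral.nodes))
        tests = inference.pathway_tests(
            sub,
            cg,
            B=config.B,
            seed=seed + k,
            cliques=jt.cliques,
            tol=config.tol,
            max_iter=config.max_iter,
        )
        results.append(
            ComponentResult(pathway_id, k, moral, cg, jt, tests)
        )
    return results


def _mine_component(comp: ComponentResult, config: RunConfig) -> paths.ClipperReport:
    weights = [
        w.w
        for w in comp.tests.clique_weights(config.alpha, source=config.weight_source)
    ]
    return paths.mine(comp.junction_tree, weights, alpha=config.alpha, t=config.t)


def run_clipper(
    config: RunConfig,
    data: ExpressionDataset,
    pathways: dict[str, nx.DiGraph],
    out_dir=None,
) -> ClipperRun:
    """Full two-step analysis over many pathways.

    Step 1 runs on every pathway component; mean and concentration p-values
    are Bonferroni-adjusted across components within each test family. Step
    2 runs on components passing the gating rule (default: both adjusted
    p-values < 0.05). Per-pathway failures are isolated and logged. When
    ``out_dir`` is given, writes ``pathway_table.tsv``,
    ``subpath_table.tsv`` and ``run_log.txt``.
    """
    components: list[ComponentResult] = []
    failures: list[tuple[str, str]] = []
    seeds = np.random.SeedSequence(config.seed).spawn(len(pathways))
    for (pid, g), ss in zip(sorted(pathways.items()), seeds):
        try:
            g_m = io_restrict(g, data)
            components.extend(
                analyze_pathway(
                    pid, g_m, data, config, seed=int(ss.generate_state(1)[0] % 2**31)
                )
            )
        except Exception as exc:  # noqa: BLE001 - isolate per-pathway failures
            logger.error("pathway %s failed: %s", pid, exc)
            failures.append((pid, str(exc)))
    run = ClipperRun(config=config, components=components)

    mean_raw = [c.tests.mean(config.alpha).p_value for c in components]
    conc_raw = [c.tests.concentration.p_value for c in components]
    mean_adj = inference.bonferroni(mean_raw)
    conc_adj = inference.bonferroni(conc_raw)
    for c, mp, cp, mpa, cpa in zip(components, mean_raw, conc_raw, mean_adj, conc_adj):
        run.summaries.append(
            inference.PathwaySummary(
                pathway_id=c.component_id,
                mean_p=mp,
                concentration_p=cp,
                mean_p_adj=mpa,
                concentration_p_adj=cpa,
                mean_variant=c.tests.mean(config.alpha).kind,
                clique_weights=c.tests.clique_weights(
                    config.alpha, source=config.weight_source
                ),
            )
        )
        gate = (
            config.gating == "always"
            or (config.gating == "both" and mpa < 0.05 and cpa < 0.05)
        )
        if gate:
            c.report = _mine_component(c, config)

    if out_dir is not None:
        _write_reports(Path(out_dir), run, failures)
    return run


def _config_header(config: RunConfig) -> str:
    import clipper

    lines = [f"# clipper {clipper.__version__}"]
    for k, v in asdict(config).items():
        lines.append(f"# {k} = {v}")
    return "\n".join(lines) + "\n"


def _write_reports(out_dir: Path, run: ClipperRun, failures) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    header = _config_header(run.config)

    pw = pd.DataFrame(
        [
            {
                "pathway": s.pathway_id,
                "mean_p": s.mean_p,
                "mean_p_adj": s.mean_p_adj,
                "concentration_p": s.concentration_p,
                "concentration_p_adj": s.concentration_p_adj,
                "mean_variant": s.mean_variant,
            }
            for s in run.summaries
        ]
    )
    with open(out_dir / "pathway_table.tsv", "w") as fh:
        fh.write(header)
        pw.to_csv(fh, sep="\t", index=False)

    rows = []
    for c in run.components:
        if c.report is None:
            continue
        for i, sp in enumerate(c.report.best_per_path):
            rep = sp in c.report.representatives
            rows.append(
                {
                    "pathway": c.component_id,
                    "cliques": ";".join(
                        ",".join(genes) for genes in sp.genes_by_clique
                    ),
                    "l": sp.length,
                    "r": sp.r,
                    "m": sp.m,
                    "r_star": sp.r_star,
                    "cluster": c.report.cluster_of.get(i, 0),
                    "representative": rep,
                }
            )
    sp_df = pd.DataFrame(
        rows,
        columns=[
            "pathway", "cliques", "l", "r", "m", "r_star", "cluster", "representative",
        ],
    )
    with open(out_dir / "subpath_table.tsv", "w") as fh:
        fh.write(header)
        sp_df.to_csv(fh, sep="\t", index=False)

    with open(out_dir / "run_log.txt", "w") as fh:
        fh.write(header)
        fh.write(f"# components analyzed: {len(run.components)}\n")
        for pid, msg in failures:
            fh.write(f"# FAILED {pid}: {msg}\n")


class ClipperAnalysis(BaseEstimator, TransformerMixin):
    """Two-step pathway analysis as a feature-selecting transformer.

    Fits the whole pipeline on one pathway: topology decomposition, the
    step-1 permutation tests and (subject to the gating rule) the step-2
    signal-path mining. ``transform`` keeps only the genes of the reported
    representative sub-paths, so the estimator slots into sklearn pipelines
    as a topology-aware feature selector.

    Parameters
    ----------
    graph : networkx.DiGraph
        Directed gene-gene pathway graph; node names must match feature
        names (DataFrame columns or ``feature_names``).
    alpha : clique/test significance cut-off (default 0.05).
    t : sub-path collapse threshold (default 0.2).
    n_permutations : label permutations B (default 1000).
    random_state : permutation/cycle seed.
    weight_source : 'concentration' (default) or 'mean' clique weights.
    gating : 'both' (default) run step 2 only when both whole-pathway tests
        reject; 'always' / 'never' override.

    Attributes
    ----------
    components_ : list of ComponentResult
    summaries_ : per-component PathwaySummary list
    selected_genes_ : sorted genes of the representative sub-paths
    """

    def __init__(
        self,
        graph=None,
        alpha: float = 0.05,
        t: float = 0.2,
        n_permutations: int = 1000,
        random_state: int = 0,
        tol: float = 1e-8,
        max_iter: int = 5000,
        weight_source: str = "concentration",
        gating: str = "both",
        feature_names=None,
    ):
        self.graph = graph
        self.alpha = alpha
        self.t = t
        self.n_permutations = n_permutations
        self.random_state = random_state
        self.tol = tol
        self.max_iter = max_iter
        self.weight_source = weight_source
        self.gating = gating
        self.feature_names = feature_names

    def _dataset(self, X, y) -> ExpressionDataset:
        if hasattr(X, "columns"):
            names = [str(c) for c in X.columns]
        elif self.feature_names is not None:
            names = [str(g) for g in self.feature_names]
        else:
            raise ValueError(
                "gene names required: pass a DataFrame or feature_names"
            )
        Xa = np.asarray(X, dtype=np.float64)
        y = np.asarray(y)
        classes = sorted(map(str, np.unique(y)))
        if len(classes) != 2:
            raise ValueError("two classes required")
        labels = np.array([classes.index(str(v)) for v in y])
        return ExpressionDataset(
            Xa.T,
            names,
            [f"s{i}" for i in range(Xa.shape[0])],
            labels,
            (classes[0], classes[1]),
        )

    def fit(self, X, y):
        if self.graph is None:
            raise ValueError("a pathway graph is required")
        config = RunConfig(
            alpha=self.alpha,
            t=self.t,
            B=self.n_permutations,
            seed=self.random_state,
            tol=self.tol,
            max_iter=self.max_iter,
            weight_source=self.weight_source,
            gating=self.gating,
        )
        data = self._dataset(X, y)
        g = io_restrict(self.graph, data)
        run = run_clipper(config, data, {"pathway": g})
        self.components_ = run.components
        self.summaries_ = run.summaries
        genes: set[str] = set()
        for c in run.components:
            if c.report is not None:
                for sp in c.report.representatives:
                    genes |= sp.genes
        self.selected_genes_ = sorted(genes)
        self.feature_names_in_ = data.gene_ids
        self.n_features_in_ = len(data.gene_ids)
        return self

    def get_support(self):
        check_is_fitted(self, "selected_genes_")
        sel = set(self.selected_genes_)
        return np.array([g in sel for g in self.feature_names_in_])

    def transform(self, X):
        check_is_fitted(self, "selected_genes_")
        if hasattr(X, "columns"):
            return X.loc[:, [c for c in X.columns if str(c) in set(self.selected_genes_)]]
        mask = self.get_support()
        return np.asarray(X)[:, mask]


def io_restrict(g, data):
    from .io import restrict_to_measured

    return restrict_to_measured(g, data)
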