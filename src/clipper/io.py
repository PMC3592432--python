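"""Readers for expression matrices, class labels and pathway graphs."""

from __future__ import annotations

import logging
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .datasets import ExpressionDataset

logger = logging.getLogger(__name__)

__all__ = ["read_expression", "read_graph", "restrict_to_measured"]


def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_expression(expression_path, labels_path) -> ExpressionDataset:
    """Load a genes x samples matrix plus a two-column sample label file.

    The expression file is TSV (or CSV by extension) with gene identifiers
    in the first column and sample identifiers in the header. The label file
    has two columns (sample id, class), no header, and must cover exactly
    the samples of the matrix with exactly two classes.
    """
    expression_path = Path(expression_path)
    labels_path = Path(labels_path)
    df = pd.read_csv(expression_path, sep=_sep_for(expression_path), index_col=0)
    if df.index.has_duplicates:
        dup = sorted(df.index[df.index.duplicated()].unique())
        raise ValueError(f"duplicated gene row(s): {', '.join(map(str, dup))}")
    if df.isna().any().any():
        raise ValueError("expression matrix contains missing values")

    lab = pd.read_csv(
        labels_path, sep=_sep_for(labels_path), header=None, names=["sample", "cls"]
    )
    lab["sample"] = lab["sample"].astype(str)
    lab = lab.set_index("sample")["cls"]
    samples = [str(s) for s in df.columns]
    missing = [s for s in samples if s not in lab.index]
    extra = [s for s in lab.index if s not in samples]
    if missing or extra:
        raise ValueError(
            "label/sample mismatch: "
            f"unlabelled samples {missing or 'none'}, "
            f"labels without samples {extra or 'none'}"
        )
    classes = sorted(map(str, lab.unique()))
    if len(classes) != 2:
        raise ValueError(f"two classes required, found {len(classes)}: {classes}")
    labels = np.array([classes.index(str(lab[s])) for s in samples])
    return ExpressionDataset(
        df.to_numpy(dtype=float),
        [str(g) for g in df.index],
        samples,
        labels,
        (classes[0], classes[1]),
    )


def _read_sif(path: Path) -> nx.DiGraph:
    g = nx.DiGraph()
    dropped = 0
    for line in path.read_text().splitlines():
        tokens = line.replace("\t", " ").split()
        if not tokens:
            continue
        if len(tokens) == 1:
            g.add_node(tokens[0])
            continue
        src, interaction, *targets = tokens
        for tgt in targets:
            if g.has_edge(src, tgt):
                dropped += 1
            g.add_edge(src, tgt, interaction=interaction)
    if dropped:
        logger.info("deduplicated %d repeated SIF edge(s)", dropped)
    return g


def _read_edgelist(path: Path) -> nx.DiGraph:
    g = nx.DiGraph()
    dropped = 0
    for line in path.read_text().splitlines():
        tokens = line.replace("\t", " ").split()
        if not tokens:
            continue
        if len(tokens) != 2:
            raise ValueError(f"edge list lines need exactly two columns: {line!r}")
        if g.has_edge(*tokens):
            dropped += 1
        g.add_edge(*tokens)
    if dropped:
        logger.info("deduplicated %d repeated edge(s)", dropped)
    return g


def read_graph(path, format: str = "edgelist") -> nx.DiGraph:
    """Read a directed pathway graph (``graphml``, ``sif`` or ``edgelist``).

    SIF interaction types are kept as edge attribute ``interaction`` but
    ignored by the analysis.
    """
    path = Path(path)
    if format == "graphml":
        raw = nx.read_graphml(path)
        g = nx.DiGraph()
        g.add_nodes_from(str(n) for n in raw.nodes)
        g.add_edges_from((str(u), str(v)) for u, v in raw.edges())
    elif format == "sif":
        g = _read_sif(path)
    elif format == "edgelist":
        g = _read_edgelist(path)
    else:
        raise ValueError(f"unknown graph format: {format!r}")
    if g.number_of_nodes() == 0:
        raise ValueError(f"empty graph: {path}")
    return g


def restrict_to_measured(g: nx.DiGraph, data: ExpressionDataset) -> nx.DiGraph:
    """Drop pathway genes without expression rows (with their edges)."""
    measured = [v for v in g.nodes if data.has_gene(v)]
    dropped = sorted(set(g.nodes) - set(measured))
    if dropped:
        logger.warning(
            "dropping %d unmeasured gene(s): %s", len(dropped), ", ".join(dropped)
        )
    if not measured:
        raise ValueError("no pathway gene has expression data")
    return g.subgraph(measured).copy()
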