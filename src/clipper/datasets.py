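"""Two-class expression data container.

Expression values are stored genes x samples (the layout expression matrices
ship in); the numerical kernels consume the transposed samples x genes view.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class ExpressionDataset:
    """Genes x samples real-valued matrix with a binary phenotype.

    Parameters
    ----------
    values : ndarray, shape (P, n)
        Expression values, one row per gene. Assumed already normalized.
    gene_ids : list of str
        Row labels; must be unique.
    sample_ids : list of str
        Column labels.
    labels : ndarray of int, shape (n,)
        Class membership coded 0/1.
    class_names : tuple of str
        Original names of the two classes, index-aligned with the 0/1 codes.
    """

    values: np.ndarray
    gene_ids: list[str]
    sample_ids: list[str]
    labels: np.ndarray
    class_names: tuple[str, str] = ("0", "1")
    _index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.values.ndim != 2:
            raise ValueError("expression matrix must be 2-D (genes x samples)")
        P, n = self.values.shape
        if len(self.gene_ids) != P:
            raise ValueError("gene_ids length does not match matrix rows")
        if len(self.sample_ids) != n:
            raise ValueError("sample_ids length does not match matrix columns")
        if len(set(self.gene_ids)) != P:
            dup = sorted({g for g in self.gene_ids if self.gene_ids.count(g) > 1})
            raise ValueError(f"duplicated gene identifier(s): {', '.join(dup)}")
        if np.isnan(self.values).any():
            raise ValueError("expression matrix contains missing values")
        if self.labels.shape != (n,):
            raise ValueError("labels length does not match sample count")
        uniq = np.unique(self.labels)
        if not np.array_equal(uniq, np.array([0, 1])):
            raise ValueError("two classes required (labels must contain both 0 and 1)")
        if self.n1 < 3 or self.n2 < 3:
            raise ValueError("each class needs at least 3 samples")
        self._index = {g: i for i, g in enumerate(self.gene_ids)}

    # -- basic dimensions ---------------------------------------------------
    @property
    def P(self) -> int:
        return self.values.shape[0]

    @property
    def n(self) -> int:
        return self.values.shape[1]

    @property
    def n1(self) -> int:
        return int(np.sum(self.labels == 0))

    @property
    def n2(self) -> int:
        return int(np.sum(self.labels == 1))

    # -- views --------------------------------------------------------------
    @property
    def X(self) -> np.ndarray:
        """Samples x genes view (C-contiguous copy) used by the kernels."""
        return np.ascontiguousarray(self.values.T)

    def row(self, gene: str) -> np.ndarray:
        return self.values[self._index[gene]]

    def has_gene(self, gene: str) -> bool:
        return gene in self._index

    def class_matrix(self, k: int) -> np.ndarray:
        """Samples x genes matrix of class ``k`` (0 or 1)."""
        return np.ascontiguousarray(self.values[:, self.labels == k].T)

    def subset(self, genes: list[str]) -> "ExpressionDataset":
        """Restrict to ``genes`` (kept in the given order)."""
        missing = [g for g in genes if g not in self._index]
        if missing:
            raise KeyError(f"genes not in dataset: {', '.join(missing)}")
        idx = [self._index[g] for g in genes]
        return ExpressionDataset(
            self.values[idx, :],
            list(genes),
            list(self.sample_ids),
            self.labels.copy(),
            self.class_names,
        )
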