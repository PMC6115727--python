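"""Core in-memory containers shared across the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

TUMOR = "tumor"
NORMAL = "normal"


@dataclass
class ExpressionMatrix:
    """A genes x samples continuous expression matrix with group labels.

    Values are taken as given (already normalised / log-transformed upstream
    if desired); no internal rescaling is applied anywhere downstream.

    Attributes
    ----------
    values : ndarray, shape (P, N)
        Expression values, genes in rows, samples in columns.
    gene_ids : list of str
        P unique gene identifiers.
    sample_ids : list of str
        N unique sample identifiers.
    group : ndarray of str, shape (N,)
        Per-sample label, ``"tumor"`` or ``"normal"``.
    """

    values: np.ndarray
    gene_ids: list[str]
    sample_ids: list[str]
    group: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D genes x samples matrix")
        P, N = self.values.shape
        if P < 2 or N < 3:
            raise ValueError(f"matrix too small: P={P} (need >=2), N={N} (need >=3)")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression matrix contains non-finite values")
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        if len(self.gene_ids) != P:
            raise ValueError("gene_ids length does not match number of rows")
        if len(self.sample_ids) != N:
            raise ValueError("sample_ids length does not match number of columns")
        if len(set(self.gene_ids)) != P:
            raise ValueError("gene_ids must be unique")
        if len(set(self.sample_ids)) != N:
            raise ValueError("sample_ids must be unique")
        if self.group is None:
            self.group = np.array([TUMOR] * N)
        self.group = np.asarray(self.group, dtype=object)
        if self.group.shape != (N,):
            raise ValueError("group must have one label per sample")
        bad = set(self.group) - {TUMOR, NORMAL}
        if bad:
            raise ValueError(f"unknown group labels: {sorted(bad)}")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def is_tumor(self) -> np.ndarray:
        return np.asarray([g == TUMOR for g in self.group], dtype=bool)

    @property
    def is_normal(self) -> np.ndarray:
        return ~self.is_tumor

    def subset_genes(self, gene_ids: list[str]) -> "ExpressionMatrix":
        """Return a new matrix restricted to ``gene_ids`` (in the given order)."""
        index = {g: i for i, g in enumerate(self.gene_ids)}
        rows = [index[g] for g in gene_ids]
        return ExpressionMatrix(
            values=self.values[rows, :],
            gene_ids=list(gene_ids),
            sample_ids=list(self.sample_ids),
            group=self.group.copy(),
        )
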