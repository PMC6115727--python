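"""Tumor-vs-normal differential expression filter.

Genes are screened with a per-gene two-sample t-test (Welch by default,
since tumor and normal group sizes are typically very unbalanced),
Benjamini-Hochberg correction, and a fold-change cutoff, before feature
selection sees them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datatypes import ExpressionMatrix


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("p must be a non-empty 1-D array")
    if np.any(~np.isfinite(p)) or p.min() < 0.0 or p.max() > 1.0:
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class DEGResult:
    """Genes passing the DE screen, with the full per-gene table attached.

    ``gene_ids``, ``p_values``, ``q_values`` and ``fold_changes`` are
    aligned lists over the *passing* genes (input order); ``table`` holds
    the same statistics for every tested gene plus a ``pass`` column.
    """

    gene_ids: list[str]
    p_values: np.ndarray
    q_values: np.ndarray
    fold_changes: np.ndarray
    table: pd.DataFrame


def deg_filter(Y: ExpressionMatrix, alpha: float = 0.05, fc_cut: float = 1.5,
               scale: str = "log2", equal_var: bool = False) -> DEGResult:
    """Keep genes with BH-adjusted p < ``alpha`` and fold change beyond
    ``fc_cut`` in either direction.

    ``scale`` declares how expression values are stored, which determines
    how fold change is computed: ``"log2"`` uses ``|mean_t - mean_n| >=
    log2(fc_cut)`` and reports ``2**(mean_t - mean_n)``; ``"linear"`` uses
    the ratio of group means.  The threshold on p is applied to the
    *adjusted* values (the correction would be pointless otherwise).
    Genes with zero variance in both groups get p = 1.
    """
    if scale not in {"log2", "linear"}:
        raise ValueError("scale must be 'log2' or 'linear'")
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must lie in [0, 1]")
    if fc_cut < 1.0:
        raise ValueError("fc_cut must be >= 1")
    t_mask, n_mask = Y.is_tumor, Y.is_normal
    if t_mask.sum() < 2 or n_mask.sum() < 2:
        raise ValueError("both tumor and normal groups need at least 2 samples")
    Xt, Xn = Y.values[:, t_mask], Y.values[:, n_mask]

    with np.errstate(invalid="ignore", divide="ignore"):
        p = stats.ttest_ind(Xt, Xn, axis=1, equal_var=equal_var).pvalue
    p = np.where(np.isfinite(p), p, 1.0)  # zero variance in both groups -> 1
    q = bh_adjust(p)

    mt, mn = Xt.mean(axis=1), Xn.mean(axis=1)
    if scale == "log2":
        fc = np.power(2.0, mt - mn)
        fc_pass = np.abs(mt - mn) >= np.log2(fc_cut)
    else:
        with np.errstate(divide="ignore", invalid="ignore"):
            fc = mt / mn
        up = (mn > 0) & (fc >= fc_cut)
        down = (mt > 0) & (mn > 0) & (fc <= 1.0 / fc_cut)
        flipped = (mn <= 0) & (mt > 0) | (mt <= 0) & (mn > 0)  # sign change: unbounded FC
        fc_pass = up | down | flipped

    keep = (q < alpha) & fc_pass
    table = pd.DataFrame({
        "gene_id": Y.gene_ids,
        "p": p,
        "q": q,
        "fc": fc,
        "pass": keep,
    })
    idx = np.nonzero(keep)[0]
    return DEGResult(
        gene_ids=[Y.gene_ids[i] for i in idx],
        p_values=p[idx],
        q_values=q[idx],
        fold_changes=fc[idx],
        table=table,
    )
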