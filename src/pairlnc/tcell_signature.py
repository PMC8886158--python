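"""Immune-panel preprocessing and T-cell-specific lncRNA selection.

Quantile normalization across samples, a per-gene location (optionally
scale) batch alignment, moderated two-group differential expression, and
threshold selection of cell-type-specific lncRNAs at |logFC| > 1 and
BH-FDR < 0.05 (strict inequalities).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import bh_adjust, squeeze_variances
from .datatypes import ExpressionMatrix


@dataclass
class DEResult:
    """Per-gene two-group differential expression summary.

    logFC is mean(group A) - mean(group B) on the log2 scale; fdr is the
    Benjamini-Hochberg adjustment of the two-sided p-values.
    """

    table: pd.DataFrame  # columns: logFC, p, fdr (index = gene ids)

    def __post_init__(self):
        need = {"logFC", "p", "fdr"}
        if not need <= set(self.table.columns):
            raise ValueError("DEResult table needs logFC, p, fdr columns")


def quantile_normalize(m: ExpressionMatrix) -> ExpressionMatrix:
    """Force every sample onto the cross-sample mean distribution.

    Each sample's values are replaced by the mean of the order statistics at
    the same rank, so all sorted sample vectors coincide afterwards and
    within-sample ranks are preserved. Tied values receive the interpolated
    target at their average rank.
    """
    if m.values.shape[1] < 2:
        warnings.warn("quantile_normalize: single sample, returned unchanged")
        return m
    vals = m.values.to_numpy(dtype=float)
    n_genes = vals.shape[0]
    mean_sorted = np.sort(vals, axis=0).mean(axis=1)
    out = np.empty_like(vals)
    grid = np.arange(n_genes, dtype=float)
    for j in range(vals.shape[1]):
        ranks = stats.rankdata(vals[:, j], method="average") - 1.0
        out[:, j] = np.interp(ranks, grid, mean_sorted)
    return ExpressionMatrix(
        pd.DataFrame(out, index=m.values.index, columns=m.values.columns),
        m.biotype,
    )


def batch_adjust(m: ExpressionMatrix, batch: pd.Series, equalize_scale: bool = False) -> ExpressionMatrix:
    """Align per-gene batch means to the gene's grand mean.

    A deliberately simple location (optionally scale) adjustment: for every
    gene, each batch's mean is shifted onto the grand mean; with
    ``equalize_scale`` the batch residuals are also rescaled to the pooled
    per-gene standard deviation. Single-sample batches get the mean shift
    only (their scale is not estimable).
    """
    batch = batch.reindex(m.values.columns)
    if batch.isna().any():
        raise ValueError("every sample needs a batch label")
    vals = m.values.to_numpy(dtype=float).copy()
    grand_mean = vals.mean(axis=1, keepdims=True)
    grand_sd = vals.std(axis=1, ddof=1, keepdims=True)
    for b in batch.unique():
        cols = np.asarray(batch == b)
        sub = vals[:, cols]
        b_mean = sub.mean(axis=1, keepdims=True)
        centered = sub - b_mean
        if equalize_scale and cols.sum() > 1:
            b_sd = sub.std(axis=1, ddof=1, keepdims=True)
            safe = np.where(b_sd > 0, b_sd, 1.0)
            centered = centered / safe * grand_sd
        elif equalize_scale:
            warnings.warn(f"batch {b!r} has one sample; mean shift only")
        vals[:, cols] = centered + grand_mean
    return ExpressionMatrix(
        pd.DataFrame(vals, index=m.values.index, columns=m.values.columns),
        m.biotype,
    )


def differential_expression(
    m: ExpressionMatrix,
    groups: pd.Series,
    group_a: str | None = None,
    moderated: bool = True,
) -> DEResult:
    """Two-group differential expression with optional variance moderation.

    With ``moderated`` (default) the per-gene pooled variances are shrunk
    toward an empirical-Bayes prior fit by method of moments on the log
    variances, and a pooled-variance t statistic with augmented degrees of
    freedom is used — an approximation of limma's moderated t. Without it, a
    plain Welch t-test per gene.
    """
    groups = groups.reindex(m.values.columns)
    levels = sorted(groups.dropna().unique())
    if len(levels) != 2:
        raise ValueError("differential_expression needs exactly two groups")
    if group_a is None:
        group_a = levels[0]
    group_b = [g for g in levels if g != group_a][0]
    a = m.values.loc[:, np.asarray(groups == group_a)].to_numpy(dtype=float)
    b = m.values.loc[:, np.asarray(groups == group_b)].to_numpy(dtype=float)
    n1, n2 = a.shape[1], b.shape[1]
    if min(n1, n2) < 2:
        raise ValueError("need >= 2 samples per group")

    logfc = a.mean(axis=1) - b.mean(axis=1)
    if moderated:
        df_resid = n1 + n2 - 2
        s2 = (a.var(axis=1, ddof=1) * (n1 - 1) + b.var(axis=1, ddof=1) * (n2 - 1)) / df_resid
        s2_post, d0, _s0 = squeeze_variances(s2, df_resid)
        denom = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
        df_total = min(df_resid + d0, 1e6)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(denom > 0, logfc / denom, 0.0)
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    else:
        with np.errstate(divide="ignore", invalid="ignore"):
            t, p = stats.ttest_ind(a, b, axis=1, equal_var=False)
        p = np.asarray(p)
    # degenerate genes: no variance anywhere and equal means -> p = 1
    flat = (a.std(axis=1) == 0) & (b.std(axis=1) == 0)
    p = np.where(flat & (logfc == 0), 1.0, p)
    p = np.clip(np.nan_to_num(p, nan=1.0), np.finfo(float).tiny, 1.0)

    table = pd.DataFrame(
        {"logFC": logfc, "p": p, "fdr": bh_adjust(p)}, index=m.values.index
    )
    return DEResult(table)


def select_specific_lncrnas(
    de: DEResult,
    biotype: pd.Series,
    lfc_threshold: float = 1.0,
    fdr_threshold: float = 0.05,
) -> list[str]:
    """lncRNA-biotype genes with |logFC| > lfc and FDR < fdr (both strict)."""
    if lfc_threshold < 0 or fdr_threshold <= 0:
        raise ValueError("thresholds must be positive")
    tab = de.table
    keep = (tab["logFC"].abs() > lfc_threshold) & (tab["fdr"] < fdr_threshold)
    lnc = biotype.reindex(tab.index) == "lncRNA"
    return sorted(tab.index[keep & lnc])
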