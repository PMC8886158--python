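"""Immune enrichment, infiltration and drug-sensitivity comparisons.

Classic two-phenotype GSEA (signal-to-noise ranking, weighted
Kolmogorov-Smirnov running sum, phenotype-permutation NES/p), per-cell-type
infiltration differences and risk correlations, checkpoint/RBP gene
correlates, the combined risk-group x gene-expression four-group survival
analysis, and per-drug IC50 comparisons between risk groups.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import bh_adjust
from .datatypes import ExpressionMatrix
from .prognostic_model import km_logrank


@dataclass
class GseaResult:
    """Enrichment score, normalized score and permutation significance."""

    es: float
    nes: float
    nominal_p: float
    fdr_q: float
    leading_edge: list[str] = field(default_factory=list)

    def __post_init__(self):
        if not -1.0 - 1e-9 <= self.es <= 1.0 + 1e-9:
            raise ValueError("ES must lie in [-1, 1]")


def _signal_to_noise(values: np.ndarray, is_a: np.ndarray) -> np.ndarray:
    """GSEA's signal-to-noise ratio with the software's std floor."""
    a, b = values[:, is_a], values[:, ~is_a]
    mu_a, mu_b = a.mean(axis=1), b.mean(axis=1)
    sd_a = np.maximum(a.std(axis=1, ddof=1), 0.2 * np.abs(mu_a))
    sd_b = np.maximum(b.std(axis=1, ddof=1), 0.2 * np.abs(mu_b))
    denom = np.maximum(sd_a + sd_b, 1e-12)
    return (mu_a - mu_b) / denom


def enrichment_score(
    metric: np.ndarray,
    in_set: np.ndarray,
    weight_exponent: float = 1.0,
) -> tuple[float, int]:
    """Weighted-KS enrichment score for a ranked list.

    ``metric`` must already be sorted descending; ``in_set`` flags set
    members in the same order. Hits advance the running sum by
    |metric|^exponent (normalized); misses retreat by 1/(N - N_hits). The ES
    is the maximum deviation from zero (signed); the second return value is
    the position of that extremum (for the leading edge).
    """
    n = metric.size
    n_hit = int(in_set.sum())
    if n_hit < 1 or n_hit >= n:
        raise ValueError("gene set must be a proper non-empty subset")
    w = np.abs(metric) ** weight_exponent
    hit_w = np.where(in_set, w, 0.0)
    total = hit_w.sum()
    if total <= 0:
        hit_w = in_set.astype(float)
        total = hit_w.sum()
    step_hit = hit_w / total
    step_miss = np.where(in_set, 0.0, 1.0 / (n - n_hit))
    running = np.cumsum(step_hit - step_miss)
    i_max = int(np.argmax(np.abs(running)))
    return float(running[i_max]), i_max


def gsea(
    expr: ExpressionMatrix,
    phenotype: pd.Series,
    gene_set,
    positive: str | None = None,
    n_perm: int = 1000,
    seed: int = 0,
    weight_exponent: float = 1.0,
) -> GseaResult:
    """Two-phenotype GSEA of one gene set with phenotype permutation.

    Genes are ranked by signal-to-noise of ``positive`` phenotype minus the
    other; a positive ES/NES means the set crowds the ``positive``-correlated
    end of the list. NES = ES / mean(|permuted ES| of the same sign);
    nominal p is the same-sign permutation tail. For a single set the FDR q
    equals the nominal p (across sets use :func:`gsea_collection`).
    """
    res = gsea_collection(
        expr, phenotype, {"set": list(gene_set)}, positive=positive,
        n_perm=n_perm, seed=seed, weight_exponent=weight_exponent,
    )
    return res["set"]


def gsea_collection(
    expr: ExpressionMatrix,
    phenotype: pd.Series,
    gene_sets: dict[str, list[str]],
    positive: str | None = None,
    n_perm: int = 1000,
    seed: int = 0,
    weight_exponent: float = 1.0,
) -> dict[str, GseaResult]:
    """GSEA over several gene sets sharing one permutation stream.

    FDR q across sets is the BH adjustment of the nominal permutation
    p-values (a simplification of the GSEA software's pooled-NES FDR).
    """
    phenotype = phenotype.reindex(expr.values.columns)
    levels = sorted(phenotype.dropna().unique())
    if len(levels) != 2:
        raise ValueError("phenotype must have exactly two levels")
    if positive is None:
        positive = levels[0]
    is_a = np.asarray(phenotype == positive)
    if is_a.sum() < 3 or (~is_a).sum() < 3:
        raise ValueError("need >= 3 samples per phenotype")

    values = expr.values.to_numpy(dtype=float)
    gene_index = {g: i for i, g in enumerate(expr.values.index)}
    masks = {}
    for name, members in gene_sets.items():
        rows = sorted({gene_index[g] for g in members if g in gene_index})
        if len(rows) < 2:
            raise ValueError(f"gene set {name!r} overlaps < 2 genes")
        mask = np.zeros(values.shape[0], dtype=bool)
        mask[rows] = True
        masks[name] = mask

    rng = np.random.default_rng(seed)
    labels = is_a.copy()
    perm_labels = [rng.permutation(labels) for _ in range(n_perm)]

    def _score(lab, mask):
        metric = _signal_to_noise(values, lab)
        order = np.argsort(-metric, kind="stable")
        es, i_max = enrichment_score(metric[order], mask[order], weight_exponent)
        return es, order, i_max

    out: dict[str, GseaResult] = {}
    nominal = {}
    cache = {}
    for name, mask in masks.items():
        es, order, i_max = _score(labels, mask)
        perm_es = np.array([_score(lab, mask)[0] for lab in perm_labels])
        same = perm_es[np.sign(perm_es) == np.sign(es)] if es != 0 else perm_es
        if same.size == 0:
            nes = float(np.sign(es)) * 10.0 if es != 0 else 0.0
            p = 1.0 / (n_perm + 1)
        else:
            nes = es / np.mean(np.abs(same))
            p = (np.sum(np.abs(same) >= abs(es)) + 1) / (same.size + 1)
        sorted_in = mask[order]
        if es >= 0:
            leading = expr.values.index.to_numpy()[order[: i_max + 1]][
                sorted_in[: i_max + 1]
            ]
        else:
            leading = expr.values.index.to_numpy()[order[i_max:]][
                sorted_in[i_max:]
            ]
        nominal[name] = float(p)
        cache[name] = (float(es), float(nes), [str(g) for g in leading])
    qvals = bh_adjust([nominal[n] for n in masks])
    for (name, _), q in zip(masks.items(), qvals):
        es, nes, leading = cache[name]
        out[name] = GseaResult(
            es=es, nes=nes, nominal_p=nominal[name],
            fdr_q=float(q), leading_edge=leading,
        )
    return out


# ----------------------------------------------------------- infiltration

def infiltration_diff(infiltration: pd.DataFrame, groups: pd.Series) -> pd.DataFrame:
    """Two-sided Mann-Whitney per cell type between risk groups, BH across types."""
    groups = groups.reindex(infiltration.index)
    levels = sorted(groups.dropna().unique())
    if len(levels) != 2:
        raise ValueError("need exactly two groups")
    a_sel = np.asarray(groups == levels[0])
    b_sel = np.asarray(groups == levels[1])
    rows = []
    for ct in infiltration.columns:
        x = infiltration[ct].to_numpy(dtype=float)
        a, b = x[a_sel], x[b_sel]
        if np.all(x == x[0]):
            rows.append({"celltype": ct, "p": 1.0, "direction": "constant",
                         "median_diff": 0.0})
            warnings.warn(f"infiltration column {ct} is constant")
            continue
        res = stats.mannwhitneyu(a, b, alternative="two-sided")
        diff = float(np.median(a) - np.median(b))
        rows.append({
            "celltype": ct, "p": float(res.pvalue),
            "direction": f"higher_in_{levels[0] if diff > 0 else levels[1]}",
            "median_diff": diff,
        })
    out = pd.DataFrame(rows).set_index("celltype")
    out["fdr"] = bh_adjust(out["p"])
    return out


def infiltration_correlation(scores: pd.Series, infiltration: pd.DataFrame) -> pd.DataFrame:
    """Spearman correlation of each cell type's score with the risk score."""
    common = [s for s in infiltration.index if s in scores.index]
    if len(common) < 4:
        raise ValueError("need >= 4 paired observations")
    sc = scores.reindex(common).to_numpy(dtype=float)
    rows = []
    for ct in infiltration.columns:
        x = infiltration.loc[common, ct].to_numpy(dtype=float)
        if np.all(x == x[0]) or np.all(sc == sc[0]):
            rows.append({"celltype": ct, "rho": np.nan, "p": np.nan})
            warnings.warn(f"constant vector for {ct}; rho undefined")
            continue
        rho, p = stats.spearmanr(sc, x)
        rows.append({"celltype": ct, "rho": float(rho), "p": float(p)})
    return pd.DataFrame(rows).set_index("celltype")


def partial_spearman(x, y, covariate=None) -> tuple[float, float]:
    """Spearman correlation of rank residuals after regressing out a covariate.

    With no covariate this is plain Spearman. Mirrors purity-adjusted
    correlations: ranks of x and y are each linearly adjusted for the ranks
    of the covariate, then correlated.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if covariate is None:
        rho, p = stats.spearmanr(x, y)
        return float(rho), float(p)
    z = stats.rankdata(np.asarray(covariate, dtype=float))
    rx, ry = stats.rankdata(x), stats.rankdata(y)
    zc = np.column_stack([np.ones_like(z), z])
    res_x = rx - zc @ np.linalg.lstsq(zc, rx, rcond=None)[0]
    res_y = ry - zc @ np.linalg.lstsq(zc, ry, rcond=None)[0]
    r, p = stats.pearsonr(res_x, res_y)
    return float(r), float(p)


# -------------------------------------------------------------- correlates

def gene_correlates(
    expr: ExpressionMatrix,
    groups: pd.Series,
    panel,
    scores: pd.Series,
) -> dict[str, pd.DataFrame]:
    """Risk-group differences and correlation structure of a gene panel.

    Per panel gene: two-sided rank-sum between risk groups, Pearson and
    Spearman correlation with the risk score; plus the pairwise Pearson /
    Spearman matrix among the panel genes. Absent genes are skipped with a
    warning naming them.
    """
    present = [g for g in panel if g in expr.values.index]
    absent = sorted(set(panel) - set(present))
    if absent:
        warnings.warn(f"panel genes absent from expression: {absent}")
    if not present:
        raise ValueError("no panel gene found in the expression matrix")
    samples = [s for s in expr.sample_ids if s in scores.index]
    groups = groups.reindex(samples)
    sc = scores.reindex(samples).to_numpy(dtype=float)
    levels = sorted(groups.dropna().unique())
    rows = []
    for g in present:
        x = expr.values.loc[g, samples].to_numpy(dtype=float)
        entry = {"gene": g}
        if len(levels) == 2:
            a = x[np.asarray(groups == levels[0])]
            b = x[np.asarray(groups == levels[1])]
            res = stats.mannwhitneyu(a, b, alternative="two-sided")
            entry["ranksum_p"] = float(res.pvalue)
            diff = float(np.median(a) - np.median(b))
            entry["direction"] = f"higher_in_{levels[0] if diff > 0 else levels[1]}"
        pr, pp = stats.pearsonr(x, sc)
        sr, sp = stats.spearmanr(x, sc)
        entry.update({"pearson_r": float(pr), "pearson_p": float(pp),
                      "spearman_rho": float(sr), "spearman_p": float(sp)})
        rows.append(entry)
    per_gene = pd.DataFrame(rows).set_index("gene")

    mat = expr.values.loc[present, samples].T
    pearson = mat.corr(method="pearson")
    spearman = mat.corr(method="spearman")
    return {"per_gene": per_gene, "pearson": pearson, "spearman": spearman}


def four_group_survival(
    groups: pd.Series,
    gene_expression: pd.Series,
    surv: pd.DataFrame,
) -> dict:
    """KM/log-rank across risk-group x gene-high/low (median split) labels."""
    common = [s for s in surv.index if s in groups.index and s in gene_expression.index]
    surv = surv.loc[common]
    g = groups.reindex(common)
    x = gene_expression.reindex(common).astype(float)
    cut = float(x.median())
    gene_lab = np.where(x > cut, "gene-high", "gene-low")
    labels = pd.Series(
        [f"{a}-risk/{b}" for a, b in zip(g, gene_lab)], index=common,
        name="four_group",
    )
    sizes = labels.value_counts().to_dict()
    empty = [
        f"{r}-risk/{e}" for r in ("high", "low") for e in ("gene-high", "gene-low")
        if f"{r}-risk/{e}" not in sizes
    ]
    if empty:
        warnings.warn(f"empty subgroups: {empty}")
    result = km_logrank(labels, surv)
    result["labels"] = labels
    result["group_sizes"] = sizes
    result["gene_cutoff"] = cut
    return result


# ---------------------------------------------------------------- IC50 drugs

def drug_sensitivity_diff(ic50: pd.DataFrame, groups: pd.Series) -> pd.DataFrame:
    """Per-drug two-sided Mann-Whitney of predicted IC50 between risk groups.

    "more_sensitive" names the group with the lower median IC50 (lower
    half-maximal inhibitory concentration = greater sensitivity); BH across
    drugs.
    """
    groups = groups.reindex(ic50.index)
    levels = sorted(groups.dropna().unique())
    if len(levels) != 2:
        raise ValueError("need exactly two groups")
    a_sel = np.asarray(groups == levels[0])
    b_sel = np.asarray(groups == levels[1])
    rows = []
    for drug in ic50.columns:
        x = ic50[drug].to_numpy(dtype=float)
        res = stats.mannwhitneyu(x[a_sel], x[b_sel], alternative="two-sided")
        diff = float(np.median(x[a_sel]) - np.median(x[b_sel]))
        rows.append({
            "drug": drug, "p": float(res.pvalue),
            "median_ic50_diff": diff,
            "more_sensitive": levels[1] if diff > 0 else levels[0],
        })
    out = pd.DataFrame(rows).set_index("drug")
    out["fdr"] = bh_adjust(out["p"])
    return out
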