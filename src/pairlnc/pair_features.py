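"""Cyclic pairwise binarization of lncRNA expression.

The core feature transform: every unordered pair of signature lncRNAs
becomes a binary indicator per sample — 1 when the lexicographically
smaller-named partner is expressed above the other, 0 otherwise (ties score
0). Near-constant indicators are removed by the 20-80% prevalence filter.
Because the indicator only compares two genes within the same sample, the
features are invariant to any strictly increasing per-sample transform of
expression.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .datatypes import ExpressionMatrix, PairMatrix, pair_key


def intersect_with_cohort(specific_lncrnas, tumor: ExpressionMatrix) -> list[str]:
    """lncRNAs both cell-type-specific and quantified in the tumor cohort."""
    cohort = set(tumor.gene_ids)
    out = sorted(set(specific_lncrnas) & cohort)
    if not out:
        warnings.warn("no specific lncRNAs found in the tumor cohort")
    return out


def build_pair_matrix(tumor: ExpressionMatrix, hilt_lncrnas) -> PairMatrix:
    """All C(m, 2) pair indicators over the tumor samples.

    Each unordered pair appears once, oriented with the lexicographically
    smaller gene first; indicator = 1 iff expr(first) > expr(second) in that
    sample (strict; ties give 0).
    """
    genes = sorted(set(hilt_lncrnas))
    if len(genes) < 2:
        raise ValueError("need at least 2 lncRNAs to build pairs")
    missing = [g for g in genes if g not in tumor.values.index]
    if missing:
        raise KeyError(f"genes absent from the tumor matrix: {missing[:5]}")
    vals = tumor.values.loc[genes].to_numpy(dtype=float)
    m = len(genes)
    ia, ib = np.triu_indices(m, k=1)
    ind = (vals[ia] > vals[ib]).astype("int8")
    index = [pair_key(genes[i], genes[j]) for i, j in zip(ia, ib)]
    return PairMatrix(pd.DataFrame(ind, index=index, columns=tumor.sample_ids))


def prevalence_filter(pm: PairMatrix, lower: float = 0.20, upper: float = 0.80) -> PairMatrix:
    """Keep pairs whose indicator prevalence lies in [lower, upper] (inclusive)."""
    if not 0.0 <= lower < upper <= 1.0:
        raise ValueError("require 0 <= lower < upper <= 1")
    prev = pm.prevalence
    keep = prev.index[(prev >= lower) & (prev <= upper)]
    return PairMatrix(pm.indicators.loc[keep])
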