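"""Core in-memory containers shared across the pipeline stages."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

BIOTYPES = ("lncRNA", "mRNA", "other")


@dataclass
class ExpressionMatrix:
    """Log2-scale gene x sample expression with a per-gene biotype.

    ``values`` is a genes-by-samples DataFrame (index = gene ids, columns =
    sample ids); ``biotype`` maps every gene id to one of ``lncRNA``,
    ``mRNA`` or ``other``.
    """

    values: pd.DataFrame
    biotype: pd.Series

    def __post_init__(self):
        if self.values.index.has_duplicates:
            raise ValueError("duplicate gene ids")
        if self.values.columns.has_duplicates:
            raise ValueError("duplicate sample ids")
        if not np.isfinite(self.values.to_numpy(dtype=float)).all():
            raise ValueError("expression values must be finite")
        self.biotype = self.biotype.reindex(self.values.index).fillna("other")
        bad = set(self.biotype.unique()) - set(BIOTYPES)
        if bad:
            raise ValueError(f"unknown biotypes: {sorted(bad)}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        genes = [g for g in genes if g in self.values.index]
        return ExpressionMatrix(self.values.loc[genes], self.biotype.loc[genes])

    def subset_samples(self, samples: Sequence[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values[list(samples)], self.biotype)

    def lncrnas(self) -> list[str]:
        return list(self.biotype.index[self.biotype == "lncRNA"])

    def mrnas(self) -> list[str]:
        return list(self.biotype.index[self.biotype == "mRNA"])


PAIR_SEP = "|"


def pair_key(a: str, b: str) -> str:
    return f"{a}{PAIR_SEP}{b}"


@dataclass
class PairMatrix:
    """Binary pair-indicator features over a shared sample list.

    Rows are oriented pairs "lncA|lncB" with lncA < lncB lexicographically;
    entry (pair, sample) is 1 when lncA is expressed above lncB in that
    sample and 0 otherwise (ties score 0).
    """

    indicators: pd.DataFrame  # pairs x samples, int8 in {0,1}

    def __post_init__(self):
        if self.indicators.index.has_duplicates:
            raise ValueError("duplicate pair features")
        vals = self.indicators.to_numpy()
        if vals.size and not np.isin(vals, (0, 1)).all():
            raise ValueError("indicators must be 0/1")

    @property
    def pairs(self) -> list[tuple[str, str]]:
        return [tuple(k.split(PAIR_SEP, 1)) for k in self.indicators.index]

    @property
    def sample_ids(self) -> list[str]:
        return list(self.indicators.columns)

    @property
    def prevalence(self) -> pd.Series:
        return self.indicators.mean(axis=1)

    def __len__(self) -> int:
        return len(self.indicators)

    def subset(self, keys: Sequence[str]) -> "PairMatrix":
        return PairMatrix(self.indicators.loc[list(keys)])


@dataclass
class SignatureModel:
    """Fitted pair signature: selected pairs, Cox betas and the risk cutoff."""

    pairs: list[tuple[str, str]]
    betas: list[float]
    cutoff: float = float("nan")
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        if len(self.pairs) != len(self.betas):
            raise ValueError("pairs and betas must align")

    @property
    def pair_keys(self) -> list[str]:
        return [pair_key(a, b) for a, b in self.pairs]

    def to_json(self, path):
        payload = {
            "pairs": [list(p) for p in self.pairs],
            "betas": [float(b) for b in self.betas],
            "cutoff": None if np.isnan(self.cutoff) else float(self.cutoff),
            "metadata": self.metadata,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "SignatureModel":
        with open(path) as fh:
            payload = json.load(fh)
        cutoff = payload.get("cutoff")
        return cls(
            pairs=[tuple(p) for p in payload["pairs"]],
            betas=[float(b) for b in payload["betas"]],
            cutoff=float("nan") if cutoff is None else float(cutoff),
            metadata=payload.get("metadata", {}),
        )


@dataclass
class RocCurve:
    """Time-dependent ROC at horizon ``t``: one row per score threshold."""

    horizon: float
    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float

    def youden(self) -> np.ndarray:
        return self.sensitivity + self.specificity - 1.0


SURVIVAL_COLUMNS = ["time", "event"]
CLINICAL_COLUMNS = ["age", "sex", "grade", "stage", "T", "N", "M"]


def validate_survival(surv: pd.DataFrame) -> pd.DataFrame:
    """Check a survival table: positive times, binary events."""
    for col in SURVIVAL_COLUMNS:
        if col not in surv.columns:
            raise ValueError(f"survival table missing column {col!r}")
    if (surv["time"] <= 0).any():
        raise ValueError("survival times must be positive")
    if not surv["event"].isin([0, 1]).all():
        raise ValueError("event must be 0/1")
    return surv
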