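"""Readers and writers for the plain-text formats the pipeline exchanges.

Expression matrices travel as TSV (rows = genes, first column ``gene_id``,
header = sample ids) with a sibling two-column biotype TSV, or as GCT 1.2.
Gene sets use GMT; interaction tables, survival/clinical tables, infiltration
and IC50 tables are TSV. All writers are deterministic.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd
import yaml

from .datatypes import ExpressionMatrix, PairMatrix, validate_survival


# ---------------------------------------------------------------- expression

def write_expression_tsv(expr: ExpressionMatrix, path, biotype_path=None):
    df = expr.values.copy()
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t", float_format="%.6g")
    if biotype_path is not None:
        bt = expr.biotype.rename("biotype").to_frame()
        bt.index.name = "gene_id"
        bt.to_csv(biotype_path, sep="\t")


def read_expression_tsv(path, biotype_path=None, default_biotype="other"):
    df = pd.read_csv(path, sep="\t", index_col="gene_id")
    if biotype_path is not None:
        bt = pd.read_csv(biotype_path, sep="\t", index_col="gene_id")["biotype"]
    else:
        bt = pd.Series(default_biotype, index=df.index)
    return ExpressionMatrix(df, bt)


def write_gct(expr: ExpressionMatrix, path):
    """GCT 1.2 (gene id, description=biotype, then sample columns)."""
    with open(path, "w") as fh:
        fh.write("#1.2\n")
        fh.write(f"{expr.values.shape[0]}\t{expr.values.shape[1]}\n")
        fh.write("NAME\tDescription\t" + "\t".join(expr.sample_ids) + "\n")
        for gid, row in expr.values.iterrows():
            vals = "\t".join(f"{v:.6g}" for v in row)
            fh.write(f"{gid}\t{expr.biotype[gid]}\t{vals}\n")


def read_gct(path) -> ExpressionMatrix:
    with open(path) as fh:
        fh.readline()
        fh.readline()
        df = pd.read_csv(fh, sep="\t", index_col="NAME")
    bt = df.pop("Description")
    bt = bt.where(bt.isin(["lncRNA", "mRNA", "other"]), "other")
    return ExpressionMatrix(df, bt)


# ------------------------------------------------------------------ survival

def write_survival_tsv(surv: pd.DataFrame, path):
    out = surv.copy()
    out.index.name = "sample"
    out.to_csv(path, sep="\t")


def read_survival_tsv(path) -> pd.DataFrame:
    surv = pd.read_csv(path, sep="\t", index_col="sample")
    return validate_survival(surv)


# --------------------------------------------------------------- pair matrix

def write_pair_matrix_tsv(pm: PairMatrix, path):
    out = pm.indicators.copy()
    out.index.name = "pair"
    out.to_csv(path, sep="\t")


def read_pair_matrix_tsv(path) -> PairMatrix:
    return PairMatrix(pd.read_csv(path, sep="\t", index_col="pair").astype("int8"))


# -------------------------------------------------------------- interactions

def write_interaction_tsv(edges: pd.DataFrame, path):
    edges.to_csv(path, sep="\t", index=False)


def read_interaction_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    need = {"source_id", "target_id", "source_db"}
    missing = need - set(df.columns)
    if missing:
        raise ValueError(f"interaction table missing columns {sorted(missing)}")
    return df


# ----------------------------------------------------------------------- GMT

def write_gmt(gene_sets: dict[str, list[str]], path):
    with open(path, "w") as fh:
        for name in gene_sets:
            members = "\t".join(gene_sets[name])
            fh.write(f"{name}\tsynthetic\t{members}\n")


def read_gmt(path) -> dict[str, list[str]]:
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


# --------------------------------------------------------------- misc tables

def write_table_tsv(df: pd.DataFrame, path, index_name="sample"):
    out = df.copy()
    out.index.name = index_name
    out.to_csv(path, sep="\t", float_format="%.6g")


def read_table_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


# -------------------------------------------------------------------- config

def load_yaml(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def dump_yaml(obj: dict, path):
    with open(path, "w") as fh:
        yaml.safe_dump(obj, fh, sort_keys=True)


def config_hash(obj) -> str:
    """Stable short hash of a JSON-serializable config for output headers."""
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
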