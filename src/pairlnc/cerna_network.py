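"""Competing-endogenous-RNA network assembly and hub-mRNA enrichment.

Tumor-vs-normal differential mRNAs (rank-sum test, |logFC| > 2, FDR < 0.05),
target prediction by walking lncRNA -> miRNA -> mRNA interaction tables
under a consensus rule, hub mRNAs as the intersection of predicted and
differential mRNAs, back-propagated tripartite network construction, and
hypergeometric over-representation of annotation terms among the hubs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from ._stats import bh_adjust
from .datatypes import ExpressionMatrix
from .tcell_signature import DEResult


def de_mrna(
    tumor: ExpressionMatrix,
    sample_type: pd.Series,
    lfc: float = 2.0,
    fdr: float = 0.05,
) -> tuple[DEResult, list[str]]:
    """Tumor-vs-normal mRNA differential expression by two-sided rank sum.

    logFC is the difference of group means on the log2 scale (tumor minus
    normal); the reported list keeps mRNAs with |logFC| strictly above
    ``lfc`` and BH FDR strictly below ``fdr``.
    """
    sample_type = sample_type.reindex(tumor.values.columns)
    tum = np.asarray(sample_type == "tumor")
    nor = np.asarray(sample_type == "normal")
    if tum.sum() < 3 or nor.sum() < 3:
        raise ValueError("need >= 3 tumor and >= 3 normal samples")
    sub = tumor.subset_genes(tumor.mrnas())
    a = sub.values.loc[:, tum].to_numpy(dtype=float)
    b = sub.values.loc[:, nor].to_numpy(dtype=float)
    logfc = a.mean(axis=1) - b.mean(axis=1)
    res = stats.mannwhitneyu(a, b, axis=1, alternative="two-sided")
    p = np.asarray(res.pvalue, dtype=float)
    flat = (a.std(axis=1) == 0) & (b.std(axis=1) == 0) & (logfc == 0)
    p = np.where(flat, 1.0, p)
    table = pd.DataFrame(
        {"logFC": logfc, "p": p, "fdr": bh_adjust(p)}, index=sub.values.index
    )
    de = DEResult(table)
    keep = table.index[(table["logFC"].abs() > lfc) & (table["fdr"] < fdr)]
    return de, sorted(keep)


def predict_targets(
    lnc_list,
    lnc_mirna: pd.DataFrame,
    target_tables: list[pd.DataFrame],
    consensus: str = "all",
) -> tuple[list[str], list[str]]:
    """miRNAs bound by the lncRNAs, and their consensus target mRNAs.

    A (miRNA, mRNA) edge counts under ``consensus="all"`` only when present
    in every provided target table, or in at least one under ``"any"``.
    """
    if consensus not in {"all", "any"}:
        raise ValueError("consensus must be 'all' or 'any'")
    lnc_set = set(lnc_list)
    mirnas = sorted(set(
        lnc_mirna.loc[lnc_mirna["source_id"].isin(lnc_set), "target_id"]
    ))
    if not mirnas:
        return [], []
    edge_sets = [
        set(zip(t["source_id"], t["target_id"])) for t in target_tables
    ]
    if consensus == "all":
        edges = set.intersection(*edge_sets) if edge_sets else set()
    else:
        edges = set.union(*edge_sets) if edge_sets else set()
    mir_set = set(mirnas)
    mrnas = sorted({m for (mi, m) in edges if mi in mir_set})
    return mirnas, mrnas


def hub_mrnas(predicted_mrnas, de_mrnas) -> list[str]:
    """Sorted intersection of predicted targets and differential mRNAs."""
    return sorted(set(predicted_mrnas) & set(de_mrnas))


@dataclass
class CeRnaNetwork:
    """Tripartite lncRNA-miRNA-mRNA graph rooted at the hub mRNAs."""

    graph: nx.Graph
    hubs: list[str] = field(default_factory=list)

    def nodes_of_type(self, kind: str) -> list[str]:
        return sorted(
            n for n, d in self.graph.nodes(data=True) if d.get("kind") == kind
        )

    def to_edge_list(self) -> pd.DataFrame:
        rows = [
            {"source": a, "target": b,
             "edge_type": self.graph.edges[a, b]["edge_type"]}
            for a, b in sorted(self.graph.edges)
        ]
        return pd.DataFrame(rows, columns=["source", "target", "edge_type"])

    def to_sif(self, path):
        with open(path, "w") as fh:
            for a, b in sorted(self.graph.edges):
                fh.write(f"{a}\t{self.graph.edges[a, b]['edge_type']}\t{b}\n")

    def to_graphml(self, path):
        nx.write_graphml(self.graph, path)


def assemble_network(
    hubs,
    lnc_mirna: pd.DataFrame,
    target_tables: list[pd.DataFrame],
    consensus: str = "all",
) -> CeRnaNetwork:
    """Back-propagate from hub mRNAs to their miRNAs and lncRNAs.

    Keeps miRNAs that target >= 1 hub under the consensus rule, then lncRNAs
    interacting with >= 1 kept miRNA; hubs with no consensus miRNA are
    dropped with a warning so the graph has no orphan nodes.
    """
    edge_sets = [set(zip(t["source_id"], t["target_id"])) for t in target_tables]
    if consensus == "all":
        mi_edges = set.intersection(*edge_sets) if edge_sets else set()
    elif consensus == "any":
        mi_edges = set.union(*edge_sets) if edge_sets else set()
    else:
        raise ValueError("consensus must be 'all' or 'any'")

    hubs = sorted(set(hubs))
    g = nx.Graph()
    kept_hubs = []
    kept_mirnas: set[str] = set()
    for h in hubs:
        mirs = {mi for (mi, m) in mi_edges if m == h}
        if not mirs:
            warnings.warn(f"hub mRNA {h} has no consensus miRNA; dropped")
            continue
        kept_hubs.append(h)
        g.add_node(h, kind="mRNA")
        for mi in mirs:
            g.add_node(mi, kind="miRNA")
            g.add_edge(mi, h, edge_type="miRNA-mRNA")
            kept_mirnas.add(mi)
    lnc_edges = set(zip(lnc_mirna["source_id"], lnc_mirna["target_id"]))
    for lnc, mi in sorted(lnc_edges):
        if mi in kept_mirnas:
            g.add_node(lnc, kind="lncRNA")
            g.add_edge(lnc, mi, edge_type="lncRNA-miRNA")
    # miRNAs with no lncRNA upstream break the layer invariant; prune them
    for mi in sorted(kept_mirnas):
        has_lnc = any(
            g.nodes[n].get("kind") == "lncRNA" for n in g.neighbors(mi)
        )
        if not has_lnc:
            g.remove_node(mi)
    orphans = [n for n in list(g.nodes) if g.degree[n] == 0]
    g.remove_nodes_from(orphans)
    kept_hubs = [h for h in kept_hubs if h in g]
    return CeRnaNetwork(g, kept_hubs)


def enrichment_test(
    hubs, annotation: dict[str, list[str]], universe
) -> pd.DataFrame:
    """One-sided hypergeometric over-representation per annotation term.

    p = P(overlap >= observed) drawing |hubs| genes from the universe with
    |term| successes; BH adjustment across terms; fold enrichment is the
    observed/expected overlap ratio.
    """
    universe = sorted(set(universe))
    n_univ = len(universe)
    hub_set = set(hubs) & set(universe)
    if set(hubs) - set(universe):
        raise ValueError("hub genes must be contained in the universe")
    n_hub = len(hub_set)
    rows = []
    for term, members in annotation.items():
        members_in = set(members) & set(universe)
        k_term = len(members_in)
        if k_term == 0:
            warnings.warn(f"term {term!r} has no genes in the universe; skipped")
            continue
        overlap = len(members_in & hub_set)
        p = float(stats.hypergeom.sf(overlap - 1, n_univ, k_term, n_hub))
        expected = n_hub * k_term / n_univ
        rows.append({
            "term": term, "overlap": overlap, "term_size": k_term,
            "p": min(p, 1.0),
            "fold_enrichment": overlap / expected if expected > 0 else np.nan,
        })
    out = pd.DataFrame(rows, columns=["term", "overlap", "term_size", "p",
                                      "fold_enrichment"])
    if len(out):
        out["fdr"] = bh_adjust(out["p"])
    else:
        out["fdr"] = []
    return out.set_index("term")
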