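"""End-to-end orchestration: simulate -> signature -> pairs -> model -> downstream.

A single :class:`PipelineConfig` drives every stage in order, emits
per-stage artifacts under an output directory and a machine-readable
``summary.json`` holding the filtering funnel (specific lncRNAs -> pairs
built -> prevalence survivors -> screen survivors -> lasso survivors ->
signature size -> hub mRNAs) plus the headline statistics. All outputs carry
the config hash and seed; rerunning with the same config reproduces them
byte for byte.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import cerna_network as cn
from . import immune_correlates as ic
from . import pair_features as pf
from . import prognostic_model as pmod
from . import tcell_signature as ts
from .datatypes import SignatureModel
from .io import (config_hash, dump_yaml, ensure_dir, load_yaml, write_gmt,
                 write_pair_matrix_tsv, write_table_tsv, write_expression_tsv,
                 write_survival_tsv, write_interaction_tsv)
from .synthetic_data import (SimulationConfig, generate_auxiliary_tables,
                             generate_immune_panel, generate_interaction_tables,
                             generate_tumor_cohort)


@dataclass
class PipelineConfig:
    """Thresholds, horizons and toggles for a full run."""

    outdir: str = "pairlnc_run"
    seed: int = 0
    simulation: dict = field(default_factory=dict)
    # differential expression
    lfc_threshold: float = 1.0
    fdr_threshold: float = 0.05
    mrna_lfc_threshold: float = 2.0
    mrna_fdr_threshold: float = 0.05
    # pairing / model
    prevalence_lower: float = 0.20
    prevalence_upper: float = 0.80
    screen_alpha: float = 0.01
    lasso_folds: int = 10
    lasso_rule: str = "min"
    horizon: float = 36.0
    roc_horizons: tuple[float, ...] = (24.0, 36.0, 48.0)
    # downstream
    consensus: str = "all"
    gsea_permutations: int = 1000
    stratify_by: str = "stage"
    # reporting
    write_expression: bool = False
    make_plots: bool = False

    def __post_init__(self):
        if not 0 <= self.prevalence_lower < self.prevalence_upper <= 1:
            raise ValueError("invalid prevalence bounds")
        if not 0 < self.screen_alpha < 1:
            raise ValueError("screen_alpha must be in (0, 1)")
        if self.consensus not in {"all", "any"}:
            raise ValueError("consensus must be 'all' or 'any'")
        if self.horizon not in self.roc_horizons:
            self.roc_horizons = tuple(sorted({*self.roc_horizons, self.horizon}))

    def simulation_config(self) -> SimulationConfig:
        sim = dict(self.simulation)
        sim.setdefault("seed", self.seed)
        return SimulationConfig.from_dict(sim)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["roc_horizons"] = list(self.roc_horizons)
        return d

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = load_yaml(path)
        if "roc_horizons" in raw:
            raw["roc_horizons"] = tuple(raw["roc_horizons"])
        return cls(**raw)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


class StageFailure(RuntimeError):
    """A pipeline stage failed; partial artifacts are preserved on disk."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def run_full_pipeline(cfg: PipelineConfig) -> dict:
    """Execute every stage in order; return (and write) the run summary."""
    out = ensure_dir(cfg.outdir)
    sim_cfg = cfg.simulation_config()
    chash = config_hash(cfg.to_dict())
    summary: dict = {
        "config_hash": chash,
        "seed": cfg.seed,
        "funnel": {},
        "stages": [],
    }
    dump_yaml(cfg.to_dict(), out / "config.yaml")

    def stage(name):
        summary["stages"].append(name)
        return name

    try:
        stage("simulate")
        panel = generate_immune_panel(sim_cfg)
        cohort = generate_tumor_cohort(sim_cfg)
        interactions = generate_interaction_tables(sim_cfg)
        aux = generate_auxiliary_tables(sim_cfg, cohort.true_lp)
        write_survival_tsv(cohort.survival, out / "survival.tsv")
        write_gmt(aux.gene_sets, out / "gene_sets.gmt")
        write_table_tsv(aux.infiltration, out / "infiltration.tsv")
        write_table_tsv(aux.ic50, out / "ic50.tsv")
        write_interaction_tsv(interactions.lnc_mirna, out / "lnc_mirna.tsv")
        for i, tab in enumerate(interactions.mirna_mrna):
            write_interaction_tsv(tab, out / f"mirna_mrna_{i}.tsv")
        if cfg.write_expression:
            write_expression_tsv(panel.expr, out / "panel_expression.tsv",
                                 out / "panel_biotype.tsv")
            write_expression_tsv(cohort.expr, out / "tumor_expression.tsv",
                                 out / "tumor_biotype.tsv")
    except Exception as exc:
        raise StageFailure("simulate", exc) from exc

    try:
        stage("signature")
        norm = panel.expr
        if panel.batch is not None:
            norm = ts.batch_adjust(norm, panel.batch)
        norm = ts.quantile_normalize(norm)
        de = ts.differential_expression(norm, panel.celltype, group_a="T")
        specific = ts.select_specific_lncrnas(
            de, norm.biotype, cfg.lfc_threshold, cfg.fdr_threshold
        )
        write_table_tsv(de.table, out / "panel_de.tsv", index_name="gene_id")
        summary["funnel"]["specific_lncrnas"] = len(specific)
    except Exception as exc:
        raise StageFailure("signature", exc) from exc

    tumor_samples = list(cohort.survival.index)
    tumor_expr = cohort.expr.subset_samples(tumor_samples)
    model: SignatureModel | None = None
    scores = groups = None
    try:
        stage("pair")
        hilt = pf.intersect_with_cohort(specific, tumor_expr)
        summary["funnel"]["hilt_lncrnas"] = len(hilt)
        if len(hilt) >= 2:
            pm_all = pf.build_pair_matrix(tumor_expr, hilt)
            pm = pf.prevalence_filter(pm_all, cfg.prevalence_lower,
                                      cfg.prevalence_upper)
            write_pair_matrix_tsv(pm, out / "pair_matrix.tsv")
            summary["funnel"]["pairs_built"] = len(pm_all)
            summary["funnel"]["pairs_after_prevalence"] = len(pm)
        else:
            pm = None
            summary["funnel"]["pairs_built"] = 0
            summary["funnel"]["pairs_after_prevalence"] = 0
    except Exception as exc:
        raise StageFailure("pair", exc) from exc

    try:
        stage("fit")
        if pm is not None and len(pm) >= 1:
            survivors, screen_tab = pmod.univariate_cox_screen(
                pm, cohort.survival, alpha=cfg.screen_alpha
            )
            write_table_tsv(screen_tab, out / "screen.tsv", index_name="pair")
        else:
            survivors, screen_tab = [], None
        summary["funnel"]["screen_survivors"] = len(survivors)
        selected = []
        if len(survivors) >= 2:
            selected, lasso_info = pmod.lasso_cox_select(
                pm.subset(survivors), cohort.survival,
                folds=cfg.lasso_folds, seed=cfg.seed, rule=cfg.lasso_rule,
            )
            summary["lasso_chosen_alpha"] = lasso_info["chosen_alpha"]
        elif len(survivors) == 1:
            selected = survivors
        summary["funnel"]["lasso_survivors"] = len(selected)

        if selected:
            model, cox_tab = pmod.multivariate_cox_fit(
                pm.subset(selected), cohort.survival,
                extra_metadata={"seed": cfg.seed, "cv_folds": cfg.lasso_folds,
                                "horizon": cfg.horizon},
            )
            write_table_tsv(cox_tab, out / "multivariate_cox.tsv",
                            index_name="pair")
            scores = pmod.risk_score(model, pm)
            aucs = {}
            for h in cfg.roc_horizons:
                roc = pmod.time_dependent_roc(scores, cohort.survival, h)
                aucs[f"auc_{int(h)}"] = roc.auc
                if h == cfg.horizon:
                    model.cutoff = pmod.select_cutoff(roc)
                    roc_tab = pd.DataFrame({
                        "threshold": roc.thresholds,
                        "sensitivity": roc.sensitivity,
                        "specificity": roc.specificity,
                    })
                    write_table_tsv(roc_tab, out / "roc_curve.tsv",
                                    index_name="idx")
            summary["roc_auc"] = aucs
            summary["cutoff"] = model.cutoff
            model.to_json(out / "signature_model.json")
            groups = pmod.assign_risk_groups(scores, model.cutoff)
            write_table_tsv(
                pd.DataFrame({"risk_score": scores, "risk_group": groups}),
                out / "risk_scores.tsv",
            )
            if groups.nunique() == 2:
                lr = pmod.km_logrank(groups, cohort.survival)
                summary["logrank_p"] = lr["p"]
                for gname, curve in lr["curves"].items():
                    write_table_tsv(curve, out / f"km_{gname}.tsv",
                                    index_name="idx")
                uni = pmod.clinical_cox(cohort.survival, scores, "univariate")
                multi = pmod.clinical_cox(cohort.survival, scores, "multivariate")
                write_table_tsv(uni, out / "clinical_cox_univariate.tsv",
                                index_name="covariate")
                write_table_tsv(multi, out / "clinical_cox_multivariate.tsv",
                                index_name="covariate")
                summary["risk_score_hr_multivariate"] = float(
                    multi.loc["risk_score", "hr"]
                ) if "risk_score" in multi.index else None
                assoc = pmod.group_association_tests(
                    groups, cohort.survival, scores, seed=cfg.seed
                )
                write_table_tsv(assoc["chi_square"], out / "chi_square.tsv",
                                index_name="idx")
                write_table_tsv(assoc["score_by_stratum"],
                                out / "score_by_stratum.tsv", index_name="idx")
            else:
                summary["non_prognostic"] = True
        else:
            summary["non_prognostic"] = True
        summary["funnel"]["signature_size"] = 0 if model is None else len(model.pairs)
    except Exception as exc:
        raise StageFailure("fit", exc) from exc

    try:
        stage("cerna")
        de_m, de_list = cn.de_mrna(cohort.expr, cohort.sample_type,
                                   cfg.mrna_lfc_threshold, cfg.mrna_fdr_threshold)
        summary["funnel"]["de_mrnas"] = len(de_list)
        mirnas, predicted = cn.predict_targets(
            specific, interactions.lnc_mirna, interactions.mirna_mrna,
            consensus=cfg.consensus,
        )
        hubs = cn.hub_mrnas(predicted, de_list)
        summary["funnel"]["predicted_mrnas"] = len(predicted)
        summary["funnel"]["hub_mrnas"] = len(hubs)
        network = cn.assemble_network(hubs, interactions.lnc_mirna,
                                      interactions.mirna_mrna, cfg.consensus)
        network.to_edge_list().to_csv(out / "cerna_edges.tsv", sep="\t",
                                      index=False)
        summary["network_nodes"] = int(network.graph.number_of_nodes())
        summary["network_edges"] = int(network.graph.number_of_edges())
        enr = cn.enrichment_test(hubs, aux.gene_sets,
                                 universe=cohort.expr.mrnas())
        write_table_tsv(enr, out / "hub_enrichment.tsv", index_name="term")
    except Exception as exc:
        raise StageFailure("cerna", exc) from exc

    try:
        stage("immune")
        if groups is not None and groups.nunique() == 2:
            mrna_expr = tumor_expr.subset_genes(tumor_expr.mrnas())
            gres = ic.gsea_collection(
                mrna_expr, groups, aux.gene_sets, positive="low",
                n_perm=cfg.gsea_permutations, seed=cfg.seed,
            )
            gsea_tab = pd.DataFrame([
                {"set": name, "es": r.es, "nes": r.nes,
                 "nominal_p": r.nominal_p, "fdr_q": r.fdr_q,
                 "leading_edge_size": len(r.leading_edge)}
                for name, r in gres.items()
            ]).set_index("set")
            write_table_tsv(gsea_tab, out / "gsea.tsv", index_name="set")
            up = aux.truth["upshifted_set"]
            summary["gsea_nes_immune"] = float(gres[up].nes)
            summary["gsea_fdr_immune"] = float(gres[up].fdr_q)

            inf_diff = ic.infiltration_diff(aux.infiltration, groups)
            inf_corr = ic.infiltration_correlation(scores, aux.infiltration)
            write_table_tsv(inf_diff, out / "infiltration_diff.tsv",
                            index_name="celltype")
            write_table_tsv(inf_corr, out / "infiltration_correlation.tsv",
                            index_name="celltype")
            summary["median_infiltration_rho"] = float(inf_corr["rho"].median())

            corr = ic.gene_correlates(tumor_expr, groups,
                                      cohort.truth["checkpoints"], scores)
            write_table_tsv(corr["per_gene"], out / "checkpoint_correlates.tsv",
                            index_name="gene")
            pd1 = cohort.truth["checkpoints"][0]
            fg = ic.four_group_survival(
                groups, tumor_expr.values.loc[pd1], cohort.survival
            )
            summary["four_group_logrank_p"] = fg["p"]

            drugs = ic.drug_sensitivity_diff(aux.ic50, groups)
            write_table_tsv(drugs, out / "drug_sensitivity.tsv",
                            index_name="drug")
            summary["drug_min_p"] = float(drugs["p"].min())

            strat = pmod.stratified_analysis(
                cohort.survival, groups, scores, cfg.stratify_by
            )
            summary["strata_analyzed"] = sorted(
                k for k, v in strat.items() if "skipped" not in v
            )
    except Exception as exc:
        raise StageFailure("immune", exc) from exc

    summary = _jsonable(summary)
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return summary


def render_report(outdir) -> Path:
    """Human-readable report from a finished run's artifacts.

    Tables come straight from the stage TSVs; KM/ROC/funnel plots are drawn
    when the artifacts exist, and any missing section is skipped with a
    notice. Every figure's numbers are already on disk as TSV.
    """
    out = Path(outdir)
    summary_path = out / "summary.json"
    if not summary_path.exists():
        raise FileNotFoundError("no summary.json: run the pipeline first")
    with open(summary_path) as fh:
        summary = json.load(fh)

    lines = ["# pairlnc run report", "",
             f"config hash: {summary['config_hash']}  seed: {summary['seed']}", ""]
    lines += ["## Filtering funnel", ""]
    for key, val in summary.get("funnel", {}).items():
        lines.append(f"- {key}: {val}")
    lines.append("")

    if "roc_auc" in summary:
        lines += ["## Time-dependent ROC", ""]
        for k, v in summary["roc_auc"].items():
            lines.append(f"- {k}: {v:.3f}")
        lines.append(f"- cutoff: {summary.get('cutoff'):.4f}")
        lines.append("")
    else:
        lines += ["## Time-dependent ROC", "", "_skipped: no fitted signature_", ""]

    if "logrank_p" in summary:
        lines += ["## Risk-group survival", "",
                  f"- log-rank p: {summary['logrank_p']:.3g}", ""]
    for key, title in [("gsea_nes_immune", "GSEA immune NES"),
                       ("median_infiltration_rho", "median infiltration rho"),
                       ("drug_min_p", "smallest drug-sensitivity p")]:
        if key in summary:
            lines.append(f"- {title}: {summary[key]:.3g}")
    lines.append("")

    plots = []
    try:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        km_files = sorted(out.glob("km_*.tsv"))
        if km_files:
            fig, ax = plt.subplots(figsize=(5, 4))
            for f in km_files:
                tab = pd.read_csv(f, sep="\t")
                ax.step(tab["time"], tab["survival"], where="post",
                        label=f.stem.replace("km_", ""))
            ax.set_xlabel("time (months)")
            ax.set_ylabel("survival probability")
            ax.set_ylim(0, 1.02)
            ax.legend()
            fig.savefig(out / "km_curves.png", dpi=120, bbox_inches="tight")
            plt.close(fig)
            plots.append("km_curves.png")
        roc_file = out / "roc_curve.tsv"
        if roc_file.exists():
            tab = pd.read_csv(roc_file, sep="\t")
            fig, ax = plt.subplots(figsize=(4.5, 4.5))
            ax.plot(1 - tab["specificity"], tab["sensitivity"], marker=".")
            ax.plot([0, 1], [0, 1], ls="--", c="grey")
            ax.set_xlabel("1 - specificity")
            ax.set_ylabel("sensitivity")
            fig.savefig(out / "roc_curve.png", dpi=120, bbox_inches="tight")
            plt.close(fig)
            plots.append("roc_curve.png")
        funnel = summary.get("funnel", {})
        if funnel:
            fig, ax = plt.subplots(figsize=(6, 3.5))
            keys = list(funnel)
            ax.barh(range(len(keys)), [funnel[k] for k in keys])
            ax.set_yticks(range(len(keys)), keys)
            ax.set_xlabel("count")
            fig.savefig(out / "funnel.png", dpi=120, bbox_inches="tight")
            plt.close(fig)
            plots.append("funnel.png")
    except Exception as exc:  # plotting is best-effort
        warnings.warn(f"plot rendering skipped: {exc}")
    if plots:
        lines += ["## Figures", ""] + [f"- {p}" for p in plots] + [""]

    report = out / "report.md"
    report.write_text("\n".join(lines))
    return report
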