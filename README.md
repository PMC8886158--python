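# pairlnc

Rank-pair lncRNA prognostic signatures for tumor-infiltrating T lymphocytes.

`pairlnc` builds a survival signature for a tumor cohort out of *pairs* of
cell-type-specific long non-coding RNAs, and runs the downstream analyses
that typically accompany such a signature: a ceRNA (competing endogenous
RNA) network, immune gene-set enrichment, infiltration and checkpoint-gene
correlates, and drug-sensitivity comparisons. It is aimed at computational
biologists who want the whole chain — from an immune-cell expression panel
to risk-stratified survival curves — as tested, reusable, scriptable Python
rather than a one-off collection of R snippets. Every input can be simulated
with planted, recoverable signal, so the full pipeline runs (and is
validated) without downloading any cohort data.

## The method

1. **Cell-type-specific lncRNAs.** From a multi-cell-type immune expression
   panel (log2 scale), T-cell-specific lncRNAs are selected by moderated
   two-group differential expression at |logFC| > 1 and BH-FDR < 0.05
   (strict inequalities), after an optional per-gene batch-location
   adjustment and quantile normalization.
2. **Pair binarization.** The specific lncRNAs present in the tumor cohort
   are exhaustively paired. For each unordered pair (A, B) with A < B
   lexicographically, the feature is the within-sample indicator

   z<sub>AB</sub>(s) = 1 if expr(A, s) > expr(B, s), else 0.

   Because only the within-sample ordering of two genes matters, the
   features are invariant to any strictly increasing per-sample transform
   of expression (and hence to most normalization choices). Pairs whose
   indicator is 1 in fewer than 20% or more than 80% of samples are
   discarded (near-constant features carry no contrast).
3. **Staged survival modeling.** Pairs are screened by univariate Cox
   regression (Efron ties, Wald p < 0.01), reduced by an L1-penalized Cox
   model whose penalty is chosen by 10-fold cross-validated partial-
   likelihood deviance, and the survivors are jointly refit by multivariate
   Cox. The risk score is the linear predictor

   risk(s) = Σ<sub>k</sub> β<sub>k</sub> · z<sub>k</sub>(s).

4. **Cutoff and stratification.** A time-dependent ROC curve at a fixed
   horizon (default 3 years) is estimated with the Kaplan-Meier-based
   cumulative-case/dynamic-control estimator; the risk cutoff maximizes
   sensitivity + specificity (the Youden rule), and patients with
   score > cutoff form the high-risk group. Kaplan-Meier/log-rank,
   clinical-covariate Cox models, chi-square composition tests and
   stratified analyses assess the signature.
5. **Downstream.** Hub mRNAs are the intersection of (a) consensus miRNA
   targets reachable from the specific lncRNAs through lncRNA-miRNA and
   miRNA-mRNA interaction tables and (b) tumor-vs-normal differential mRNAs
   (rank-sum, |logFC| > 2, FDR < 0.05); they seed a tripartite ceRNA network
   and a hypergeometric term-enrichment test. Risk groups are compared by
   two-phenotype GSEA (weighted Kolmogorov-Smirnov, signal-to-noise ranking,
   phenotype permutation), per-cell-type infiltration tests and Spearman
   correlations, checkpoint-gene correlates, a four-group (risk x gene
   expression) survival analysis, and per-drug IC50 rank-sum tests.

## Worked example

```python
from pairlnc.pipeline import PipelineConfig, run_full_pipeline

cfg = PipelineConfig(outdir="pairlnc_run", seed=1)
summary = run_full_pipeline(cfg)
print(summary["funnel"])
print(summary["roc_auc"], summary["cutoff"])
```

prints (seed 1, default synthetic conditions: 300 patients, 30% censoring,
three planted pairs with β = 0.8, −0.8, 0.6):

```
{'specific_lncrnas': 15, 'hilt_lncrnas': 15, 'pairs_built': 105,
 'pairs_after_prevalence': 39, 'screen_survivors': 11,
 'lasso_survivors': 9, 'signature_size': 9, 'de_mrnas': 40,
 'predicted_mrnas': 15, 'hub_mrnas': 5}
{'auc_24': 0.7400761732006831, 'auc_36': 0.7579520543937093,
 'auc_48': 0.7311876935950343} 0.6121504583858609
```

Reading this: all 15 planted T-cell-specific lncRNAs were detected; their
105 pairs shrank to 39 after the 20–80% prevalence filter; the univariate
screen kept 11, the lasso 9, and the joint Cox fit defined a 9-pair
signature whose 2/3/4-year time-dependent AUCs are ≈0.73–0.76. The risk
cutoff 0.612 splits the cohort into groups whose survival separates at
log-rank p ≈ 6e−16 (`summary["logrank_p"]`), and all 5 planted
lncRNA–miRNA–mRNA triads resurface as hub mRNAs. `render_report(outdir)`
(or `pairlnc report --outdir ...`) turns the run directory into a Markdown
report with KM, ROC and funnel figures.

The same stages are exposed individually (`pairlnc.tcell_signature`,
`pairlnc.pair_features`, `pairlnc.prognostic_model`,
`pairlnc.cerna_network`, `pairlnc.immune_correlates`) and via the CLI:

```sh
pairlnc simulate --seed 1 --outdir sim/     # write all synthetic inputs
pairlnc run --seed 1 --outdir run/          # full pipeline + summary.json
pairlnc fit --seed 1 --horizon 36 --outdir fitdir/
pairlnc report --outdir run/
```

## Layout

- `src/pairlnc/synthetic_data.py` — seeded generators for every input
- `src/pairlnc/tcell_signature.py` — normalization, batch adjust, DE
- `src/pairlnc/pair_features.py` — pair binarization + prevalence filter
- `src/pairlnc/prognostic_model.py` — Cox screen, lasso, ROC, stratification
- `src/pairlnc/cerna_network.py` — targets, hubs, network, enrichment
- `src/pairlnc/immune_correlates.py` — GSEA, infiltration, drugs
- `src/pairlnc/pipeline.py`, `cli.py` — orchestration and CLI
- `docs/methods.md` — modeling assumptions, parameter choices, limitations
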