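# Methods notes

This note records the modeling assumptions behind `pairlnc`, the defaults
that matter, what the synthetic cohorts do and do not emulate, and the
numerical choices made where the design was genuinely open. It states no
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Pair-indicator survival model

The signature feature for a lncRNA pair (A, B), oriented A < B
lexicographically, is the within-sample binary indicator
z(s) = 1[expr(A, s) > expr(B, s)], with ties scoring 0. Each unordered pair
appears once: the reversed orientation is the exact complement wherever
there are no ties, so keeping both would feed the lasso perfectly
anti-correlated duplicate columns while adding no information. The 20–80%
prevalence filter (bounds inclusive; boundary behavior is unit-tested) then
removes near-constant indicators. Because the indicator depends only on the
ordering of two genes within one sample, the entire downstream model is
invariant to strictly increasing per-sample transforms of expression — the
property that makes pair signatures attractive across platforms.

Survival follows a proportional-hazards model on these indicators,
h(t | z) = h0(t) · exp(Σ β_k z_k). Fitting is staged:

1. univariate Cox per pair, Wald p < 0.01. Ties are handled by the Efron
   approximation throughout (the standard choice; nothing here depends on
   Breslow-vs-Efron at the simulated tie densities). The screen is a
   vectorized one-parameter Newton solver specialized to binary covariates:
   for 0/1 features the Efron sums reduce to carrier counts in the risk and
   tie sets, so thousands of pairs fit in a few array operations. It is
   validated against `lifelines` to ~1e-4 in the tests. Zero-variance
   indicators are skipped; fits drifting past |β| = 12 are flagged as
   monotone likelihood (perfect separation) and excluded with a reason.
2. L1-penalized Cox on the survivors. The penalty path comes from
   scikit-survival's coordinate descent; the penalty is chosen by 10-fold
   cross-validated held-out partial-likelihood deviance (computed with our
   own Efron log-likelihood, since the library scores by concordance). The
   deviance minimizer λ_min is the default; a one-standard-error rule is
   available (`rule="1se"`). The CV fold split is seeded and logged.
3. multivariate Cox on the selected pairs (lifelines); its coefficients are
   the signature betas. The risk score is the plain linear predictor with
   no intercept.

### Time-dependent ROC and cutoff

The ROC at horizon t uses the Kaplan-Meier cumulative-case/dynamic-control
estimator: with S the KM survival function and X the score,

- sensitivity(c, t) = (1 − S(t | X > c)) · P(X > c) / (1 − S(t)),
- specificity(c, t) = 1 − S(t | X > c) · P(X > c) / S(t).

With no censoring before t this reduces *exactly* to the empirical binary
ROC for the outcome "event by t", which is the reduction oracle used in the
tests. AUC is integrated by the trapezoidal rule walking the curve in
descending-threshold order (both coordinates are monotone along the
threshold path; re-sorting points by FPR is deliberately avoided because
floating-point noise in tied FPRs scrambles staircase corners). The curve
is not forced monotone otherwise; the estimator's known small
non-monotonicities under censoring are left visible.

The cutoff maximizes sensitivity + specificity (the Youden rule), breaking
ties toward the smallest threshold; scores exactly equal to the cutoff are
assigned to the low-risk group (strict "greater than"). The operational
cutoff rule in the source material also mentions a per-point AIC; AIC is
not defined per ROC point, so the Youden sentence is implemented as the
primary rule and the AIC phrasing is treated as an open question. The
default horizon is 3 years (36 months) — the horizon privileged for
cutoff selection — with 2/3/4-year AUCs all reported.

### Clinical covariate coding

Age numeric; sex binary (male 0, female 1); grade/stage/T/N/M mapped to
ordinal integers in their natural order. Rows with missing covariates are
dropped per fit and the remaining n is reported with each fit. Chi-square
composition tests switch to a seeded Monte-Carlo permutation p when any
expected cell count falls below 1.

## Immune-panel preprocessing

Quantile normalization maps every sample onto the cross-sample mean of
order statistics; within-sample ranks are preserved, ties receive the
interpolated target at their average rank. Idempotence and the
equal-sorted-columns postcondition hold exactly for tie-free data (the
same caveat applies to limma's `normalizeQuantiles`). Note that quantile
normalization compresses planted group shifts when a non-negligible
fraction of genes moves in one group — with strong planted signal a gene
near the distribution edge can land below the |logFC| > 1 gate. This is an
inherent property of the normalization, visible in the generator tests,
not a defect of the DE step; the pipeline applies batch adjustment before
normalization, matching the usual correct-then-normalize order.

Batch adjustment is per-gene location alignment (each batch mean shifted to
the gene's grand mean; optional scale equalization). The full
empirical-Bayes batch model is intentionally not reimplemented: the
downstream pipeline is rank-based where it matters, and at synthetic scale
the EB refinement changes nothing the tests can detect. Single-sample
batches get the mean shift only.

Differential expression uses a pooled-variance t statistic with
empirical-Bayes variance moderation by default: per-gene variances are
shrunk toward a scaled-inverse-chi-square prior fit by method of moments on
the log variances (trigamma inversion by bisection; infinite prior dof
capped at 1e6 when the observed spread is within sampling noise). This
mirrors the moderated-t behavior of limma without binding to it; an
unmoderated Welch t is available. Multiple testing is Benjamini-Hochberg
everywhere an FDR is reported, and all selection thresholds are strict
inequalities.

## ceRNA network

The target-table consensus rule defaults to "all": a (miRNA, mRNA) edge
counts only if present in every provided miRNA-target table ("any" is
available). Hub mRNAs are the sorted intersection of consensus targets and
tumor-vs-normal differential mRNAs. Network assembly back-propagates from
hubs (miRNAs targeting ≥ 1 hub under consensus, then lncRNAs bound to a
kept miRNA); hubs with no consensus miRNA and miRNAs with no upstream
lncRNA are pruned so every edge connects adjacent layers and no orphan
nodes remain. Term enrichment is the one-sided hypergeometric tail with BH
across terms. Gene identifiers are opaque strings; no symbol resolution.

## GSEA

Classic two-phenotype GSEA: genes ranked by signal-to-noise
(μ_a − μ_b)/(σ_a + σ_b) with the GSEA software's floor σ ≥ 0.2|μ|; running
sum with hit increments |metric|^p (weight exponent p = 1 by default,
configurable) and miss decrements 1/(N − N_hit); ES is the extreme running
deviation; significance by phenotype permutation with a recorded seed.
NES = ES / mean |same-sign permuted ES|; the nominal p is the same-sign
permutation tail with the +1 continuity correction. The FDR q across a
collection of sets is the BH adjustment of the nominal p-values — a
simplification of the GSEA software's pooled-NES FDR that is exact for a
single set (q = p) and conservative enough at the handful of sets used
here.

## Synthetic cohorts

The generator produces every input the pipeline consumes, with planted
truth carried alongside:

- **Immune panel**: per-gene baselines U(3, 9) on the log2 scale plus
  Gaussian noise; the first `n_specific` lncRNAs get a +`specific_logfc`
  shift in T-cell samples, so their expected logFC equals the configured
  effect exactly. Optional additive per-(gene, batch) offsets emulate batch
  structure. No probe effects, background, or count model — the pipeline is
  rank-based where that matters.
- **Tumor cohort**: lncRNA layer as above (planted-pair partners' means are
  tied so the pair indicator has prevalence Φ((μ_A − μ_B)/(√2 σ)),
  defaulting to 0.5 — safely inside the 20–80% filter). Survival times are
  Weibull-baseline proportional hazards driven by the planted pair
  indicators computed from the generated expression itself; censoring is
  independent exponential with its rate calibrated by root-finding so the
  expected censored fraction matches the configuration (±0.1 empirically at
  n ≥ 200, tested). Defaults: scale 60 months, shape 1.2, 30% censoring,
  300 patients — the real cohort's censoring structure and follow-up are
  not public, so these are the package's own choices, set once and
  configurable. Clinical covariates are drawn independently of the planted
  pairs by default (a confounding flag skews stage with risk when wanted)
  so multivariate recovery stays interpretable.
- **mRNA layer**: planted tumor-vs-normal differential mRNAs (+2.5 log2 by
  default), an immune gene-set module and four checkpoint-analogue genes
  (`PDCD1_SYN`, `CD274_SYN`, `DNMT1_SYN`, `ZC3H12D_SYN` — synthetic
  stand-ins, as the names say) whose expression rises as the true linear
  predictor falls, i.e. up-shifted in low-risk patients.
- **Interactions**: `n_planted_triads` complete lncRNA→miRNA→mRNA chains
  whose mRNA is planted-differential and present in all three target
  tables, plus decoys that each break exactly one rule (2-of-3-table
  targets, consensus targets that are not differential, chains rooted at
  non-specific lncRNAs).
- **Auxiliary tables**: infiltration scores tied to the risk predictor
  through a Gaussian copula targeting a configured Spearman ρ (default
  −0.5); two drugs with opposite planted IC50 shifts between risk halves
  and at least one null drug; a GMT with the up-shifted immune set and a
  null set.

All randomness flows from one seed through named `SeedSequence` spawns;
identical configurations are bit-identical, which the end-to-end
determinism test asserts at the byte level on the run summary.

**What passing tests show — and what they do not.** The planted-signal
tests demonstrate that each stage recovers exactly the structure the
generator encodes, under Gaussian noise, independent censoring, and clean
proportional hazards. Real cohorts add platform effects, non-proportional
hazards, informative censoring, correlated gene modules and annotation
noise that the generator deliberately omits; passing here validates the
machinery, not biological discovery on any particular dataset.

## Problem sizes

The default test-suite and acceptance sizes are chosen so the whole chain
exercises comfortably on a single CPU: 300-patient cohorts, 1000-pair null
calibrations, 10–20-seed recovery experiments, 200–1000 GSEA permutations.
All are configuration fields, and scale up linearly.

## Known limitations

- The lasso CV deviance uses per-fold held-out likelihood (not the
  "all-minus-fold" variant); at the simulated scale the two agree on the
  chosen penalty's neighborhood, and the 1-SE rule is exposed for users who
  want sparser models.
- The KM-based ROC estimator can produce locally non-monotone curves under
  heavy censoring; no isotonic correction is applied.
- GSEA FDR across sets is BH over permutation p-values, not the pooled-NES
  empirical FDR.
- The IC50 table is an input (real or synthetic); no cell-line ridge
  imputation model is included.
- No competing risks, time-varying covariates, or external-cohort
  validation utilities.
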