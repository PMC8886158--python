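"""Staged fitting of the pair-indicator prognostic signature.

Univariate Cox screening of pair features (vectorized binary-covariate
Newton solver, Efron ties), L1-penalized Cox selection with the penalty
chosen by cross-validated partial-likelihood deviance, a joint multivariate
Cox fit that fixes the signature betas, the linear risk score, a
Kaplan-Meier-estimator time-dependent ROC with a Youden cutoff, risk-group
assignment and the downstream survival / clinical association analyses.
"""

from __future__ import annotations

import warnings
from typing import Iterable

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats
from sklearn.model_selection import KFold
from sksurv.linear_model import CoxnetSurvivalAnalysis
from sksurv.util import Surv

from ._stats import binary_cox_many, cox_partial_loglik, km_survival_at
from .datatypes import PairMatrix, RocCurve, SignatureModel, validate_survival

ORDINAL_CODING = {
    "grade": ["G1", "G2", "G3", "G4"],
    "stage": ["I", "II", "III", "IV"],
    "T": ["T1", "T2", "T3", "T4"],
    "N": ["N0", "N1", "N2", "N3"],
    "M": ["M0", "M1"],
}


def _align(pm: PairMatrix, surv: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    surv = validate_survival(surv)
    common = [s for s in pm.sample_ids if s in surv.index]
    if len(common) < len(surv):
        warnings.warn("samples without pair features dropped from survival table")
    return pm.indicators[common], surv.loc[common]


# ------------------------------------------------------------------- screen

def univariate_cox_screen(
    pm: PairMatrix, surv: pd.DataFrame, alpha: float = 0.01
) -> tuple[list[str], pd.DataFrame]:
    """Single-covariate Cox fit per pair; keep Wald p < alpha.

    Constant indicators and monotone-likelihood (perfectly separating)
    pairs are excluded and reported in the returned table's ``status``
    column. Returns (retained pair keys, per-pair fit table).
    """
    ind, surv = _align(pm, surv)
    if int(surv["event"].sum()) < 2:
        raise ValueError("need at least 2 events to screen")
    X = ind.to_numpy(dtype=float)
    fit = binary_cox_many(X, surv["time"].to_numpy(), surv["event"].to_numpy())
    se = fit["se"]
    with np.errstate(over="ignore"):
        table = pd.DataFrame(
            {
                "beta": fit["beta"],
                "hr": np.exp(fit["beta"]),
                "ci_low": np.exp(fit["beta"] - 1.959963984540054 * se),
                "ci_high": np.exp(fit["beta"] + 1.959963984540054 * se),
                "wald_p": fit["p"],
            },
            index=ind.index,
        )
    status = np.where(
        fit["zero_variance"], "zero variance",
        np.where(fit["flagged"], "monotone likelihood", "ok"),
    )
    table["status"] = status
    keep = table.index[(table["status"] == "ok") & (table["wald_p"] < alpha)]
    return list(keep), table


# -------------------------------------------------------------------- lasso

def _surv_array(surv: pd.DataFrame):
    return Surv.from_arrays(surv["event"].astype(bool), surv["time"].astype(float))


def lasso_cox_select(
    candidates: PairMatrix,
    surv: pd.DataFrame,
    folds: int = 10,
    seed: int = 0,
    rule: str = "min",
    n_alphas: int = 50,
) -> tuple[list[str], dict]:
    """L1-penalized Cox path; keep pairs with nonzero coefficient at the CV-chosen penalty.

    The penalty grid comes from the full-data coordinate-descent path; each
    fold refits the path on the training split and is scored by the held-out
    Efron partial-likelihood deviance. ``rule`` picks either the deviance
    minimizer ("min") or the largest penalty within one standard error of it
    ("1se"). Returns (selected pair keys, diagnostics).
    """
    if rule not in {"min", "1se"}:
        raise ValueError("rule must be 'min' or '1se'")
    ind, surv = _align(candidates, surv)
    if ind.shape[0] < 2:
        raise ValueError("need at least 2 candidate pairs")
    X = ind.to_numpy(dtype=float).T  # samples x pairs
    y = _surv_array(surv)
    time = surv["time"].to_numpy()
    event = surv["event"].to_numpy()

    path = CoxnetSurvivalAnalysis(l1_ratio=1.0, n_alphas=n_alphas,
                                  alpha_min_ratio=0.01, fit_baseline_model=False)
    path.fit(X, y)
    alphas = np.asarray(path.alphas_)

    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    dev = np.full((folds, alphas.size), np.nan)
    for k, (tr, te) in enumerate(kf.split(X)):
        if event[tr].sum() < 2 or event[te].sum() < 1:
            continue
        fold_fit = CoxnetSurvivalAnalysis(l1_ratio=1.0, alphas=alphas,
                                          fit_baseline_model=False)
        try:
            fold_fit.fit(X[tr], y[tr])
        except (ValueError, ArithmeticError):
            continue
        coefs = fold_fit.coef_  # (p, n_alphas_fit)
        fitted_alphas = np.asarray(fold_fit.alphas_)
        for j, a in enumerate(alphas):
            jj = int(np.argmin(np.abs(fitted_alphas - a)))
            lp = X[te] @ coefs[:, jj]
            dev[k, j] = -2.0 * cox_partial_loglik(lp, time[te], event[te])
    mean_dev = np.nanmean(dev, axis=0)
    if np.all(np.isnan(mean_dev)):
        raise RuntimeError("cross-validation failed in every fold")
    j_min = int(np.nanargmin(mean_dev))
    if rule == "1se":
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            se_dev = np.nanstd(dev, axis=0, ddof=1) / np.sqrt(
                np.sum(np.isfinite(dev), axis=0).clip(min=1)
            )
        bound = mean_dev[j_min] + se_dev[j_min]
        ok = np.nonzero(mean_dev <= bound)[0]
        j_chosen = int(ok[0]) if ok.size else j_min  # alphas descend: first = largest
    else:
        j_chosen = j_min
    chosen_alpha = float(alphas[j_chosen])

    coef = path.coef_[:, j_chosen]
    selected = [ind.index[i] for i in np.nonzero(np.abs(coef) > 1e-10)[0]]
    if not selected:
        warnings.warn("lasso selected no pairs at the chosen penalty")
    info = {
        "alphas": alphas.tolist(),
        "mean_deviance": mean_dev.tolist(),
        "chosen_alpha": chosen_alpha,
        "rule": rule,
        "folds": folds,
        "seed": seed,
    }
    return selected, info


# -------------------------------------------------------- multivariate model

def multivariate_cox_fit(
    pairs: PairMatrix, surv: pd.DataFrame, extra_metadata: dict | None = None
) -> tuple[SignatureModel, pd.DataFrame]:
    """Joint Cox fit of the selected pairs; betas define the signature."""
    ind, surv = _align(pairs, surv)
    if ind.shape[0] < 1:
        raise ValueError("need at least one pair")
    if (ind.nunique(axis=1) < 2).any():
        raise ValueError("constant pair indicator in multivariate fit")
    df = ind.T.astype(float)
    df["time"] = surv["time"].astype(float)
    df["event"] = surv["event"].astype(int)
    cph = CoxPHFitter()
    cph.fit(df, duration_col="time", event_col="event")
    summ = cph.summary
    table = pd.DataFrame(
        {
            "beta": summ["coef"],
            "hr": summ["exp(coef)"],
            "ci_low": summ["exp(coef) lower 95%"],
            "ci_high": summ["exp(coef) upper 95%"],
            "wald_p": summ["p"],
        }
    )
    meta = {"n": int(len(df)), "n_events": int(df["event"].sum())}
    meta.update(extra_metadata or {})
    model = SignatureModel(
        pairs=[tuple(k.split("|", 1)) for k in ind.index],
        betas=[float(summ.loc[k, "coef"]) for k in ind.index],
        metadata=meta,
    )
    return model, table


def risk_score(model: SignatureModel, pm: PairMatrix) -> pd.Series:
    """score(s) = sum_k indicator_k(s) * beta_k (linear, no intercept)."""
    missing = [k for k in model.pair_keys if k not in pm.indicators.index]
    if missing:
        raise KeyError(f"pair matrix lacks signature pairs: {missing}")
    ind = pm.indicators.loc[model.pair_keys].to_numpy(dtype=float)
    scores = np.asarray(model.betas, dtype=float) @ ind
    return pd.Series(scores, index=pm.sample_ids, name="risk_score")


# ------------------------------------------------------- time-dependent ROC

def time_dependent_roc(scores: pd.Series, surv: pd.DataFrame, horizon: float) -> RocCurve:
    """Cumulative-case/dynamic-control ROC at ``horizon`` via Kaplan-Meier.

    The Heagerty-Lumley-Pepe estimator: with S the KM survival function,
    sensitivity(c, t) = (1 - S(t | X > c)) P(X > c) / (1 - S(t)) and
    specificity(c, t) = 1 - S(t | X > c) P(X > c) / S(t). With no censoring
    before t this reduces exactly to the empirical binary ROC for the
    outcome "event by t". AUC by the trapezoidal rule.
    """
    surv = validate_survival(surv)
    scores = scores.reindex(surv.index)
    if scores.isna().any():
        raise ValueError("scores missing for some samples")
    time = surv["time"].to_numpy(dtype=float)
    event = surv["event"].to_numpy(dtype=int)
    if not np.any((time <= horizon) & (event == 1)):
        raise ValueError(f"no events observed before horizon {horizon}")
    x = scores.to_numpy(dtype=float)

    s_t = km_survival_at(time, event, horizon)
    f_t = 1.0 - s_t
    thresholds = np.unique(x)
    sens = np.empty(thresholds.size)
    spec = np.empty(thresholds.size)
    for i, c in enumerate(thresholds):
        sel = x > c
        p_c = sel.mean()
        if p_c == 0:
            s_cond = 1.0
        else:
            s_cond = km_survival_at(time[sel], event[sel], horizon)
        joint_case = (1.0 - s_cond) * p_c      # P(T <= t, X > c)
        joint_ctrl = s_cond * p_c              # P(T > t, X > c)
        sens[i] = joint_case / f_t if f_t > 0 else np.nan
        spec[i] = 1.0 - (joint_ctrl / s_t if s_t > 0 else 0.0)
    sens = np.clip(sens, 0.0, 1.0)
    spec = np.clip(spec, 0.0, 1.0)

    # descending threshold order walks the curve from (0,0) to (1,1); both
    # coordinates are monotone along it, so no re-sorting (which float noise
    # in tied FPRs would scramble) is needed before integrating
    fpr = 1.0 - spec
    xs = np.concatenate([[0.0], fpr[::-1], [1.0]])
    ys = np.concatenate([[0.0], sens[::-1], [1.0]])
    auc = float(np.trapezoid(ys, xs))
    return RocCurve(horizon=float(horizon), thresholds=thresholds,
                    sensitivity=sens, specificity=spec, auc=auc)


def select_cutoff(roc: RocCurve) -> float:
    """Threshold maximizing sensitivity + specificity (Youden); ties -> smallest."""
    if roc.thresholds.size == 0:
        raise ValueError("empty ROC curve")
    youden = roc.sensitivity + roc.specificity
    best = np.flatnonzero(youden >= youden.max() - 1e-12)[0]
    return float(roc.thresholds[best])


def assign_risk_groups(scores: pd.Series, cutoff: float) -> pd.Series:
    """score > cutoff -> "high", else "low" (strictly greater than)."""
    if not np.isfinite(cutoff):
        raise ValueError("cutoff must be finite")
    return pd.Series(
        np.where(scores.to_numpy(dtype=float) > cutoff, "high", "low"),
        index=scores.index, name="risk_group",
    )


# ------------------------------------------------------- survival comparisons

def km_logrank(groups: pd.Series, surv: pd.DataFrame) -> dict:
    """Kaplan-Meier curves per group and the k-group log-rank test."""
    surv = validate_survival(surv)
    groups = groups.reindex(surv.index)
    if groups.isna().any():
        raise ValueError("every sample needs a group label")
    counts = groups.value_counts()
    if (counts == 0).any() or len(counts) < 2:
        raise ValueError("need >= 2 non-empty groups")
    curves = {}
    for g in sorted(counts.index):
        sel = np.asarray(groups == g)
        kmf = KaplanMeierFitter()
        kmf.fit(surv["time"][sel], surv["event"][sel], label=str(g))
        tab = kmf.survival_function_.reset_index()
        tab.columns = ["time", "survival"]
        tab["at_risk"] = [
            int((surv["time"][sel] >= t).sum()) for t in tab["time"]
        ]
        curves[str(g)] = tab
    res = multivariate_logrank_test(surv["time"], groups, surv["event"])
    return {
        "curves": curves,
        "statistic": float(res.test_statistic),
        "p": float(res.p_value),
        "df": int(len(counts) - 1),
    }


# ------------------------------------------------------------- clinical Cox

def encode_clinical(surv: pd.DataFrame, scores: pd.Series | None = None) -> pd.DataFrame:
    """Numeric coding: age as-is, sex binary, staging ordinals, plus score."""
    out = pd.DataFrame(index=surv.index)
    if "age" in surv:
        out["age"] = pd.to_numeric(surv["age"], errors="coerce")
    if "sex" in surv:
        out["sex"] = surv["sex"].map({"male": 0, "female": 1})
    for col, order in ORDINAL_CODING.items():
        if col in surv:
            out[col] = surv[col].map({lab: i + 1 for i, lab in enumerate(order)})
    if scores is not None:
        out["risk_score"] = scores.reindex(surv.index)
    return out


def clinical_cox(
    surv: pd.DataFrame,
    scores: pd.Series | None = None,
    mode: str = "multivariate",
    covariates: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Cox fits of clinical covariates (and the risk score) on survival.

    ``mode="univariate"`` fits one model per covariate; ``"multivariate"``
    one joint model. Rows with missing covariate values are dropped per fit
    (dropped counts in the ``n`` column); collinear covariates surface as a
    lifelines convergence warning/error and are reported.
    """
    if mode not in {"univariate", "multivariate"}:
        raise ValueError("mode must be 'univariate' or 'multivariate'")
    surv = validate_survival(surv)
    coded = encode_clinical(surv, scores)
    if covariates is not None:
        coded = coded[[c for c in covariates if c in coded.columns]]
    coded = coded.loc[:, coded.nunique(dropna=True) > 1]
    base = pd.concat(
        [surv[["time", "event"]].astype(float), coded], axis=1
    )

    def _fit(cols):
        df = base[["time", "event"] + cols].dropna()
        cph = CoxPHFitter(penalizer=0.0)
        cph.fit(df, duration_col="time", event_col="event")
        s = cph.summary
        return pd.DataFrame(
            {
                "beta": s["coef"],
                "hr": s["exp(coef)"],
                "ci_low": s["exp(coef) lower 95%"],
                "ci_high": s["exp(coef) upper 95%"],
                "wald_p": s["p"],
                "n": int(len(df)),
                "n_events": int(df["event"].sum()),
                "mode": mode,
            }
        )

    if mode == "univariate":
        out = []
        for col in coded.columns:
            try:
                out.append(_fit([col]))
            except Exception as exc:  # degenerate stratum fits
                warnings.warn(f"univariate Cox failed for {col}: {exc}")
        if not out:
            raise RuntimeError("no univariate Cox fit succeeded")
        return pd.concat(out)
    return _fit(list(coded.columns))


def group_association_tests(
    groups: pd.Series, clinical: pd.DataFrame, scores: pd.Series, seed: int = 0
) -> dict[str, pd.DataFrame]:
    """Risk-group vs clinical composition and score-by-stratum comparisons.

    Pearson chi-square (no continuity correction) per categorical covariate
    against the risk-group label, switching to a seeded Monte-Carlo
    permutation p when any expected cell count drops below 1; two-sided
    Mann-Whitney tests of the risk score between every pair of levels of
    each covariate.
    """
    rng = np.random.default_rng(seed)
    cat_cols = [c for c in ["sex", "grade", "stage", "T", "N", "M"] if c in clinical]
    chi_rows = []
    for col in cat_cols:
        tab = pd.crosstab(clinical[col], groups.reindex(clinical.index))
        if tab.shape[0] < 2 or tab.shape[1] < 2:
            continue
        obs = tab.to_numpy(dtype=float)
        expected = stats.contingency.expected_freq(obs)
        if (expected < 1).any():
            stat = stats.chi2_contingency(obs, correction=False)[0]
            null = _mc_chi2_null(obs, rng, 2000)
            p = float((np.sum(null >= stat - 1e-12) + 1) / (null.size + 1))
            method = "chi2-montecarlo"
        else:
            stat, p, _, _ = stats.chi2_contingency(obs, correction=False)
            method = "chi2"
        chi_rows.append({"covariate": col, "statistic": float(stat),
                         "p": float(p), "method": method})
    chi_table = pd.DataFrame(chi_rows)

    mw_rows = []
    sc = scores.reindex(clinical.index)
    for col in cat_cols:
        levels = sorted(clinical[col].dropna().unique())
        for i in range(len(levels)):
            for j in range(i + 1, len(levels)):
                a = sc[clinical[col] == levels[i]].dropna()
                b = sc[clinical[col] == levels[j]].dropna()
                if len(a) == 0 or len(b) == 0:
                    continue
                res = stats.mannwhitneyu(a, b, alternative="two-sided")
                mw_rows.append({
                    "covariate": col, "level_a": levels[i], "level_b": levels[j],
                    "statistic": float(res.statistic), "p": float(res.pvalue),
                })
    return {"chi_square": chi_table, "score_by_stratum": pd.DataFrame(mw_rows)}


def _mc_chi2_null(obs: np.ndarray, rng, n_sim: int) -> np.ndarray:
    """Permutation null of the chi-square statistic at fixed margins."""
    rows = np.repeat(np.arange(obs.shape[0]), obs.sum(axis=1).astype(int))
    cols = np.repeat(np.arange(obs.shape[1]), obs.sum(axis=0).astype(int))
    stats_out = np.empty(n_sim)
    for s in range(n_sim):
        perm = rng.permutation(cols)
        tab = np.zeros_like(obs)
        np.add.at(tab, (rows, perm), 1.0)
        exp = stats.contingency.expected_freq(tab)
        with np.errstate(divide="ignore", invalid="ignore"):
            contrib = np.where(exp > 0, (tab - exp) ** 2 / exp, 0.0)
        stats_out[s] = contrib.sum()
    return stats_out


def stratified_analysis(
    surv: pd.DataFrame,
    groups: pd.Series,
    scores: pd.Series,
    stratum: str,
    min_size: int = 20,
) -> dict[str, dict]:
    """Repeat KM/log-rank and the multivariate clinical Cox inside each stratum."""
    surv = validate_survival(surv)
    if stratum not in surv.columns:
        raise KeyError(f"no such stratum variable: {stratum}")
    out: dict[str, dict] = {}
    for level in sorted(surv[stratum].dropna().unique()):
        sel = surv.index[surv[stratum] == level]
        entry: dict = {"n": int(len(sel))}
        if len(sel) < min_size:
            entry["skipped"] = f"stratum below min size {min_size}"
            out[str(level)] = entry
            continue
        sub_surv = surv.loc[sel]
        sub_groups = groups.reindex(sel)
        try:
            if sub_groups.nunique() >= 2 and sub_surv["event"].sum() >= 1:
                entry["logrank"] = {
                    k: v for k, v in km_logrank(sub_groups, sub_surv).items()
                    if k != "curves"
                }
            cov = [c for c in ["age", "sex", "risk_score"] if c != stratum]
            entry["cox"] = clinical_cox(
                sub_surv, scores.reindex(sel), mode="multivariate", covariates=cov
            )
        except Exception as exc:
            entry["skipped"] = f"analysis failed: {exc}"
        out[str(level)] = entry
    return out
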