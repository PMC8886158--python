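"""Cox screening, lasso selection, risk scoring, ROC/cutoff and survival tests."""

import numpy as np
import pandas as pd
import pytest
from lifelines import CoxPHFitter

from pairlnc.datatypes import PairMatrix, SignatureModel
from pairlnc.prognostic_model import (assign_risk_groups, clinical_cox,
                                      group_association_tests, km_logrank,
                                      lasso_cox_select, multivariate_cox_fit,
                                      risk_score, select_cutoff,
                                      stratified_analysis, time_dependent_roc,
                                      univariate_cox_screen)


def _pm(arr, samples=None, names=None):
    arr = np.asarray(arr, dtype="int8")
    samples = samples or [f"s{j}" for j in range(arr.shape[1])]
    names = names or [f"A{i:03d}|B{i:03d}" for i in range(arr.shape[0])]
    return PairMatrix(pd.DataFrame(arr, index=names, columns=samples))


def _weibull_surv(rng, lp, scale=60.0, shape=1.2, censor_frac=0.0, samples=None):
    n = len(lp)
    u = rng.uniform(size=n)
    t = scale * (-np.log(u) / np.exp(lp)) ** (1 / shape)
    event = np.ones(n, dtype=int)
    if censor_frac > 0:
        c = rng.exponential(np.quantile(t, 1 - censor_frac), size=n)
        event = (t <= c).astype(int)
        t = np.minimum(t, c)
    samples = samples or [f"s{j}" for j in range(n)]
    return pd.DataFrame({"time": t, "event": event},
                        index=pd.Index(samples, name="sample"))


class TestUnivariateScreen:
    def test_constant_indicator_excluded(self, rng):
        n = 40
        z = rng.integers(0, 2, n)
        pm = _pm(np.vstack([z, np.ones(n)]),
                 names=["A|B", "C|D"])
        surv = _weibull_surv(rng, 0.5 * z)
        kept, table = univariate_cox_screen(pm, surv, alpha=0.5)
        assert table.loc["C|D", "status"] == "zero variance"
        assert "C|D" not in kept

    def test_matches_lifelines_fit(self, rng):
        n = 150
        z = rng.integers(0, 2, n)
        surv = _weibull_surv(rng, 0.8 * z, censor_frac=0.25)
        pm = _pm(z[None, :], samples=list(surv.index), names=["A|B"])
        _, table = univariate_cox_screen(pm, surv, alpha=1.0)
        df = pd.DataFrame({"z": z, "time": surv["time"].to_numpy(),
                           "event": surv["event"].to_numpy()})
        cph = CoxPHFitter().fit(df, "time", "event")
        assert table.loc["A|B", "beta"] == pytest.approx(
            cph.summary.loc["z", "coef"], abs=1e-4
        )
        assert table.loc["A|B", "wald_p"] == pytest.approx(
            cph.summary.loc["z", "p"], rel=1e-3
        )

    def test_true_hr2_in_wald_ci(self):
        covered = 0
        for seed in range(50):
            r = np.random.default_rng(seed)
            n = 300
            z = r.integers(0, 2, n)
            surv = _weibull_surv(r, np.log(2.0) * z, censor_frac=0.3)
            pm = _pm(z[None, :], samples=list(surv.index), names=["A|B"])
            _, tab = univariate_cox_screen(pm, surv, alpha=1.0)
            lo, hi = tab.loc["A|B", ["ci_low", "ci_high"]]
            covered += int(lo <= 2.0 <= hi)
        assert covered >= 45  # nominal 95% coverage

    def test_too_few_events_errors(self, rng):
        pm = _pm(rng.integers(0, 2, (2, 10)))
        surv = pd.DataFrame({"time": np.arange(1.0, 11.0),
                             "event": np.zeros(10, int)},
                            index=[f"s{j}" for j in range(10)])
        with pytest.raises(ValueError):
            univariate_cox_screen(pm, surv)


class TestLasso:
    def test_bad_rule_rejected(self, rng):
        pm = _pm(rng.integers(0, 2, (3, 30)))
        surv = _weibull_surv(rng, np.zeros(30))
        with pytest.raises(ValueError):
            lasso_cox_select(pm, surv, rule="median")

    def test_near_zero_penalty_matches_newton_fit(self, rng):
        """The coordinate-descent path at tiny lambda agrees with plain Cox."""
        from sksurv.linear_model import CoxnetSurvivalAnalysis
        from sksurv.util import Surv

        n = 400
        Z = rng.integers(0, 2, (3, n)).astype(float)
        lp = 0.8 * Z[0] - 0.5 * Z[1]
        surv = _weibull_surv(rng, lp)
        X = Z.T
        y = Surv.from_arrays(surv["event"].astype(bool), surv["time"])
        net = CoxnetSurvivalAnalysis(l1_ratio=1.0, alphas=[1e-6],
                                     fit_baseline_model=False)
        net.fit(X, y)
        df = pd.DataFrame(X, columns=["z0", "z1", "z2"])
        df["time"], df["event"] = surv["time"].to_numpy(), surv["event"].to_numpy()
        cph = CoxPHFitter().fit(df, "time", "event")
        np.testing.assert_allclose(
            net.coef_[:, 0], cph.summary["coef"].to_numpy(), atol=1e-3
        )

    def test_selection_subset_and_diagnostics(self, rng):
        n = 200
        Z = rng.integers(0, 2, (10, n)).astype(float)
        lp = 1.0 * Z[0] - 1.0 * Z[1]
        surv = _weibull_surv(rng, lp, censor_frac=0.2)
        pm = _pm(Z, samples=list(surv.index))
        sel, info = lasso_cox_select(pm, surv, folds=5, seed=0)
        assert set(sel) <= set(pm.indicators.index)
        assert info["chosen_alpha"] in info["alphas"]
        assert len(info["mean_deviance"]) == len(info["alphas"])


class TestMultivariateAndScore:
    def test_null_covariate_beta_near_zero(self, rng):
        n = 500
        z = rng.integers(0, 2, n)
        surv = _weibull_surv(rng, np.zeros(n))
        pm = _pm(z[None, :], samples=list(surv.index), names=["A|B"])
        model, table = multivariate_cox_fit(pm, surv)
        assert abs(model.betas[0]) < 0.1

    def test_planted_betas_recovered(self):
        ok = 0
        for seed in range(20):
            r = np.random.default_rng(seed)
            n = 500
            Z = r.integers(0, 2, (2, n)).astype(float)
            surv = _weibull_surv(r, 0.8 * Z[0] - 0.8 * Z[1], censor_frac=0.2)
            pm = _pm(Z, samples=list(surv.index))
            model, _ = multivariate_cox_fit(pm, surv)
            err = np.abs(np.array(model.betas) - np.array([0.8, -0.8]))
            ok += int((err <= 0.2).all())
        assert ok >= 16  # >= 80% of seeds within +-0.2

    def test_refit_deterministic(self, rng):
        n = 120
        Z = rng.integers(0, 2, (2, n))
        surv = _weibull_surv(rng, 0.5 * Z[0])
        pm = _pm(Z, samples=list(surv.index))
        m1, _ = multivariate_cox_fit(pm, surv)
        m2, _ = multivariate_cox_fit(pm, surv)
        assert m1.betas == m2.betas

    def test_risk_score_arithmetic_and_oracle(self, rng):
        pm = _pm([[1, 0], [1, 1]], names=["A|B", "C|D"])
        model = SignatureModel(pairs=[("A", "B"), ("C", "D")], betas=[0.5, -0.3])
        s = risk_score(model, pm)
        assert s.iloc[0] == pytest.approx(0.2)
        assert s.iloc[1] == pytest.approx(-0.3)
        zero = SignatureModel(pairs=[("A", "B")], betas=[0.0])
        assert (risk_score(zero, pm) == 0).all()
        # random matrix-vector oracle
        Z = rng.integers(0, 2, (5, 8))
        pm2 = _pm(Z)
        betas = rng.normal(size=5)
        model2 = SignatureModel(pairs=pm2.pairs, betas=list(betas))
        np.testing.assert_allclose(
            risk_score(model2, pm2).to_numpy(), betas @ Z, atol=1e-12
        )

    def test_missing_pair_named_in_error(self):
        pm = _pm([[1, 0]], names=["A|B"])
        model = SignatureModel(pairs=[("X", "Y")], betas=[1.0])
        with pytest.raises(KeyError, match="X|Y"):
            risk_score(model, pm)


class TestRocAndCutoff:
    def test_perfect_ranking_auc_one(self, rng):
        n = 30
        scores = pd.Series(np.arange(n, dtype=float),
                           index=[f"s{j}" for j in range(n)])
        # highest scores fail first, all events, horizon catches top half
        surv = pd.DataFrame(
            {"time": (n - np.arange(n)) * 1.0, "event": 1}, index=scores.index
        )
        roc = time_dependent_roc(scores, surv, horizon=n / 2)
        assert roc.auc == pytest.approx(1.0)

    def test_sign_reversal_symmetry(self, rng):
        n = 60
        scores = pd.Series(rng.normal(size=n), index=[f"s{j}" for j in range(n)])
        surv = _weibull_surv(rng, scores.to_numpy(), samples=list(scores.index))
        roc = time_dependent_roc(scores, surv, float(surv["time"].median()))
        roc_neg = time_dependent_roc(-scores, surv, float(surv["time"].median()))
        assert roc.auc == pytest.approx(1.0 - roc_neg.auc, abs=1e-9)

    def test_no_events_before_horizon_errors(self, rng):
        scores = pd.Series([1.0, 2.0, 3.0], index=["a", "b", "c"])
        surv = pd.DataFrame({"time": [10.0, 11.0, 12.0], "event": [1, 1, 1]},
                            index=["a", "b", "c"])
        with pytest.raises(ValueError):
            time_dependent_roc(scores, surv, horizon=5.0)

    def test_cutoff_perfect_separation_smallest_threshold(self):
        scores = pd.Series([1.0, 2.0, 3.0, 4.0], index=list("abcd"))
        surv = pd.DataFrame({"time": [10, 9, 1, 2], "event": [1, 1, 1, 1]},
                            index=list("abcd"), dtype=float)
        roc = time_dependent_roc(scores, surv, horizon=5.0)
        assert select_cutoff(roc) == 2.0  # smallest c with X>c = cases

    def test_cutoff_matches_grid_oracle(self, rng):
        for seed in range(10):
            r = np.random.default_rng(seed)
            n = 50
            scores = pd.Series(r.normal(size=n),
                               index=[f"s{j}" for j in range(n)])
            surv = _weibull_surv(r, scores.to_numpy(),
                                 samples=list(scores.index))
            h = float(surv["time"].median())
            roc = time_dependent_roc(scores, surv, h)
            cutoff = select_cutoff(roc)
            # brute-force grid over observed scores (no censoring => binary)
            y = (surv["time"] <= h).to_numpy().astype(int)
            x = scores.to_numpy()
            best_c, best_j = None, -np.inf
            for c in np.sort(np.unique(x)):
                pred = x > c
                sens = (pred & (y == 1)).sum() / max(y.sum(), 1)
                spec = (~pred & (y == 0)).sum() / max((y == 0).sum(), 1)
                if sens + spec > best_j + 1e-12:
                    best_j, best_c = sens + spec, c
            assert cutoff == pytest.approx(best_c)

    def test_assign_groups_boundary_and_oracle(self, rng):
        scores = pd.Series([0.9, 1.0, 1.1], index=list("abc"))
        groups = assign_risk_groups(scores, cutoff=1.0)
        assert groups.tolist() == ["low", "low", "high"]
        s = pd.Series(rng.normal(size=30), index=[f"s{j}" for j in range(30)])
        g = assign_risk_groups(s, 0.2)
        assert (g == np.where(s > 0.2, "high", "low")).all()


class TestKmLogrank:
    def test_identical_groups_statistic_zero(self):
        times = [3.0, 5.0, 7.0, 9.0]
        events = [1, 0, 1, 1]
        surv = pd.DataFrame({"time": times * 2, "event": events * 2},
                            index=[f"s{j}" for j in range(8)])
        groups = pd.Series(["a"] * 4 + ["b"] * 4, index=surv.index)
        res = km_logrank(groups, surv)
        assert res["statistic"] == pytest.approx(0.0, abs=1e-12)
        assert res["p"] == pytest.approx(1.0)

    def test_six_patient_hand_example(self):
        surv = pd.DataFrame(
            {"time": [1.0, 2.0, 3.0, 4.0, 5.0, 6.0],
             "event": [1, 1, 1, 1, 0, 1]}, index=list("abcdef")
        )
        groups = pd.Series(list("ABABAB"), index=surv.index)
        res = km_logrank(groups, surv)
        # hand O-E arithmetic: O_A=3, E_A = 1/2+2/5+1/2+1/3+1/1... computed below
        O = E = V = 0.0
        t = surv["time"].to_numpy()
        e = surv["event"].to_numpy()
        in_a = (groups == "A").to_numpy()
        for tj in np.unique(t[e == 1]):
            at = t >= tj
            d = int(((t == tj) & (e == 1)).sum())
            n_at, n1 = int(at.sum()), int((at & in_a).sum())
            O += int(((t == tj) & (e == 1) & in_a).sum())
            E += d * n1 / n_at
            if n_at > 1:
                V += d * (n1 / n_at) * (1 - n1 / n_at) * (n_at - d) / (n_at - 1)
        assert res["statistic"] == pytest.approx((O - E) ** 2 / V, rel=1e-10)
        assert res["statistic"] == pytest.approx(0.0739030023094689, rel=1e-9)

    def test_km_curves_start_at_one_nonincreasing(self, rng):
        surv = _weibull_surv(rng, rng.normal(size=40), censor_frac=0.3)
        groups = pd.Series(np.where(np.arange(40) % 2 == 0, "a", "b"),
                           index=surv.index)
        res = km_logrank(groups, surv)
        for tab in res["curves"].values():
            s = tab["survival"].to_numpy()
            assert s[0] == pytest.approx(1.0)
            assert (np.diff(s) <= 1e-12).all()

    def test_empty_group_errors(self, rng):
        surv = _weibull_surv(rng, np.zeros(10))
        groups = pd.Series("a", index=surv.index)
        with pytest.raises(ValueError):
            km_logrank(groups, surv)


class TestClinicalCox:
    @staticmethod
    def _cohort(seed=0, n=300):
        r = np.random.default_rng(seed)
        score = r.normal(size=n)
        age = np.round(r.normal(60, 10, n))
        lp = 1.0 * score + 0.02 * (age - 60)
        surv = _weibull_surv(r, lp, censor_frac=0.2)
        surv["age"] = age
        surv["sex"] = r.choice(["male", "female"], n)
        surv["grade"] = r.choice(["G1", "G2", "G3"], n)
        surv["stage"] = r.choice(["I", "II", "III", "IV"], n)
        return surv, pd.Series(score, index=surv.index)

    def test_score_is_prognostic_multivariate(self):
        surv, score = self._cohort()
        tab = clinical_cox(surv, score, mode="multivariate")
        assert tab.loc["risk_score", "hr"] > 1.0
        assert tab.loc["risk_score", "wald_p"] < 0.05

    def test_univariate_equals_multivariate_single_covariate(self):
        surv, score = self._cohort(seed=3)
        uni = clinical_cox(surv, score, mode="univariate", covariates=["age"])
        multi = clinical_cox(surv, score, mode="multivariate", covariates=["age"])
        assert uni.loc["age", "beta"] == pytest.approx(
            multi.loc["age", "beta"], rel=1e-9
        )

    def test_null_covariate_ci_coverage(self):
        covered = 0
        for seed in range(30):
            r = np.random.default_rng(seed)
            n = 200
            surv = _weibull_surv(r, np.zeros(n))
            surv["age"] = np.round(r.normal(60, 10, n))
            tab = clinical_cox(surv, None, mode="univariate", covariates=["age"])
            covered += int(tab.loc["age", "ci_low"] <= 1.0 <= tab.loc["age", "ci_high"])
        assert covered >= 24  # ~95% nominal with 30 draws

    def test_bad_mode(self):
        surv, score = self._cohort(seed=1, n=50)
        with pytest.raises(ValueError):
            clinical_cox(surv, score, mode="bayesian")


class TestGroupAssociations:
    def test_balanced_2x2_chi_square_zero(self):
        idx = [f"s{j}" for j in range(40)]
        groups = pd.Series(["high"] * 20 + ["low"] * 20, index=idx)
        clinical = pd.DataFrame(
            {"sex": (["male"] * 10 + ["female"] * 10) * 2}, index=idx
        )
        scores = pd.Series(np.linspace(0, 1, 40), index=idx)
        res = group_association_tests(groups, clinical, scores)
        row = res["chi_square"].set_index("covariate").loc["sex"]
        assert row["statistic"] == pytest.approx(0.0, abs=1e-12)
        assert row["p"] == pytest.approx(1.0)

    def test_exact_ranksum_125_vs_456(self):
        idx = [f"s{j}" for j in range(6)]
        groups = pd.Series(["x"] * 6, index=idx)
        clinical = pd.DataFrame({"grade": ["G1"] * 3 + ["G2"] * 3}, index=idx)
        scores = pd.Series([1.0, 2.0, 3.0, 4.0, 5.0, 6.0], index=idx)
        res = group_association_tests(groups, clinical, scores)
        row = res["score_by_stratum"].iloc[0]
        assert row["p"] == pytest.approx(0.1)  # two-sided exact = 2 * 1/20

    def test_chi_square_matches_textbook_formula(self, rng):
        for _ in range(10):
            idx = [f"s{j}" for j in range(120)]
            groups = pd.Series(rng.choice(["high", "low"], 120), index=idx)
            clinical = pd.DataFrame(
                {"stage": rng.choice(["I", "II", "III"], 120)}, index=idx
            )
            scores = pd.Series(rng.normal(size=120), index=idx)
            res = group_association_tests(groups, clinical, scores)
            tab = pd.crosstab(clinical["stage"], groups).to_numpy(dtype=float)
            exp = tab.sum(1, keepdims=True) @ tab.sum(0, keepdims=True) / tab.sum()
            stat = float(((tab - exp) ** 2 / exp).sum())
            row = res["chi_square"].set_index("covariate").loc["stage"]
            assert row["statistic"] == pytest.approx(stat, rel=1e-10)


class TestStratified:
    def test_single_stratum_equals_unstratified(self):
        surv, score = TestClinicalCox._cohort(seed=5, n=200)
        surv["cohort"] = "all"
        groups = assign_risk_groups(score, float(score.median()))
        out = stratified_analysis(surv, groups, score, "cohort")
        direct = clinical_cox(surv, score, mode="multivariate",
                              covariates=["age", "sex", "risk_score"])
        got = out["all"]["cox"]
        assert got.loc["risk_score", "beta"] == pytest.approx(
            direct.loc["risk_score", "beta"], rel=1e-9
        )

    def test_small_stratum_skipped(self):
        surv, score = TestClinicalCox._cohort(seed=6, n=100)
        surv["rare"] = ["tiny"] * 5 + ["big"] * 95
        groups = assign_risk_groups(score, float(score.median()))
        out = stratified_analysis(surv, groups, score, "rare", min_size=20)
        assert "skipped" in out["tiny"]
        assert "cox" in out["big"]
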