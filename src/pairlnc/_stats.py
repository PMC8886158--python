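"""Shared survival and testing numerics.

Small, heavily reused primitives: Benjamini-Hochberg adjustment, Kaplan-Meier
evaluation, the Efron-tie Cox partial likelihood for an arbitrary linear
predictor, a vectorized one-parameter Newton solver for Cox models with a
binary covariate (used to screen thousands of pair indicators at once), and
limma-style variance moderation for the moderated t-test.
"""

from __future__ import annotations

import numpy as np
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "bh_adjust",
    "km_survival_at",
    "cox_partial_loglik",
    "binary_cox_many",
    "squeeze_variances",
]


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (FDR), NaN-tolerant."""
    p = np.asarray(pvalues, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = np.isfinite(p)
    if ok.any():
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out


def km_survival_at(time, event, t: float) -> float:
    """Kaplan-Meier estimate of S(t) = P(T > t).

    Product-limit over event times <= t. With no censoring before ``t`` this
    reduces exactly to the empirical fraction of times exceeding ``t``.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if time.size == 0:
        return np.nan
    s = 1.0
    for tj in np.unique(time[(event == 1) & (time <= t)]):
        n_at_risk = np.sum(time >= tj)
        d = np.sum((time == tj) & (event == 1))
        if n_at_risk > 0:
            s *= 1.0 - d / n_at_risk
    return float(s)


def cox_partial_loglik(lp, time, event) -> float:
    """Cox log partial likelihood with the Efron tie correction.

    ``lp`` is the linear predictor (no intercept). Used to score held-out
    folds when tuning the lasso penalty.
    """
    lp = np.asarray(lp, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    theta = np.exp(lp)
    ll = 0.0
    for tj in np.unique(time[event == 1]):
        at_risk = time >= tj
        dead = (time == tj) & (event == 1)
        d = int(dead.sum())
        s_risk = theta[at_risk].sum()
        s_dead = theta[dead].sum()
        ll += lp[dead].sum()
        for ell in range(d):
            ll -= np.log(s_risk - (ell / d) * s_dead)
    return float(ll)


def _tie_structure(time, event):
    """Sort by time; return per-event-time risk/tie bookkeeping.

    Returns (order, starts, d, n_risk, dead_cols) where for event-time group
    g the risk set is the sorted suffix starting at ``starts[g]`` and
    ``dead_cols[g]`` are sorted-sample indices of its events.
    """
    order = np.argsort(time, kind="stable")
    ts = np.asarray(time, float)[order]
    es = np.asarray(event, int)[order]
    n = ts.size
    uniq = np.unique(ts[es == 1])
    starts = np.searchsorted(ts, uniq, side="left")
    dead_cols = [
        np.nonzero((ts == u) & (es == 1))[0] for u in uniq
    ]
    d = np.array([c.size for c in dead_cols])
    n_risk = n - starts
    return order, starts, d, n_risk, dead_cols


def binary_cox_many(X, time, event, max_iter=40, tol=1e-10, beta_cap=12.0):
    """Fit univariate Cox models with a single binary covariate, vectorized.

    Parameters
    ----------
    X : (n_features, n_samples) array of 0/1 indicators
    time, event : survival outcome (event 1 = observed)
    beta_cap : |beta| beyond which the fit is flagged as monotone likelihood
        (perfect separation of the partial likelihood).

    Returns
    -------
    dict of arrays keyed ``beta, se, z, p, converged, flagged`` plus a
    ``zero_variance`` mask. Efron ties throughout; for a binary covariate the
    Efron sums reduce to at-risk/dead counts of carriers, so one Newton
    iteration is a handful of (n_features x n_eventtimes) array ops.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    n_feat, n = X.shape
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if np.any(time <= 0):
        raise ValueError("survival times must be positive")

    zero_var = (X.min(axis=1) == X.max(axis=1))

    order, starts, d, n_risk, dead_cols = _tie_structure(time, event)
    Xs = X[:, order]
    # suffix sums of carriers -> carriers at risk per event time
    suffix = np.concatenate(
        [np.cumsum(Xs[:, ::-1], axis=1)[:, ::-1], np.zeros((n_feat, 1))], axis=1
    )
    nR1 = suffix[:, starts]                       # (F, G) carriers at risk
    nD1 = np.stack([Xs[:, c].sum(axis=1) for c in dead_cols], axis=1)
    G = d.size
    dG = d.astype(float)[None, :]
    nR = n_risk.astype(float)[None, :]
    nD = dG
    m1_total = nD1.sum(axis=1)                    # sum of x over all events

    beta = np.zeros(n_feat)
    converged = np.zeros(n_feat, dtype=bool)
    max_d = int(d.max()) if G else 0
    for _ in range(max_iter):
        eb = np.exp(beta)[:, None]
        U = m1_total.copy()
        I = np.zeros(n_feat)
        for ell in range(max_d):
            active = ell < d                       # groups with >= ell+1 ties
            frac = np.where(active, ell / np.maximum(d, 1), 0.0)[None, :]
            c1 = nR1 - frac * nD1                  # carrier weight in phi
            c0 = (nR - frac * nD) - c1             # non-carriers
            A = c1 * eb
            phi = c0 + A
            ratio = np.where(active[None, :], A / phi, 0.0)
            U -= ratio.sum(axis=1)
            I += (ratio - ratio**2).sum(axis=1)
        ok = I > 1e-12
        step = np.zeros(n_feat)
        step[ok] = U[ok] / I[ok]
        np.clip(step, -2.0, 2.0, out=step)
        beta = beta + np.where(zero_var, 0.0, step)
        newly = np.abs(step) < tol
        converged = newly | zero_var
        if converged.all() or np.all(np.abs(beta) > beta_cap):
            break
        beta = np.clip(beta, -beta_cap - 1, beta_cap + 1)

    flagged = (~converged) | (np.abs(beta) > beta_cap)
    # final information for the SE
    eb = np.exp(beta)[:, None]
    I = np.zeros(n_feat)
    for ell in range(max_d):
        active = ell < d
        frac = np.where(active, ell / np.maximum(d, 1), 0.0)[None, :]
        c1 = nR1 - frac * nD1
        c0 = (nR - frac * nD) - c1
        A = c1 * eb
        ratio = np.where(active[None, :], A / (c0 + A), 0.0)
        I += (ratio - ratio**2).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.where(I > 0, 1.0 / np.sqrt(I), np.inf)
        z = np.where(np.isfinite(se) & (se > 0), beta / se, 0.0)
    p = 2.0 * stats.norm.sf(np.abs(z))
    p[zero_var | flagged] = np.nan
    return {
        "beta": beta,
        "se": se,
        "z": z,
        "p": p,
        "converged": converged,
        "flagged": flagged & ~zero_var,
        "zero_variance": zero_var,
    }


def _solve_trigamma(y: float, lo=1e-4, hi=1e7) -> float:
    """Invert trigamma(x) = y by bisection (trigamma is decreasing)."""
    if y <= special.polygamma(1, hi):
        return hi
    if y >= special.polygamma(1, lo):
        return lo
    for _ in range(200):
        mid = np.sqrt(lo * hi)
        if special.polygamma(1, mid) > y:
            lo = mid
        else:
            hi = mid
    return float(np.sqrt(lo * hi))


def squeeze_variances(s2, df):
    """Empirical-Bayes shrinkage of per-gene variances toward a common prior.

    Method-of-moments fit of a scaled inverse chi-square prior on the log
    scale: Var(log s^2) = trigamma(df/2) + trigamma(d0/2), solved for the
    prior dof d0 by trigamma inversion. Returns (s2_post, d0, s0_sq); d0 is
    capped at 1e6 when the observed spread is no larger than sampling noise.
    """
    s2 = np.asarray(s2, dtype=float)
    s2 = np.maximum(s2, 1e-12)
    logs2 = np.log(s2)
    e = logs2 - special.digamma(df / 2.0) + np.log(df / 2.0)
    n = s2.size
    if n < 2:
        return s2, 0.0, float(np.mean(s2))
    excess = np.mean((e - e.mean()) ** 2) * n / (n - 1) - special.polygamma(1, df / 2.0)
    if excess <= 1e-10:
        d0 = 1e6
    else:
        d0 = 2.0 * _solve_trigamma(float(excess))
        d0 = min(d0, 1e6)
    s0_sq = float(np.exp(e.mean() + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    s2_post = (d0 * s0_sq + df * s2) / (d0 + df)
    return s2_post, d0, s0_sq
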