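"""Predictive validity: multilevel logistic models of late-stage odds.

Cases are nested in block groups; the outcome (late- vs early-stage
diagnosis) is modelled with a logistic regression carrying a
block-group Gaussian random intercept, estimated by maximizing the
Gauss-Hermite-quadrature approximation to the marginal likelihood.
Accessibility and deprivation enter as binary exposures dichotomized
at their medians, with higher accessibility and lower deprivation as
the reference categories.

Model forms, each also adjusted as noted:
  I     exposure + age
  II    exposure + age + race
  III   exposure + deprivation + age + race
  joint 4-level accessibility x deprivation factor + age + race
  stratified  form II fit separately within each deprivation stratum
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import expit, logsumexp
from statsmodels.tools.numdiff import approx_hess

from .synth import AGE_GROUPS, RACE_GROUPS

FORMS = ("I", "II", "III", "joint", "stratified")


def dichotomize_at_median(values, high_is_exposure: bool = False) -> np.ndarray:
    """Binary exposure split at the median.

    With the default orientation the exposed category (1) is *below*
    the median — lower accessibility — and values exactly at the median
    go to the reference side (0).  ``high_is_exposure=True`` flips the
    direction (used for travel times and deprivation, where larger
    values mean worse access / more deprivation); ties still go to the
    reference.
    """
    v = np.asarray(values, dtype=float)
    if np.unique(v).size < 2:
        raise ValueError("constant input cannot be dichotomized")
    med = np.median(v)
    return (v > med).astype(int) if high_is_exposure else (v < med).astype(int)


class ConvergenceError(RuntimeError):
    pass


class RandomInterceptLogit:
    """Logistic regression with a group-level Gaussian random intercept.

    The marginal log-likelihood integrates the random intercept out by
    Gauss-Hermite quadrature; the gradient is computed analytically
    from the posterior node weights, and the model is fit by L-BFGS-B
    over (beta, sigma) with sigma bounded below by zero.  Fixing
    ``var_fixed=0`` reduces the model exactly to ordinary logistic
    maximum likelihood.
    """

    def __init__(self, endog, exog, groups, n_nodes: int = 15):
        y = np.asarray(endog, dtype=float)
        X = np.asarray(exog, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        codes, _ = pd.factorize(np.asarray(groups))
        order = np.argsort(codes, kind="stable")
        self.y = y[order]
        self.X = X[order]
        self.codes = codes[order]
        self.n_groups = self.codes.max() + 1
        self.starts = np.searchsorted(self.codes, np.arange(self.n_groups))
        nodes, wts = np.polynomial.hermite.hermgauss(n_nodes)
        self.nodes = nodes
        self.log_wts = np.log(wts) - 0.5 * np.log(np.pi)

    def _loglike_grad(self, params, var_fixed=None):
        if var_fixed is None:
            beta, sigma = params[:-1], params[-1]
        else:
            beta, sigma = params, np.sqrt(var_fixed)
        eta0 = self.X @ beta
        b = np.sqrt(2.0) * sigma * self.nodes          # (Q,) intercept offsets
        eta = eta0[:, None] + b[None, :]               # (n, Q)
        ll_obs = self.y[:, None] * eta - np.logaddexp(0.0, eta)
        ll_grp = np.add.reduceat(ll_obs, self.starts, axis=0)  # (G, Q)
        ll_grp = ll_grp + self.log_wts[None, :]
        loglik = logsumexp(ll_grp, axis=1).sum()

        post = np.exp(ll_grp - logsumexp(ll_grp, axis=1, keepdims=True))  # (G, Q)
        resid = self.y[:, None] - expit(eta)           # (n, Q)
        obs_w = post[self.codes]                        # (n, Q)
        r = (obs_w * resid).sum(axis=1)                 # (n,)
        g_beta = self.X.T @ r
        if var_fixed is None:
            g_sigma = np.sqrt(2.0) * ((obs_w * resid) @ self.nodes).sum()
            grad = np.append(g_beta, g_sigma)
        else:
            grad = g_beta
        return loglik, grad

    def fit(self, var_fixed=None, start=None, maxiter: int = 500):
        k = self.X.shape[1]
        if start is None:
            start = np.zeros(k)
        if var_fixed is None:
            x0 = np.append(start, 0.5)
            bounds = [(None, None)] * k + [(0.0, 20.0)]
        else:
            x0 = np.asarray(start, dtype=float)
            bounds = [(None, None)] * k

        def negloglike(p):
            ll, g = self._loglike_grad(p, var_fixed=var_fixed)
            return -ll, -g

        res = optimize.minimize(
            negloglike, x0, jac=True, method="L-BFGS-B", bounds=bounds,
            options={"maxiter": maxiter, "ftol": 1e-12, "gtol": 1e-9},
        )
        beta = res.x[:k]
        if not res.success and np.max(np.abs(res.jac[:k])) > 1e-3:
            raise ConvergenceError(f"optimizer failed: {res.message}")
        if np.max(np.abs(beta)) > 30:
            raise ConvergenceError(
                "coefficients diverged; data are likely completely separated"
            )
        sigma = np.sqrt(var_fixed) if var_fixed is not None else res.x[-1]

        # observed-information covariance for the fixed effects; sigma is
        # profiled out at its estimate when it sits on the zero boundary
        def nll_only(p):
            return -self._loglike_grad(p, var_fixed=var_fixed)[0]

        if var_fixed is None and sigma > 1e-4:
            hess = approx_hess(res.x, nll_only)
            cov_full = np.linalg.pinv(hess)
            cov = cov_full[:k, :k]
        else:
            hess = approx_hess(
                beta, lambda b: -self._loglike_grad(b, var_fixed=sigma ** 2)[0]
            )
            cov = np.linalg.pinv(hess)

        loglik = -res.fun
        return RandomInterceptLogitResult(
            params=beta, cov=cov, sigma=float(sigma), loglik=float(loglik),
            scaled_deviance=float(-2 * loglik), nobs=len(self.y),
            n_groups=int(self.n_groups),
        )


@dataclass
class RandomInterceptLogitResult:
    params: np.ndarray
    cov: np.ndarray
    sigma: float
    loglik: float
    scaled_deviance: float
    nobs: int
    n_groups: int

    def odds_ratios(self, names) -> pd.DataFrame:
        se = np.sqrt(np.diag(self.cov))
        lo = self.params - 1.96 * se
        hi = self.params + 1.96 * se
        return pd.DataFrame(
            {"OR": np.exp(self.params), "ci_low": np.exp(lo), "ci_high": np.exp(hi),
             "log_or": self.params, "se": se},
            index=list(names),
        )


@dataclass
class ModelResult:
    form: str
    exposure: str
    terms: pd.DataFrame              # OR, ci_low, ci_high per term
    random_intercept_var: float
    scaled_deviance: float
    strata: dict | None = None       # stratified form only


def _design(cases: pd.DataFrame, columns: list[str]) -> tuple[np.ndarray, list[str]]:
    parts = [np.ones((len(cases), 1))]
    names = ["intercept"]
    for col in columns:
        if col == "age":
            for lev in AGE_GROUPS[1:]:
                parts.append((cases["age_group"] == lev).to_numpy(float)[:, None])
                names.append(f"age[{lev}]")
        elif col == "race":
            for lev in RACE_GROUPS[1:]:
                parts.append((cases["race_group"] == lev).to_numpy(float)[:, None])
                names.append(f"race[{lev}]")
        else:
            parts.append(cases[col].to_numpy(float)[:, None])
            names.append(col)
    return np.hstack(parts), names


def fit_multilevel_logistic(
    cases: pd.DataFrame,
    form: str = "II",
    exposure_col: str = "low_access",
    deprivation_col: str = "high_deprivation",
    var_fixed: float | None = None,
    n_nodes: int = 15,
) -> ModelResult:
    """Fit one predictive-validity model.

    ``cases`` must carry ``late_stage``, ``bg_id``, ``age_group``,
    ``race_group`` and the binary exposure columns named by
    ``exposure_col`` / ``deprivation_col``.
    """
    if form not in FORMS:
        raise ValueError(f"unknown form {form!r}")
    if cases["bg_id"].nunique() < 2:
        raise ValueError("need cases in at least 2 block groups")

    if form == "stratified":
        strata = {}
        for label, sub in cases.groupby(deprivation_col):
            name = "more_deprived" if label == 1 else "less_deprived"
            if sub["late_stage"].nunique() < 2:
                warnings.warn(f"stratum {name} has a single outcome class; skipped")
                continue
            strata[name] = fit_multilevel_logistic(
                sub, form="II", exposure_col=exposure_col,
                deprivation_col=deprivation_col, var_fixed=var_fixed,
                n_nodes=n_nodes,
            )
        any_fit = next(iter(strata.values()))
        return ModelResult(form="stratified", exposure=exposure_col,
                           terms=any_fit.terms,
                           random_intercept_var=any_fit.random_intercept_var,
                           scaled_deviance=any_fit.scaled_deviance,
                           strata=strata)

    work = cases.copy()
    if form == "joint":
        combo = 2 * work[deprivation_col].to_numpy(int) + work[exposure_col].to_numpy(int)
        # reference: more accessible & less deprived (0)
        levels = {1: "less_deprived:less_accessible",
                  2: "more_deprived:more_accessible",
                  3: "more_deprived:less_accessible"}
        for code, name in levels.items():
            work[name] = (combo == code).astype(int)
        X, names = _design(work, [*levels.values(), "age", "race"])
    elif form == "I":
        X, names = _design(work, [exposure_col, "age"])
    elif form == "II":
        X, names = _design(work, [exposure_col, "age", "race"])
    else:  # III
        X, names = _design(work, [exposure_col, deprivation_col, "age", "race"])

    model = RandomInterceptLogit(work["late_stage"], X, work["bg_id"], n_nodes=n_nodes)
    res = model.fit(var_fixed=var_fixed)
    return ModelResult(
        form=form,
        exposure=exposure_col,
        terms=res.odds_ratios(names),
        random_intercept_var=res.sigma ** 2,
        scaled_deviance=res.scaled_deviance,
    )


#: Measures whose raw value increases with accessibility; travel times
#: (DST, DST5) decrease, so their exposure orientation is flipped.
TIME_MEASURES = ("DST", "DST5")


def attach_exposures(
    cases: pd.DataFrame,
    access: pd.DataFrame | pd.Series,
    deprivation: pd.Series,
    measure: str | None = None,
) -> pd.DataFrame:
    """Join block-group exposures onto the case table.

    Accessibility is dichotomized at the block-group median over cases'
    block groups ... the exposure is "lower accessibility": below-median
    score, or above-median travel time for DST/DST5.  Deprivation
    exposure is above-median ("more deprived").
    """
    if isinstance(access, pd.DataFrame):
        if measure is None:
            raise ValueError("measure name required with an access table")
        score = access[measure]
    else:
        score = access
        measure = measure or str(score.name)
    low = dichotomize_at_median(score, high_is_exposure=measure in TIME_MEASURES)
    high_dep = dichotomize_at_median(deprivation, high_is_exposure=True)
    out = cases.copy()
    out["low_access"] = pd.Series(low, index=score.index).reindex(out["bg_id"]).to_numpy()
    out["high_deprivation"] = (
        pd.Series(high_dep, index=deprivation.index).reindex(out["bg_id"]).to_numpy()
    )
    if out[["low_access", "high_deprivation"]].isna().any().any():
        raise ValueError("cases reference block groups missing from the score tables")
    return out


def run_validity_suite(
    cases: pd.DataFrame,
    access: pd.DataFrame,
    deprivation: pd.Series,
    measures=None,
    forms=FORMS,
    var_fixed: float | None = None,
    n_nodes: int = 15,
) -> dict[str, dict[str, ModelResult]]:
    """Fit every form for every accessibility measure.

    Returns ``{measure: {form: ModelResult}}`` — with all nine measures
    and the five forms this is the full 45-fit battery.
    """
    measures = list(measures) if measures is not None else list(access.columns)
    out: dict[str, dict[str, ModelResult]] = {}
    for m in measures:
        tagged = attach_exposures(cases, access, deprivation, measure=m)
        out[m] = {
            f: fit_multilevel_logistic(tagged, form=f, var_fixed=var_fixed,
                                       n_nodes=n_nodes)
            for f in forms
        }
    return out


def validity_table(results: dict[str, dict[str, ModelResult]]) -> pd.DataFrame:
    """Flatten a suite into one row per measure/form/term with OR and CI."""
    rows = []
    for measure, by_form in results.items():
        for form, res in by_form.items():
            if res.strata is not None:
                for stratum, sres in res.strata.items():
                    for term, r in sres.terms.iterrows():
                        rows.append((measure, f"stratified[{stratum}]", term,
                                     r["OR"], r["ci_low"], r["ci_high"],
                                     sres.scaled_deviance))
            else:
                for term, r in res.terms.iterrows():
                    rows.append((measure, form, term, r["OR"], r["ci_low"],
                                 r["ci_high"], res.scaled_deviance))
    return pd.DataFrame(rows, columns=["measure", "form", "term", "OR",
                                       "ci_low", "ci_high", "scaled_deviance"])
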