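"""Inter-measure agreement: Spearman correlation, quartile weighted kappa.

Accessibility measures built from different principles (travel time,
density, floating catchment) need not rank block groups the same way.
This module quantifies their pairwise concordance with rank
correlations and, after quartile categorization, chance-corrected
weighted kappa with bootstrap confidence intervals and the conventional
Landis-Koch verbal scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


def spearman_matrix(table: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Spearman rank correlations with p-values.

    Ties receive average ranks.  A constant column yields NaN cells
    (flagged with a warning) since rank correlation is undefined there.
    """
    if len(table) < 3:
        raise ValueError("need at least 3 observations")
    cols = list(table.columns)
    constant = [c for c in cols if table[c].nunique() <= 1]
    if constant:
        warnings.warn(f"constant columns have undefined correlations: {constant}")
    rho = pd.DataFrame(np.eye(len(cols)), index=cols, columns=cols)
    pval = pd.DataFrame(np.zeros((len(cols), len(cols))), index=cols, columns=cols)
    for i, a in enumerate(cols):
        for j in range(i + 1, len(cols)):
            b = cols[j]
            if a in constant or b in constant:
                r, p = np.nan, np.nan
            else:
                r, p = stats.spearmanr(table[a], table[b])
            rho.loc[a, b] = rho.loc[b, a] = r
            pval.loc[a, b] = pval.loc[b, a] = p
    return rho, pval


def quartile_categorize(values) -> np.ndarray:
    """Quartile categories 1-4 (linear-interpolation quantile cuts).

    Intervals are closed on the right: a value exactly at a cut point
    falls in the lower category.
    """
    v = np.asarray(values, dtype=float)
    if np.unique(v).size < 4:
        raise ValueError("need at least 4 distinct values for quartiles")
    cuts = np.percentile(v, [25, 50, 75])  # linear interpolation
    return 1 + (v[:, None] > cuts[None, :]).sum(axis=1)


@dataclass
class KappaResult:
    kappa: float
    ci_low: float
    ci_high: float
    scheme: str
    label: str


def _kappa_stat(a: np.ndarray, b: np.ndarray, n_cat: int, w: np.ndarray) -> float:
    obs = np.zeros((n_cat, n_cat))
    np.add.at(obs, (a - 1, b - 1), 1.0)
    obs /= obs.sum()
    exp = np.outer(obs.sum(axis=1), obs.sum(axis=0))
    we = (w * exp).sum()
    if we == 0:
        return np.nan
    return 1.0 - (w * obs).sum() / we


def weighted_kappa(
    cat_a,
    cat_b,
    scheme: str = "linear",
    n_boot: int = 1000,
    seed: int | None = None,
    n_categories: int | None = None,
) -> KappaResult:
    """Weighted kappa between two ordinal categorizations.

    ``kappa = 1 - sum(w O) / sum(w E)`` with disagreement weights
    ``w_ij = |i - j|`` (linear, the default) or ``(i - j)^2``
    (quadratic); expected proportions E come from the marginal products.
    The 95% CI is a seeded nonparametric percentile bootstrap over
    paired observations.  A rater using a single category makes kappa
    undefined (NaN, flagged).
    """
    a = np.asarray(cat_a, dtype=int)
    b = np.asarray(cat_b, dtype=int)
    if a.shape != b.shape:
        raise ValueError("categorizations must have equal length")
    if a.min() < 1 or b.min() < 1:
        raise ValueError("categories must be numbered from 1")
    n_cat = n_categories or int(max(a.max(), b.max()))
    if scheme == "linear":
        idx = np.arange(n_cat)
        w = np.abs(idx[:, None] - idx[None, :]).astype(float)
    elif scheme == "quadratic":
        idx = np.arange(n_cat)
        w = (idx[:, None] - idx[None, :]).astype(float) ** 2
    else:
        raise ValueError("scheme must be 'linear' or 'quadratic'")

    if np.unique(a).size < 2 or np.unique(b).size < 2:
        warnings.warn("a rater used a single category; kappa undefined")
        return KappaResult(np.nan, np.nan, np.nan, scheme, "undefined")

    k = _kappa_stat(a, b, n_cat, w)
    rng = np.random.default_rng(seed)
    n = a.size
    boots = np.empty(n_boot)
    for r in range(n_boot):
        pick = rng.integers(0, n, n)
        boots[r] = _kappa_stat(a[pick], b[pick], n_cat, w)
    lo, hi = np.nanpercentile(boots, [2.5, 97.5])
    return KappaResult(float(k), float(lo), float(hi), scheme, interpret_kappa(k))


def interpret_kappa(kappa: float) -> str:
    """Landis-Koch verbal category for a kappa value."""
    if not -1 <= kappa <= 1:
        raise ValueError("kappa must lie in [-1, 1]")
    if kappa <= 0:
        return "no agreement"
    if kappa <= 0.20:
        return "slight agreement"
    if kappa <= 0.40:
        return "fair agreement"
    if kappa <= 0.60:
        return "moderate agreement"
    if kappa <= 0.80:
        return "substantial agreement"
    return "perfect agreement"


@dataclass
class AgreementMatrix:
    measures: list[str]
    rho: pd.DataFrame
    rho_p: pd.DataFrame
    kappa: pd.DataFrame
    kappa_ci_low: pd.DataFrame
    kappa_ci_high: pd.DataFrame
    labels: pd.DataFrame


def agreement_matrix(
    table: pd.DataFrame,
    scheme: str = "linear",
    n_boot: int = 1000,
    seed: int | None = None,
) -> AgreementMatrix:
    """Full pairwise comparison battery over the measure columns."""
    cols = list(table.columns)
    rho, rho_p = spearman_matrix(table)
    cats = {c: quartile_categorize(table[c]) for c in cols}
    kap = pd.DataFrame(np.eye(len(cols)), index=cols, columns=cols)
    lo = pd.DataFrame(np.eye(len(cols)), index=cols, columns=cols)
    hi = pd.DataFrame(np.eye(len(cols)), index=cols, columns=cols)
    lab = pd.DataFrame("", index=cols, columns=cols)
    ss = np.random.SeedSequence(seed) if seed is not None else np.random.SeedSequence()
    for i, a in enumerate(cols):
        lab.loc[a, a] = "perfect agreement"
        for j in range(i + 1, len(cols)):
            b = cols[j]
            pair_seed = int(np.random.default_rng(ss.spawn(1)[0]).integers(2 ** 31))
            res = weighted_kappa(cats[a], cats[b], scheme=scheme,
                                 n_boot=n_boot, seed=pair_seed)
            kap.loc[a, b] = kap.loc[b, a] = res.kappa
            lo.loc[a, b] = lo.loc[b, a] = res.ci_low
            hi.loc[a, b] = hi.loc[b, a] = res.ci_high
            lab.loc[a, b] = lab.loc[b, a] = res.label
    return AgreementMatrix(cols, rho, rho_p, kap, lo, hi, lab)
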