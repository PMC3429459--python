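"""Neighborhood socioeconomic deprivation index.

A composite block-group deprivation score is built from 21 census
covariates spanning education, occupation, housing, income and poverty,
racial composition, and residential stability: common factor analysis
(principal-factor extraction with varimax rotation) identifies the
deprivation factor, variables loading strongly on it are selected, their
internal consistency is checked with Cronbach's alpha, and the index is
the mean of the selected variables' z-scores, oriented so that higher
values mean more deprivation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

#: The 21 deprivation covariates, grouped by domain.
DEPRIVATION_VARIABLES = (
    # education
    "pct_less_than_high_school",
    "pct_college_degree",
    # occupation
    "pct_unemployed",
    "pct_white_collar",
    # housing
    "pct_renter_occupied",
    "pct_vacant_housing",
    "pct_crowded_housing",
    "median_home_value",
    "pct_female_headed_hh",
    "pct_public_assistance",
    "pct_no_vehicle",
    "pct_no_kitchen",
    "pct_no_phone",
    "pct_incomplete_plumbing",
    # income and poverty
    "median_family_income",
    "pct_income_4x_median",
    "pct_below_poverty",
    # racial composition
    "pct_nh_african_american",
    "pct_foreign_born",
    # residential stability
    "pct_same_house_5yr",
    "pct_age_65_plus",
)

#: Reference single-factor loading profile over the 21 covariates, used
#: as the default generating loadings of the synthetic covariate model
#: and as the fixture for the selection rule.
REFERENCE_LOADINGS = pd.Series(
    [0.46353, -0.42384, 0.79788, -0.46336, 0.58504, 0.81785, 0.61979,
     -0.19721, 0.67542, 0.81928, 0.82504, 0.10527, 0.63371, 0.20827,
     -0.42799, -0.03565, 0.86242, 0.75122, -0.19410, -0.25038, -0.15917],
    index=list(DEPRIVATION_VARIABLES),
    name="loading",
)

#: Variable whose loading anchors the orientation of the deprivation factor.
POVERTY_VARIABLE = "pct_below_poverty"

DEFAULT_SELECTION_THRESHOLD = 0.60


@dataclass
class FactorResult:
    """Outcome of the deprivation factor analysis."""

    loadings: pd.Series            # loadings of all variables on the deprivation factor
    variance_explained: float      # fraction of total variance carried by that factor
    n_factors: int                 # factors retained before rotation
    all_loadings: pd.DataFrame     # rotated loading matrix, all retained factors
    scores: pd.Series              # regression-method factor scores (oriented)
    n_iter: int


def _standardize(df: pd.DataFrame) -> pd.DataFrame:
    sd = df.std(ddof=1)
    constant = sd[sd == 0].index
    if len(constant):
        raise ValueError(f"constant columns: {list(constant)}")
    return (df - df.mean()) / sd


def _varimax(loadings: np.ndarray, max_iter: int = 200, tol: float = 1e-8) -> np.ndarray:
    """Varimax rotation with Kaiser normalization."""
    p, m = loadings.shape
    if m < 2:
        return loadings
    h = np.sqrt((loadings ** 2).sum(axis=1))
    h[h == 0] = 1.0
    A = loadings / h[:, None]
    R = np.eye(m)
    d_old = 0.0
    for _ in range(max_iter):
        L = A @ R
        u, s, vt = np.linalg.svd(
            A.T @ (L ** 3 - L @ np.diag((L ** 2).sum(axis=0)) / p)
        )
        R = u @ vt
        d = s.sum()
        if d_old != 0 and d < d_old * (1 + tol):
            break
        d_old = d
    return (A @ R) * h[:, None]


def fit_deprivation_factor(
    covariates: pd.DataFrame,
    n_factors: int | None = None,
    max_iter: int = 2000,
    tol: float = 1e-6,
) -> FactorResult:
    """Common factor analysis of the deprivation covariates.

    Principal-factor extraction: starting from squared-multiple-
    correlation communalities, the reduced correlation matrix (diagonal
    replaced by communalities) is eigendecomposed and communalities
    re-estimated until convergence.  The number of factors defaults to
    the count of reduced-matrix eigenvalues above 1 (at least one).
    Retained factors are varimax-rotated; the factor with the largest
    absolute loading on the poverty variable is taken as the deprivation
    factor and sign-flipped, if needed, so poverty loads positively.
    """
    df = covariates
    if df.shape[0] < df.shape[1] + 1:
        raise ValueError(
            f"need more block groups ({df.shape[0]}) than variables ({df.shape[1]})"
        )
    z = _standardize(df)
    corr = np.corrcoef(z.to_numpy(), rowvar=False)
    p = corr.shape[0]

    # initial communalities: squared multiple correlations
    inv = np.linalg.pinv(corr)
    h2 = 1.0 - 1.0 / np.diag(inv)
    h2 = np.clip(h2, 0.0, 0.999)

    if n_factors is None:
        red = corr.copy()
        np.fill_diagonal(red, h2)
        m = max(1, int((np.linalg.eigvalsh(red) > 1.0).sum()))
    else:
        m = int(n_factors)

    loadings = None
    change = np.inf
    for it in range(1, max_iter + 1):
        red = corr.copy()
        np.fill_diagonal(red, h2)
        vals, vecs = np.linalg.eigh(red)
        order = np.argsort(vals)[::-1][:m]
        lam = np.clip(vals[order], 0.0, None)
        loadings = vecs[:, order] * np.sqrt(lam)
        h2_new = np.clip((loadings ** 2).sum(axis=1), 0.0, 0.999)
        change = np.max(np.abs(h2_new - h2))
        h2 = h2_new
        if change < tol:
            break
    else:
        raise RuntimeError(
            f"principal-factor iteration did not converge in {max_iter} steps "
            f"(last max communality change {change:.2e})"
        )

    rotated = _varimax(loadings) if m > 1 else loadings

    pov = list(df.columns).index(POVERTY_VARIABLE) if POVERTY_VARIABLE in df.columns else int(
        np.argmax(np.abs(rotated).max(axis=1))
    )
    which = int(np.argmax(np.abs(rotated[pov, :])))
    dep = rotated[:, which].copy()
    if dep[pov] < 0:
        dep = -dep

    # regression (Thurstone) factor scores for the deprivation factor
    coef = np.linalg.solve(corr, dep)
    scores = pd.Series(z.to_numpy() @ coef, index=df.index, name="deprivation_factor")

    return FactorResult(
        loadings=pd.Series(dep, index=df.columns, name="loading"),
        variance_explained=float((dep ** 2).sum() / p),
        n_factors=m,
        all_loadings=pd.DataFrame(rotated, index=df.columns,
                                  columns=[f"factor{i+1}" for i in range(m)]),
        scores=scores,
        n_iter=it,
    )


def select_variables(
    loadings: pd.Series, threshold: float = DEFAULT_SELECTION_THRESHOLD
) -> list[str]:
    """Names of variables with ``|loading| >= threshold``."""
    if not 0 < threshold < 1:
        raise ValueError("threshold must be in (0, 1)")
    selected = list(loadings.index[loadings.abs() >= threshold])
    if not selected:
        raise ValueError(
            f"no variable reaches |loading| >= {threshold}; lower the threshold"
        )
    return selected


def cronbach_alpha(items: pd.DataFrame) -> float:
    """Cronbach's alpha of the (standardized) selected items.

    ``alpha = k/(k-1) * (1 - sum(item variances) / var(item sum))``.
    """
    if items.shape[1] < 2:
        raise ValueError("alpha needs at least two items")
    z = _standardize(items).to_numpy()
    k = z.shape[1]
    item_var = z.var(axis=0, ddof=1).sum()
    total_var = z.sum(axis=1).var(ddof=1)
    return float(k / (k - 1) * (1.0 - item_var / total_var))


def deprivation_score(
    items: pd.DataFrame, loadings: pd.Series | None = None
) -> pd.Series:
    """Composite deprivation index: mean of column z-scores.

    When ``loadings`` are supplied, each item enters with the sign of
    its loading so the composite always increases with deprivation.
    """
    z = _standardize(items)
    if loadings is not None:
        signs = np.sign(loadings.reindex(z.columns).to_numpy())
        signs[signs == 0] = 1.0
        z = z * signs
    return pd.Series(z.to_numpy().mean(axis=1), index=items.index, name="deprivation")


def build_deprivation_index(
    covariates: pd.DataFrame,
    threshold: float = DEFAULT_SELECTION_THRESHOLD,
    use_factor_scores: bool = False,
) -> dict:
    """Full pipeline: factor fit, selection, alpha, composite score."""
    fit = fit_deprivation_factor(covariates)
    selected = select_variables(fit.loadings, threshold=threshold)
    alpha = cronbach_alpha(covariates[selected])
    if use_factor_scores:
        score = fit.scores.rename("deprivation")
    else:
        score = deprivation_score(covariates[selected], fit.loadings[selected])
    return {
        "fit": fit,
        "selected": selected,
        "alpha": alpha,
        "score": score,
    }
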