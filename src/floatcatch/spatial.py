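"""Spatial autocorrelation: global and local Moran's I.

Spatial weights follow the inverse-distance convention: every pair of
units interacts, with influence decaying as a power of distance
(optionally truncated at a threshold and row-standardized).  The global
statistic summarizes map-wide clustering; the local (LISA)
decomposition classifies each unit as part of a high-high or low-low
cluster, a high-low or low-high outlier, or not significant, with
significance from seeded conditional permutations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import squareform, pdist


@dataclass
class SpatialWeights:
    """Dense spatial weight matrix with zero diagonal."""

    ids: list
    w: np.ndarray
    power: float
    threshold: float
    row_standardized: bool

    def __post_init__(self) -> None:
        if self.w.shape != (len(self.ids), len(self.ids)):
            raise ValueError("weight matrix shape does not match id list")
        if np.any(np.diag(self.w) != 0):
            raise ValueError("diagonal weights must be zero")
        if np.any(self.w < 0):
            raise ValueError("weights must be non-negative")
        isolated = ~(self.w.sum(axis=1) > 0)
        if isolated.any():
            warnings.warn(
                f"isolated units (no positive weight): {[self.ids[i] for i in np.flatnonzero(isolated)]}"
            )


def inverse_distance_weights(
    centroids: pd.DataFrame,
    power: float = 1.0,
    threshold: float = np.inf,
    row_standardize: bool = True,
) -> SpatialWeights:
    """Inverse-distance weights ``w_ij = 1 / d_ij^power`` (``d <= threshold``).

    By default every unit influences every other (no cutoff), mirroring
    the convention that all features impact one another with influence
    shrinking in distance.  Coincident centroids are an error (infinite
    weight).
    """
    xy = centroids[["x", "y"]].to_numpy(dtype=float)
    d = squareform(pdist(xy))
    off = ~np.eye(len(xy), dtype=bool)
    if np.any(d[off] == 0):
        raise ValueError("coincident centroids give infinite inverse-distance weights")
    w = np.zeros_like(d)
    mask = off & (d <= threshold)
    w[mask] = 1.0 / d[mask] ** power
    if row_standardize:
        rs = w.sum(axis=1, keepdims=True)
        rs[rs == 0] = 1.0
        w = w / rs
    return SpatialWeights(list(centroids.index), w, power, threshold, row_standardize)


def contiguity_weights(ids, pairs, row_standardize: bool = False) -> SpatialWeights:
    """Binary contiguity weights from an explicit neighbor-pair list."""
    ids = list(ids)
    pos = {u: i for i, u in enumerate(ids)}
    w = np.zeros((len(ids), len(ids)))
    for a, b in pairs:
        w[pos[a], pos[b]] = w[pos[b], pos[a]] = 1.0
    if row_standardize:
        rs = w.sum(axis=1, keepdims=True)
        rs[rs == 0] = 1.0
        w = w / rs
    return SpatialWeights(ids, w, power=0.0, threshold=np.inf,
                          row_standardized=row_standardize)


@dataclass
class GlobalMoran:
    I: float
    expected: float
    variance: float
    z: float
    p_norm: float
    ci_low: float
    ci_high: float


def global_morans_i(values, weights: SpatialWeights) -> GlobalMoran:
    """Global Moran's I with moments under the randomization assumption.

    ``I = (n / S0) * sum_ij w_ij z_i z_j / sum_i z_i^2`` with ``z`` the
    mean deviations.  ``E[I] = -1/(n-1)``; the variance uses the
    standard randomization (permutation) formula, from which a normal
    z-score and symmetric 95% CI are built.
    """
    y = np.asarray(values, dtype=float)
    w = weights.w
    n = y.size
    if n != w.shape[0]:
        raise ValueError("values do not match weights")
    z = y - y.mean()
    m2 = (z ** 2).sum()
    if m2 == 0:
        raise ValueError("constant values: spatial autocorrelation undefined")
    s0 = w.sum()
    I = n / s0 * (z @ w @ z) / m2

    e_i = -1.0 / (n - 1)
    s1 = 0.5 * ((w + w.T) ** 2).sum()
    s2 = ((w.sum(axis=1) + w.sum(axis=0)) ** 2).sum()
    b2 = n * (z ** 4).sum() / m2 ** 2
    num = (n * ((n ** 2 - 3 * n + 3) * s1 - n * s2 + 3 * s0 ** 2)
           - b2 * ((n ** 2 - n) * s1 - 2 * n * s2 + 6 * s0 ** 2))
    var = num / ((n - 1) * (n - 2) * (n - 3) * s0 ** 2) - e_i ** 2
    sd = np.sqrt(var)
    zscore = (I - e_i) / sd
    from scipy.stats import norm
    p = 2 * norm.sf(abs(zscore))
    return GlobalMoran(float(I), float(e_i), float(var), float(zscore), float(p),
                       float(I - 1.96 * sd), float(I + 1.96 * sd))


def local_morans_i(
    values,
    weights: SpatialWeights,
    n_perm: int = 999,
    alpha: float = 0.05,
    seed: int | None = None,
) -> pd.DataFrame:
    """Anselin local Moran's I with conditional-permutation significance.

    ``I_i = (z_i / m2) * sum_j w_ij z_j`` with ``m2 = sum(z^2)/n``, so
    that the local statistics sum to ``S0`` times the global I.  For
    each unit the remaining values are permuted ``n_perm`` times with
    the unit's own value held fixed; the pseudo p-value is the
    one-tailed rank of the observed statistic in the permutation
    distribution (in the direction of the observed deviation).  Units
    with pseudo-p < alpha are classified by the quadrant of
    ``(z_i, spatial lag_i)``: HH/LL clusters, HL/LH outliers; all
    others are "ns".
    """
    y = np.asarray(values, dtype=float)
    w = weights.w
    n = y.size
    z = y - y.mean()
    m2 = (z ** 2).sum() / n
    if m2 == 0:
        raise ValueError("constant values: spatial autocorrelation undefined")
    lag = w @ z
    I_loc = z * lag / m2

    rng = np.random.default_rng(seed)
    p_sim = np.empty(n)
    for i in range(n):
        others = np.delete(z, i)
        wi = np.delete(w[i], i)
        # permute the other values across the other positions (vectorized:
        # each row of `order` is an independent permutation)
        order = np.argsort(rng.random((n_perm, n - 1)), axis=1)
        sims = z[i] * (others[order] @ wi) / m2
        if I_loc[i] >= 0:
            extreme = (sims >= I_loc[i]).sum()
        else:
            extreme = (sims <= I_loc[i]).sum()
        p_sim[i] = (extreme + 1) / (n_perm + 1)

    quad = np.where(z > 0,
                    np.where(lag > 0, "HH", "HL"),
                    np.where(lag > 0, "LH", "LL"))
    cls = np.where(p_sim < alpha, quad, "ns")
    return pd.DataFrame(
        {"local_i": I_loc, "z": z, "lag": lag, "p_sim": p_sim, "cluster": cls},
        index=weights.ids,
    )
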