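"""Spatial accessibility measures: service density and 2SFCA scores.

The two-step floating catchment area (2SFCA) method scores each demand
location (census block group) by (1) computing, for every facility, the
ratio of its supply (mammography machines) to the decay-weighted demand
population whose centroids fall inside the facility's travel-time
catchment, and (2) summing those ratios, decay-weighted again, over all
facilities reachable from the block group.  With the weighting function
identically 1 this is the classic unweighted 2SFCA; stepwise zonal
weights give the "enhanced" variant and a continuous Gaussian kernel the
"Gaussian" variant.

All scores here are expressed, by default, as machines per 10,000 women
aged 40 and above (``scale=1e4``); the scale is cosmetic and
configurable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: The nine accessibility measures, in canonical column order.
MEASURES = ("DST", "DST5", "DES", "SAU", "SAC", "SA3Q", "SA3S", "SA6Q", "SA6S")

#: Default catchment limit in minutes.
DEFAULT_T0 = 30.0

#: Default reporting scale: scores per 10,000 eligible women.
DEFAULT_SCALE = 1e4

# Zonal decay weight vectors.  The 3-zone schemes use 10-minute bands,
# the 6-zone schemes 5-minute bands, spanning the 30-minute catchment.
ZONAL_3_QUICK = (1.00, 0.51, 0.07)
ZONAL_3_SLOW = (1.00, 0.75, 0.32)
ZONAL_6_QUICK = (1.00, 0.82, 0.45, 0.17, 0.04, 0.01)
ZONAL_6_SLOW = (1.00, 0.96, 0.85, 0.70, 0.53, 0.37)


@dataclass(frozen=True)
class DecaySpec:
    """Travel-time weighting function ``W(t)`` for 2SFCA scores.

    Parameters
    ----------
    kind:
        ``"none"`` (weight 1 inside the catchment), ``"zonal"``
        (stepwise weights per travel-time band) or ``"continuous"``
        (truncated, normalized Gaussian kernel).
    t0:
        Catchment limit in minutes; every kind gives weight 0 beyond it.
    zone_width:
        Band width in minutes (zonal only); ``len(weights) * zone_width``
        must equal ``t0``.
    weights:
        Per-band weights in ``(0, 1]``, non-increasing, first element 1
        (zonal only).  Band ``i`` covers the half-open interval
        ``((i-1)*zone_width, i*zone_width]`` with ``t = 0`` in band 1.
    beta:
        Gaussian bandwidth in minutes (continuous only); the kernel is
        ``(exp(-t^2 / (2 beta^2)) - exp(-t0^2 / (2 beta^2))) /
        (1 - exp(-t0^2 / (2 beta^2)))`` so that ``W(0) = 1`` and
        ``W(t0) = 0``.
    """

    kind: str
    t0: float = DEFAULT_T0
    zone_width: float | None = None
    weights: tuple[float, ...] | None = None
    beta: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("none", "zonal", "continuous"):
            raise ValueError(f"unknown decay kind {self.kind!r}")
        if self.t0 <= 0:
            raise ValueError("t0 must be positive")
        if self.kind == "zonal":
            if self.weights is None or self.zone_width is None:
                raise ValueError("zonal decay requires weights and zone_width")
            w = np.asarray(self.weights, dtype=float)
            if not np.isclose(len(w) * self.zone_width, self.t0):
                raise ValueError(
                    f"{len(w)} zones of {self.zone_width} min do not span t0={self.t0}"
                )
            if np.any(w <= 0) or np.any(w > 1):
                raise ValueError("zonal weights must lie in (0, 1]")
            if w[0] != 1.0:
                raise ValueError("first zonal weight must be 1.00")
            if np.any(np.diff(w) > 0):
                raise ValueError("zonal weights must be non-increasing")
        if self.kind == "continuous":
            if self.beta is None or self.beta <= 0:
                raise ValueError("continuous decay requires beta > 0")

    def weight(self, t) -> np.ndarray | float:
        """Evaluate ``W(t)`` elementwise for travel times ``t`` in minutes."""
        t_arr = np.asarray(t, dtype=float)
        if np.any(t_arr < 0):
            raise ValueError("travel times must be non-negative")
        inside = t_arr <= self.t0
        if self.kind == "none":
            out = inside.astype(float)
        elif self.kind == "zonal":
            w = np.asarray(self.weights, dtype=float)
            # zone(t) = ceil(t / width), with t = 0 assigned to zone 1
            zone = np.ceil(t_arr / self.zone_width).astype(int)
            zone = np.clip(zone, 1, len(w))
            out = np.where(inside, w[zone - 1], 0.0)
        else:  # continuous
            g = np.exp(-0.5 * (t_arr / self.beta) ** 2)
            g0 = np.exp(-0.5 * (self.t0 / self.beta) ** 2)
            out = np.where(inside, (g - g0) / (1.0 - g0), 0.0)
        if np.isscalar(t) or np.ndim(t) == 0:
            return float(out)
        return out


def decay_weight(t, spec: DecaySpec):
    """Weight ``W(t)`` of travel time ``t`` under ``spec`` (see DecaySpec)."""
    return spec.weight(t)


def default_decay_specs(t0: float = DEFAULT_T0, beta: float = 15.0) -> dict[str, DecaySpec]:
    """The six decay schemes behind the SA columns, keyed by measure name."""
    return {
        "SAU": DecaySpec("none", t0=t0),
        "SAC": DecaySpec("continuous", t0=t0, beta=beta),
        "SA3Q": DecaySpec("zonal", t0=t0, zone_width=t0 / 3, weights=ZONAL_3_QUICK),
        "SA3S": DecaySpec("zonal", t0=t0, zone_width=t0 / 3, weights=ZONAL_3_SLOW),
        "SA6Q": DecaySpec("zonal", t0=t0, zone_width=t0 / 6, weights=ZONAL_6_QUICK),
        "SA6S": DecaySpec("zonal", t0=t0, zone_width=t0 / 6, weights=ZONAL_6_SLOW),
    }


def _as_matrix(times: pd.DataFrame) -> pd.DataFrame:
    if not isinstance(times, pd.DataFrame):
        raise TypeError("times must be a DataFrame (block groups x facilities)")
    return times


def service_density(
    times: pd.DataFrame,
    machines: pd.Series,
    populations: pd.Series,
    t0: float = DEFAULT_T0,
    scale: float = DEFAULT_SCALE,
) -> pd.Series:
    """Service density: machines reachable within ``t0`` per capita.

    ``D_k = scale * sum_{j : t_kj <= t0} S_j / P_k`` where ``S_j`` is the
    machine count of facility ``j`` and ``P_k`` the eligible population
    of block group ``k``.
    """
    times = _as_matrix(times)
    machines = machines.reindex(times.columns)
    populations = populations.reindex(times.index)
    if machines.isna().any():
        raise ValueError("machine counts missing for some facilities")
    if populations.isna().any() or (populations <= 0).any():
        bad = populations.index[populations.isna() | (populations <= 0)]
        raise ValueError(f"non-positive or missing population for block groups {list(bad)}")
    reach = (times.to_numpy() <= t0).astype(float)
    total = reach @ machines.to_numpy(dtype=float)
    return pd.Series(scale * total / populations.to_numpy(dtype=float),
                     index=times.index, name="DES")


def two_step_fca(
    times: pd.DataFrame,
    machines: pd.Series,
    populations: pd.Series,
    spec: DecaySpec,
    scale: float = DEFAULT_SCALE,
) -> pd.Series:
    """Two-step floating catchment area accessibility score.

    Step 1 computes each facility's supply-to-weighted-demand ratio
    ``R_j = S_j / sum_{k : t_kj <= t0} W(t_kj) P_k``; step 2 sums the
    decay-weighted ratios over reachable facilities,
    ``A_k = scale * sum_{j : t_kj <= t0} W(t_kj) R_j``.

    A facility whose catchment contains no block-group centroid has an
    undefined ratio; it contributes nothing and is logged.
    """
    times = _as_matrix(times)
    machines = machines.reindex(times.columns)
    populations = populations.reindex(times.index)
    if machines.isna().any():
        raise ValueError("machine counts missing for some facilities")
    if populations.isna().any() or (populations <= 0).any():
        raise ValueError("populations must be positive for every block group")

    t = times.to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        w = np.where(np.isfinite(t), spec.weight(np.where(np.isfinite(t), t, 0.0)), 0.0)
    pop = populations.to_numpy(dtype=float)
    supply = machines.to_numpy(dtype=float)

    demand = w.T @ pop  # weighted population in each facility's catchment
    ratio = np.zeros_like(demand)
    nonempty = demand > 0
    ratio[nonempty] = supply[nonempty] / demand[nonempty]
    if not nonempty.all():
        empty = [c for c, ok in zip(times.columns, nonempty) if not ok]
        logger.info("facilities with empty catchments contribute nothing: %s", empty)

    scores = scale * (w @ ratio)
    return pd.Series(scores, index=times.index, name="SA")


def multi_year_average(tables: Sequence[pd.DataFrame]) -> pd.DataFrame:
    """Element-wise mean of per-year accessibility tables.

    Travel-time columns (DST, DST5), when present, are computed on the
    year-invariant road network and are simply carried through (they are
    identical across years by construction; a mismatch raises).
    """
    if len(tables) == 0:
        raise ValueError("need at least one yearly table")
    first = tables[0]
    for tab in tables[1:]:
        if not tab.index.equals(first.index) or list(tab.columns) != list(first.columns):
            raise ValueError("yearly tables have misaligned block groups or columns")
    stacked = np.stack([t.to_numpy(dtype=float) for t in tables])
    out = pd.DataFrame(stacked.mean(axis=0), index=first.index, columns=first.columns)
    for col in ("DST", "DST5"):
        if col in first.columns:
            vals = np.stack([t[col].to_numpy(dtype=float) for t in tables])
            if not np.allclose(vals, vals[0], equal_nan=True):
                raise ValueError(f"{col} varies across years but the network is year-invariant")
            out[col] = first[col]
    return out


def compute_all_measures(
    times: pd.DataFrame,
    machines_by_year: pd.DataFrame | pd.Series,
    populations: pd.Series,
    t0: float = DEFAULT_T0,
    scale: float = DEFAULT_SCALE,
    beta: float = 15.0,
    decay_specs: dict[str, DecaySpec] | None = None,
) -> pd.DataFrame:
    """Compute the full nine-column accessibility table.

    Parameters
    ----------
    times:
        Origin-destination travel-time matrix in minutes (block groups x
        facilities).
    machines_by_year:
        Machine counts per facility; a DataFrame with one column per
        year triggers per-year scoring followed by multi-year averaging,
        a Series scores a single year.
    populations:
        Eligible (women 40+) population per block group.
    """
    from . import travel  # local import to avoid a cycle

    if isinstance(machines_by_year, pd.Series):
        machines_by_year = machines_by_year.to_frame("y1")
    specs = decay_specs or default_decay_specs(t0=t0, beta=beta)

    yearly = []
    for year in machines_by_year.columns:
        machines = machines_by_year[year]
        tab = pd.DataFrame(index=times.index)
        tab["DES"] = service_density(times, machines, populations, t0=t0, scale=scale)
        for name, spec in specs.items():
            tab[name] = two_step_fca(times, machines, populations, spec, scale=scale)
        yearly.append(tab)
    averaged = multi_year_average(yearly)

    out = pd.DataFrame(index=times.index)
    out["DST"] = travel.dst(times)
    out["DST5"] = travel.dst5(times)
    for col in ("DES", *specs):
        out[col] = averaged[col]
    return out[list(MEASURES)]


def summarize_measures(access: pd.DataFrame) -> pd.DataFrame:
    """Distribution summary per measure: mean, SD, min, quartiles, max, IQR, range."""
    rows = {}
    for col in access.columns:
        v = access[col].to_numpy(dtype=float)
        q25, q50, q75 = np.percentile(v, [25, 50, 75])
        rows[col] = {
            "mean": v.mean(), "std": v.std(ddof=1), "min": v.min(),
            "p25": q25, "median": q50, "p75": q75, "max": v.max(),
            "iqr": q75 - q25, "range": v.max() - v.min(),
        }
    return pd.DataFrame(rows).T[["mean", "std", "min", "p25", "median", "p75",
                                 "max", "iqr", "range"]]
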