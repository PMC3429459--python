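"""Seeded synthetic study regions, deprivation covariates, and case records.

The generator emulates the statistical frame of a metropolitan
accessibility study: block groups with heterogeneous eligible
populations scattered over a square region, mammography facilities
clustered around a few urban attraction centers with per-year machine
counts, a connected planar road network giving realistic travel times,
21 deprivation covariates driven by a single latent factor, and
diagnosed cases nested in block groups whose late-stage outcome follows
a logistic model with block-group random intercepts.

Every generator is a pure function of its spec, including the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.spatial import Delaunay

from .deprivation import DEPRIVATION_VARIABLES, REFERENCE_LOADINGS

AGE_GROUPS = ("<50", "50-64", "65+")
RACE_GROUPS = ("NH-White", "African American", "Other")


@dataclass(frozen=True)
class RegionSpec:
    """Parameters of a synthetic study region.

    Distances are km, speeds km/min; populations are women aged 40+.
    """

    n_blockgroups: int = 200
    n_facilities: int = 20
    region_extent: float = 40.0          # square side, km
    network_style: str = "random-planar"  # or "grid"
    mean_speed: float = 0.8              # km/min (~48 km/h)
    pop_log_mean: float = 5.7            # lognormal: median ~300 women 40+
    pop_log_sd: float = 0.5
    machines_mean: float = 2.0           # Poisson mean, floored at 1
    n_years: int = 5
    n_attraction_centers: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_blockgroups < 3:
            raise ValueError("need at least 3 block groups")
        if self.n_facilities < 1:
            raise ValueError("need at least 1 facility")
        for name in ("region_extent", "mean_speed", "pop_log_sd", "machines_mean"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.network_style not in ("grid", "random-planar"):
            raise ValueError("network_style must be 'grid' or 'random-planar'")
        if self.n_years < 1:
            raise ValueError("n_years must be >= 1")


@dataclass(frozen=True)
class OutcomeModelSpec:
    """Logistic model generating late-stage outcomes.

    Log-odds of a late-stage diagnosis:
    ``intercept + beta_access * low_access + beta_deprivation * high_dep
    + beta_age[age] + beta_race[race] + u``, with ``u`` a per-block-group
    normal random intercept.  Exposures are the accessibility and
    deprivation scores dichotomized at their medians (low accessibility
    and high deprivation are the exposed categories).
    """

    intercept: float = -0.5
    beta_access: float = float(np.log(1.2))
    beta_deprivation: float = float(np.log(1.2))
    beta_age: tuple[float, float, float] = (0.0, 0.0, 0.0)
    beta_race: tuple[float, float, float] = (0.0, 0.0, 0.0)
    random_intercept_sd: float = 0.3
    n_cases: int = 4000
    age_probs: tuple[float, float, float] = (0.25, 0.35, 0.40)
    race_probs: tuple[float, float, float] = (0.60, 0.35, 0.05)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.random_intercept_sd < 0:
            raise ValueError("random_intercept_sd must be >= 0")
        if self.n_cases < 1:
            raise ValueError("n_cases must be >= 1")
        for probs in (self.age_probs, self.race_probs):
            if len(probs) != 3 or not np.isclose(sum(probs), 1.0):
                raise ValueError("category probabilities must be length 3 and sum to 1")


def _grid_network(spec: RegionSpec) -> nx.Graph:
    k = max(8, int(np.ceil(np.sqrt(2 * spec.n_blockgroups))))
    spacing = spec.region_extent / (k - 1)
    g = nx.Graph()
    for i in range(k):
        for j in range(k):
            g.add_node((i, j), x=i * spacing, y=j * spacing)
    minutes = spacing / spec.mean_speed
    for i in range(k):
        for j in range(k):
            if i + 1 < k:
                g.add_edge((i, j), (i + 1, j), minutes=minutes, length=spacing)
            if j + 1 < k:
                g.add_edge((i, j), (i, j + 1), minutes=minutes, length=spacing)
    return g


def _planar_network(spec: RegionSpec, rng: np.random.Generator) -> nx.Graph:
    n_nodes = max(30, 2 * spec.n_blockgroups)
    pts = rng.uniform(0, spec.region_extent, size=(n_nodes, 2))
    tri = Delaunay(pts)
    g = nx.Graph()
    for i, (x, y) in enumerate(pts):
        g.add_node(i, x=float(x), y=float(y))
    for simplex in tri.simplices:
        for a, b in ((0, 1), (1, 2), (0, 2)):
            u, v = int(simplex[a]), int(simplex[b])
            length = float(np.hypot(*(pts[u] - pts[v])))
            g.add_edge(u, v, minutes=length / spec.mean_speed, length=length)
    return g


def generate_region(
    spec: RegionSpec, max_retries: int = 5
) -> tuple[pd.DataFrame, pd.DataFrame, nx.Graph]:
    """Generate (block-group table, facility table, road network).

    Block groups get distinct uniform centroids and integer lognormal
    populations (>= 1).  Facilities cluster around a small number of
    attraction centers and carry an integer machine count >= 1 for each
    year (a base Poisson draw, perturbed by +/-1 with small probability
    across years).  The network is connected; a disconnected draw is
    regenerated up to ``max_retries`` times before failing.
    """
    rng = np.random.default_rng(spec.seed)

    network = None
    for attempt in range(max_retries):
        cand = _grid_network(spec) if spec.network_style == "grid" else _planar_network(spec, rng)
        if nx.is_connected(cand):
            network = cand
            break
    if network is None:
        raise RuntimeError(
            f"could not generate a connected network in {max_retries} attempts"
        )

    bg_xy = rng.uniform(0, spec.region_extent, size=(spec.n_blockgroups, 2))
    pops = np.maximum(
        1, np.round(rng.lognormal(spec.pop_log_mean, spec.pop_log_sd, spec.n_blockgroups))
    ).astype(int)
    blockgroups = pd.DataFrame(
        {"x": bg_xy[:, 0], "y": bg_xy[:, 1], "population": pops},
        index=pd.Index([f"bg{i:04d}" for i in range(spec.n_blockgroups)], name="bg_id"),
    )

    # facilities scatter around urban attraction centers
    centers = rng.uniform(
        0.25 * spec.region_extent, 0.75 * spec.region_extent,
        size=(spec.n_attraction_centers, 2),
    )
    which = rng.integers(0, spec.n_attraction_centers, spec.n_facilities)
    fac_xy = centers[which] + rng.normal(0, spec.region_extent / 10, (spec.n_facilities, 2))
    fac_xy = np.clip(fac_xy, 0, spec.region_extent)

    base = np.maximum(1, rng.poisson(spec.machines_mean, spec.n_facilities))
    machines = np.empty((spec.n_facilities, spec.n_years), dtype=int)
    for y in range(spec.n_years):
        jitter = rng.choice([-1, 0, 1], size=spec.n_facilities, p=[0.05, 0.90, 0.05])
        machines[:, y] = np.maximum(1, base + jitter)
    facilities = pd.DataFrame(
        {"x": fac_xy[:, 0], "y": fac_xy[:, 1]},
        index=pd.Index([f"fac{i:03d}" for i in range(spec.n_facilities)], name="fac_id"),
    )
    for y in range(spec.n_years):
        facilities[f"machines_y{y + 1}"] = machines[:, y]

    return blockgroups, facilities, network


def machine_columns(facilities: pd.DataFrame) -> pd.DataFrame:
    """Per-year machine counts (facility x year) from a facility table."""
    cols = [c for c in facilities.columns if c.startswith("machines_")]
    if not cols:
        raise ValueError("facility table has no machines_* columns")
    return facilities[cols]


def generate_deprivation_covariates(
    blockgroups: pd.DataFrame,
    loadings: pd.Series | None = None,
    noise_sd="unit",
    seed: int = 0,
) -> pd.DataFrame:
    """Single-latent-factor covariates for the 21 deprivation variables.

    Each block group draws one standard-normal latent deprivation factor
    ``f``; covariate ``i`` is ``loading_i * f + noise``.  With
    ``noise_sd="unit"`` the noise standard deviation is
    ``sqrt(1 - loading_i^2)`` so every covariate has unit total
    variance; a positive scalar applies uniformly.
    """
    if loadings is None:
        loadings = REFERENCE_LOADINGS
    lam = loadings.reindex(list(DEPRIVATION_VARIABLES))
    if lam.isna().any():
        raise ValueError("loadings must cover all 21 deprivation variables")
    lam = lam.to_numpy(dtype=float)
    if np.any(np.abs(lam) > 1):
        raise ValueError("loadings must lie in [-1, 1]")
    if isinstance(noise_sd, str):
        if noise_sd != "unit":
            raise ValueError("noise_sd must be a positive number or 'unit'")
        sd = np.sqrt(1.0 - lam ** 2)
    else:
        if noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        sd = np.full(lam.shape, float(noise_sd))

    rng = np.random.default_rng(seed)
    n = len(blockgroups)
    factor = rng.standard_normal(n)
    noise = rng.standard_normal((n, len(lam))) * sd
    data = factor[:, None] * lam + noise
    out = pd.DataFrame(data, index=blockgroups.index, columns=list(DEPRIVATION_VARIABLES))
    out.attrs["latent_factor"] = pd.Series(factor, index=blockgroups.index)
    return out


def generate_cases(
    blockgroups: pd.DataFrame,
    access_score: pd.Series,
    deprivation_score: pd.Series,
    spec: OutcomeModelSpec,
) -> pd.DataFrame:
    """Simulate diagnosed cases nested in block groups.

    Cases are assigned to block groups multinomially in proportion to
    population; age and race follow the spec's marginals; the late-stage
    indicator is Bernoulli with log-odds from the spec's logistic model
    (exposures dichotomized at their median over block groups) plus a
    per-block-group Gaussian random intercept.
    """
    pop = blockgroups["population"].to_numpy(dtype=float)
    if pop.sum() <= 0:
        raise ValueError("all block-group populations are zero")
    access_score = access_score.reindex(blockgroups.index)
    deprivation_score = deprivation_score.reindex(blockgroups.index)
    if access_score.isna().any() or deprivation_score.isna().any():
        raise ValueError("score vectors must align with the block-group table")

    # exposure indicators at the block-group level
    low_access = (access_score < access_score.median()).to_numpy()
    high_dep = (deprivation_score.to_numpy()
                > np.median(deprivation_score.to_numpy()))

    rng = np.random.default_rng(spec.seed)
    counts = rng.multinomial(spec.n_cases, pop / pop.sum())
    bg_idx = np.repeat(np.arange(len(blockgroups)), counts)
    u = rng.normal(0.0, spec.random_intercept_sd, len(blockgroups))

    age = rng.choice(len(AGE_GROUPS), size=spec.n_cases, p=spec.age_probs)
    race = rng.choice(len(RACE_GROUPS), size=spec.n_cases, p=spec.race_probs)

    eta = (
        spec.intercept
        + spec.beta_access * low_access[bg_idx]
        + spec.beta_deprivation * high_dep[bg_idx]
        + np.asarray(spec.beta_age)[age]
        + np.asarray(spec.beta_race)[race]
        + u[bg_idx]
    )
    late = (rng.uniform(size=spec.n_cases) < 1.0 / (1.0 + np.exp(-eta))).astype(int)

    return pd.DataFrame(
        {
            "bg_id": blockgroups.index.to_numpy()[bg_idx],
            "age_group": np.asarray(AGE_GROUPS)[age],
            "race_group": np.asarray(RACE_GROUPS)[race],
            "late_stage": late,
        },
        index=pd.Index([f"case{i:06d}" for i in range(spec.n_cases)], name="case_id"),
    )
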