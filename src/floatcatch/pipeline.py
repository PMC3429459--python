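"""End-to-end orchestration: simulate -> travel -> access -> deprivation
-> agreement -> spatial stats -> validity, from one config and one seed.

Each stage draws its seed deterministically from the master seed and the
stage name, so re-running any stage (or the whole pipeline) with the
same config is byte-reproducible and independent of execution order.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as fio
from .access import DEFAULT_SCALE, DEFAULT_T0, MEASURES, compute_all_measures, summarize_measures
from .agreement import agreement_matrix
from .deprivation import build_deprivation_index
from .spatial import global_morans_i, inverse_distance_weights, local_morans_i
from .synth import (OutcomeModelSpec, RegionSpec, generate_cases,
                    generate_deprivation_covariates, generate_region,
                    machine_columns)
from .travel import od_matrix
from .validity import run_validity_suite, validity_table

logger = logging.getLogger(__name__)

STAGES = ("simulate", "covariates", "cases", "agreement", "spatial", "validity")


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic sub-seed: SHA-256 of (master seed, stage name)."""
    digest = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2 ** 31)


@dataclass
class RunConfig:
    region: RegionSpec = field(default_factory=RegionSpec)
    outcome: OutcomeModelSpec = field(default_factory=OutcomeModelSpec)
    t0: float = DEFAULT_T0
    scale: float = DEFAULT_SCALE
    beta: float = 15.0
    kappa_scheme: str = "linear"
    n_boot: int = 1000
    moran_power: float = 1.0
    n_perm: int = 999
    alpha: float = 0.05
    validity_measures: tuple | None = None  # None = all nine
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        region = RegionSpec(**raw.pop("region", {}))
        outcome = OutcomeModelSpec(**raw.pop("outcome", {}))
        return cls(region=region, outcome=outcome, **raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def _config_hash(config: RunConfig) -> str:
    blob = json.dumps(config.to_dict(), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_all(config: RunConfig, out_dir) -> dict:
    """Run the full pipeline and persist every table; returns the manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "stage_seeds": {s: stage_seed(config.seed, s) for s in STAGES},
        "versions": _versions(),
        "stages": {},
    }

    current = {"stage": None}

    def _stage(name):
        current["stage"] = name
        logger.info("stage %s", name)
        return time.perf_counter()

    def _done(name, t0, **info):
        logger.info("stage %s finished in %.2fs", name, time.perf_counter() - t0)
        manifest["stages"][name] = info

    try:
        # --- simulate ---------------------------------------------------
        t = _stage("simulate")
        region = dataclasses.replace(config.region,
                                     seed=stage_seed(config.seed, "simulate"))
        blockgroups, facilities, network = generate_region(region)
        blockgroups.to_csv(out / "blockgroups.csv")
        fio.write_facilities_long(facilities, out / "facilities.csv")
        fio.write_network(network, out / "network_edges.csv", out / "network_nodes.csv")
        _done("simulate", t, n_blockgroups=len(blockgroups),
              n_facilities=len(facilities))

        # --- travel + access --------------------------------------------
        t = _stage("access")
        times = od_matrix(network, blockgroups, facilities)
        fio.write_od_long(times, out / "od_times.csv")
        access = compute_all_measures(times, machine_columns(facilities),
                                      blockgroups["population"],
                                      t0=config.t0, scale=config.scale,
                                      beta=config.beta)
        access.to_csv(out / "access.csv")
        summarize_measures(access).to_csv(out / "access_summary.csv")
        _done("access", t)

        # --- deprivation -------------------------------------------------
        t = _stage("covariates")
        covariates = generate_deprivation_covariates(
            blockgroups, seed=stage_seed(config.seed, "covariates"))
        covariates.to_csv(out / "deprivation_covariates.csv")
        dep = build_deprivation_index(covariates)
        dep["score"].to_csv(out / "deprivation_score.csv")
        (out / "deprivation.json").write_text(json.dumps({
            "loadings": dep["fit"].loadings.round(6).to_dict(),
            "variance_explained": round(dep["fit"].variance_explained, 6),
            "selected": dep["selected"],
            "alpha": round(dep["alpha"], 6),
        }, sort_keys=True, indent=1))
        _done("covariates", t, n_selected=len(dep["selected"]))

        # --- agreement ---------------------------------------------------
        t = _stage("agreement")
        agree = agreement_matrix(access, scheme=config.kappa_scheme,
                                 n_boot=config.n_boot,
                                 seed=stage_seed(config.seed, "agreement"))
        agree.rho.round(6).to_csv(out / "spearman.csv")
        agree.kappa.round(6).to_csv(out / "kappa.csv")
        (out / "kappa.json").write_text(json.dumps({
            a: {b: {"kappa": round(float(agree.kappa.loc[a, b]), 4),
                    "ci": [round(float(agree.kappa_ci_low.loc[a, b]), 4),
                           round(float(agree.kappa_ci_high.loc[a, b]), 4)],
                    "label": agree.labels.loc[a, b]}
                for b in agree.measures if b != a}
            for a in agree.measures}, sort_keys=True, indent=1))
        _done("agreement", t)

        # --- spatial -----------------------------------------------------
        t = _stage("spatial")
        weights = inverse_distance_weights(blockgroups, power=config.moran_power)
        global_res = {}
        local_frames = {}
        for m in MEASURES:
            g = global_morans_i(access[m], weights)
            global_res[m] = {"I": round(g.I, 6), "expected": round(g.expected, 6),
                             "variance": round(g.variance, 9), "z": round(g.z, 4),
                             "ci": [round(g.ci_low, 6), round(g.ci_high, 6)]}
            loc = local_morans_i(access[m], weights, n_perm=config.n_perm,
                                 alpha=config.alpha,
                                 seed=stage_seed(config.seed, f"spatial:{m}"))
            local_frames[m] = loc["cluster"]
        (out / "moran_global.json").write_text(
            json.dumps(global_res, sort_keys=True, indent=1))
        local = pd.DataFrame(local_frames)
        local.to_csv(out / "moran_local.csv")
        fio.write_blockgroups_geojson(blockgroups, out / "blockgroups.geojson",
                                      extra=local)
        _done("spatial", t)

        # --- cases + validity ---------------------------------------------
        t = _stage("validity")
        outcome = dataclasses.replace(config.outcome,
                                      seed=stage_seed(config.seed, "cases"))
        cases = generate_cases(blockgroups, access["SA6Q"], dep["score"], outcome)
        cases.to_csv(out / "cases.csv")
        measures = (list(config.validity_measures)
                    if config.validity_measures else list(MEASURES))
        suite = run_validity_suite(cases, access, dep["score"], measures=measures)
        table = validity_table(suite)
        table.round(6).to_csv(out / "validity.csv", index=False)
        _done("validity", t, n_fits=int(table[["measure", "form"]]
                                        .drop_duplicates().shape[0]))
    except Exception as exc:
        manifest["failed_stage"] = current["stage"]
        (out / "manifest.json").write_text(json.dumps(manifest, sort_keys=True, indent=1))
        raise

    (out / "manifest.json").write_text(json.dumps(manifest, sort_keys=True, indent=1))
    return manifest


def _versions() -> dict:
    import networkx
    import scipy
    import statsmodels

    from . import __version__

    return {
        "floatcatch": __version__,
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "pandas": pd.__version__,
        "networkx": networkx.__version__,
        "statsmodels": statsmodels.__version__,
    }
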