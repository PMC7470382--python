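"""Scenario configuration and pipeline orchestration.

Binds the regimen builder, population simulator, exposure metrics and
poisoning analysis into reproducible end-to-end runs.  Configs are
plain YAML key-value files with units embedded in the field names
(``cl_f_l_per_h`` etc.); every output bundle embeds the seed, a config
hash, and the package version so a run can be verified by rerunning.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .exposure import (
    EC50Spec,
    SAFETY_THRESHOLD_UM,
    fraction_exceeding,
    scale_ec50_to_blood,
    summarize_population,
)
from .formulation import (
    FORMULATIONS,
    build_prophylaxis_schedule,
    build_treatment_schedule,
)
from .poisoning import (
    DEFAULT_BIN_EDGES,
    binned_mortality,
    load_cohort,
    mortality_above,
    zero_death_threshold,
)
from .poppk import (
    PKParameters,
    PopulationSpec,
    apply_renal_impairment,
    simulate_population,
)

__all__ = ["RunConfig", "load_pk_config", "run_scenario", "run_poisoning", "SCENARIOS"]

SCENARIOS = (
    "treatment-7d",
    "treatment-10d",
    "prophylaxis-90d",
    "renal-treatment",
    "renal-prophylaxis",
    "renal-half-maintenance",
)

# In vitro EC50s (uM, plasma-equivalent) reported for SARS-CoV-2.
EC50_INVITRO = {"chloroquine": 1.13, "hydroxychloroquine": 0.72}

_PK_KEYS = {
    "cl_f_l_per_h": "cl_f",
    "vc_f_l": "vc_f",
    "q_f_l_per_h": "q_f",
    "vp_f_l": "vp_f",
    "q2_f_l_per_h": "q2_f",
    "vp2_f_l": "vp2_f",
    "ka_per_h": "ka",
    "tlag_h": "tlag",
    "f_rel": "f_rel",
    "n_peripheral": "n_peripheral",
    "renal_fraction": "renal_fraction",
    "blood_plasma_ratio": "blood_plasma_ratio",
    "mw_base_g_per_mol": "mw_base",
}


@dataclass(frozen=True)
class RunConfig:
    """One dosing-simulation scenario.

    ``scenario`` selects regimen and renal handling; ``strategy`` is the
    dosing rule (flat / weight_loading / weight_both); ``weights`` the
    body weights (kg) simulated (a scalar replicates one weight for all
    subjects).
    """

    scenario: str
    drug: str = "chloroquine"
    strategy: str = "flat"
    weights: tuple[float, ...] | float = 62.0
    pk_file: str | Path | None = None
    n_subjects: int = 1000
    omega: float = 0.30
    seed: int | None = None
    out_dir: str | Path = "quinpk-output"

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}; expected one of {SCENARIOS}")
        if self.drug not in FORMULATIONS:
            raise ValueError(f"unknown drug {self.drug!r}")
        if self.pk_file is not None and not Path(self.pk_file).exists():
            raise FileNotFoundError(self.pk_file)
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")


def load_pk_config(path: str | Path) -> PKParameters:
    """Read a PK parameter set from a unit-suffixed YAML key-value file."""
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: expected a key-value mapping")
    kwargs = {}
    for key, value in raw.items():
        if key in _PK_KEYS:
            kwargs[_PK_KEYS[key]] = value
        elif key not in ("provenance", "drug"):
            raise ValueError(f"{path}: unknown PK config key {key!r}")
    return PKParameters(**kwargs)


def _config_hash(obj) -> str:
    text = json.dumps(obj, sort_keys=True, default=str)
    return hashlib.sha256(text.encode()).hexdigest()[:12]


def _provenance(config_repr: dict, seed) -> dict:
    return {
        "package_version": __version__,
        "seed": seed,
        "config_hash": _config_hash(config_repr),
        "config": config_repr,
    }


def _build_schedule(config: RunConfig, formulation, *, maintenance_scale: float = 1.0):
    scenario = config.scenario
    weight = float(np.mean(np.atleast_1d(config.weights)))
    if scenario in ("treatment-7d", "renal-treatment") or (
        scenario == "renal-half-maintenance"
    ):
        return build_treatment_schedule(
            config.strategy, weight, formulation, days=7, maintenance_scale=maintenance_scale
        )
    if scenario == "treatment-10d":
        return build_treatment_schedule(
            config.strategy, weight, formulation, days=10, maintenance_scale=maintenance_scale
        )
    if scenario in ("prophylaxis-90d", "renal-prophylaxis"):
        return build_prophylaxis_schedule(
            weight, formulation, months=3, maintenance_scale=maintenance_scale
        )
    raise ValueError(scenario)


def run_scenario(config: RunConfig) -> dict[str, Path]:
    """Run one dosing scenario end-to-end and write its output bundle.

    Builds the schedule, simulates the virtual population, and writes
    ``profiles.csv`` (subject_id,time_h,conc_um), ``exposure.json``
    (mean/PI/Cmax/AUC quantiles, threshold report, EC50 overlay), and
    ``schedule.csv``.  Renal scenarios reduce the renal half of
    clearance by 90%; the half-maintenance scenario additionally halves
    maintenance tablet counts while keeping the loading dose.
    """
    formulation = FORMULATIONS[config.drug]
    params = (
        load_pk_config(config.pk_file)
        if config.pk_file is not None
        else _default_params(config.drug)
    )
    renal = config.scenario.startswith("renal")
    if renal:
        params = apply_renal_impairment(params, 0.9)
    maintenance_scale = 0.5 if config.scenario == "renal-half-maintenance" else 1.0
    schedule = _build_schedule(config, formulation, maintenance_scale=maintenance_scale)

    spec = PopulationSpec(
        n_subjects=config.n_subjects,
        omega=config.omega,
        seed=config.seed,
        weights=config.weights,
    )
    profiles = simulate_population(params, schedule, spec)

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sched_path = out / "schedule.csv"
    pd.DataFrame(
        {
            "time_h": [e.time for e in schedule.events],
            "amount_mg_base": [e.amount for e in schedule.events],
            "tablets": [e.tablets for e in schedule.events],
        }
    ).to_csv(sched_path, index=False)

    prof_path = out / "profiles.csv"
    frames = [
        pd.DataFrame(
            {"subject_id": p.subject_id, "time_h": p.time_grid, "conc_um": p.conc}
        )
        for p in profiles
    ]
    pd.concat(frames, ignore_index=True).to_csv(prof_path, index=False, float_format="%.6g")

    threshold = fraction_exceeding(profiles, SAFETY_THRESHOLD_UM)
    ec50 = EC50Spec(EC50_INVITRO[config.drug], params.blood_plasma_ratio)
    summary_payload = {
        "scenario": config.scenario,
        "drug": config.drug,
        "schedule_total_mg_base": schedule.total_base_mg,
        "threshold_um": threshold.threshold,
        "fraction_cmax_exceeding_threshold": threshold.fraction_exceeding,
        "ec50_blood_um": scale_ec50_to_blood(ec50),
        "renal_impairment": renal,
        "n_peripheral": params.n_peripheral,
    }
    if config.n_subjects >= 2:
        summary = summarize_population(
            profiles, auc_horizon=schedule.last_dose_time + 720.0
        )
        summary_payload |= {
            "cmax_quantiles_um": {str(k): v for k, v in summary.cmax_quantiles.items()},
            "auc_quantiles_um_h": {str(k): v for k, v in summary.auc_quantiles.items()},
        }
    config_repr = {
        "scenario": config.scenario,
        "drug": config.drug,
        "strategy": config.strategy,
        "weights": config.weights,
        "n_subjects": config.n_subjects,
        "omega": config.omega,
        "pk_file": str(config.pk_file),
    }
    summary_payload["provenance"] = _provenance(config_repr, config.seed)
    expo_path = out / "exposure.json"
    expo_path.write_text(json.dumps(summary_payload, indent=2, sort_keys=True) + "\n")
    return {"schedule": sched_path, "profiles": prof_path, "exposure": expo_path}


def _default_params(drug: str) -> PKParameters:
    from .synthetic import make_fixture_pk_set

    return make_fixture_pk_set(drug)


def run_poisoning(
    cohort_path: str | Path,
    out_dir: str | Path,
    edges: tuple[float, ...] = DEFAULT_BIN_EDGES,
    n_boot: int = 2000,
    seed: int | None = None,
) -> dict[str, Path]:
    """Run the cohort concentration-mortality analysis and write outputs.

    Writes ``bins.csv`` (lower,upper,n,deaths,mortality,ci_low,ci_high)
    and ``poisoning_summary.json`` (cohort counts, zero-death threshold
    on a 5-uM grid, mortality above 20 uM, provenance).
    """
    records, summary = load_cohort(cohort_path)
    bins = binned_mortality(records, edges, n_boot=n_boot, seed=seed)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bins_path = out / "bins.csv"
    pd.DataFrame(
        {
            "lower": [b.lower for b in bins],
            "upper": [b.upper for b in bins],
            "n": [b.n for b in bins],
            "deaths": [b.deaths for b in bins],
            "mortality": [b.mortality for b in bins],
            "ci_low": [b.ci_low for b in bins],
            "ci_high": [b.ci_high for b in bins],
        }
    ).to_csv(bins_path, index=False)

    grid = tuple(float(g) for g in np.arange(5.0, edges[-1] + 1e-9, 5.0))
    deaths20, n20, prop20 = mortality_above(records, 20.0)
    payload = {
        "n": summary.n,
        "n_deaths": summary.n_deaths,
        "conc_min_um": summary.conc_min,
        "conc_max_um": summary.conc_max,
        "per_study": summary.per_study,
        "zero_death_threshold_um": zero_death_threshold(records, grid),
        "mortality_above_20um": {"deaths": deaths20, "n": n20, "proportion": prop20},
        "provenance": _provenance(
            {"cohort": str(cohort_path), "edges": list(edges), "n_boot": n_boot}, seed
        ),
    }
    summary_path = out / "poisoning_summary.json"
    summary_path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    return {"bins": bins_path, "summary": summary_path}
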