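"""Synthetic study inputs with the statistical structure the analysis assumes.

Neither the pooled self-poisoning patient table nor the typical
population-PK parameter values are distributable with this package, so
every pipeline stage is exercised on synthetic stand-ins:

* a poisoning cohort whose admission concentrations follow a truncated
  lognormal over the reported 1.1-81 uM range and whose deaths are
  Bernoulli draws from a logistic concentration-mortality law,
  calibrated so that (like the real pooled data) deaths essentially
  never occur below 15 uM while mortality above 20 uM exceeds 5%;
* illustrative PK parameter fixtures that satisfy the qualitative
  constraints of chloroquine-class disposition (terminal half-life
  beyond a month, total apparent volume above 100 L/kg) without
  claiming to be the estimated values;
* uniform body-weight draws over the 40-90 kg simulation range.

The cohort generator's truth is echoed back so recovery tests can
compare estimated to generating quantities.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
from scipy import stats

from .formulation import FORMULATIONS
from .poisoning import CohortSummary, PoisoningRecord, load_cohort, records_to_frame
from .poppk import PKParameters

__all__ = [
    "SyntheticCohortTruth",
    "generate_poisoning_cohort",
    "generate_weights",
    "make_fixture_pk_set",
    "simulate_study_bundle",
]


@dataclass(frozen=True)
class SyntheticCohortTruth:
    """Generating law for a synthetic self-poisoning cohort.

    Concentrations are lognormal with log-median ``log_median`` and
    log-sd ``log_sd``, truncated to [``conc_low``, ``conc_high``] uM
    (defaults span the 1.1-81 uM range of the pooled cohort).  Death is
    Bernoulli with probability logistic((conc - c50) / steepness): the
    defaults (c50 38 uM, steepness 2.5 uM) keep mortality negligible
    below 15 uM and above 5% beyond 20 uM, the qualitative pattern of
    the pooled data.
    """

    n: int = 258
    log_median: float = float(np.log(10.0))
    log_sd: float = 0.8
    conc_low: float = 1.1
    conc_high: float = 81.0
    c50: float = 38.0
    steepness: float = 2.5
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0 < self.conc_low < self.conc_high:
            raise ValueError("truncation bounds must be positive and ordered")
        if self.steepness <= 0:
            raise ValueError("steepness must be positive")
        if self.n < 0:
            raise ValueError("n must be >= 0")

    def death_probability(self, conc: np.ndarray) -> np.ndarray:
        return stats.logistic.cdf((np.asarray(conc) - self.c50) / self.steepness)


def generate_poisoning_cohort(
    truth: SyntheticCohortTruth,
) -> tuple[list[PoisoningRecord], SyntheticCohortTruth]:
    """Draw a synthetic cohort from ``truth``; deterministic under its seed.

    The log of a truncated lognormal is truncated normal, so
    concentrations are drawn with :func:`scipy.stats.truncnorm` on the
    log scale and exponentiated.
    """
    rng = np.random.default_rng(truth.seed)
    a = (np.log(truth.conc_low) - truth.log_median) / truth.log_sd
    b = (np.log(truth.conc_high) - truth.log_median) / truth.log_sd
    log_conc = stats.truncnorm.rvs(
        a, b, loc=truth.log_median, scale=truth.log_sd, size=truth.n, random_state=rng
    )
    conc = np.exp(log_conc)
    died = rng.random(truth.n) < truth.death_probability(conc)
    records = [
        PoisoningRecord("synthetic", round(float(c), 2), bool(d))
        for c, d in zip(conc, died)
    ]
    return records, truth


def generate_weights(
    n: int, low: float = 40.0, high: float = 90.0, seed: int | None = None
) -> np.ndarray:
    """Uniform integer body weights (kg) over [low, high], seeded."""
    if low >= high:
        raise ValueError("low must be < high")
    rng = np.random.default_rng(seed)
    return rng.integers(int(low), int(high) + 1, size=n).astype(float)


# Illustrative parameter sets: constructed, not estimated.  They satisfy
# the qualitative disposition constraints (terminal half-life > 28 days,
# total apparent volume > 100 L/kg at 62 kg) and give peak whole-blood
# concentrations of a few uM under the standard treatment regimen.
_FIXTURE_PK = {
    "chloroquine": dict(
        cl_f=60.0,
        vc_f=1200.0,
        q_f=55.0,
        vp_f=39000.0,
        ka=0.4,
        tlag=0.5,
        f_rel=1.0,
        n_peripheral=1,
        renal_fraction=0.5,
        blood_plasma_ratio=3.0,
        mw_base=319.87,
    ),
    "hydroxychloroquine": dict(
        cl_f=46.0,
        vc_f=900.0,
        q_f=45.0,
        vp_f=30000.0,
        ka=0.5,
        tlag=0.5,
        f_rel=1.0,
        n_peripheral=1,
        renal_fraction=0.5,
        blood_plasma_ratio=4.0,
        mw_base=335.87,
    ),
}


def make_fixture_pk_set(drug: str) -> PKParameters:
    """ILLUSTRATIVE whole-blood PK parameters for a 62-kg reference adult.

    These are synthetic fixture values for testing and demonstration:
    they reproduce the qualitative disposition of the 4-aminoquinolines
    (multi-week terminal half-life, enormous apparent distribution
    volume) but are not estimates from any clinical dataset.
    """
    try:
        return PKParameters(**_FIXTURE_PK[drug])
    except KeyError:
        raise ValueError(f"unknown drug {drug!r}; expected one of {sorted(_FIXTURE_PK)}")


def simulate_study_bundle(seed: int, out_dir: str | Path) -> dict[str, Path]:
    """Write a self-contained synthetic input set for an end-to-end run.

    Produces ``cohort.csv`` (synthetic poisoning cohort), ``truth.json``
    (the generating law), ``pk_<drug>.yaml`` parameter configs, and a
    ``regimen.yaml`` scenario config.  Byte-identical for a fixed seed.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    truth = SyntheticCohortTruth(seed=seed)
    records, _ = generate_poisoning_cohort(truth)
    cohort_path = out / "cohort.csv"
    records_to_frame(records).to_csv(cohort_path, index=False)
    load_cohort(cohort_path)  # self-validation

    truth_path = out / "truth.json"
    truth_path.write_text(json.dumps(asdict(truth), indent=2, sort_keys=True) + "\n")

    paths = {"cohort": cohort_path, "truth": truth_path}
    for drug in FORMULATIONS:
        p = make_fixture_pk_set(drug)
        lines = [f"# ILLUSTRATIVE synthetic PK parameters for {drug} (whole blood, 62-kg adult)"]
        lines += [
            f"cl_f_l_per_h: {p.cl_f}",
            f"vc_f_l: {p.vc_f}",
            f"q_f_l_per_h: {p.q_f}",
            f"vp_f_l: {p.vp_f}",
            f"ka_per_h: {p.ka}",
            f"tlag_h: {p.tlag}",
            f"f_rel: {p.f_rel}",
            f"n_peripheral: {p.n_peripheral}",
            f"renal_fraction: {p.renal_fraction}",
            f"blood_plasma_ratio: {p.blood_plasma_ratio}",
            f"mw_base_g_per_mol: {p.mw_base}",
            "provenance: synthetic-illustrative",
        ]
        pk_path = out / f"pk_{drug}.yaml"
        pk_path.write_text("\n".join(lines) + "\n")
        paths[f"pk_{drug}"] = pk_path

    regimen_path = out / "regimen.yaml"
    regimen_path.write_text(
        "\n".join(
            [
                "scenario: treatment-7d",
                "drug: chloroquine",
                "strategy: flat",
                "weight_kg: 62",
                "n_subjects: 50",
                f"seed: {seed}",
                f"pk_file: pk_chloroquine.yaml",
            ]
        )
        + "\n"
    )
    paths["regimen"] = regimen_path
    return paths
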