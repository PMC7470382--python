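"""Pooled self-poisoning concentration-mortality analysis.

Prospectively studied chloroquine self-poisoning cohorts recorded the
admission whole-blood concentration of chloroquine plus its desethyl
metabolite (legacy UV-spectrophotometric assays do not separate them)
and the outcome.  This module validates such cohort tables, computes
mortality within concentration bins with percentile-bootstrap 95%
confidence intervals, locates the highest concentration below which no
deaths occurred, corrects measured totals for the metabolite share, and
summarises two-group contingency tables (e.g. admission concentration
below vs above 25 uM).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "PoisoningRecord",
    "CohortSummary",
    "MortalityBin",
    "ContingencyResult",
    "load_cohort",
    "records_to_frame",
    "binned_mortality",
    "mortality_above",
    "zero_death_threshold",
    "parent_fraction_correction",
    "contingency_mortality",
    "DEFAULT_BIN_EDGES",
]

#: Default concentration bin edges (uM), aligned with the 15/20/25 uM
#: thresholds discussed for the pooled cohort.  Bins are half-open
#: [lower, upper).
DEFAULT_BIN_EDGES = (0.0, 5.0, 10.0, 15.0, 20.0, 25.0, 30.0, 40.0, 55.0, 85.0)


@dataclass(frozen=True)
class PoisoningRecord:
    """One overdose patient: study, admission concentration (uM), outcome."""

    study_id: str
    conc_admission: float
    died: bool

    def __post_init__(self) -> None:
        if not self.conc_admission > 0:
            raise ValueError("conc_admission must be positive")


@dataclass(frozen=True)
class CohortSummary:
    n: int
    n_deaths: int
    conc_min: float
    conc_max: float
    per_study: dict[str, int]

    def __post_init__(self) -> None:
        if self.n_deaths > self.n:
            raise ValueError("deaths cannot exceed cohort size")
        if self.conc_min > self.conc_max:
            raise ValueError("conc_min must be <= conc_max")


@dataclass(frozen=True)
class MortalityBin:
    """Mortality within [lower, upper) uM with bootstrap 95% CI.

    Empty bins carry n = 0 and NaN mortality/CI rather than raising.
    """

    lower: float
    upper: float
    n: int
    deaths: int
    mortality: float
    ci_low: float
    ci_high: float

    def __post_init__(self) -> None:
        if self.n > 0 and not (
            0 <= self.ci_low <= self.mortality + 1e-12
            and self.mortality <= self.ci_high + 1e-12
            and self.ci_high <= 1
        ):
            raise ValueError("CI must bracket the point estimate within [0, 1]")


@dataclass(frozen=True)
class ContingencyResult:
    """Two-group mortality comparison (group b vs reference group a)."""

    pct_a: float
    pct_b: float
    risk_ratio: float
    odds_ratio: float
    odds_ratio_haldane: float


def load_cohort(
    path: str | Path | pd.DataFrame,
    *,
    column_map: dict[str, str] | None = None,
) -> tuple[list[PoisoningRecord], CohortSummary]:
    """Read and validate a cohort CSV with columns study_id, conc_um, died.

    ``died`` must be coded 0/1.  ``column_map`` renames alternative
    headers onto the expected ones, e.g. ``{"outcome": "died"}``.
    Validation failures report the offending row index.
    """
    if isinstance(path, pd.DataFrame):
        df = path.copy()
    else:
        df = pd.read_csv(path)
    if column_map:
        df = df.rename(columns=column_map)
    required = ["study_id", "conc_um", "died"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"cohort table is missing columns: {missing}")
    if len(df) == 0:
        raise ValueError("cohort table is empty")

    records = []
    for idx, row in df.iterrows():
        conc = pd.to_numeric(pd.Series([row["conc_um"]]), errors="coerce").iloc[0]
        if pd.isna(conc) or conc <= 0:
            raise ValueError(f"row {idx}: concentration must be a positive number, got {row['conc_um']!r}")
        died = row["died"]
        if died not in (0, 1, "0", "1", False, True):
            raise ValueError(f"row {idx}: outcome must be coded 0/1, got {died!r}")
        records.append(PoisoningRecord(str(row["study_id"]), float(conc), bool(int(died))))

    concs = [r.conc_admission for r in records]
    per_study: dict[str, int] = {}
    for r in records:
        per_study[r.study_id] = per_study.get(r.study_id, 0) + 1
    summary = CohortSummary(
        n=len(records),
        n_deaths=sum(r.died for r in records),
        conc_min=min(concs),
        conc_max=max(concs),
        per_study=per_study,
    )
    return records, summary


def records_to_frame(records: list[PoisoningRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "study_id": [r.study_id for r in records],
            "conc_um": [r.conc_admission for r in records],
            "died": [int(r.died) for r in records],
        }
    )


def binned_mortality(
    records: list[PoisoningRecord],
    edges: tuple[float, ...] = DEFAULT_BIN_EDGES,
    n_boot: int = 2000,
    seed: int | None = None,
) -> list[MortalityBin]:
    """Per-bin death proportion with percentile-bootstrap 95% CIs.

    Patients are resampled with replacement within each bin; the CI is
    the (2.5, 97.5) percentile of the resampled proportions.  The point
    estimate does not depend on the seed; the CI is reproducible given
    one.  Bins are half-open [lower, upper); the last upper edge must
    cover the data maximum.
    """
    edges_arr = np.asarray(edges, dtype=float)
    if edges_arr.size < 2 or np.any(np.diff(edges_arr) <= 0):
        raise ValueError("edges must be strictly increasing with >= 2 values")
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    conc = np.array([r.conc_admission for r in records])
    died = np.array([r.died for r in records], dtype=float)
    if conc.size and (conc.min() < edges_arr[0] or conc.max() >= edges_arr[-1]):
        raise ValueError("edges must cover the observed concentration range")
    rng = np.random.default_rng(seed)
    bins = []
    for lo, hi in zip(edges_arr[:-1], edges_arr[1:]):
        mask = (conc >= lo) & (conc < hi)
        outcomes = died[mask]
        n = int(mask.sum())
        if n == 0:
            bins.append(MortalityBin(lo, hi, 0, 0, math.nan, math.nan, math.nan))
            continue
        deaths = int(outcomes.sum())
        resamples = rng.integers(0, n, size=(n_boot, n))
        boot_props = outcomes[resamples].mean(axis=1)
        ci_low, ci_high = np.percentile(boot_props, [2.5, 97.5])
        bins.append(
            MortalityBin(lo, hi, n, deaths, deaths / n, float(ci_low), float(ci_high))
        )
    return bins


def mortality_above(
    records: list[PoisoningRecord], cutoff: float
) -> tuple[int, int, float]:
    """(deaths, n, proportion) among records with concentration > cutoff."""
    sel = [r for r in records if r.conc_admission > cutoff]
    if not sel:
        raise ValueError(f"no records with concentration above {cutoff} uM")
    deaths = sum(r.died for r in sel)
    return deaths, len(sel), deaths / len(sel)


def zero_death_threshold(
    records: list[PoisoningRecord], grid: tuple[float, ...]
) -> float:
    """Largest grid value below which no deaths occurred.

    Returns the largest t in ``grid`` such that every record with
    concentration < t survived; if even the smallest grid value has a
    death below it, that smallest value is returned as a floor flag.
    """
    grid_arr = np.asarray(grid, dtype=float)
    if grid_arr.size == 0 or np.any(np.diff(grid_arr) <= 0):
        raise ValueError("grid must be non-empty and strictly increasing")
    death_concs = np.array([r.conc_admission for r in records if r.died])
    best = grid_arr[0]
    for t in grid_arr:
        if death_concs.size == 0 or not np.any(death_concs < t):
            best = t
    return float(best)


def parent_fraction_correction(conc_total: float, metabolite_fraction: float = 0.30) -> float:
    """Parent-drug equivalent of a combined parent + metabolite measurement.

    Legacy assays report chloroquine + desethylchloroquine together;
    assuming ~30% of the measured total is metabolite, the parent
    concentration is total x 0.7 (so the 15 uM no-death bound maps to
    ~10 uM parent drug).
    """
    if not 0 <= metabolite_fraction < 1:
        raise ValueError("metabolite_fraction must be in [0, 1)")
    if conc_total < 0:
        raise ValueError("concentration must be >= 0")
    return conc_total * (1.0 - metabolite_fraction)


def _round_pct(p: float, decimals: int | None) -> float:
    """Round a percentage; None = integer precision, but keep one decimal
    for nonzero values that would round to 0 (0.94% -> 0.9, 21.3% -> 21)."""
    if decimals is not None:
        return round(p, decimals)
    if 0 < p < 0.95:
        return round(p, 1)
    return float(round(p))


def contingency_mortality(
    deaths_a: int, n_a: int, deaths_b: int, n_b: int, *, pct_decimals: int | None = None
) -> ContingencyResult:
    """Mortality percentages, risk ratio and odds ratio of group b vs a.

    With a zero cell the unadjusted odds ratio is infinite (or zero);
    the Haldane-Anscombe corrected odds ratio (adding 0.5 to every cell)
    is reported alongside.  The canonical comparison is 1/106 deaths at
    admission concentrations < 25 uM vs 13/61 (21%) above.
    """
    for deaths, n in ((deaths_a, n_a), (deaths_b, n_b)):
        if n <= 0:
            raise ValueError("group size must be positive")
        if not 0 <= deaths <= n:
            raise ValueError("deaths must lie in [0, n]")
    p_a, p_b = deaths_a / n_a, deaths_b / n_b
    risk_ratio = p_b / p_a if p_a > 0 else math.inf
    surv_a, surv_b = n_a - deaths_a, n_b - deaths_b
    if deaths_a > 0 and surv_b > 0:
        odds_ratio = (deaths_b * surv_a) / (deaths_a * surv_b)
    else:
        odds_ratio = math.inf if deaths_b > 0 else math.nan
    odds_ratio_h = ((deaths_b + 0.5) * (surv_a + 0.5)) / ((deaths_a + 0.5) * (surv_b + 0.5))
    return ContingencyResult(
        pct_a=_round_pct(100 * p_a, pct_decimals),
        pct_b=_round_pct(100 * p_b, pct_decimals),
        risk_ratio=risk_ratio,
        odds_ratio=odds_ratio,
        odds_ratio_haldane=odds_ratio_h,
    )
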