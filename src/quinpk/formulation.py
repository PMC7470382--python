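"""Salt/base dose arithmetic, tablet quantisation, and dosing schedules.

Chloroquine and hydroxychloroquine are formulated as different salts
(diphosphate and sulphate respectively) whose tablets contain different
salt masses but the same 155 mg of free base.  Dosing is therefore done
in base equivalents.  This module converts between salt and base masses,
rounds mg/kg targets to whole tablets, and builds the multi-dose
schedules used in COVID-19 treatment (loading dose at 0 and 6 h, then
twice-daily maintenance) and prophylaxis (loading dose, then one tablet
daily) simulations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

__all__ = [
    "DrugFormulation",
    "DoseEvent",
    "DoseSchedule",
    "RegimenStrategy",
    "CHLOROQUINE_PHOSPHATE",
    "HYDROXYCHLOROQUINE_SULFATE",
    "salt_to_base",
    "base_to_salt",
    "tablets_for_target",
    "build_treatment_schedule",
    "build_prophylaxis_schedule",
    "schedule_mg_per_kg",
]

#: Supported body-weight range (kg) for the shipped regimen strategies.
WEIGHT_RANGE = (40.0, 90.0)


@dataclass(frozen=True)
class DrugFormulation:
    """A drug/salt/tablet combination with its base-equivalent arithmetic.

    Parameters
    ----------
    drug_name, salt_name : str
        Identity of the active moiety and of the formulated salt.
    tablet_salt_mass : float
        Salt mass per tablet (mg).
    mw_base, mw_salt : float
        Molecular weights (g/mol) of the free base and the salt.
    tablet_base_mass : float
        Base-equivalent mass per tablet (mg).  Defaults to the rounded
        salt-to-base conversion; both marketed tablets round to 155 mg.
    """

    drug_name: str
    salt_name: str
    tablet_salt_mass: float
    mw_base: float
    mw_salt: float
    tablet_base_mass: float = field(default=0.0)

    def __post_init__(self) -> None:
        if not (self.mw_salt > self.mw_base > 0):
            raise ValueError("molecular weights must satisfy mw_salt > mw_base > 0")
        if self.tablet_salt_mass <= 0:
            raise ValueError("tablet_salt_mass must be positive")
        exact = self.tablet_salt_mass * self.mw_base / self.mw_salt
        if self.tablet_base_mass == 0.0:
            object.__setattr__(self, "tablet_base_mass", round(exact))
        elif abs(self.tablet_base_mass - exact) > 1.0:
            raise ValueError(
                f"tablet_base_mass {self.tablet_base_mass} mg inconsistent with "
                f"salt arithmetic ({exact:.2f} mg)"
            )


# MW of chloroquine base 319.87 g/mol; diphosphate adds 2 x H3PO4 (97.995).
CHLOROQUINE_PHOSPHATE = DrugFormulation(
    drug_name="chloroquine",
    salt_name="diphosphate",
    tablet_salt_mass=250.0,
    mw_base=319.87,
    mw_salt=515.86,
)

# MW of hydroxychloroquine base 335.87 g/mol; sulphate adds H2SO4 (98.08).
HYDROXYCHLOROQUINE_SULFATE = DrugFormulation(
    drug_name="hydroxychloroquine",
    salt_name="sulphate",
    tablet_salt_mass=200.0,
    mw_base=335.87,
    mw_salt=433.95,
)

FORMULATIONS = {
    "chloroquine": CHLOROQUINE_PHOSPHATE,
    "hydroxychloroquine": HYDROXYCHLOROQUINE_SULFATE,
}


@dataclass(frozen=True)
class DoseEvent:
    """A single oral dose: time (h since first dose), base mg, tablet count."""

    time: float
    amount: float
    tablets: int

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ValueError("dose time must be >= 0")
        if self.amount <= 0 or self.tablets <= 0:
            raise ValueError("dose amount and tablet count must be positive")


@dataclass(frozen=True)
class DoseSchedule:
    """An ordered multi-dose schedule.

    ``events`` are strictly increasing in time with the first at t = 0;
    ``duration`` is the nominal regimen length in days and ``strategy``
    the label of the rule that generated it.
    """

    events: tuple[DoseEvent, ...]
    duration: float
    strategy: str

    def __post_init__(self) -> None:
        if self.events:
            times = [e.time for e in self.events]
            if times[0] != 0:
                raise ValueError("first dose must be at time 0")
            if any(b <= a for a, b in zip(times, times[1:])):
                raise ValueError("dose times must be strictly increasing")

    @property
    def total_base_mg(self) -> float:
        return sum(e.amount for e in self.events)

    @property
    def last_dose_time(self) -> float:
        return self.events[-1].time if self.events else 0.0


@dataclass(frozen=True)
class RegimenStrategy:
    """mg/kg targets and tablet bounds for a weight-based regimen.

    ``loading_target`` is in mg base/kg; ``maintenance_target`` in mg
    base/kg per maintenance interval (12 h for treatment, 24 h for
    prophylaxis).
    """

    loading_target: float = 10.0
    maintenance_target: float = 5.0
    loading_tablet_bounds: tuple[int, int] = (3, 5)
    maintenance_tablet_bounds: tuple[int, int] = (1, 3)

    def __post_init__(self) -> None:
        for lo, hi in (self.loading_tablet_bounds, self.maintenance_tablet_bounds):
            if lo > hi or lo < 1:
                raise ValueError("tablet bounds must be a non-empty positive interval")
        if self.loading_target <= 0 or self.maintenance_target <= 0:
            raise ValueError("mg/kg targets must be positive")


def salt_to_base(mass_salt: float, formulation: DrugFormulation, *, rounded: bool = False) -> float:
    """Convert a salt mass (mg) to its free-base equivalent (mg).

    With ``rounded=True`` the result is rounded to the nearest mg, the
    precision at which tablet strengths are quoted (both the 250-mg
    chloroquine diphosphate and 200-mg hydroxychloroquine sulphate
    tablets contain 155 mg base).
    """
    if mass_salt < 0:
        raise ValueError("salt mass must be >= 0")
    base = mass_salt * formulation.mw_base / formulation.mw_salt
    return float(round(base)) if rounded else base


def base_to_salt(mass_base: float, formulation: DrugFormulation) -> float:
    """Inverse of :func:`salt_to_base` (exact, unrounded)."""
    if mass_base < 0:
        raise ValueError("base mass must be >= 0")
    return mass_base * formulation.mw_salt / formulation.mw_base


def tablets_for_target(
    target: float, formulation: DrugFormulation, bounds: tuple[int, int]
) -> int:
    """Whole-tablet count within ``bounds`` closest to a mg-base target.

    Ties are broken toward fewer tablets (the safety-conservative
    choice).
    """
    lo, hi = int(bounds[0]), int(bounds[1])
    if lo > hi:
        raise ValueError("empty tablet bounds")
    if target < 0:
        raise ValueError("target must be >= 0")
    best = lo
    best_err = abs(lo * formulation.tablet_base_mass - target)
    for n in range(lo + 1, hi + 1):
        err = abs(n * formulation.tablet_base_mass - target)
        if err < best_err:
            best, best_err = n, err
    return best


def _check_weight(weight: float) -> None:
    if weight <= 0:
        raise ValueError("weight must be positive")
    if not (WEIGHT_RANGE[0] <= weight <= WEIGHT_RANGE[1]):
        warnings.warn(
            f"weight {weight} kg outside the supported {WEIGHT_RANGE} kg range; "
            "regimens were designed for 40-90 kg adults",
            stacklevel=3,
        )


def build_treatment_schedule(
    strategy: str | RegimenStrategy,
    weight: float,
    formulation: DrugFormulation,
    days: int = 7,
    *,
    maintenance_scale: float = 1.0,
) -> DoseSchedule:
    """Build a COVID-19 treatment schedule.

    Loading doses are given at 0 and 6 h, maintenance doses every 12 h
    from 12 h up to (but excluding) ``days`` x 24 h — 13 maintenance
    doses over 7 days, 19 over 10 days.

    Parameters
    ----------
    strategy : {"flat", "weight_loading", "weight_both"} or RegimenStrategy
        ``flat``: 4 tablets loading, 2 tablets maintenance regardless of
        weight (the RECOVERY/SOLIDARITY regimen for 155-mg-base tablets).
        ``weight_loading``: loading quantised to 10 mg base/kg within
        3-5 tablets, flat 2-tablet maintenance. ``weight_both``:
        additionally quantises maintenance to 5 mg base/kg within 1-3
        tablets. Passing a :class:`RegimenStrategy` behaves as
        ``weight_both`` with custom targets/bounds.
    maintenance_scale : float
        Multiplier on maintenance tablet counts (0.5 gives the
        half-maintenance alternative for severe renal impairment);
        loading is never scaled. Scaled counts are rounded up to >= 1
        tablet.
    days : int
        Total treatment duration in days (7 or 10 in the simulations).
    """
    _check_weight(weight)
    if days < 1:
        raise ValueError("treatment duration must be >= 1 day")

    custom = isinstance(strategy, RegimenStrategy)
    spec = strategy if custom else RegimenStrategy()
    label = "weight_both" if custom else str(strategy)
    if label == "flat":
        load_tabs, maint_tabs = 4, 2
    elif label == "weight_loading":
        load_tabs = tablets_for_target(
            spec.loading_target * weight, formulation, spec.loading_tablet_bounds
        )
        maint_tabs = 2
    elif label == "weight_both":
        load_tabs = tablets_for_target(
            spec.loading_target * weight, formulation, spec.loading_tablet_bounds
        )
        maint_tabs = tablets_for_target(
            spec.maintenance_target * weight, formulation, spec.maintenance_tablet_bounds
        )
    else:
        raise ValueError(f"unknown treatment strategy {label!r}")

    maint_tabs = max(1, round(maint_tabs * maintenance_scale))
    per_tab = formulation.tablet_base_mass
    events = [
        DoseEvent(0.0, load_tabs * per_tab, load_tabs),
        DoseEvent(6.0, load_tabs * per_tab, load_tabs),
    ]
    t = 12.0
    while t < days * 24.0:
        events.append(DoseEvent(t, maint_tabs * per_tab, maint_tabs))
        t += 12.0
    return DoseSchedule(tuple(events), float(days), label)


def build_prophylaxis_schedule(
    weight: float,
    formulation: DrugFormulation,
    months: int = 3,
    *,
    strategy: RegimenStrategy | None = None,
    maintenance_scale: float = 1.0,
) -> DoseSchedule:
    """Build a prophylaxis schedule: weight-based loading then one tablet daily.

    The loading dose targets 10 mg base/kg within 3-5 tablets; the flat
    one-tablet daily maintenance (155 mg = 2.5 mg/kg at 62 kg) runs from
    24 h to ``months`` x 30 days. ``months=0`` yields a loading-only
    schedule.

    ``maintenance_scale=0.5`` (the renal-impairment alternative) halves
    the maintenance rate by giving one whole tablet every 48 h rather
    than splitting tablets, so every dose stays a whole-tablet multiple.
    """
    _check_weight(weight)
    if months < 0:
        raise ValueError("months must be >= 0")
    if maintenance_scale not in (0.5, 1.0):
        raise ValueError("prophylaxis maintenance_scale must be 1.0 or 0.5")
    spec = strategy or RegimenStrategy(maintenance_target=2.5)
    load_tabs = tablets_for_target(
        spec.loading_target * weight, formulation, spec.loading_tablet_bounds
    )
    per_tab = formulation.tablet_base_mass
    events = [DoseEvent(0.0, load_tabs * per_tab, load_tabs)]
    interval = 24.0 / maintenance_scale
    t = 24.0
    while t < months * 30 * 24.0:
        events.append(DoseEvent(t, per_tab, 1))
        t += interval
    return DoseSchedule(tuple(events), months * 30.0, "prophylaxis")


def schedule_mg_per_kg(schedule: DoseSchedule, weight: float) -> list[float]:
    """Per-event doses expressed in mg base/kg."""
    if weight <= 0:
        raise ValueError("weight must be positive")
    return [e.amount / weight for e in schedule.events]
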