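"""Per-cycle, state- and time-dependent costing of each treatment strategy.

Costs follow the Chinese healthcare-system perspective of the analysis:
drug acquisition (whole-vial billing at national tender prices), routine
follow-up and tests, best supportive care after progression, one-off
management of grade >=3 adverse events, and end-of-life care.

Dosing uses a reference patient (65 kg, 1.64 m, BSA 1.72 m^2, creatinine
clearance 70 mL/min): carboplatin by the Calvert formula at AUC 5,
etoposide 100 mg/m^2 on days 1-3 of each 21-day cycle, adebrelimab
20 mg/kg each cycle while progression-free, capped at 24 months.
On progression a fixed fraction of patients receives second-line
irinotecan + cisplatin for 3.6 cycles (last cycle pro-rated) and the rest
move straight to best supportive care; after second-line failure everyone
receives best supportive care.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

__all__ = [
    "PatientProfile",
    "DrugPrice",
    "DrugAdministration",
    "AdverseEvent",
    "StrategyDefinition",
    "carboplatin_dose",
    "bsa_dose",
    "weight_dose",
    "drug_cost",
    "cycle_cost",
    "ae_burden",
    "second_line_weight",
]

STATES = ("pfs", "pd", "death")


@dataclass(frozen=True)
class PatientProfile:
    """Reference patient used to convert per-kg / per-m^2 doses to mg."""

    weight_kg: float = 65.0
    height_m: float = 1.64
    bsa_m2: float = 1.72
    crcl_ml_min: float = 70.0

    def __post_init__(self) -> None:
        for name in ("weight_kg", "height_m", "bsa_m2", "crcl_ml_min"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class DrugPrice:
    name: str
    vial_mg: float
    price_per_vial: float

    def __post_init__(self) -> None:
        if not (self.vial_mg > 0 and self.price_per_vial >= 0):
            raise ValueError("vial size must be positive and price non-negative")


def carboplatin_dose(target_auc: float, crcl_ml_min: float) -> float:
    """Calvert formula: dose (mg) = AUC x (CrCl + 25)."""
    if target_auc < 0 or crcl_ml_min < 0:
        raise ValueError("AUC and creatinine clearance must be non-negative")
    return target_auc * (crcl_ml_min + 25.0)


def bsa_dose(mg_per_m2: float, bsa_m2: float) -> float:
    """Body-surface-area dosing: mg/m^2 x m^2."""
    return mg_per_m2 * bsa_m2


def weight_dose(mg_per_kg: float, weight_kg: float) -> float:
    """Weight-based dosing: mg/kg x kg."""
    return mg_per_kg * weight_kg


def drug_cost(dose_mg: float, price: DrugPrice) -> float:
    """Whole-vial billing with no vial sharing: ceil(dose/vial) vials."""
    if dose_mg < 0:
        raise ValueError("dose must be non-negative")
    if dose_mg == 0:
        return 0.0
    # tolerate float fuzz so an exact multiple never buys a spare vial
    vials = math.ceil(dose_mg / price.vial_mg - 1e-9)
    return vials * price.price_per_vial


@dataclass(frozen=True)
class DrugAdministration:
    """One drug's administration within a cycle: dose per administration in
    mg, and how many administrations per 21-day cycle."""

    price: DrugPrice
    dose_mg: float
    times_per_cycle: int = 1

    def cost_per_cycle(self) -> float:
        return self.times_per_cycle * drug_cost(self.dose_mg, self.price)


@dataclass(frozen=True)
class AdverseEvent:
    """A grade >=3 adverse event: incidence, management cost, disutility."""

    name: str
    incidence: float
    cost: float
    disutility: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.incidence <= 1.0:
            raise ValueError(f"incidence must be in [0, 1], got {self.incidence}")


@dataclass(frozen=True)
class StrategyDefinition:
    """Everything that distinguishes one arm: survival curves, regimen,
    second-line mix, adverse-event profile and care costs."""

    name: str
    pfs_model: Callable
    os_model: Callable
    chemo_drugs: tuple[DrugAdministration, ...] = ()
    chemo_max_cycles: int = 6
    maintenance_drug: DrugAdministration | None = None
    maintenance_cap_months: float = 24.0
    second_line_drugs: tuple[DrugAdministration, ...] = ()
    second_line_fraction: float = 0.0
    second_line_duration_cycles: float = 3.6
    ae_profile: tuple[AdverseEvent, ...] = ()
    followup_per_cycle: float = 0.0
    tests_per_cycle: float = 0.0
    bsc_per_cycle: float = 0.0
    end_of_life_cost: float = 0.0
    pd_followup: bool = True
    pd_tests: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.second_line_fraction <= 1.0:
            raise ValueError("second_line_fraction must be in [0, 1]")
        if self.second_line_duration_cycles < 0 or self.maintenance_cap_months < 0:
            raise ValueError("durations must be non-negative")

    def chemo_cost_per_cycle(self) -> float:
        return sum(d.cost_per_cycle() for d in self.chemo_drugs)

    def second_line_cost_per_cycle(self) -> float:
        return sum(d.cost_per_cycle() for d in self.second_line_drugs)


def second_line_weight(strategy: StrategyDefinition, pd_age: int) -> float:
    """Fraction of a second-line cycle delivered ``pd_age`` cycles after
    progression entry: full cycles up to the integer part of the duration,
    then one pro-rated cycle (3.6 cycles -> weights 1, 1, 1, 0.6)."""
    return min(max(strategy.second_line_duration_cycles - pd_age, 0.0), 1.0)


def cycle_cost(
    strategy: StrategyDefinition,
    state: str,
    k: int,
    settings,
    pd_age: int = 0,
) -> float:
    """Undiscounted cost per occupant of ``state`` during cycle ``k``.

    For the progressive-disease state the cost depends on time since
    progression: ``pd_age`` counts cycles since entering PD (0 = first).
    The second-line fraction receives second-line drugs while their
    pro-rating weight is positive; everyone else (and everyone afterwards)
    receives best supportive care.
    """
    if state not in STATES:
        raise ValueError(f"unknown state {state!r}; expected one of {STATES}")
    if state == "death":
        return 0.0

    t_months = k * settings.cycle_length_months
    if state == "pfs":
        cost = strategy.tests_per_cycle + strategy.followup_per_cycle
        if k < strategy.chemo_max_cycles:
            cost += strategy.chemo_cost_per_cycle()
        if strategy.maintenance_drug is not None and t_months < strategy.maintenance_cap_months:
            cost += strategy.maintenance_drug.cost_per_cycle()
        return cost

    # progressive disease
    w = second_line_weight(strategy, pd_age)
    on_second_line = strategy.second_line_fraction * w
    cost = on_second_line * strategy.second_line_cost_per_cycle()
    cost += (1.0 - on_second_line) * strategy.bsc_per_cycle
    if strategy.pd_followup:
        cost += strategy.followup_per_cycle
    if strategy.pd_tests:
        cost += strategy.tests_per_cycle
    return cost


def ae_burden(ae_profile: Sequence[AdverseEvent]) -> tuple[float, float]:
    """Expected one-off adverse-event burden: (cost, utility decrement).

    Both are incidence-weighted sums over the profile.  The utility
    decrement is applied by the cohort engine for one cycle's duration.
    """
    cost = sum(ae.incidence * ae.cost for ae in ae_profile)
    disutility = sum(ae.incidence * ae.disutility for ae in ae_profile)
    return cost, disutility
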