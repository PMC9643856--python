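"""Three-state (PFS / PD / death) cohort simulation over 21-day cycles.

The cohort starts progression-free.  Each cycle, per-cycle transition
probabilities are derived from the fitted progression-free-survival and
overall-survival curves:

    p(PFS -> PD at cycle k)    = 1 - S_pfs(t_{k+1}) / S_pfs(t_k)
    p(PD  -> death at cycle k) = 1 - S_os(t_{k+1})  / S_os(t_k)

with no direct PFS -> death transition and no recovery — the structure used
when trial hazards are only available marginally.  In this default
"state-transition" mode the death flow is drawn from the PD occupancy at
the overall-survival per-cycle hazard, so total life expectancy exceeds the
area under the OS curve alone.  An alternative "partitioned-survival" mode
(occupancy read directly off the two curves) is also provided.

Costs and quality-adjusted life-years are discounted at 5%/year
(continuous-equivalent per-cycle factors); the headline life-year total is
reported undiscounted, matching the convention of discounting costs and
health utilities only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .costing import StrategyDefinition, ae_burden, cycle_cost

__all__ = [
    "ModelSettings",
    "MarkovTrace",
    "ArmResult",
    "IcerReport",
    "discount_factor",
    "cycle_transition_probs",
    "run_trace",
    "accumulate",
    "run_arm",
    "compute_icer",
]

DAYS_PER_MONTH = 365.25 / 12.0  # 30.4375


@dataclass(frozen=True)
class ModelSettings:
    """Global cohort-model settings.

    Defaults: 21-day cycles, 120 cycles (a 6.9-year horizon, long enough
    for ~99% of the modelled cohort to die), 5%/year discounting, and a
    willingness-to-pay threshold of $37,653/QALY (3x Chinese per-capita
    GDP, 2021).
    """

    cycle_length_days: float = 21.0
    n_cycles: int = 120
    annual_discount_rate: float = 0.05
    wtp_threshold: float = 37653.0
    engine_mode: str = "state_transition"
    half_cycle_correction: bool = False
    utility_pfs: float = 0.673
    utility_pd: float = 0.473

    def __post_init__(self) -> None:
        if self.cycle_length_days <= 0 or self.n_cycles <= 0:
            raise ValueError("cycle length and cycle count must be positive")
        if not 0.0 <= self.annual_discount_rate <= 1.0:
            raise ValueError("discount rate must be in [0, 1]")
        if self.engine_mode not in ("state_transition", "partitioned_survival"):
            raise ValueError(f"unknown engine mode {self.engine_mode!r}")

    @property
    def cycle_length_months(self) -> float:
        return self.cycle_length_days / DAYS_PER_MONTH

    @property
    def cycle_length_years(self) -> float:
        return self.cycle_length_days / 365.25


@dataclass
class MarkovTrace:
    """Cycle-by-cycle cohort occupancy (length n_cycles + 1, index = start
    of cycle) plus the incoming flows needed for time-since-progression
    costing."""

    t_months: np.ndarray
    pfs: np.ndarray
    pd: np.ndarray
    dead: np.ndarray
    new_pd: np.ndarray  # flow PFS->PD arriving at the start of cycle k
    new_dead: np.ndarray  # flow PD->death arriving at the start of cycle k
    s_os: np.ndarray  # OS curve at cycle starts (PD survivorship kernel)
    # per-cycle accruals, filled in by accumulate() (length n_cycles)
    cost_accrual: np.ndarray | None = None  # discounted
    ly_accrual: np.ndarray | None = None  # undiscounted
    qaly_accrual: np.ndarray | None = None  # discounted

    def occupancy_ok(self, tol: float = 1e-12) -> bool:
        total = self.pfs + self.pd + self.dead
        return bool(np.all(np.abs(total - 1.0) < tol))


@dataclass(frozen=True)
class ArmResult:
    """Totals for one arm.  ``total_ly`` is undiscounted; ``total_qaly``
    and ``total_cost`` are discounted."""

    name: str
    total_cost: float
    total_ly: float
    total_qaly: float
    discounted_ly: float = 0.0
    undiscounted_qaly: float = 0.0
    undiscounted_cost: float = 0.0


@dataclass(frozen=True)
class IcerReport:
    delta_cost: float
    delta_qaly: float
    delta_ly: float
    icer_per_qaly: float | None
    icer_per_ly: float | None
    status: str  # "ratio", "dominant", "dominated", or "undefined"


def discount_factor(k: int, settings: ModelSettings) -> float:
    """Discount factor at the start of cycle k: (1+r)^(-k*c/365.25 days)."""
    r = settings.annual_discount_rate
    years = k * settings.cycle_length_days / 365.25
    return (1.0 + r) ** (-years)


def cycle_transition_probs(s_pfs, s_os, k: int, settings: ModelSettings) -> tuple[float, float]:
    """Per-cycle transition probabilities at cycle k from the two survival
    curves, clamped to [0, 1].  A zero denominator means the curve has been
    exhausted; the probability is set to 1 with a warning."""
    if k < 0:
        raise ValueError("cycle index must be non-negative")
    c = settings.cycle_length_months
    t0, t1 = k * c, (k + 1) * c
    probs = []
    for s in (s_pfs, s_os):
        denom = float(s(t0))
        if denom <= 0.0:
            warnings.warn(f"survival exhausted at cycle {k}; transition probability set to 1")
            probs.append(1.0)
        else:
            probs.append(min(max(1.0 - float(s(t1)) / denom, 0.0), 1.0))
    return probs[0], probs[1]


def run_trace(strategy: StrategyDefinition, settings: ModelSettings) -> MarkovTrace:
    """Propagate the cohort (initially 100% progression-free) through all
    cycles under the configured engine mode."""
    n = settings.n_cycles
    c = settings.cycle_length_months
    t = np.arange(n + 1) * c
    s_pfs = np.asarray(strategy.pfs_model(t), dtype=float)
    s_os = np.asarray(strategy.os_model(t), dtype=float)

    pfs = np.zeros(n + 1)
    pd = np.zeros(n + 1)
    dead = np.zeros(n + 1)
    new_pd = np.zeros(n + 1)
    new_dead = np.zeros(n + 1)

    if settings.engine_mode == "partitioned_survival":
        pfs[:] = np.minimum(s_pfs, s_os)
        dead[:] = 1.0 - s_os
        pd[:] = 1.0 - pfs - dead
        new_pd[1:] = np.maximum(pfs[:-1] - pfs[1:], 0.0)
        new_dead[1:] = dead[1:] - dead[:-1]
    else:
        with np.errstate(divide="ignore", invalid="ignore"):
            p_prog = np.clip(1.0 - s_pfs[1:] / s_pfs[:-1], 0.0, 1.0)
            p_die = np.clip(1.0 - s_os[1:] / s_os[:-1], 0.0, 1.0)
        p_prog = np.where(s_pfs[:-1] <= 0.0, 1.0, p_prog)
        p_die = np.where(s_os[:-1] <= 0.0, 1.0, p_die)
        pfs[0] = 1.0
        for k in range(n):
            new_pd[k + 1] = pfs[k] * p_prog[k]
            new_dead[k + 1] = pd[k] * p_die[k]
            pfs[k + 1] = pfs[k] - new_pd[k + 1]
            pd[k + 1] = pd[k] + new_pd[k + 1] - new_dead[k + 1]
            dead[k + 1] = dead[k] + new_dead[k + 1]

    return MarkovTrace(
        t_months=t, pfs=pfs, pd=pd, dead=dead, new_pd=new_pd, new_dead=new_dead, s_os=s_os
    )


def _pd_age_weights(trace: MarkovTrace, k: int, max_age: int) -> np.ndarray:
    """Occupancy of the PD state at cycle k, split by cycles since entry.

    A patient entering PD at cycle j survives to cycle k with probability
    S_os(t_k)/S_os(t_j) (the per-cycle death hazards telescope), so the
    split is exact in state-transition mode and needs no extra bookkeeping.
    """
    ages = np.arange(min(max_age, k) + 1)
    js = k - ages
    with np.errstate(divide="ignore", invalid="ignore"):
        surv = np.where(trace.s_os[js] > 0, trace.s_os[k] / trace.s_os[js], 0.0)
    return trace.new_pd[js] * surv


def accumulate(trace: MarkovTrace, strategy: StrategyDefinition, settings: ModelSettings) -> ArmResult:
    """Sum discounted costs and QALYs (and undiscounted life-years) over
    the trace.

    Per cycle, state occupants accrue state utility and state cost;
    second-line drug costs depend on time since progression and are
    resolved by vintage.  The one-off adverse-event burden lands at cycle
    0: its cost in full, its disutility for one cycle's duration.  The
    end-of-life cost is charged to each death at its cycle.
    """
    n = settings.n_cycles
    c_yr = settings.cycle_length_years
    df = np.array([discount_factor(k, settings) for k in range(n + 1)])

    if settings.half_cycle_correction:
        pfs_w = 0.5 * (trace.pfs[:-1] + trace.pfs[1:])
        pd_w = 0.5 * (trace.pd[:-1] + trace.pd[1:])
    else:
        pfs_w = trace.pfs[:-1]
        pd_w = trace.pd[:-1]

    alive = pfs_w + pd_w
    ly_undisc = float(np.sum(alive * c_yr))
    ly_disc = float(np.sum(alive * c_yr * df[:-1]))

    q_per_cycle = (pfs_w * settings.utility_pfs + pd_w * settings.utility_pd) * c_yr
    ae_cost, ae_disutility = ae_burden(strategy.ae_profile)
    qaly_disc = float(np.sum(q_per_cycle * df[:-1])) - ae_disutility * c_yr
    qaly_undisc = float(np.sum(q_per_cycle)) - ae_disutility * c_yr

    max_age = int(np.ceil(strategy.second_line_duration_cycles))
    cost_undisc = ae_cost
    cost_disc = ae_cost
    per_cycle_cost = np.zeros(n)
    for k in range(n):
        ck = pfs_w[k] * cycle_cost(strategy, "pfs", k, settings)
        occ_by_age = _pd_age_weights(trace, k, max_age)
        resolved = float(occ_by_age.sum())
        for age, occ in enumerate(occ_by_age):
            ck += occ * cycle_cost(strategy, "pd", k, settings, pd_age=age)
        # occupancy older than the second-line window is pure supportive care
        ck += max(pd_w[k] - resolved, 0.0) * cycle_cost(strategy, "pd", k, settings, pd_age=max_age)
        ck += trace.new_dead[k + 1] * strategy.end_of_life_cost
        cost_undisc += ck
        per_cycle_cost[k] = ck * df[k]
        cost_disc += per_cycle_cost[k]

    trace.cost_accrual = per_cycle_cost
    trace.ly_accrual = alive * c_yr
    trace.qaly_accrual = q_per_cycle * df[:-1]

    return ArmResult(
        name=strategy.name,
        total_cost=cost_disc,
        total_ly=ly_undisc,
        total_qaly=qaly_disc,
        discounted_ly=ly_disc,
        undiscounted_qaly=qaly_undisc,
        undiscounted_cost=cost_undisc,
    )


def run_arm(strategy: StrategyDefinition, settings: ModelSettings) -> ArmResult:
    """Convenience wrapper: trace the cohort and accumulate outcomes."""
    return accumulate(run_trace(strategy, settings), strategy, settings)


def compute_icer(a: ArmResult, b: ArmResult) -> IcerReport:
    """Incremental cost-effectiveness of a versus b (a minus b).

    Dominance is flagged instead of reporting a meaningless ratio:
    cheaper-and-better is "dominant", dearer-and-worse "dominated", and a
    zero effectiveness difference "undefined".
    """
    dc = a.total_cost - b.total_cost
    dq = a.total_qaly - b.total_qaly
    dl = a.total_ly - b.total_ly

    if dq == 0.0:
        status = "undefined"
        icer_q = None
    elif dc < 0.0 and dq > 0.0:
        status = "dominant"
        icer_q = None
    elif dc > 0.0 and dq < 0.0:
        status = "dominated"
        icer_q = None
    else:
        status = "ratio"
        icer_q = dc / dq
    icer_l = dc / dl if dl != 0.0 else None
    return IcerReport(
        delta_cost=dc, delta_qaly=dq, delta_ly=dl,
        icer_per_qaly=icer_q, icer_per_ly=icer_l, status=status,
    )
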