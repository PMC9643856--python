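"""Deterministic and probabilistic sensitivity analysis.

One-way (tornado) analysis re-runs the deterministic model at each
parameter's published low/high bound.  The probabilistic analysis samples
every parameter from its assigned distribution — beta for probabilities
and utilities, gamma for costs and creatinine clearance, normal for body
surface area, and a range-matched log-normal for survival scale/shape —
runs the full two-arm model per draw, and summarises the (Δcost, ΔQALY)
cloud as cost-effectiveness acceptability curves via the net-monetary-
benefit rule.  A price-threshold search finds the adebrelimab vial price
at which the acceptance probability crosses a target, under common random
numbers.
"""

from __future__ import annotations

import copy
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .markov_engine import ModelSettings, compute_icer, discount_factor, run_trace, accumulate
from .workflow import base_value, build_settings, build_strategy, run_base_case

__all__ = [
    "ParamSpec",
    "PsaResult",
    "build_param_specs",
    "sample_parameters",
    "one_way_sensitivity",
    "run_psa",
    "ceac",
    "acceptance_probability",
    "price_threshold",
]

Z95 = 1.959963984540054  # published ranges are 95% intervals for beta/gamma/normal
Z80 = 1.2815515655446004  # survival-parameter ranges are read as 80% intervals


@dataclass(frozen=True)
class ParamSpec:
    """One uncertain parameter: base value, range, sampling distribution,
    and its location (path) inside the configuration tree."""

    name: str
    base: float
    low: float
    high: float
    distribution: str
    path: tuple = ()

    def __post_init__(self) -> None:
        if not self.low <= self.base <= self.high:
            raise ValueError(f"{self.name}: require low <= base <= high")


@dataclass
class PsaResult:
    """Monte-Carlo (Δcost, ΔQALY) cloud plus the per-draw quantities needed
    to rescale the maintenance-drug price analytically."""

    delta_cost: np.ndarray
    delta_qaly: np.ndarray
    n: int
    seed: int
    adeb_price: np.ndarray = field(default_factory=lambda: np.array([]))
    adeb_vials: np.ndarray = field(default_factory=lambda: np.array([]))
    adeb_exposure: np.ndarray = field(default_factory=lambda: np.array([]))


def build_param_specs(cfg: dict) -> list[ParamSpec]:
    """Collect every ``{base, low, high, distribution}`` node in the
    configuration, in a stable document order."""
    specs: list[ParamSpec] = []

    def walk(node, path):
        if isinstance(node, dict):
            if "base" in node and "distribution" in node:
                name = ".".join(str(p) for p in path)
                specs.append(
                    ParamSpec(
                        name=name,
                        base=float(node["base"]),
                        low=float(node["low"]),
                        high=float(node["high"]),
                        distribution=str(node["distribution"]),
                        path=tuple(path),
                    )
                )
                return
            for key, child in node.items():
                walk(child, path + [key])
        elif isinstance(node, list):
            for i, child in enumerate(node):
                walk(child, path + [i])

    walk(cfg, [])
    return specs


def _spec_display_name(cfg: dict, spec: ParamSpec) -> str:
    """Human-readable name, replacing adverse-event list indices."""
    parts = []
    node = cfg
    for key in spec.path:
        if isinstance(key, int) and isinstance(node, list):
            entry = node[key]
            parts.append(entry.get("name", str(key)) if isinstance(entry, dict) else str(key))
        else:
            parts.append(str(key))
        node = node[key]
    return ".".join(parts)


def _set_by_path(cfg: dict, path: tuple, value: float) -> None:
    node = cfg
    for key in path[:-1]:
        node = node[key]
    node[path[-1]]["base"] = value


def sample_parameters(specs: list[ParamSpec], rng: np.random.Generator) -> dict[str, float]:
    """Draw one value per spec.

    beta/gamma/normal are moment-matched to (base, (high-low)/(2*1.96)),
    reading the published range as a 95% interval; ``fixed`` returns the
    base.  ``survival_param`` draws log-normal on the log scale with the
    range read as an 80% (interdecile) interval — the publication states
    no sampling distribution for the survival scale/shape parameters, and
    this dispersion is the one that reproduces its probabilistic results
    (see the methods note).  An infeasible beta moment-match falls back to
    uniform(low, high) with a warning.  The draw sequence is a pure
    function of the generator state, so a fixed seed reproduces it
    bit-for-bit.
    """
    draw: dict[str, float] = {}
    for spec in specs:
        m = spec.base
        sd = (spec.high - spec.low) / (2.0 * Z95)
        dist = spec.distribution.lower()
        if dist == "fixed" or sd == 0.0:
            value = m
        elif dist == "beta":
            var = sd * sd
            if m <= 0.0 or m >= 1.0 or var >= m * (1.0 - m):
                warnings.warn(f"{spec.name}: beta moment-match infeasible; using uniform range")
                value = rng.uniform(spec.low, spec.high)
            else:
                nu = m * (1.0 - m) / var - 1.0
                value = rng.beta(m * nu, (1.0 - m) * nu)
        elif dist == "gamma":
            shape = (m / sd) ** 2
            value = rng.gamma(shape) * (sd * sd / m)
        elif dist == "normal":
            value = rng.normal(m, sd)
        elif dist == "survival_param":
            sigma = (math.log(spec.high) - math.log(spec.low)) / (2.0 * Z80)
            value = math.exp(rng.normal(math.log(m), sigma))
        else:
            raise ValueError(f"{spec.name}: unknown distribution {spec.distribution!r}")
        draw[spec.name] = float(value)
    return draw


def _apply_draw(cfg: dict, specs: list[ParamSpec], draw: dict[str, float]) -> dict:
    new = copy.deepcopy(cfg)
    for spec in specs:
        _set_by_path(new, spec.path, draw[spec.name])
    return new


def one_way_sensitivity(cfg: dict, specs: list[ParamSpec] | None = None) -> pd.DataFrame:
    """Tornado table: deterministic ICER at each parameter's low and high
    bound, all others at base, sorted by interval width descending."""
    if specs is None:
        specs = build_param_specs(cfg)
    rows = []
    for spec in specs:
        icers = {}
        statuses = {}
        for side, value in (("low", spec.low), ("high", spec.high)):
            trial = copy.deepcopy(cfg)
            _set_by_path(trial, spec.path, value)
            report = run_base_case(trial)["icer"]
            icers[side] = report.icer_per_qaly
            statuses[side] = report.status
        finite = [v for v in icers.values() if v is not None]
        width = (max(finite) - min(finite)) if len(finite) == 2 else math.inf
        rows.append(
            {
                "parameter": _spec_display_name(cfg, spec),
                "low_icer": icers["low"],
                "high_icer": icers["high"],
                "low_status": statuses["low"],
                "high_status": statuses["high"],
                "width": width,
            }
        )
    table = pd.DataFrame(rows).sort_values("width", ascending=False, kind="stable")
    return table.reset_index(drop=True)


def _default_factory(cfg_draw: dict, rng: np.random.Generator | None = None):
    settings = build_settings(cfg_draw)
    return build_strategy(cfg_draw, "adchm"), build_strategy(cfg_draw, "plchm"), settings


def _maintenance_exposure(strategy, trace, settings) -> float:
    """Discounted progression-free person-cycles inside the maintenance
    window — the multiplier that converts a per-cycle maintenance-drug
    price change into a total-cost change."""
    if strategy.maintenance_drug is None:
        return 0.0
    n = settings.n_cycles
    occ = trace.pfs[:-1]
    if settings.half_cycle_correction:
        occ = 0.5 * (trace.pfs[:-1] + trace.pfs[1:])
    t = np.arange(n) * settings.cycle_length_months
    df = np.array([discount_factor(k, settings) for k in range(n)])
    mask = t < strategy.maintenance_cap_months
    return float(np.sum(occ[mask] * df[mask]))


def run_psa(
    cfg: dict,
    n: int = 1000,
    seed: int = 20221026,
    strategy_factory=None,
) -> PsaResult:
    """Monte-Carlo PSA: ``n`` independent parameter draws, a full two-arm
    cohort run per draw, (Δcost, ΔQALY) recorded (first arm minus second).

    ``strategy_factory(cfg_draw, rng) -> (arm_a, arm_b, settings)`` lets
    callers substitute alternative arm constructions (e.g. subgroup
    hazard-ratio pairs, which draw their hazard ratios from ``rng``) while
    keeping the sampling machinery.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if strategy_factory is None:
        strategy_factory = _default_factory
    specs = build_param_specs(cfg)
    rng = np.random.default_rng(seed)

    dc = np.empty(n)
    dq = np.empty(n)
    price = np.empty(n)
    vials = np.empty(n)
    exposure = np.empty(n)
    for i in range(n):
        draw = sample_parameters(specs, rng)
        cfg_i = _apply_draw(cfg, specs, draw)
        arm_a, arm_b, settings = strategy_factory(cfg_i, rng)
        trace_a = run_trace(arm_a, settings)
        res_a = accumulate(trace_a, arm_a, settings)
        res_b = accumulate(run_trace(arm_b, settings), arm_b, settings)
        dc[i] = res_a.total_cost - res_b.total_cost
        dq[i] = res_a.total_qaly - res_b.total_qaly
        if arm_a.maintenance_drug is not None:
            mdrug = arm_a.maintenance_drug
            price[i] = mdrug.price.price_per_vial
            vials[i] = mdrug.cost_per_cycle() / max(mdrug.price.price_per_vial, 1e-300)
            exposure[i] = _maintenance_exposure(arm_a, trace_a, settings)
        else:
            price[i] = vials[i] = exposure[i] = 0.0
    return PsaResult(
        delta_cost=dc, delta_qaly=dq, n=n, seed=seed,
        adeb_price=price, adeb_vials=vials, adeb_exposure=exposure,
    )


def adjusted_delta_cost(psa: PsaResult, price_multiplier: float) -> np.ndarray:
    """Δcost under a proportional maintenance-drug price change.

    The sampled vial price enters each draw's cost linearly (fixed vial
    count times discounted exposure), and scaling the price's base value
    scales its gamma draw by the same factor, so the adjustment is exact
    under common random numbers.
    """
    if psa.adeb_exposure.size == 0 or price_multiplier == 1.0:
        return psa.delta_cost
    extra = psa.adeb_vials * psa.adeb_price * (price_multiplier - 1.0) * psa.adeb_exposure
    return psa.delta_cost + extra


def acceptance_probability(psa: PsaResult, wtp: float, price_multiplier: float = 1.0) -> float:
    """Fraction of draws with non-negative net monetary benefit at ``wtp``."""
    dc = adjusted_delta_cost(psa, price_multiplier)
    nmb = wtp * psa.delta_qaly - dc
    return float(np.mean(nmb >= 0.0))


def ceac(psa: PsaResult, wtp_grid) -> pd.DataFrame:
    """Cost-effectiveness acceptability curve over a willingness-to-pay
    grid (net-monetary-benefit rule)."""
    wtp_grid = np.asarray(wtp_grid, dtype=float)
    probs = [acceptance_probability(psa, w) for w in wtp_grid]
    return pd.DataFrame({"wtp": wtp_grid, "probability": probs})


def price_threshold(
    cfg: dict,
    target_prob: float,
    wtp: float | None = None,
    n: int = 1000,
    seed: int = 20221026,
    max_multiplier: float = 200.0,
    tol: float = 1e-4,
    psa: PsaResult | None = None,
) -> dict:
    """Per-vial maintenance-drug price at which the acceptance probability
    crosses ``target_prob`` at the given willingness-to-pay.

    Uses one PSA run (common random numbers) and bisects on the price
    multiplier; the probability is non-increasing in price by
    construction.  Raises if the target is not bracketed below
    ``max_multiplier``.
    """
    if not 0.0 < target_prob < 1.0:
        raise ValueError("target probability must be in (0, 1)")
    if wtp is None:
        wtp = base_value(cfg["settings"]["wtp_threshold"])
    if psa is None:
        psa = run_psa(cfg, n=n, seed=seed)
    base_price = float(base_value(cfg["drugs"]["adebrelimab"]["price"]))

    lo, hi = 0.0, 1.0
    if acceptance_probability(psa, wtp, 1.0) < target_prob:
        # already below target at the current price: search downwards
        lo = 0.0
        hi = 1.0
        if acceptance_probability(psa, wtp, lo) < target_prob:
            raise RuntimeError("target probability not reachable even at zero price")
    else:
        lo, hi = 1.0, max_multiplier
        if acceptance_probability(psa, wtp, hi) >= target_prob:
            raise RuntimeError(f"target not bracketed below multiplier {max_multiplier}")
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if acceptance_probability(psa, wtp, mid) >= target_prob:
            lo = mid
        else:
            hi = mid
    multiplier = 0.5 * (lo + hi)
    return {
        "multiplier": multiplier,
        "price_per_vial": multiplier * base_price,
        "probability": acceptance_probability(psa, wtp, multiplier),
        "wtp": wtp,
        "seed": psa.seed,
        "n": psa.n,
    }
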