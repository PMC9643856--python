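"""Subgroup cost-effectiveness via hazard-ratio adjusted survival.

Per-subgroup Kaplan–Meier curves are rarely published, so subgroup arms
are constructed indirectly: every subgroup's comparator (chemotherapy)
arm keeps the baseline PLCHM survival functions, and the ADCHM arm's
progression-free and overall survival are the baseline curves raised to
the subgroup-specific hazard ratios, S(t)**HR.  All cost and utility
parameters stay at their base-case values; only the hazard ratios vary.

Deterministic subgroup ICERs use the point hazard ratios.  The subgroup
probabilistic analysis additionally samples each hazard ratio
log-normally from its reported 95% confidence interval (when one is
available), since treatment-effect uncertainty — not parameter
uncertainty — dominates a subgroup's probability of cost-effectiveness.
"""

from __future__ import annotations

import importlib.resources
import io
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .markov_engine import IcerReport, compute_icer, run_arm
from .parametric_survival import apply_hazard_ratio
from .uncertainty import Z95, acceptance_probability, run_psa
from .workflow import build_settings, build_strategy

__all__ = [
    "SubgroupSpec",
    "load_subgroup_specs",
    "subgroup_pair",
    "subgroup_icer",
    "subgroup_table",
]


@dataclass(frozen=True)
class SubgroupSpec:
    """A subgroup's treatment-effect summary: PFS and OS hazard ratios for
    ADCHM versus PLCHM (both positive), optionally with 95% CIs."""

    label: str
    hr_pfs: float
    hr_os: float
    category: str = ""
    hr_pfs_ci: tuple[float, float] | None = None
    hr_os_ci: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if not (self.hr_pfs > 0 and self.hr_os > 0):
            raise ValueError(f"{self.label}: hazard ratios must be positive")


def load_subgroup_specs(path: str | None = None) -> list[SubgroupSpec]:
    """Load the packaged subgroup hazard-ratio table (or a CSV mirroring
    its columns: category,label,hr_pfs[,hr_pfs_lo,hr_pfs_hi],hr_os[,...])."""
    if path is None:
        text = importlib.resources.files("sclcea.data").joinpath("subgroup_hr.csv").read_text()
        df = pd.read_csv(io.StringIO(text))
    else:
        df = pd.read_csv(path)

    def ci(row, stem):
        lo, hi = f"{stem}_lo", f"{stem}_hi"
        if lo in row and hi in row and pd.notna(row[lo]) and pd.notna(row[hi]):
            return (float(row[lo]), float(row[hi]))
        return None

    return [
        SubgroupSpec(
            label=row["label"],
            hr_pfs=float(row["hr_pfs"]),
            hr_os=float(row["hr_os"]),
            category=row.get("category", ""),
            hr_pfs_ci=ci(row, "hr_pfs"),
            hr_os_ci=ci(row, "hr_os"),
        )
        for _, row in df.iterrows()
    ]


def _sample_hr(point: float, ci: tuple[float, float] | None, rng) -> float:
    """Log-normal draw with the reported 95% CI; the point value if no CI
    or no generator is supplied."""
    if ci is None or rng is None:
        return point
    sigma = (math.log(ci[1]) - math.log(ci[0])) / (2.0 * Z95)
    return math.exp(rng.normal(math.log(point), sigma))


def _pair_factory(spec: SubgroupSpec, sample_hr: bool = False):
    def factory(cfg: dict, rng=None):
        settings = build_settings(cfg)
        plchm = build_strategy(cfg, "plchm")
        hr_pfs = _sample_hr(spec.hr_pfs, spec.hr_pfs_ci if sample_hr else None, rng)
        hr_os = _sample_hr(spec.hr_os, spec.hr_os_ci if sample_hr else None, rng)
        adchm = build_strategy(
            cfg,
            "adchm",
            pfs_model=apply_hazard_ratio(plchm.pfs_model, hr_pfs),
            os_model=apply_hazard_ratio(plchm.os_model, hr_os),
        )
        return adchm, plchm, settings

    return factory


def subgroup_pair(cfg: dict, spec: SubgroupSpec):
    """Build the (ADCHM, PLCHM) strategy pair for one subgroup: PLCHM at
    baseline, ADCHM with S_baseline**HR survival, costs unchanged."""
    adchm, plchm, _ = _pair_factory(spec)(cfg)
    return adchm, plchm


def subgroup_icer(cfg: dict, spec: SubgroupSpec) -> IcerReport:
    """Deterministic subgroup ICER (ADCHM versus PLCHM) at base values and
    point hazard ratios."""
    adchm, plchm, settings = _pair_factory(spec)(cfg)
    return compute_icer(run_arm(adchm, settings), run_arm(plchm, settings))


def subgroup_table(
    cfg: dict,
    specs: list[SubgroupSpec] | None = None,
    psa_n: int = 1000,
    seed: int = 20221026,
    sample_hr: bool = True,
) -> pd.DataFrame:
    """One row per subgroup: deterministic ICER plus (if ``psa_n`` > 0) the
    probability of cost-effectiveness at the configured willingness-to-pay
    from a subgroup-specific probabilistic sensitivity analysis."""
    if specs is None:
        specs = load_subgroup_specs()
    if not specs:
        raise ValueError("need at least one subgroup spec")
    wtp = cfg["settings"]["wtp_threshold"]
    rows = []
    for spec in specs:
        report = subgroup_icer(cfg, spec)
        row = {
            "category": spec.category,
            "label": spec.label,
            "hr_pfs": spec.hr_pfs,
            "hr_os": spec.hr_os,
            "icer_per_qaly": report.icer_per_qaly,
            "status": report.status,
        }
        if psa_n > 0:
            psa = run_psa(
                cfg, n=psa_n, seed=seed,
                strategy_factory=_pair_factory(spec, sample_hr=sample_hr),
            )
            row["acceptance_probability"] = acceptance_probability(psa, wtp)
        rows.append(row)
    return pd.DataFrame(rows)
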