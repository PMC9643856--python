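"""Synthetic stand-ins for the study's external inputs.

The published analysis starts from digitized Kaplan–Meier figures, which
cannot be redistributed.  This module generates the equivalent artefacts
from known ground truth: patient-level survival times drawn from a chosen
parametric family (with administrative censoring), their product-limit
curve and numbers-at-risk table on a reporting grid, and the full
base-case parameter configuration.  Because the generating parameters are
known, the whole curve-to-parameters pipeline (digitize -> reconstruct
pseudo-IPD -> fit) can be validated end-to-end.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .km_reconstruction import DigitizedCurve
from .parametric_survival import IpdRecord, SurvivalModel
from .workflow import load_config

__all__ = ["SimulationSpec", "simulate_ipd", "km_from_ipd", "make_base_fixture"]


@dataclass(frozen=True)
class SimulationSpec:
    """Recipe for one synthetic trial arm.

    Defaults emulate a two-arm phase-III trial arm: 230 patients with
    administrative censoring at 24 months.
    """

    model: SurvivalModel
    n: int = 230
    censor_time_months: float = 24.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if not self.censor_time_months > 0:
            raise ValueError("censor time must be positive")


def _inverse_cdf(model: SurvivalModel, u: np.ndarray) -> np.ndarray:
    """Event time with survival u: t = S^{-1}(u), per family."""
    lam, gam = model.scale, model.shape
    if model.family == "exponential":
        return -np.log(u) / lam
    if model.family == "weibull":
        return np.power(-np.log(u), 1.0 / gam) / lam
    if model.family == "lognormal":
        from scipy.stats import norm

        return np.exp(norm.isf(u) / gam) / lam
    # log-logistic: S(t)=u  <=>  t = (1/lam) * (1/u - 1)^(1/gam)
    return np.power(1.0 / u - 1.0, 1.0 / gam) / lam


def simulate_ipd(spec: SimulationSpec) -> list[IpdRecord]:
    """Draw event times by inversion and apply administrative censoring.

    Reproducible: the same spec (including seed) yields the same dataset.
    """
    rng = np.random.default_rng(spec.seed)
    u = rng.uniform(size=spec.n)
    times = _inverse_cdf(spec.model, u)
    records = []
    for t in times:
        if t > spec.censor_time_months:
            records.append(IpdRecord(time=spec.censor_time_months, event=False))
        else:
            records.append(IpdRecord(time=float(t), event=True))
    return records


def km_from_ipd(ipd: Sequence[IpdRecord], grid) -> DigitizedCurve:
    """Product-limit estimate with numbers-at-risk, shaped like a digitized
    figure.

    The curve is reported at its own step times (each unique event time up
    to the end of ``grid``, plus the origin) — what a digitizer clicking
    every visible step of a published figure produces — while the
    at-risk table is tabulated at the ``grid`` times, emulating the
    coarser printed numbers-at-risk row.
    """
    if not ipd:
        raise ValueError("need at least one record")
    grid = np.asarray(grid, dtype=float)
    t_max = float(grid[-1])
    times = np.array([r.time for r in ipd])
    events = np.array([r.event for r in ipd])

    from lifelines import KaplanMeierFitter

    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events.astype(int))
    steps = np.unique(times[events & (times <= t_max)])
    curve_t = np.concatenate([[0.0], steps])
    if t_max > (curve_t[-1] if len(curve_t) else 0.0):
        curve_t = np.concatenate([curve_t, [t_max]])
    surv = kmf.survival_function_at_times(curve_t).to_numpy()
    at_risk = np.array([(times >= g - 1e-12).sum() for g in grid], dtype=int)
    return DigitizedCurve(
        times=curve_t, survival=surv, at_risk_times=grid, at_risk_counts=at_risk
    )


def make_base_fixture(out_dir=None) -> dict:
    """Emit the full base-case configuration bundle (survival parameters,
    adverse events, prices, utilities, proportions, patient profile) plus
    the subgroup hazard-ratio table.

    With ``out_dir`` the bundle is also written as the same text formats
    the pipeline reads (YAML config + CSV hazard-ratio table).
    """
    import importlib.resources
    from pathlib import Path

    cfg = load_config()
    hr_text = importlib.resources.files("sclcea.data").joinpath("subgroup_hr.csv").read_text()
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        import yaml

        (out / "base_config.yaml").write_text(yaml.safe_dump(cfg, sort_keys=False))
        (out / "subgroup_hr.csv").write_text(hr_text)
    return cfg
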