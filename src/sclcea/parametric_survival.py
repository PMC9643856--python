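"""Parametric survival families for extrapolating trial endpoint curves.

All models use a (scale, shape) parameterisation in which ``scale`` (lambda)
has units of 1/month and, for every family except the Weibull and
exponential, the median survival time equals ``1/scale``.  This makes the
scale directly interpretable against the medians a trial report prints:
e.g. a log-logistic overall-survival scale of 0.0628/month implies a median
of 15.9 months.

The log-logistic family, which drives the base-case model, has

    S(t) = 1 / (1 + (lambda * t)**gamma)

with shape gamma > 1 giving a unimodal hazard — the usual choice for
immunotherapy trials whose hazards rise and then decay.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy.stats import norm

__all__ = [
    "FAMILIES",
    "SurvivalModel",
    "IpdRecord",
    "FitResult",
    "FittingError",
    "survival_probability",
    "median_survival",
    "fit_ipd",
    "fit_all_families",
    "select_best",
    "apply_hazard_ratio",
    "HazardScaledSurvival",
    "read_ipd",
    "write_ipd",
]

#: Families considered for endpoint extrapolation, in report order.  This
#: order is also the final tie-break in :func:`select_best`.
FAMILIES = ("exponential", "weibull", "lognormal", "loglogistic")


class FittingError(RuntimeError):
    """Raised when maximum-likelihood fitting is impossible or diverges."""


@dataclass(frozen=True)
class SurvivalModel:
    """A parametric survival function S(t) with time measured in months.

    Parameters
    ----------
    family:
        One of :data:`FAMILIES`.
    scale:
        Rate-like scale parameter lambda (1/month); must be positive.
    shape:
        Dimensionless shape parameter gamma; must be positive.  ``None``
        for the exponential family (which has no shape).
    """

    family: str
    scale: float
    shape: float | None = None

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; expected one of {FAMILIES}")
        if not (self.scale > 0 and math.isfinite(self.scale)):
            raise ValueError(f"scale must be positive and finite, got {self.scale}")
        if self.family == "exponential":
            if self.shape is not None:
                raise ValueError("exponential family takes no shape parameter")
        else:
            if self.shape is None or not (self.shape > 0 and math.isfinite(self.shape)):
                raise ValueError(f"shape must be positive and finite, got {self.shape}")

    def survival(self, t):
        return survival_probability(self, t)

    # survival objects are used interchangeably with plain callables
    __call__ = survival

    def median(self) -> float:
        return median_survival(self)


@dataclass(frozen=True)
class IpdRecord:
    """One (possibly right-censored) patient observation, time in months."""

    time: float
    event: bool

    def __post_init__(self) -> None:
        if not (self.time >= 0 and math.isfinite(self.time)):
            raise ValueError(f"time must be finite and non-negative, got {self.time}")


@dataclass(frozen=True)
class FitResult:
    """Maximum-likelihood fit of one family, with information criteria."""

    model: SurvivalModel
    loglik: float
    aic: float
    bic: float
    n: int
    k_params: int


def survival_probability(model: SurvivalModel, t):
    """Evaluate S(t) for ``model`` at time ``t`` (months; scalar or array).

    Raises ``ValueError`` for negative times.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("survival is only defined for t >= 0")
    lam, gam = model.scale, model.shape
    if model.family == "exponential":
        s = np.exp(-lam * t)
    elif model.family == "weibull":
        s = np.exp(-np.power(lam * t, gam))
    elif model.family == "lognormal":
        # S(t) = 1 - Phi(gamma * ln(lambda t)); median 1/lambda, gamma = 1/sigma
        with np.errstate(divide="ignore"):
            z = gam * np.log(np.where(t > 0, lam * t, 1.0))
        s = np.where(t > 0, norm.sf(z), 1.0)
    elif model.family == "loglogistic":
        s = 1.0 / (1.0 + np.power(lam * t, gam))
    else:  # pragma: no cover - guarded by __post_init__
        raise ValueError(model.family)
    return float(s) if s.ndim == 0 else s


def median_survival(model: SurvivalModel) -> float:
    """Closed-form median, i.e. the t with S(t) = 1/2 (months)."""
    lam, gam = model.scale, model.shape
    if model.family == "exponential":
        return math.log(2.0) / lam
    if model.family == "weibull":
        return math.log(2.0) ** (1.0 / gam) / lam
    # lognormal and loglogistic share median = 1/lambda in this parameterisation
    return 1.0 / lam


@dataclass(frozen=True)
class HazardScaledSurvival:
    """Baseline survival raised to a hazard ratio: S(t)**hr.

    This is the proportional-hazards adjustment applied on the cumulative
    survival scale, the standard construction when only a subgroup hazard
    ratio (not a refitted curve) is available.
    """

    base: Callable[[np.ndarray], np.ndarray]
    hr: float

    def survival(self, t):
        return np.power(self.base(t), self.hr)

    __call__ = survival


def apply_hazard_ratio(base, hr: float) -> HazardScaledSurvival:
    """Return the survival function t -> S_base(t)**hr.

    ``hr < 1`` improves survival at every t, ``hr > 1`` worsens it; S(0)=1
    and monotonicity are preserved for any positive hr.
    """
    if not (hr > 0 and math.isfinite(hr)):
        raise ValueError(f"hazard ratio must be positive and finite, got {hr}")
    return HazardScaledSurvival(base=base, hr=float(hr))


# ---------------------------------------------------------------------------
# Maximum-likelihood fitting (right-censored), via lifelines


def _to_arrays(data: Sequence[IpdRecord]) -> tuple[np.ndarray, np.ndarray]:
    times = np.array([r.time for r in data], dtype=float)
    events = np.array([r.event for r in data], dtype=bool)
    return times, events


def _lifelines_fitter(family: str):
    import lifelines

    return {
        "exponential": lifelines.ExponentialFitter,
        "weibull": lifelines.WeibullFitter,
        "lognormal": lifelines.LogNormalFitter,
        "loglogistic": lifelines.LogLogisticFitter,
    }[family]()


def _model_from_fitter(family: str, fitter) -> SurvivalModel:
    # translate lifelines' native parameterisations into (scale 1/month, shape)
    if family == "exponential":
        return SurvivalModel("exponential", scale=1.0 / fitter.lambda_)
    if family == "weibull":
        return SurvivalModel("weibull", scale=1.0 / fitter.lambda_, shape=fitter.rho_)
    if family == "lognormal":
        return SurvivalModel("lognormal", scale=math.exp(-fitter.mu_), shape=1.0 / fitter.sigma_)
    return SurvivalModel("loglogistic", scale=1.0 / fitter.alpha_, shape=fitter.beta_)


def fit_ipd(data: Sequence[IpdRecord], family: str) -> FitResult:
    """Fit one parametric family to right-censored patient-level data by
    maximum likelihood.

    Requires at least two events.  Non-convergence raises
    :class:`FittingError` rather than returning garbage estimates.
    """
    if family not in FAMILIES:
        raise ValueError(f"unknown family {family!r}")
    times, events = _to_arrays(data)
    if events.sum() < 2:
        raise FittingError(f"need at least 2 events to fit, got {int(events.sum())}")
    if np.any(~np.isfinite(times)):
        raise FittingError("non-finite times in input")

    from lifelines.exceptions import ConvergenceError

    fitter = _lifelines_fitter(family)
    try:
        # lifelines rejects t=0 for log-location families; nudge exact zeros
        t = np.maximum(times, 1e-9)
        fitter.fit(t, event_observed=events.astype(int))
    except (ConvergenceError, ValueError) as exc:
        raise FittingError(f"{family} fit did not converge: {exc}") from exc

    model = _model_from_fitter(family, fitter)
    loglik = float(fitter.log_likelihood_)
    k = 1 if family == "exponential" else 2
    n = len(times)
    return FitResult(
        model=model,
        loglik=loglik,
        aic=2.0 * k - 2.0 * loglik,
        bic=k * math.log(n) - 2.0 * loglik,
        n=n,
        k_params=k,
    )


def fit_all_families(data: Sequence[IpdRecord]) -> list[FitResult]:
    """Fit every family in :data:`FAMILIES`, skipping ones that fail."""
    fits = []
    for family in FAMILIES:
        try:
            fits.append(fit_ipd(data, family))
        except FittingError:
            continue
    if not fits:
        raise FittingError("no family could be fitted")
    return fits


def select_best(fits: Sequence[FitResult]) -> FitResult:
    """Pick the best fit: minimal AIC, ties by minimal BIC, then by the
    listing order of :data:`FAMILIES`."""
    if not fits:
        raise ValueError("select_best requires a non-empty list of fits")
    order = {f: i for i, f in enumerate(FAMILIES)}
    return min(fits, key=lambda f: (f.aic, f.bic, order[f.model.family]))


# ---------------------------------------------------------------------------
# Delimited-text I/O (columns: time,event — months, 0/1)


def write_ipd(records: Sequence[IpdRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write("time,event\n")
        for r in records:
            fh.write(f"{r.time:.10g},{int(r.event)}\n")


def read_ipd(path) -> list[IpdRecord]:
    records = []
    with open(path) as fh:
        header = fh.readline().strip().split(",")
        if header[:2] != ["time", "event"]:
            raise ValueError(f"expected header 'time,event', got {header}")
        for line in fh:
            if not line.strip():
                continue
            t, e = line.strip().split(",")[:2]
            records.append(IpdRecord(time=float(t), event=bool(int(e))))
    return records
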