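"""Pseudo individual-patient-data from digitized Kaplan–Meier curves.

Published trials rarely deposit patient-level survival data; what they print
is the Kaplan–Meier curve and a numbers-at-risk table.  This module inverts
that summary: within each at-risk interval it allocates integer event and
censoring counts so that (a) the product-limit estimate of the output
matches the digitized curve at the step times as closely as integer rounding
allows and (b) the risk set at each at-risk time matches the published
table.  The reconstructed records can then be fed to parametric fitting.

Assumptions (fixed, deterministic):

* censoring is uniform within each at-risk interval;
* fractional event counts are integerised by largest-remainder rounding
  within the interval;
* event times sit exactly at the digitized step times, censor times are
  spread evenly over the interval.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .parametric_survival import IpdRecord

__all__ = [
    "DigitizedCurve",
    "ReconstructionError",
    "validate_curve",
    "reconstruct_ipd",
    "read_digitized_curve",
    "write_digitized_curve",
]


class ReconstructionError(ValueError):
    """Digitized inputs are inconsistent (e.g. would need negative censoring)."""


@dataclass(frozen=True)
class DigitizedCurve:
    """Digitized survival coordinates plus a numbers-at-risk table.

    ``times``/``survival`` are the curve coordinates (months, probability);
    ``at_risk_times``/``at_risk_counts`` give the published risk set.
    """

    times: np.ndarray
    survival: np.ndarray
    at_risk_times: np.ndarray = field(default_factory=lambda: np.array([]))
    at_risk_counts: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    def __post_init__(self) -> None:
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))
        object.__setattr__(self, "survival", np.asarray(self.survival, dtype=float))
        object.__setattr__(self, "at_risk_times", np.asarray(self.at_risk_times, dtype=float))
        object.__setattr__(self, "at_risk_counts", np.asarray(self.at_risk_counts, dtype=int))
        if len(self.times) != len(self.survival):
            raise ValueError("times and survival must have equal length")
        if len(self.at_risk_times) != len(self.at_risk_counts):
            raise ValueError("at-risk times and counts must have equal length")


def validate_curve(raw: DigitizedCurve) -> DigitizedCurve:
    """Clean digitization noise: clamp survival to [0, 1], clip each value at
    the previous one (isotonic, non-increasing), and prepend the (0, 1.0)
    origin if absent.  Non-increasing time stamps are an error, not noise.
    """
    times = np.asarray(raw.times, dtype=float)
    surv = np.asarray(raw.survival, dtype=float)
    if len(times) < 2:
        raise ReconstructionError("need at least 2 digitized points")
    if np.any(np.diff(times) <= 0):
        raise ReconstructionError("digitized time stamps must be strictly increasing")

    surv = np.clip(surv, 0.0, 1.0)
    surv = np.minimum.accumulate(surv)
    if times[0] > 0:
        times = np.concatenate([[0.0], times])
        surv = np.concatenate([[1.0], surv])
    else:
        surv = surv.copy()
        surv[0] = 1.0
    return DigitizedCurve(times, surv, raw.at_risk_times, raw.at_risk_counts)


def _largest_remainder(real_counts: np.ndarray, total: int) -> np.ndarray:
    """Integerise non-negative reals to sum exactly to ``total``."""
    real_counts = np.maximum(real_counts, 0.0)
    floors = np.floor(real_counts).astype(int)
    excess = int(total - floors.sum())
    if excess > 0:
        order = np.argsort(-(real_counts - floors), kind="stable")
        floors[order[:excess]] += 1
    elif excess < 0:
        order = np.argsort(real_counts - floors, kind="stable")
        for idx in order:
            take = min(floors[idx], -excess)
            floors[idx] -= take
            excess += take
            if excess == 0:
                break
    return floors


def reconstruct_ipd(curve: DigitizedCurve) -> list[IpdRecord]:
    """Allocate events and censorings interval-by-interval.

    For each at-risk interval [T_i, T_{i+1}) the event hazard at every
    digitized step inside is taken from the survival ratio; the interval's
    censor count is whatever part of the risk-set drop events do not
    explain.  A survival drop that would require negative censoring raises
    :class:`ReconstructionError` naming the interval.
    """
    curve = validate_curve(curve)
    ar_t = curve.at_risk_times
    ar_n = curve.at_risk_counts
    if len(ar_t) < 2:
        raise ReconstructionError("need an at-risk table with at least 2 entries")
    if np.any(np.diff(ar_t) <= 0):
        raise ReconstructionError("at-risk times must be strictly increasing")
    if np.any(np.diff(ar_n) > 0):
        raise ReconstructionError("at-risk counts must be non-increasing")
    if ar_t[-1] < curve.times[-1] - 1e-9:
        raise ReconstructionError("at-risk table must cover the digitized time span")

    def S(t: float) -> float:
        # step-function value of the digitized curve at time t
        idx = np.searchsorted(curve.times, t + 1e-12) - 1
        return float(curve.survival[max(idx, 0)])

    records: list[IpdRecord] = []
    for i in range(len(ar_t) - 1):
        t0, t1 = float(ar_t[i]), float(ar_t[i + 1])
        n0, n1 = int(ar_n[i]), int(ar_n[i + 1])
        drop = n0 - n1

        inside = (curve.times > t0 + 1e-12) & (curve.times <= t1 + 1e-12)
        step_times = curve.times[inside]
        step_surv = curve.survival[inside]

        s_prev = S(t0)
        if s_prev <= 0:
            continue  # curve already at zero: nobody left to allocate

        # hazard per step from survival ratios, conditional on S at interval start
        cond = np.ones(len(step_times))
        prev = s_prev
        for j, s in enumerate(step_surv):
            cond[j] = 0.0 if prev <= 0 else max(0.0, 1.0 - s / prev)
            prev = s

        # two passes: first ignore censoring to size the event total, then
        # re-spread assuming the implied censors arrive uniformly in time
        d_real = np.zeros(len(step_times))
        c_total = 0.0
        for _ in range(2):
            r = float(n0)
            censored_rate = c_total / (t1 - t0) if t1 > t0 else 0.0
            last_t = t0
            for j, (tt, h) in enumerate(zip(step_times, cond)):
                r -= censored_rate * (tt - last_t)
                d_real[j] = max(r, 0.0) * h
                r -= d_real[j]
                last_t = tt
            events_real = float(d_real.sum())
            c_total = drop - events_real
            if c_total < -0.5:
                raise ReconstructionError(
                    f"interval [{t0:g}, {t1:g}]: survival drop implies "
                    f"{events_real:.1f} events but the risk set only falls by {drop}"
                )
            c_total = max(c_total, 0.0)

        d_int = _largest_remainder(d_real, min(int(round(events_real)), drop))
        c_int = drop - int(d_int.sum())

        for tt, d in zip(step_times, d_int):
            records.extend(IpdRecord(time=float(tt), event=True) for _ in range(d))
        for l in range(c_int):
            tc = t0 + (l + 0.5) * (t1 - t0) / c_int
            records.append(IpdRecord(time=float(tc), event=False))

    # anyone still at risk at the last table time is administratively censored there
    for _ in range(int(ar_n[-1])):
        records.append(IpdRecord(time=float(ar_t[-1]), event=False))

    records.sort(key=lambda r: (r.time, not r.event))
    return records


# ---------------------------------------------------------------------------
# Delimited-text I/O: curve as (time,survival), at-risk as (time,n_at_risk)


def write_digitized_curve(curve: DigitizedCurve, points_path, at_risk_path) -> None:
    with open(points_path, "w") as fh:
        fh.write("time,survival\n")
        for t, s in zip(curve.times, curve.survival):
            fh.write(f"{t:.10g},{s:.10g}\n")
    with open(at_risk_path, "w") as fh:
        fh.write("time,n_at_risk\n")
        for t, n in zip(curve.at_risk_times, curve.at_risk_counts):
            fh.write(f"{t:.10g},{int(n)}\n")


def read_digitized_curve(points_path, at_risk_path) -> DigitizedCurve:
    def read_two_columns(path, expected):
        rows = []
        with open(path) as fh:
            header = fh.readline().strip().split(",")
            if header[:2] != expected:
                raise ValueError(f"expected header {expected}, got {header}")
            for line in fh:
                if line.strip():
                    a, b = line.strip().split(",")[:2]
                    rows.append((float(a), float(b)))
        return rows

    points = read_two_columns(points_path, ["time", "survival"])
    at_risk = read_two_columns(at_risk_path, ["time", "n_at_risk"])
    return DigitizedCurve(
        times=[p[0] for p in points],
        survival=[p[1] for p in points],
        at_risk_times=[a[0] for a in at_risk],
        at_risk_counts=[int(a[1]) for a in at_risk],
    )
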