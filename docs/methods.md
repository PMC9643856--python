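# Methods

This note documents the model implemented in `sclcea`: its structure,
parameter conventions, numerical choices, and the places where the
published analysis it re-implements left a decision open — together with
the choice made here and why.

## Model structure

Three mutually exclusive health states: progression-free (PFS),
progressive disease (PD), death. The cohort starts 100% progression-free
and moves through 120 cycles of 21 days (6.9 years, long enough for
roughly 99% of the cohort to die; the engine reaches ~93–99% depending
on arm). Background all-cause mortality is not modelled: ES-SCLC
lethality dominates over this horizon.

Per-cycle transition probabilities are taken from the two fitted
marginal curves:

- PFS → PD: `1 − S_pfs(t_{k+1})/S_pfs(t_k)`
- PD → death: `1 − S_os(t_{k+1})/S_os(t_k)`
- PFS → death: structurally zero; no state is ever re-entered.

This is the default **state-transition** mode. Because deaths are drawn
only from the PD occupancy at the OS per-cycle hazard, cohort survival
exceeds the OS curve itself — total life expectancy is larger than the
restricted mean of the OS curve alone. That signature matches the
published life-year totals (2.47/1.59 LYs, versus ~1.9/~1.35 years for
the OS curves' areas), which is why this mode, and not area-under-curve
partitioned survival, is the default. A **partitioned-survival** mode
(occupancy read directly off the curves: PFS = min(S_pfs, S_os),
death = 1 − S_os) is implemented behind the same interface and
selectable in the configuration (`settings.engine_mode`) for structural
comparison; it yields strictly lower life-years.

### Discounting and reporting conventions

Costs and QALYs are discounted at 5%/year with per-cycle factors
`(1+r)^(−k·21/365.25)`. Life-years are reported **undiscounted**: the
published convention discounts costs and health utilities but not
life-years, and the
published incremental life-years (0.88) and ICER per LY ($11,851) are
reproduced only by undiscounted LYs (ours: 2.500/1.611, Δ = 0.889).
Discounted life-years are computed and exported as a secondary column.

Accrual uses start-of-cycle occupancy; a half-cycle correction
(averaging start and end occupancy) is available as a switch and off by
default, since the published model does not mention one. State costs
are likewise charged to start-of-cycle occupancy.

### Adverse events

Grade ≥3 events with incidence >5% (neutropenia, leukopenia,
thrombocytopenia, anemia) enter as an expected one-off burden at cycle
0: cost `Σ incidence×unit cost` (≈$824 ADCHM, ≈$739 PLCHM) and a
utility decrement `Σ incidence×disutility` applied **for one cycle's
duration** (≈0.34 × 21/365.25 years ≈ 0.019 QALYs). Treating the raw
incidence-weighted disutility sum as a whole-QALY deduction instead
would remove ~0.34 QALYs and is clearly incompatible with the published
totals (1.21/0.81 QALYs); the one-cycle reading reproduces them to
~1%. Severe haematological toxicity clusters in the early chemotherapy
cycles, so a single-cycle duration is also the clinically natural
reading.

## Survival

All families use a `(scale λ, shape γ)` parameterisation with λ in
1/month. The log-logistic survival function is
`S(t) = 1/(1+(λt)^γ)`, so the median is exactly `1/λ`. The time unit is
fixed by a sanity gate: the base-case OS scales imply medians of 15.9
(ADCHM) and 13.1 (PLCHM) months against trial medians of 15.3 and 12.8
— consistent only if λ is per month. This check is a test.

Fitting is right-censored maximum likelihood via `lifelines`
(exponential, Weibull, log-normal, log-logistic fitters), with results
translated into the package's parameterisation; the exponential fit is
verified against its closed-form MLE to 6 significant digits. Family
selection minimises AIC; ties break by BIC, then by the listing order
exponential → Weibull → log-normal → log-logistic. The AIC/BIC
disagreement rule is this package's convention — the source analysis
reports both criteria without stating one.

### Pseudo-IPD reconstruction

Digitized curves (time, survival) plus a numbers-at-risk table are
inverted interval by interval: event hazards at each digitized step come
from consecutive survival ratios; the residual risk-set drop becomes
censoring, assumed uniform in time within the interval (two passes, so
the censoring estimate feeds back into the event risk sets); fractional
event counts are integerised by largest-remainder rounding; whoever
remains at the final table time is administratively censored there. A
drop in survival that the at-risk table cannot support (negative
censoring) is a hard error naming the interval. Total event counts
reported in trial text are *not* used as an extra constraint.

The synthetic generator emulates what a careful digitizer produces: the
product-limit curve at its actual step times (each visible step of a
published figure) with the at-risk row on a coarser grid. Sampling the
curve only at grid times instead would push every event to its
interval's right edge and bias the refitted scale down by ~5% — with
step-time curves the end-to-end pipeline (simulate → KM → reconstruct →
refit, n=500, 24-month administrative censoring) recovers λ and γ with
a mean absolute relative error of ~3% over 20 replicates.

## Costing

Reference patient: 65 kg, 1.64 m, BSA 1.72 m², creatinine clearance
70 mL/min. Doses: carboplatin by the Calvert formula (AUC 5 →
475 mg/cycle), etoposide 100 mg/m² on days 1–3 of each 21-day cycle
(the trial regimen's 3 administrations; the source text says only "per
cycle"), adebrelimab 20 mg/kg (1300 mg) per cycle. Whole-vial billing:
`ceil(dose/vial) × vial price`, no sharing (e.g. adebrelimab 13 × 100 mg
vials = $335.01/cycle).

Schedule: chemotherapy for the first 6 cycles in PFS; adebrelimab
(ADCHM only) while progression-free, capped at 24 months — the reported
median treatment duration of 8 cycles is descriptive, not a cap. Tests
($152.09) and follow-up ($73.86) accrue per cycle in PFS and PD (both
PD flags are configurable; charging both reproduces the published ICER
best). On progression, a fixed fraction (0.40 ADCHM / 0.52 PLCHM)
receives second-line irinotecan+cisplatin for 3.6 cycles — full cost
for three cycles, 0.6 weight in the fourth, tracked exactly by
progression vintage (PD survivorship telescopes through the OS curve,
so the age split is closed-form) — while the remainder, and everyone
afterwards, receives best supportive care ($359/cycle). Second-line
dosing (irinotecan 65 mg/m² days 1 and 8, cisplatin 75 mg/m² day 1) is
a configurable convention; the source states only the drugs and
duration. End-of-life care ($2,176) is charged once per death at the
cycle of death.

## Sensitivity analysis

**One-way:** each parameter in the configuration is set to its
published low/high bound (95% CIs where available, ±20% otherwise;
discount rate 0–8%) with all others at base; the tornado table records
both ICERs and the interval width.

**Probabilistic (1,000 iterations):** beta for probabilities,
proportions and utilities (moment-matched to base and
sd = range/(2×1.96), falling back to uniform on the range if the
moment match is infeasible), gamma for costs and creatinine clearance,
normal for body-surface area, all reading the published range as a 95%
interval. The post-progression mix stays coherent by sampling the
second-line fraction and taking best supportive care as its
complement. The discount rate is fixed.

The survival parameters need their own rule: the source assigns them no
sampling distribution (its distribution column merely labels them as
log-logistic survival parameters, and its beta/gamma/normal enumeration
excludes them). They are sampled log-normally, independently, centred
on the base value. The dispersion was **identified from the published
probabilistic results**: reading the stated ±20% spread as a 95%
interval makes the acceptance probability 0.97 against a published
89.1% and 0.86 against 74.1% at 1.5× price, while reading it as an 80%
(interdecile) interval — σ_log = (ln hi − ln lo)/2.563 — reproduces all
three published probabilistic outputs at once (≈0.88–0.91 at base
price, ≈0.77 at 1.5×, 50% crossing at ≈2.2× versus 2.15×). The
interdecile reading is therefore the default. Note the two printed
accounts of the 50% crossing price ($55.40 vs $54.40) disagree with
each other; the threshold search here lands at $55–57 depending on
seed.

Acceptance probabilities use the net-monetary-benefit rule
(`P[w·ΔE − ΔC ≥ 0]`), which handles draws with negative incremental
effectiveness coherently. The price-threshold search exploits the fact
that the maintenance-drug price enters each draw's cost linearly (fixed
vial count × discounted progression-free exposure) and that scaling a
gamma-distributed price's base scales its draw proportionally: one PSA
provides the exact acceptance probability at every price multiplier
under common random numbers, and bisection finds the crossing. This
linearity is verified against a full re-run in a test.

## Subgroups

Every subgroup keeps the baseline PLCHM survival for the comparator and
raises it to the subgroup hazard ratios for the ADCHM arm,
`S(t)^HR_PFS` and `S(t)^HR_OS`, with all other parameters unchanged.
Applying proportional hazards on top of a log-logistic baseline is
formally inconsistent (the family is not closed under PH) but is the
only construction available from reported hazard ratios alone, and is
the published approach. The deterministic subgroup ICER uses the point
hazard ratios. The subgroup probabilistic analysis additionally samples
each hazard ratio log-normally from its reported 95% CI: subgroup
acceptance probabilities are dominated by treatment-effect uncertainty
(a subgroup whose OS hazard-ratio CI crosses 1 cannot have a published
acceptance probability near 46% under point hazard ratios), and with
HR sampling the computed probabilities track the published ones to
within a few points.

## Numerical conventions and degenerate inputs

- 1 month = 365.25/12 = 30.4375 days; cycle = 21 days = 0.68994 months.
- Transition probabilities are clamped to [0,1]; an exhausted survival
  denominator (S = 0) yields probability 1 with a warning.
- Occupancy conservation holds to 1e−12 at every cycle and is asserted
  across PSA draws in the tests.
- Vial counts tolerate 1e−9 of floating fuzz so an exact multiple of
  the vial size never buys a spare vial.
- Curve validation clamps survival to [0,1], enforces monotonicity by
  clipping each point at its predecessor, and prepends (0, 1) if the
  origin is missing; non-increasing time stamps are an error, not
  noise.
- Monte-Carlo seeds: every stochastic entry point takes an explicit
  seed; identical seeds give bit-identical outputs.

## Problem sizes

The deterministic base case is a 120-cycle two-arm computation
(milliseconds). The production PSA is 1,000 iterations × 2 arms × 120
cycles (seconds). Synthetic validation uses 230–500 patients per arm
with 24-month administrative censoring; the recovery suite runs 20
replicates at n=500. Structural tests use smaller clouds (n=40–200)
where only ordering or reproducibility, not precision, is at stake.

## What the synthetic data do and do not show

The generator draws event times by inverse-CDF from a known family with
purely administrative censoring. It validates the estimation pipeline's
correctness and calibration, not its robustness to what real digitized
figures contain: pixel noise, staggered accrual (non-administrative
censoring patterns), reporting-interval coarseness beyond the tested
grids, or dependence between PFS and OS within patients (the model only
consumes marginal curves, so patient-level dependence is out of scope by
construction).

## Known limitations

- The second-line regimen's dosing and the etoposide day-structure are
  conventions; both are configurable, and cost conclusions within ±15%
  are insensitive to them.
- The survival-parameter PSA dispersion is identified from published
  outputs rather than stated inputs (see above); the deterministic
  results do not depend on it.
- Tail extrapolation rests entirely on the log-logistic fit beyond the
  trial follow-up; alternative heavy- or light-tailed families would
  move life-year totals materially (the family-selection machinery is
  present precisely to make that explicit).
- No prophylactic cranial irradiation, no background mortality, no
  societal costs, no price-index adjustment.
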