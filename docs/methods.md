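# Methods

This note documents the models behind `lungscreen`, the assumptions and
default parameters, what the synthetic-data generator does and does not
emulate, and the numerical choices made where the design was open.

## Synthetic cohort (`lungscreen.cohort`)

The generator emulates a single-institution cohort of 997 lung-cancer
patients stratified by 2021 USPSTF screening eligibility (350 eligible,
647 not). It is constrained, not merely expected: every generated
cohort reproduces the stratum table exactly, for every seed.

**Strata.** Nine strata partition the cohort by which USPSTF criteria
fail: eligible (350); single-criterion failures — age only (41), quit
>15 y only (134), <20 pack-years only (65); two-criterion failures —
age+quit (32), age+pack-years (15), pack-years+quit among smokers (89);
age-eligible never-smokers (195); and an "all criteria" stratum (76).
Each stratum is expanded into explicit sampling cells fixing smoking
status, an age range, a pack-year interval, and a quit-time regime, so
that three aggregate capture targets hold by construction:

- exactly 61 patients have ages outside [40, 85] (13 below 40, 48 above
  85, proportional to the 9-under-50 / 32-over-80 split of the age-only
  stratum);
- a pure age-based 40–85 rule captures exactly 936/997;
- the combined expanded rule (40–85, ≥10 pack-years, no cessation
  limit) captures exactly 619/997: all 350 eligible, all 134 in the
  quit-only stratum, the 33 age-only patients inside 40–85, 41
  pack-year-only patients with 10–20 pack-years, the 18 age+quit
  patients inside 40–85, and 43 pack-years+quit patients with 10–20
  pack-years.

The source tabulations print these captures only marginally, and their
printed single-modification increments (33, 41, 130, 58) do not sum to
the printed combined increment (269); the generator calibrates to the
totals and keeps the age (33) and pack-year (41) components exact. The
52 never-smokers outside ages 50–80 sit in the all-criteria stratum
(never-smokers fail every smoking criterion), keeping total
never-smokers at 247.

**Continuous covariates.** Ages are uniform integers within each cell's
range. Pack-years are truncated log-normals matched to the group
median/IQR (eligible: 40 [30–55]; others: 20 [8–35]) and clipped to the
cell interval; quit times are |N(3, 5)| clipped to (0, 15) for recent
quitters and N(24, 16) truncated to (15, 70) for long-ago quitters.
Stored values are floored (not rounded) to 2 decimals so storage cannot
push a value across a stratum boundary. Sex, race, ethnicity, stage and
histology are assigned per group with exact counts (categories whose
published counts do not sum to the group size are repaired by largest
remainder). 263 nonguideline smokers carry `pack_years_observed =
False`, emulating unrecorded smoking exposure; values are generated
regardless so the classifier's strict mode can be exercised.

**Survival.** Overall survival is Weibull per group with a shared shape
k, which gives exact proportional hazards with
HR = (λ_guid/λ_non)^k. Solving median_non = 9.5 y, median_guid = 4.4 y
and HR = 0.67 gives k = 0.5203, λ_non = 19.215, λ_guid = 8.900.
Censoring is administrative, uniform on [0, C], with C ≈ 23.9 y solved
(by quadrature + Brent root-find, deterministically) so that ~45% of
the cohort is censored; C far exceeds both medians, so Kaplan-Meier
medians are identifiable. `generate_survival_arms` draws scaled
two-arm samples from the same families for parameter-recovery checks:
at 10 000 patients/arm a Cox fit recovers the HR well within ±0.05.

**What the generator does not emulate.** Joint covariate dependence
beyond the stratum structure (e.g. stage–smoking or stage–survival
correlation within group), realistic missing-data mechanisms,
calendar-time accrual, and any individual-level resemblance to real
patients. Tests passing on this cohort validate the pipeline's
arithmetic and calibration, not clinical generalizability.

## Eligibility rules (`lungscreen.eligibility`)

Age bounds inclusive; pack-year floor inclusive (≥); cessation limit
exclusive (quit < 15 y qualifies, 15.0 exactly does not), matching the
"quit <15 y" / "quit >15 y" phrasing of the criteria. Never-smokers
fail any smoking-required rule outright and are tabulated as
`never_smoker` (plus `age` when out of range) rather than as pack-year
failures. The default classifier is permissive about unobserved
pack-years; `strict=True` fails a pack-year criterion whose value is
flagged unobserved.

## Stage-shift model (`lungscreen.stage_shift`)

Annual lives saved is piecewise linear in the population stage I
detection rate through (0, 0), (0.16, 3 650) and (0.30, 26 124), with
secant extrapolation above 0.30. The two anchors are the
current-guideline operating point and the realistic age-based
projection; the published interior scenario rows imply slopes that are
mutually inconsistent with any single smooth curve, so they are
comparison outputs here (the model yields 20.4% for breast parity at
10 660 lives/yr and 22.2% for colorectal parity at 13 650, vs published
21.4%/22.3%). `parity_rate` inverts the curve exactly; `nns` is the
reciprocal of the absolute risk reduction rounded half away from zero.
CIs perturb the anchor values with normals scaled to their published
95% CIs.

## Cost-effectiveness engine (`lungscreen.cea`)

Each program (lung at 14.4% or 70% participation; breast; colorectal)
is a parameter set whose published operating points — annual cost,
lives saved, and (for comparators) ICER, each with a 95% CI — are
calibrated input distributions: Gamma for costs and counts
(moment-matched, sd = CI width / 3.92), truncated normal for the QALY
weight (0.85, SD 0.05, truncated at 0). Point estimates are iteration
means; derived quantities use ratios of means so the identity
cost-per-life × lives = annual cost holds exactly; CIs are 2.5/97.5
percentiles of 10 000 seeded iterations.

Participation between calibration points interpolates each quantity
piecewise linearly, with a zero-cost/zero-benefit origin at zero
participation. This preserves the published feature that cost per life
saved *rises* with participation (proportional scaling cannot).

**ICER.** QALYs per death averted = discounted life-years × QALY
weight, with continuous discounting at 3%/yr. The life-years gained
per death averted is not published; it is back-solved once so the lung
point ICER at 14.4% participation equals $85 000/QALY (yielding 1.448
years), then held fixed — at 70% participation the same value produces
$106.5k/QALY vs the published $107k. Comparator ICERs are benchmark
inputs, not formula outputs.

**Rounding.** Cost per life saved in $1000s is printed to one decimal
below 100, the nearest integer from 100–200, and the nearest 10 above —
reproducing 20.4 / 102 / 128 / 890 / 920 from the corresponding
cost–lives pairs.

**Cost-neutrality.** Net cost is fixed + marginal·p − savings·p, with
marginal cost the secant slope of the two lung cost points
($19.2 B/unit participation) and savings scaling the published
$24.76 B/yr at 70% participation proportionally ($35.4 B/unit). The
affine interpolation of the published cost points alone has a slightly
negative intercept, under which program cost never meets the scaled
savings; the fixed-cost term is therefore back-solved once from the
published 76% cost-neutral participation (the same one-free-parameter
pattern as the ICER life-years) and held fixed. The root is found by
bracketed bisection at run time; scaling savings up moves it down, and
zero savings correctly reports no root with the net-cost signs.

## Harms cascade (`lungscreen.harms`)

Program totals are eligible population × participation × per-person
rate; this denominator (22.4 M at 14.4%, 108.9 M at 70%) — not the
separate annual-screen-volume parameter — is what reproduces the
published totals from the published per-person rates. Lung defaults:
false positives 14.7%, invasive procedures 1.2%, complications 0.0045%
per person screened (published rounded to 0.004%; 0.0045% reproduces
both published complication counts, ≈1000 and ≈4900). Monte Carlo
draws are Beta, moment-matched to the published CIs; per-person rates
are participation-invariant and totals are exactly linear in
participation.

## Radiation risk (`lungscreen.radiation`)

Lifetime attributable risk per scan integrates, from exposure age +
latency (5 y) to age 100, the excess cancer rate weighted by
conditional survival to the attained age (competing mortality),
divided by DDREF 1.5. The excess rate combines an ERR projection
(coefficient × baseline lung-cancer mortality) and an EAR projection on
the log scale with weight 0.3 on ERR, using sex-specific coefficients
(ERR 0.32/1.40 per Sv; EAR 2.3/3.4 per 10⁴ PY·Sv), a per-decade
exposure-age modifier below age 30 (−0.30/−0.41) and attained-age
powers (−1.4 / 5.2). Both the coefficient table and the abridged
life table (a synthetic US-style table with baseline lung-cancer
mortality by age and sex) ship as delimited fixtures.

Because the model is linear in dose, schedule LAR is the sum of
single-scan LARs and scales exactly with per-scan dose. A per-sex
calibration multiplier is fitted once so the decennial 40–85 schedule
(5 scans × 1.3 mSv) yields 0.04% (men) / 0.05% (women); it is exposed
as `default_coefficients().calibration` for audit. Under the default
fixtures single-scan LAR decreases strictly with initiation age from
40 on, reflecting latency and competing mortality. `benefit_risk` is
the plain deaths-prevented / radiation-deaths ratio, with the
program-summary convention of rounding to the nearest hundred
(783 720 / 435 → 1800); published initiation-age-specific ratio bands
use an unpublished horizon convention and are not asserted.

## Sensitivity analysis (`lungscreen.sensitivity`)

`scenario` applies overrides (dotted paths into nested dataclasses)
atomically; `one_way` sweeps one path. Every evaluation re-seeds its
engine with a CRC-based hash of (base seed, overrides) — stable across
processes and below 2³¹ — so Monte Carlo noise is decoupled from the
parameter being swept and repeated invocations are bit-identical. A
singleton sweep equals the corresponding scenario by construction.

## Problem sizes

Default problem sizes: the 997-patient cohort; 10 000 Monte Carlo
iterations for CEA/harms CIs; 10 000 patients per arm for survival
parameter recovery. All are the package's own defaults and run in
seconds on one CPU.

## Known limitations

- The stage-shift curve is a two-anchor calibration, not a registry
  natural-history model; interior published scenarios deviate by about
  one percentage point of stage I detection.
- CEA draws are independent across quantities (no cost–lives
  correlation), so derived-ratio CIs are approximate.
- The radiation calibration multiplier absorbs the gap between the
  synthetic life-table/baseline-rate fixtures and the (unpublished)
  exact parameterization; absolute LAR values inherit the published
  anchors, while the model supplies shape (age, sex, dose dependence).
- The cost-neutrality fixed-cost term is anchored to the published
  result rather than derived, because the published inputs are mutually
  inconsistent (see the back-solve note above).
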