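"""Synthetic patient-cohort generator.

Generates 997-patient lung-cancer cohorts whose aggregate structure
matches the published institutional tabulations this package models:
the nine eligibility strata (350 eligible under the 2021 USPSTF rule,
647 ineligible, including 247 never-smokers), the capture totals of the
eligibility-expansion scenarios (619 under the combined expanded rule,
936 under a pure 40-85 age-based rule, 61 patients outside ages 40-85),
marginal demographics, stage and histology mixes per group, and
group-specific Weibull overall survival with a nonguideline-vs-guideline
hazard ratio of 0.67 and median survival of 9.5 vs 4.4 years.

Stratum counts are enforced exactly (generation is constrained, not
merely expected); continuous covariates are sampled within each
stratum's feasible region. The same seed always yields an identical
cohort.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import integrate, optimize

from . import eligibility as elig

__all__ = [
    "PatientRecord",
    "StratumSpec",
    "SurvivalParams",
    "CohortCalibration",
    "CalibrationInfeasibleError",
    "default_calibration",
    "generate_cohort",
    "generate_survival_arms",
    "summarize_cohort",
    "cohort_to_frame",
    "frame_to_cohort",
    "COHORT_SIZE",
]

COHORT_SIZE = 997

SEXES = ("female", "male")
RACES = ("Asian", "Black", "White", "other")
ETHNICITIES = ("Hispanic", "non-Hispanic", "declined")
STAGES = ("I", "II", "III", "IV")
HISTOLOGIES = (
    "adenocarcinoma",
    "carcinoid",
    "large cell",
    "NSCLC-NOS",
    "sarcomatoid",
    "SCLC",
    "squamous",
)


@dataclass
class PatientRecord:
    """One synthetic patient: demographics, smoking exposure, stage,
    and a survival endpoint.

    ``quit_years`` is NaN for never-smokers (not applicable) and 0.0
    for current smokers. ``pack_years_observed`` flags whether the
    pack-year value would have been recorded in a real chart; the
    generator assigns a value regardless so that missing-data handling
    can be exercised downstream.
    """

    id: str
    age_at_dx: int
    sex: str
    race: str
    ethnicity: str
    smoking_status: str
    pack_years: float
    quit_years: float
    stage: str
    histology: str
    survival_time: float
    event: str  # "death" | "censored"
    detected_by_ldct: bool
    pack_years_observed: bool = True


@dataclass(frozen=True)
class StratumSpec:
    """One eligibility stratum with its target count and sampling cells.

    Each cell is a dict with keys ``n``, ``smoking`` (never/current/
    former), ``age`` (an age-range tag, see ``_sample_ages``), ``py``
    (pack-year interval or None) and ``quit`` (quit-year interval tag or
    None). Cells make the joint age x pack-year x cessation allocation
    explicit so that the expansion-scenario capture totals are met by
    construction.
    """

    label: str
    count: int
    cells: tuple[dict, ...]


@dataclass(frozen=True)
class SurvivalParams:
    """Group-specific Weibull survival with shared shape.

    With a shared shape the model has proportional hazards and the
    hazard ratio equals ``(scale_guideline / scale_nonguideline) **
    shape``; the defaults embed HR 0.67 exactly with medians 9.5
    (nonguideline) and 4.4 (guideline) years. Censoring is uniform on
    ``[0, censoring_window]``, an administrative window solved so that
    about 45% of the cohort is censored.
    """

    shape: float
    scale_guideline: float
    scale_nonguideline: float
    censoring_window: float

    @property
    def hazard_ratio(self) -> float:
        """Nonguideline vs guideline hazard ratio."""
        return (self.scale_guideline / self.scale_nonguideline) ** self.shape

    def median(self, group: str) -> float:
        scale = self.scale_nonguideline if group == "nonguideline" else self.scale_guideline
        return scale * np.log(2.0) ** (1.0 / self.shape)


@dataclass(frozen=True)
class CohortCalibration:
    """Everything needed to generate a calibrated cohort."""

    stratum_specs: tuple[StratumSpec, ...]
    capture_targets: dict
    survival_params: SurvivalParams
    group_marginals: dict
    seed: int = 0

    def stratum_counts(self) -> dict[str, int]:
        return {s.label: s.count for s in self.stratum_specs}

    def validate(self) -> None:
        counts = self.stratum_counts()
        total = sum(counts.values())
        if total != COHORT_SIZE:
            raise CalibrationInfeasibleError(
                f"stratum counts sum to {total}, expected {COHORT_SIZE}"
            )
        for s in self.stratum_specs:
            if sum(c["n"] for c in s.cells) != s.count:
                raise CalibrationInfeasibleError(
                    f"cells of stratum {s.label!r} sum to "
                    f"{sum(c['n'] for c in s.cells)}, expected {s.count}"
                )
        cap = self.capture_targets
        if cap["age_based_40_85"] + cap["outside_40_85"] != total:
            raise CalibrationInfeasibleError(
                "capture targets inconsistent: age_based_40_85 + outside_40_85 "
                f"= {cap['age_based_40_85'] + cap['outside_40_85']} != {total}"
            )


class CalibrationInfeasibleError(ValueError):
    """Raised when a calibration's targets cannot be met jointly."""


# --- age-range tags -------------------------------------------------------
# in5080        : uniform integer in [50, 80]
# in4049        : uniform integer in [40, 49]
# in8185        : uniform integer in [81, 85]
# edge4085      : either side of [50, 80] but inside [40, 85]
# below40       : uniform integer in [18, 39]
# above85       : uniform integer in [86, 99]

def _sample_ages(rng: np.random.Generator, tag: str, n: int) -> np.ndarray:
    if tag == "in5080":
        return rng.integers(50, 81, n)
    if tag == "in4049":
        return rng.integers(40, 50, n)
    if tag == "in8185":
        return rng.integers(81, 86, n)
    if tag == "edge4085":
        side = rng.random(n) < 0.5
        low = rng.integers(40, 50, n)
        high = rng.integers(81, 86, n)
        return np.where(side, low, high)
    if tag == "below40":
        return rng.integers(18, 40, n)
    if tag == "above85":
        return rng.integers(86, 100, n)
    raise ValueError(f"unknown age tag {tag!r}")


# --- continuous covariate samplers ---------------------------------------

def _lognormal_from_quartiles(
    rng: np.random.Generator, n: int, median: float, q1: float, q3: float,
    lo: float, hi: float,
) -> np.ndarray:
    """Truncated log-normal moment-matched to a median and IQR.

    mu = log(median); sigma from the average of the two quartile
    offsets on the log scale (the published tables report only
    median/IQR). Values are redrawn until inside [lo, hi).
    """
    mu = np.log(median)
    z75 = 0.6744897501960817
    sigma = 0.5 * (np.log(q3 / median) - np.log(q1 / median)) / z75
    out = np.empty(n)
    filled = 0
    while filled < n:
        draw = rng.lognormal(mu, sigma, 2 * (n - filled) + 8)
        ok = draw[(draw >= lo) & (draw < hi)]
        take = min(len(ok), n - filled)
        out[filled : filled + take] = ok[:take]
        filled += take
    return out


def _sample_pack_years(rng, n, interval, group):
    if interval is None:
        return np.zeros(n)
    lo, hi = interval
    if group == "guideline":
        median, q1, q3 = 40.0, 30.0, 55.0
    else:
        median, q1, q3 = 20.0, 8.0, 35.0
    # keep strictly positive for smokers
    return _lognormal_from_quartiles(rng, n, median, q1, q3, max(lo, 0.5), hi)


def _sample_quit_years(rng, n, tag, group):
    """Quit-time samplers. Guideline formers quit recently (mean ~3 y,
    SD ~5); nonguideline formers with a cessation-limit failure quit
    long ago (mean ~24 y, SD ~16)."""
    if tag is None:
        return np.full(n, np.nan)
    if tag == "current":
        return np.zeros(n)
    if tag == "recent":  # former, quit < 15 years
        draw = np.abs(rng.normal(3.0, 5.0, n))
        return np.clip(draw, 0.1, 14.9)
    if tag == "long":  # former, quit > 15 years
        out = np.empty(n)
        filled = 0
        while filled < n:
            draw = rng.normal(24.0, 16.0, 2 * (n - filled) + 8)
            ok = draw[(draw > 15.0) & (draw < 70.0)]
            take = min(len(ok), n - filled)
            out[filled : filled + take] = ok[:take]
            filled += take
        return out
    raise ValueError(f"unknown quit tag {tag!r}")


# --- default calibration --------------------------------------------------

def _default_strata() -> tuple[StratumSpec, ...]:
    """The published stratum counts with an explicit feasible cell
    allocation.

    The joint allocation resolves, deterministically, the aggregates the
    source tables print only marginally:

    * exactly 61 patients receive ages outside [40, 85], split 13 below
      40 / 48 above 85 (proportional to the printed 9-under-50 vs
      32-over-80 split in the age-only stratum);
    * the combined expanded rule (40-85, >=10 pack-years, no cessation
      limit) captures exactly 619: all 350 eligible, all 134 in the
      quit-only stratum, 33 of the age-only stratum (those inside
      40-85), 41 of the pack-year-only stratum (pack-years in [10, 20)),
      18 of the age+quit stratum and 43 of the pack-years+quit stratum;
    * the 52 never-smokers outside ages 50-80 sit in the all-criteria
      stratum (a never-smoker fails every smoking criterion), keeping
      total never-smokers at 247.
    """

    def cell(n, smoking, age, py, quit):
        return {"n": n, "smoking": smoking, "age": age, "py": py, "quit": quit}

    return (
        StratumSpec("eligible", 350, (
            cell(138, "current", "in5080", (20, 120), "current"),
            cell(212, "former", "in5080", (20, 120), "recent"),
        )),
        StratumSpec("age_only", 41, (
            # printed split: 9 under 50, 32 over 80; of the 41, 33 stay
            # inside [40, 85] (7 + 26) and 8 fall outside (2 + 6)
            cell(3, "current", "in4049", (20, 120), "current"),
            cell(4, "former", "in4049", (20, 120), "recent"),
            cell(1, "current", "below40", (20, 120), "current"),
            cell(1, "former", "below40", (20, 120), "recent"),
            cell(6, "current", "in8185", (20, 120), "current"),
            cell(20, "former", "in8185", (20, 120), "recent"),
            cell(6, "former", "above85", (20, 120), "recent"),
        )),
        StratumSpec("quit_only", 134, (
            cell(134, "former", "in5080", (20, 120), "long"),
        )),
        StratumSpec("pack_years_only", 65, (
            cell(10, "current", "in5080", (10, 20), "current"),
            cell(31, "former", "in5080", (10, 20), "recent"),
            cell(5, "current", "in5080", (0, 10), "current"),
            cell(19, "former", "in5080", (0, 10), "recent"),
        )),
        StratumSpec("age_and_quit", 32, (
            cell(18, "former", "edge4085", (20, 120), "long"),
            cell(3, "former", "below40", (20, 120), "long"),
            cell(11, "former", "above85", (20, 120), "long"),
        )),
        StratumSpec("age_and_pack_years", 15, (
            cell(3, "current", "edge4085", (0, 10), "current"),
            cell(6, "former", "edge4085", (0, 10), "recent"),
            cell(1, "former", "below40", (0, 10), "recent"),
            cell(5, "former", "above85", (0, 10), "recent"),
        )),
        StratumSpec("pack_years_and_quit", 89, (
            cell(43, "former", "in5080", (10, 20), "long"),
            cell(46, "former", "in5080", (0, 10), "long"),
        )),
        StratumSpec("never_smoker_age_eligible", 195, (
            cell(195, "never", "in5080", None, None),
        )),
        StratumSpec("all_criteria", 76, (
            cell(24, "former", "edge4085", (0, 10), "long"),
            cell(19, "never", "edge4085", None, None),
            cell(7, "never", "below40", None, None),
            cell(26, "never", "above85", None, None),
        )),
    )


def _default_group_marginals() -> dict:
    """Per-group categorical counts (sex, race, ethnicity, stage,
    histology) matching the published baseline table; categories whose
    printed counts do not sum to the group size (unknowns, rounding)
    are scaled by largest remainder."""
    return {
        "guideline": {
            "n": 350,
            "sex": {"female": 181, "male": 169},
            "race": {"Asian": 13, "Black": 65, "White": 249, "other": 23},
            "ethnicity": {"Hispanic": 19, "non-Hispanic": 311, "declined": 20},
            "stage": {"I": 73, "II": 43, "III": 83, "IV": 151},
            "histology": {
                "adenocarcinoma": 193, "carcinoid": 2, "large cell": 4,
                "NSCLC-NOS": 31, "sarcomatoid": 1, "SCLC": 46, "squamous": 73,
            },
            "ldct_detected": 44,
            "pack_years_unobserved": 0,
        },
        "nonguideline": {
            "n": 647,
            "sex": {"female": 396, "male": 251},
            "race": {"Asian": 63, "Black": 98, "White": 437, "other": 49},
            "ethnicity": {"Hispanic": 22, "non-Hispanic": 575, "declined": 50},
            "stage": {"I": 180, "II": 72, "III": 110, "IV": 285},
            "histology": {
                "adenocarcinoma": 469, "carcinoid": 27, "large cell": 10,
                "NSCLC-NOS": 42, "sarcomatoid": 2, "SCLC": 24, "squamous": 73,
            },
            "ldct_detected": 1,
            "pack_years_unobserved": 263,
        },
    }


def _solve_censoring_window(
    shape: float, scale_g: float, scale_n: float,
    frac_guideline: float, target: float = 0.45,
) -> float:
    """Administrative censoring window: with censoring ~ U(0, C), the
    probability of censoring is (1/C) * integral_0^C S_mix(t) dt; solve
    for the C giving the target overall censoring fraction."""

    def s_mix(t):
        return frac_guideline * np.exp(-((t / scale_g) ** shape)) + (
            1.0 - frac_guideline
        ) * np.exp(-((t / scale_n) ** shape))

    def cens_frac(c):
        val, _ = integrate.quad(s_mix, 0.0, c, limit=200)
        return val / c

    return optimize.brentq(lambda c: cens_frac(c) - target, 0.5, 500.0, xtol=1e-6)


def default_calibration() -> CohortCalibration:
    """The default calibration: published stratum counts and capture
    targets, Weibull survival embedding HR 0.67 with medians 9.5/4.4
    years, and ~45% administrative censoring. Deterministic."""
    shape = float(np.log(0.67) / np.log(4.4 / 9.5))
    scale_g = float(4.4 / np.log(2.0) ** (1.0 / shape))
    scale_n = float(9.5 / np.log(2.0) ** (1.0 / shape))
    window = float(
        _solve_censoring_window(shape, scale_g, scale_n, 350 / COHORT_SIZE)
    )
    cal = CohortCalibration(
        stratum_specs=_default_strata(),
        capture_targets={
            "uspstf_2021": 350,
            "expanded": 619,
            "age_based_40_85": 936,
            "outside_40_85": 61,
            "never_smokers": 247,
        },
        survival_params=SurvivalParams(shape, scale_g, scale_n, window),
        group_marginals=_default_group_marginals(),
    )
    cal.validate()
    return cal


# --- generation -----------------------------------------------------------

def _assign_categories(rng: np.random.Generator, counts: dict[str, int]) -> np.ndarray:
    """A shuffled vector with exactly ``counts[k]`` copies of each key."""
    values = np.repeat(list(counts.keys()), list(counts.values()))
    return rng.permutation(values)


def generate_cohort(
    calibration: CohortCalibration | None = None, seed: int = 0
) -> list[PatientRecord]:
    """Generate a calibrated 997-patient cohort.

    Per-stratum counts, capture totals, never-smoker count and group
    marginals are met exactly; continuous covariates are sampled within
    stratum constraints; survival is Weibull per group (guideline vs
    nonguideline by USPSTF eligibility) with uniform administrative
    censoring. Identical ``(calibration, seed)`` yields an identical
    cohort.
    """
    cal = calibration or default_calibration()
    cal.validate()
    rng = np.random.default_rng(seed)

    rows: list[dict] = []
    for stratum in cal.stratum_specs:
        group = "guideline" if stratum.label == "eligible" else "nonguideline"
        for c in stratum.cells:
            n = c["n"]
            ages = _sample_ages(rng, c["age"], n)
            pys = _sample_pack_years(rng, n, c["py"], group)
            quits = _sample_quit_years(rng, n, c["quit"], group)
            for i in range(n):
                rows.append({
                    "stratum": stratum.label,
                    "group": group,
                    "age_at_dx": int(ages[i]),
                    "smoking_status": c["smoking"],
                    "pack_years": float(pys[i]),
                    "quit_years": float(quits[i]),
                })

    # per-group categorical marginals
    frame = pd.DataFrame(rows)
    for group, marg in cal.group_marginals.items():
        idx = frame.index[frame["group"] == group]
        if len(idx) != marg["n"]:
            raise CalibrationInfeasibleError(
                f"group {group!r} has {len(idx)} patients, marginals expect {marg['n']}"
            )
        for col in ("sex", "race", "ethnicity", "stage", "histology"):
            frame.loc[idx, col] = _assign_categories(rng, marg[col])
        ldct = np.zeros(len(idx), dtype=bool)
        ldct[: marg["ldct_detected"]] = True
        frame.loc[idx, "detected_by_ldct"] = rng.permutation(ldct)
        # unobserved pack-years only among smokers of the group
        smoker_idx = frame.index[
            (frame["group"] == group) & (frame["smoking_status"] != "never")
        ]
        n_unobs = marg["pack_years_unobserved"]
        if n_unobs > len(smoker_idx):
            raise CalibrationInfeasibleError(
                f"cannot flag {n_unobs} unobserved pack-year values among "
                f"{len(smoker_idx)} smokers in group {group!r}"
            )
        frame["pack_years_observed"] = frame.get("pack_years_observed", True)
        unobs = rng.choice(smoker_idx, size=n_unobs, replace=False)
        frame.loc[unobs, "pack_years_observed"] = False

    # survival endpoint
    sp = cal.survival_params
    scale = np.where(
        frame["group"] == "guideline", sp.scale_guideline, sp.scale_nonguideline
    )
    t_event = scale * rng.weibull(sp.shape, len(frame))
    t_cens = rng.uniform(0.0, sp.censoring_window, len(frame))
    frame["survival_time"] = np.maximum(np.minimum(t_event, t_cens), 1e-3)
    frame["event"] = np.where(t_event <= t_cens, "death", "censored")

    order = rng.permutation(frame.index.to_numpy())
    frame = frame.loc[order].reset_index(drop=True)
    records = [
        PatientRecord(
            id=f"P{i + 1:04d}",
            age_at_dx=int(r.age_at_dx),
            sex=r.sex,
            race=r.race,
            ethnicity=r.ethnicity,
            smoking_status=r.smoking_status,
            # floor (not round) to 2 decimals so stored values cannot
            # cross a stratum boundary such as the 20-pack-year floor
            pack_years=float(np.floor(r.pack_years * 100) / 100),
            quit_years=(
                float("nan")
                if np.isnan(r.quit_years)
                else float(np.floor(r.quit_years * 100) / 100)
            ),
            stage=r.stage,
            histology=r.histology,
            survival_time=round(float(r.survival_time), 4),
            event=r.event,
            detected_by_ldct=bool(r.detected_by_ldct),
            pack_years_observed=bool(r.pack_years_observed),
        )
        for i, r in enumerate(frame.itertuples())
    ]
    _check_capture_targets(records, cal)
    return records


def _check_capture_targets(records: Sequence[PatientRecord], cal: CohortCalibration):
    got = {
        "uspstf_2021": sum(elig.classify(p, elig.uspstf_2021()) for p in records),
        "expanded": sum(elig.classify(p, elig.expanded_rule()) for p in records),
        "age_based_40_85": sum(
            elig.classify(p, elig.age_based_rule()) for p in records
        ),
        "outside_40_85": sum(not 40 <= p.age_at_dx <= 85 for p in records),
        "never_smokers": sum(p.smoking_status == "never" for p in records),
    }
    for key, target in cal.capture_targets.items():
        if got[key] != target:
            raise CalibrationInfeasibleError(
                f"capture target {key!r} violated: generated {got[key]}, "
                f"calibration requires {target}"
            )


def generate_survival_arms(
    n_per_arm: int,
    seed: int = 0,
    calibration: CohortCalibration | None = None,
) -> pd.DataFrame:
    """Scaled two-arm survival sample from the calibration's Weibull
    families (for parameter-recovery checks), with the same uniform
    administrative censoring as the cohort generator.

    Returns a DataFrame with columns ``group`` (1 = nonguideline),
    ``time`` and ``event`` (1 = death).
    """
    cal = calibration or default_calibration()
    sp = cal.survival_params
    rng = np.random.default_rng(seed)
    group = np.repeat([0, 1], n_per_arm)
    scale = np.where(group == 1, sp.scale_nonguideline, sp.scale_guideline)
    t_event = scale * rng.weibull(sp.shape, 2 * n_per_arm)
    t_cens = rng.uniform(0.0, sp.censoring_window, 2 * n_per_arm)
    return pd.DataFrame({
        "group": group,
        "time": np.maximum(np.minimum(t_event, t_cens), 1e-6),
        "event": (t_event <= t_cens).astype(int),
    })


# --- summaries and I/O ----------------------------------------------------

def summarize_cohort(cohort: Iterable[PatientRecord]) -> dict:
    """Stratum counts plus covariate summaries for a cohort.

    Returns a dict with ``stratum_counts`` (every canonical stratum,
    zero-count strata included), ``detection`` (capture counts under the
    three named rules), and ``covariates`` (median/IQR summaries per
    eligibility group).
    """
    patients = list(cohort)
    if not patients:
        raise ValueError("cohort is empty")
    rule = elig.uspstf_2021()
    counts = {label: 0 for label in elig.STRATUM_LABELS}
    for p in patients:
        counts[elig.ineligibility_stratum(p, rule)] += 1

    frame = cohort_to_frame(patients)
    frame["group"] = [
        "guideline" if elig.classify(p, rule) else "nonguideline" for p in patients
    ]
    covariates = {}
    for group, sub in frame.groupby("group"):
        smokers = sub[sub["smoking_status"] != "never"]
        covariates[group] = {
            "n": int(len(sub)),
            "age_median": float(sub["age_at_dx"].median()),
            "pack_years_median_smokers": float(smokers["pack_years"].median()),
            "pack_years_iqr_smokers": [
                float(smokers["pack_years"].quantile(0.25)),
                float(smokers["pack_years"].quantile(0.75)),
            ],
            "never_smokers": int((sub["smoking_status"] == "never").sum()),
            "stage_counts": sub["stage"].value_counts().to_dict(),
        }
    detection = {
        name: elig.detection_rate(patients, rule_fn())._asdict()
        for name, rule_fn in (
            ("uspstf_2021", elig.uspstf_2021),
            ("expanded", elig.expanded_rule),
            ("age_based_40_85", elig.age_based_rule),
        )
    }
    return {
        "n": len(patients),
        "stratum_counts": counts,
        "detection": detection,
        "covariates": covariates,
    }


def cohort_to_frame(cohort: Iterable[PatientRecord]) -> pd.DataFrame:
    """Cohort as a tidy DataFrame (one row per patient)."""
    return pd.DataFrame([dataclasses.asdict(p) for p in cohort])


def frame_to_cohort(frame: pd.DataFrame) -> list[PatientRecord]:
    """Inverse of :func:`cohort_to_frame` (e.g. after a CSV round trip)."""
    fields = [f.name for f in dataclasses.fields(PatientRecord)]
    out = []
    for _, row in frame.iterrows():
        kwargs = {name: row[name] for name in fields}
        kwargs["age_at_dx"] = int(kwargs["age_at_dx"])
        kwargs["pack_years"] = float(kwargs["pack_years"])
        kwargs["quit_years"] = float(kwargs["quit_years"])
        kwargs["survival_time"] = float(kwargs["survival_time"])
        kwargs["detected_by_ldct"] = bool(kwargs["detected_by_ldct"])
        kwargs["pack_years_observed"] = bool(kwargs["pack_years_observed"])
        out.append(PatientRecord(**kwargs))
    return out
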