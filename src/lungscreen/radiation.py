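"""Radiation risk from LDCT screening schedules.

Lifetime attributable risk (LAR) of radiation-induced cancer in the
style of the BEIR VII lung model: sex-specific excess relative risk
(ERR) and excess absolute risk (EAR) coefficients with exposure-age and
attained-age modifiers, a minimum latency, a dose and dose-rate
effectiveness factor (DDREF), and competing mortality via a life table.
The ERR and EAR projections are combined on the log scale (weight 0.3
on ERR, the usual choice for lung).

Absolute scale is set by a per-sex calibration multiplier fitted once
so that the decennial ages-40-85 schedule (5 scans, 1.3 mSv each)
yields a lifetime risk of 0.04% for men and 0.05% for women; the
multiplier is exposed on :class:`RiskCoefficients` for audit. Risks are
linear in dose, so multi-scan LAR is the sum of single-scan LARs.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, replace
from functools import lru_cache

import numpy as np
import pandas as pd

__all__ = [
    "DoseSchedule",
    "RiskCoefficients",
    "decennial_schedule",
    "annual_schedule",
    "default_coefficients",
    "lar",
    "benefit_risk",
]

_END_AGE = 100  # life-table horizon


@dataclass(frozen=True)
class DoseSchedule:
    """LDCT scan ages and per-scan effective dose (mSv)."""

    scan_ages: tuple[int, ...]
    dose_per_scan: float
    surveillance_fraction: float = 0.15

    @property
    def total_dose(self) -> float:
        """Total effective dose in mSv."""
        return len(self.scan_ages) * self.dose_per_scan


def decennial_schedule(
    start_age: int, end_age: int, dose_per_scan: float = 1.3
) -> DoseSchedule:
    """Scans at ``start_age`` and every 10 years while <= ``end_age``."""
    if start_age > end_age:
        raise ValueError("start_age must not exceed end_age")
    return DoseSchedule(
        tuple(range(start_age, end_age + 1, 10)), dose_per_scan
    )


def annual_schedule(
    start_age: int, end_age: int, dose_per_scan: float = 1.3
) -> DoseSchedule:
    """Annual scans from ``start_age`` through ``end_age`` (the
    surveillance arm of the program)."""
    if start_age > end_age:
        raise ValueError("start_age must not exceed end_age")
    return DoseSchedule(tuple(range(start_age, end_age + 1)), dose_per_scan)


@dataclass(frozen=True)
class RiskCoefficients:
    """ERR/EAR model parameters plus the life-table environment.

    ``err_per_sv`` / ``ear_per_1e4_pysv`` are sex-keyed coefficients at
    the reference exposure (age >= 30) and attained age 60;
    ``exposure_age_modifier`` (per decade below age 30) and
    ``attained_age_power`` are the (ERR, EAR) modifier pairs.
    ``calibration`` is the fitted per-sex scale multiplier.
    """

    err_per_sv: dict
    ear_per_1e4_pysv: dict
    exposure_age_modifier: tuple[float, float]
    attained_age_power: tuple[float, float]
    latency: float
    ddref: float
    err_weight: float
    life_table: pd.DataFrame
    calibration: dict

    def __post_init__(self):
        if self.latency <= 0:
            raise ValueError("latency must be positive")
        if self.ddref < 1.0:
            raise ValueError("DDREF must be >= 1")


def _load_life_table() -> pd.DataFrame:
    ref = importlib.resources.files("lungscreen.data") / "life_table.csv"
    with ref.open() as fh:
        return pd.read_csv(fh, comment="#")


def _load_beir() -> pd.DataFrame:
    ref = importlib.resources.files("lungscreen.data") / "beir_lung.csv"
    with ref.open() as fh:
        return pd.read_csv(fh, comment="#")


def _survival_to_age(table: pd.DataFrame, sex: str, ages: np.ndarray) -> np.ndarray:
    col = "surv_female" if sex == "female" else "surv_male"
    return np.interp(ages, table["age"], table[col])


def _lung_mortality(table: pd.DataFrame, sex: str, ages: np.ndarray) -> np.ndarray:
    col = "lung_mort_female" if sex == "female" else "lung_mort_male"
    return np.interp(ages, table["age"], table[col]) / 1e5


def _raw_single_scan_lar(sex: str, exposure_age: float, dose_msv: float,
                         coeffs: RiskCoefficients) -> float:
    """Uncalibrated LAR of a single scan: log-blended ERR/EAR projections
    integrated from exposure + latency to the life-table horizon,
    weighted by conditional survival (competing mortality)."""
    if dose_msv == 0:
        return 0.0
    table = coeffs.life_table
    a0 = exposure_age + coeffs.latency
    ages = np.arange(np.ceil(a0), _END_AGE + 1.0)
    if ages.size == 0:
        return 0.0
    s_ratio = _survival_to_age(table, sex, ages) / _survival_to_age(
        table, sex, np.array([exposure_age])
    )
    estar = (min(exposure_age, 30.0) - 30.0) / 10.0
    g_err, g_ear = coeffs.exposure_age_modifier
    h_err, h_ear = coeffs.attained_age_power
    err_route = float(np.sum(
        coeffs.err_per_sv[sex]
        * np.exp(g_err * estar)
        * (ages / 60.0) ** h_err
        * _lung_mortality(table, sex, ages)
        * s_ratio
    ))
    ear_route = float(np.sum(
        coeffs.ear_per_1e4_pysv[sex] / 1e4
        * np.exp(g_ear * estar)
        * (ages / 60.0) ** h_ear
        * s_ratio
    ))
    if err_route <= 0 or ear_route <= 0:
        return 0.0
    w = coeffs.err_weight
    blended = float(np.exp(w * np.log(err_route) + (1 - w) * np.log(ear_route)))
    dose_sv = dose_msv / 1000.0
    return blended * dose_sv / coeffs.ddref


@lru_cache(maxsize=1)
def default_coefficients() -> RiskCoefficients:
    """Default coefficient set, with the per-sex calibration multiplier
    fitted so the decennial 40-85 schedule (1.3 mSv/scan) gives a
    lifetime risk of 0.04% (men) / 0.05% (women)."""
    beir = _load_beir().set_index(["model", "sex"])
    coeffs = RiskCoefficients(
        err_per_sv={
            "male": float(beir.loc[("err", "male"), "beta"]),
            "female": float(beir.loc[("err", "female"), "beta"]),
        },
        ear_per_1e4_pysv={
            "male": float(beir.loc[("ear", "male"), "beta"]),
            "female": float(beir.loc[("ear", "female"), "beta"]),
        },
        exposure_age_modifier=(
            float(beir.loc[("err", "male"), "gamma"]),
            float(beir.loc[("ear", "male"), "gamma"]),
        ),
        attained_age_power=(
            float(beir.loc[("err", "male"), "eta"]),
            float(beir.loc[("ear", "male"), "eta"]),
        ),
        latency=5.0,
        ddref=1.5,
        err_weight=0.3,
        life_table=_load_life_table(),
        calibration={"male": 1.0, "female": 1.0},
    )
    anchor = decennial_schedule(40, 85, 1.3)
    targets = {"male": 0.0004, "female": 0.0005}
    calib = {}
    for sex, target in targets.items():
        raw = sum(
            _raw_single_scan_lar(sex, e, anchor.dose_per_scan, coeffs)
            for e in anchor.scan_ages
        )
        calib[sex] = target / raw
    return replace(coeffs, calibration=calib)


def lar(
    sex: str,
    schedule: DoseSchedule,
    coeffs: RiskCoefficients | None = None,
) -> float:
    """Lifetime attributable risk (fraction) of radiation-induced
    cancer for a scan schedule. Additive over scans and linear in
    dose (linear no-threshold low-dose model)."""
    if sex not in ("male", "female"):
        raise ValueError("sex must be 'male' or 'female'")
    coeffs = coeffs or default_coefficients()
    return coeffs.calibration[sex] * sum(
        _raw_single_scan_lar(sex, e, schedule.dose_per_scan, coeffs)
        for e in schedule.scan_ages
    )


def benefit_risk(deaths_prevented: float, radiation_deaths: float,
                 round_to_hundred: bool = False) -> float:
    """Lung-cancer deaths prevented per radiation-induced cancer death.

    ``round_to_hundred`` applies the program-summary convention of
    rounding the ratio to the nearest hundred. Zero radiation deaths
    returns infinity (infinite-benefit sentinel).
    """
    if radiation_deaths < 0 or deaths_prevented < 0:
        raise ValueError("counts must be non-negative")
    if radiation_deaths == 0:
        return float("inf")
    ratio = deaths_prevented / radiation_deaths
    if round_to_hundred:
        return float(100 * round(ratio / 100.0))
    return ratio
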