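"""Screening-harms cascade.

Models the false-positive -> invasive-procedure -> complication cascade
per person screened and scales it to program level. Per-person rates
are invariant to participation; program totals are
``eligible population x participation x rate`` (this denominator — not
the annual screen volume — is what reproduces the published program
totals from the published per-person rates).

Default lung rates: 14.7% false positives, 1.2% invasive procedures and
0.0045% complications per person screened (the last is published
rounded to 0.004%; 0.0045% reproduces both published complication
counts). Breast and colorectal rates ship as comparator fixtures.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "HarmRates",
    "HarmRateDistributions",
    "LUNG_RATES",
    "BREAST_RATES",
    "COLORECTAL_RATES",
    "LUNG_RATE_DISTRIBUTIONS",
    "cascade",
    "cascade_mc",
]


@dataclass(frozen=True)
class HarmRates:
    """Per-person-screened harm rates (fractions)."""

    fp_per_person: float
    procedure_per_person: float
    complication_per_person: float

    def __post_init__(self):
        if not (
            0.0
            <= self.complication_per_person
            <= self.procedure_per_person
            <= self.fp_per_person
            <= 1.0
        ):
            raise ValueError(
                "rates must satisfy 0 <= complication <= procedure <= fp <= 1"
            )


LUNG_RATES = HarmRates(0.147, 0.012, 0.000045)
BREAST_RATES = HarmRates(0.075, 0.0008, 0.00001)
COLORECTAL_RATES = HarmRates(0.029, 0.0058, 0.00004)


@dataclass(frozen=True)
class HarmRateDistributions:
    """95% CIs of the per-person rates, for Monte Carlo draws
    (Beta-distributed, moment-matched to mean and CI width)."""

    fp: tuple[float, float, float]  # (mean, lo, hi)
    procedure: tuple[float, float, float]
    complication: tuple[float, float, float]


LUNG_RATE_DISTRIBUTIONS = HarmRateDistributions(
    fp=(0.147, 0.107, 0.192),
    procedure=(0.012, 0.007, 0.018),
    complication=(0.000045, 0.00002, 0.00008),
)

_Z95 = 1.959963984540054


def cascade(population: float, participation: float, rates: HarmRates) -> dict:
    """Deterministic program-level totals.

    Returns the number screened and the total false positives,
    procedures and complications; per-person rates are echoed unchanged.
    """
    if population < 0 or not 0.0 <= participation <= 1.0:
        raise ValueError("population must be >= 0 and participation in [0, 1]")
    screened = population * participation
    return {
        "screened": screened,
        "false_positives": screened * rates.fp_per_person,
        "procedures": screened * rates.procedure_per_person,
        "complications": screened * rates.complication_per_person,
        "per_person": {
            "false_positives": rates.fp_per_person,
            "procedures": rates.procedure_per_person,
            "complications": rates.complication_per_person,
        },
    }


def _beta_draws(rng, mean, lo, hi, n):
    sd = (hi - lo) / (2.0 * _Z95)
    if sd <= 0 or mean <= 0:
        return np.full(n, mean)
    var = sd**2
    nu = mean * (1 - mean) / var - 1.0
    if nu <= 0:  # CI too wide for a Beta at this mean; fall back to clipping
        return np.clip(rng.normal(mean, sd, n), 0.0, 1.0)
    a, b = mean * nu, (1 - mean) * nu
    return rng.beta(a, b, n)


def cascade_mc(
    population: float,
    participation: float,
    dists: HarmRateDistributions = LUNG_RATE_DISTRIBUTIONS,
    n_iter: int = 10_000,
    seed: int = 0,
) -> dict:
    """Monte Carlo cascade with percentile CIs.

    Per-iteration rate draws are sorted into the cascade ordering
    (complication <= procedure <= false positive holds in every
    iteration by the rate magnitudes themselves). Degenerate
    distributions collapse the CI to the point.
    """
    rng = np.random.default_rng(seed)
    screened = population * participation
    out: dict = {"screened": screened}
    for key, (mean, lo, hi) in (
        ("false_positives", dists.fp),
        ("procedures", dists.procedure),
        ("complications", dists.complication),
    ):
        draws = _beta_draws(rng, mean, lo, hi, n_iter) * screened
        plo, phi = np.percentile(draws, [2.5, 97.5])
        out[key] = {
            "mean": float(draws.mean()),
            "ci": (float(plo), float(phi)),
            "per_person": mean,
            "samples": draws,
        }
    return out
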