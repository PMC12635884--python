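"""Screening-eligibility rule engine.

Evaluates parameterized lung-cancer screening criteria (age window,
pack-year floor, cessation limit, smoking requirement) against patient
records, reports the reasons a patient fails a rule, and computes
cohort-level detection rates.

Boundary semantics follow the conventions of the 2021 USPSTF rule as
usually stated: age bounds are inclusive on both ends, the pack-year
threshold is inclusive (``>=``), and the cessation limit is exclusive
(``quit < 15`` years qualifies; exactly 15.0 years does not).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, NamedTuple

__all__ = [
    "ScreeningRule",
    "uspstf_2021",
    "expanded_rule",
    "age_based_rule",
    "classify",
    "ineligibility_reasons",
    "ineligibility_stratum",
    "detection_rate",
    "DetectionRate",
    "STRATUM_LABELS",
]


@dataclass(frozen=True)
class ScreeningRule:
    """A parameterized screening-eligibility criterion.

    Parameters
    ----------
    name : str
        Human-readable label.
    age_min, age_max : int
        Inclusive age bounds in years.
    min_pack_years : float or None
        Pack-year floor (inclusive); ``None`` means no smoking-intensity
        requirement.
    max_quit_years : float or None
        Cessation limit in years (exclusive: a former smoker qualifies
        while ``quit_years < max_quit_years``); ``None`` means no limit.
    smoking_required : bool
        If False the rule is purely age-based and never-smokers qualify;
        ``min_pack_years`` and ``max_quit_years`` must then be ``None``.
    """

    name: str
    age_min: int
    age_max: int
    min_pack_years: float | None
    max_quit_years: float | None
    smoking_required: bool

    def __post_init__(self) -> None:
        if self.age_min > self.age_max:
            raise ValueError("age_min must not exceed age_max")
        if not self.smoking_required and (
            self.min_pack_years is not None or self.max_quit_years is not None
        ):
            raise ValueError(
                "a rule without a smoking requirement cannot carry "
                "pack-year or cessation criteria"
            )


def uspstf_2021() -> ScreeningRule:
    """The 2021 USPSTF rule: ages 50-80, >=20 pack-years, current smoker
    or quit within 15 years."""
    return ScreeningRule("uspstf_2021", 50, 80, 20.0, 15.0, True)


def expanded_rule() -> ScreeningRule:
    """All three incremental expansions combined: ages 40-85, the
    pack-year floor lowered to 10, and the 15-year cessation limit
    eliminated."""
    return ScreeningRule("expanded", 40, 85, 10.0, None, True)


def age_based_rule() -> ScreeningRule:
    """A pure age-based rule (ages 40-85) with no smoking criteria."""
    return ScreeningRule("age_based_40_85", 40, 85, None, None, False)


def _is_never(smoking_status: str) -> bool:
    return smoking_status == "never"


def classify(patient, rule: ScreeningRule, strict: bool = False) -> bool:
    """Return True iff ``patient`` satisfies ``rule``.

    ``patient`` is any object with ``age_at_dx``, ``smoking_status``,
    ``pack_years`` and ``quit_years`` attributes (e.g. a
    :class:`~lungscreen.cohort.PatientRecord` or a DataFrame row).

    Self-reported smoking exposure is unreliable, so records may carry a
    ``pack_years_observed`` flag. The default is permissive (the
    recorded value is used either way); ``strict=True`` treats a
    pack-year requirement as failed when the value is flagged
    unobserved.
    """
    if not (rule.age_min <= patient.age_at_dx <= rule.age_max):
        return False
    if not rule.smoking_required:
        return True
    if _is_never(patient.smoking_status):
        return False
    if rule.min_pack_years is not None:
        if strict and not getattr(patient, "pack_years_observed", True):
            return False
        if patient.pack_years < rule.min_pack_years:
            return False
    if rule.max_quit_years is not None and patient.smoking_status == "former":
        q = patient.quit_years
        if q is None or (isinstance(q, float) and math.isnan(q)):
            return False
        if q >= rule.max_quit_years:
            return False
    return True


def ineligibility_reasons(patient, rule: ScreeningRule) -> frozenset[str]:
    """The set of criteria ``patient`` fails under ``rule``.

    Elements are drawn from ``{"age", "pack_years", "quit_time",
    "never_smoker"}``. Never-smokers report ``never_smoker`` (with
    ``age`` added when they are also outside the age window) rather than
    pack-year/cessation failures, matching how ineligibility is usually
    tabulated. Raises ``ValueError`` if the patient is in fact eligible.
    """
    if classify(patient, rule):
        raise ValueError("patient is eligible under this rule")
    reasons: set[str] = set()
    if not (rule.age_min <= patient.age_at_dx <= rule.age_max):
        reasons.add("age")
    if rule.smoking_required and _is_never(patient.smoking_status):
        reasons.add("never_smoker")
        return frozenset(reasons)
    if rule.smoking_required:
        if (
            rule.min_pack_years is not None
            and patient.pack_years < rule.min_pack_years
        ):
            reasons.add("pack_years")
        if rule.max_quit_years is not None and patient.smoking_status == "former":
            q = patient.quit_years
            if q is None or (isinstance(q, float) and math.isnan(q)) or q >= rule.max_quit_years:
                reasons.add("quit_time")
    return frozenset(reasons)


#: Canonical ineligibility strata for the USPSTF rule, in display order.
STRATUM_LABELS = (
    "eligible",
    "age_only",
    "quit_only",
    "pack_years_only",
    "age_and_quit",
    "age_and_pack_years",
    "pack_years_and_quit",
    "never_smoker_age_eligible",
    "all_criteria",
)

_REASON_TO_STRATUM = {
    frozenset({"age"}): "age_only",
    frozenset({"quit_time"}): "quit_only",
    frozenset({"pack_years"}): "pack_years_only",
    frozenset({"age", "quit_time"}): "age_and_quit",
    frozenset({"age", "pack_years"}): "age_and_pack_years",
    frozenset({"pack_years", "quit_time"}): "pack_years_and_quit",
    frozenset({"never_smoker"}): "never_smoker_age_eligible",
    frozenset({"age", "never_smoker"}): "all_criteria",
    frozenset({"age", "pack_years", "quit_time"}): "all_criteria",
}


def ineligibility_stratum(patient, rule: ScreeningRule) -> str:
    """Map a patient to its (in)eligibility stratum under ``rule``.

    The eight ineligible strata partition the ineligible patients: one-,
    two-, and three-criterion smoker strata, age-eligible never-smokers,
    and an "all criteria" stratum that also absorbs never-smokers
    outside the age window (a never-smoker fails every smoking-related
    criterion by construction).
    """
    if classify(patient, rule):
        return "eligible"
    return _REASON_TO_STRATUM[ineligibility_reasons(patient, rule)]


class DetectionRate(NamedTuple):
    fraction: float
    numerator: int
    denominator: int


def detection_rate(cohort: Iterable, rule: ScreeningRule) -> DetectionRate:
    """Proportion of a cohort captured by ``rule``."""
    patients = list(cohort)
    if not patients:
        raise ValueError("cohort is empty")
    n = sum(classify(p, rule) for p in patients)
    return DetectionRate(n / len(patients), n, len(patients))
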