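"""Eligibility rule engine: predicates, reasons, strata, monotonicity."""

import math
from types import SimpleNamespace

import pytest
from hypothesis import given
from hypothesis import strategies as st

from lungscreen import eligibility as elig


def patient(age=60, smoking="current", py=30.0, quit=0.0):
    return SimpleNamespace(
        age_at_dx=age, smoking_status=smoking, pack_years=py, quit_years=quit
    )


class TestNamedRules:
    def test_uspstf_2021(self):
        r = elig.uspstf_2021()
        assert (r.age_min, r.age_max, r.min_pack_years, r.max_quit_years) == (
            50, 80, 20.0, 15.0,
        )
        assert r.smoking_required

    def test_age_based(self):
        r = elig.age_based_rule()
        assert (r.age_min, r.age_max) == (40, 85)
        assert r.min_pack_years is None and r.max_quit_years is None
        assert not r.smoking_required

    def test_expanded(self):
        r = elig.expanded_rule()
        assert (r.age_min, r.age_max, r.min_pack_years, r.max_quit_years) == (
            40, 85, 10.0, None,
        )

    def test_invalid_rules_rejected(self):
        with pytest.raises(ValueError):
            elig.ScreeningRule("bad", 80, 50, None, None, False)
        with pytest.raises(ValueError):
            elig.ScreeningRule("bad", 40, 85, 20.0, None, False)


class TestClassify:
    @pytest.mark.parametrize(
        "kwargs,expected",
        [
            (dict(age=67, smoking="current", py=40), True),
            (dict(age=60, smoking="never", py=0, quit=math.nan), False),
            (dict(age=80, smoking="former", py=20, quit=14.9), True),
            (dict(age=81, smoking="former", py=20, quit=14.9), False),
            (dict(age=80, smoking="former", py=20, quit=15.0), False),  # exclusive
            (dict(age=50, smoking="former", py=19.99, quit=1.0), False),
            (dict(age=49, smoking="current", py=40), False),
        ],
    )
    def test_uspstf_boundaries(self, kwargs, expected):
        assert elig.classify(patient(**kwargs), elig.uspstf_2021()) is expected

    def test_age_based_ignores_smoking(self):
        rule = elig.age_based_rule()
        assert elig.classify(patient(age=40, smoking="never", py=0, quit=math.nan), rule)
        assert not elig.classify(patient(age=86, smoking="current", py=100), rule)

    def test_strict_mode_fails_unobserved_pack_years(self, default_cohort):
        """Strict classification treats unrecorded pack-years as not
        meeting the pack-year floor; the permissive default does not."""
        rule = elig.expanded_rule()
        permissive = sum(elig.classify(p, rule) for p in default_cohort)
        strict = sum(elig.classify(p, rule, strict=True) for p in default_cohort)
        assert permissive == 619
        assert strict < permissive
        # the age-based rule has no pack-year criterion; strict is a no-op
        age_rule = elig.age_based_rule()
        assert sum(elig.classify(p, age_rule, strict=True) for p in default_cohort) == 936

    def test_expanded_drops_cessation_limit(self):
        rule = elig.expanded_rule()
        assert elig.classify(patient(age=60, smoking="former", py=10, quit=40), rule)
        assert not elig.classify(patient(age=60, smoking="former", py=9.9, quit=40), rule)


class TestIneligibilityReasons:
    def test_age_only(self):
        r = elig.ineligibility_reasons(
            patient(age=90, smoking="former", py=40, quit=2), elig.uspstf_2021()
        )
        assert r == {"age"}

    def test_never_smoker_reported_alone_when_age_eligible(self):
        r = elig.ineligibility_reasons(
            patient(age=60, smoking="never", py=0, quit=math.nan), elig.uspstf_2021()
        )
        assert r == {"never_smoker"}

    def test_all_three_smoking_criteria(self):
        r = elig.ineligibility_reasons(
            patient(age=45, smoking="former", py=10, quit=20), elig.uspstf_2021()
        )
        assert r == {"age", "pack_years", "quit_time"}

    def test_eligible_patient_raises(self):
        with pytest.raises(ValueError):
            elig.ineligibility_reasons(patient(), elig.uspstf_2021())

    def test_stratum_partition(self, default_cohort):
        """Every patient maps to exactly one stratum; counts reproduce
        the calibration table."""
        rule = elig.uspstf_2021()
        counts = {label: 0 for label in elig.STRATUM_LABELS}
        for p in default_cohort:
            counts[elig.ineligibility_stratum(p, rule)] += 1
        assert sum(counts.values()) == 997
        assert counts["eligible"] == 350
        assert counts["never_smoker_age_eligible"] == 195
        assert counts["quit_only"] == 134


class TestDetectionRate:
    def test_published_rates(self, default_cohort):
        for rule, num in (
            (elig.uspstf_2021(), 350),
            (elig.expanded_rule(), 619),
            (elig.age_based_rule(), 936),
        ):
            rate = elig.detection_rate(default_cohort, rule)
            assert (rate.numerator, rate.denominator) == (num, 997)

    def test_universal_rule_captures_all(self, default_cohort):
        rule = elig.ScreeningRule("all", 0, 200, None, None, False)
        assert elig.detection_rate(default_cohort, rule).fraction == 1.0

    def test_rule_ordering_on_default_cohort(self, default_cohort):
        uspstf = elig.detection_rate(default_cohort, elig.uspstf_2021()).fraction
        expanded = elig.detection_rate(default_cohort, elig.expanded_rule()).fraction
        age = elig.detection_rate(default_cohort, elig.age_based_rule()).fraction
        assert age >= expanded >= uspstf

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            elig.detection_rate([], elig.uspstf_2021())


patients_strategy = st.builds(
    patient,
    age=st.integers(18, 99),
    smoking=st.sampled_from(["never", "current", "former"]),
    py=st.floats(0, 150, allow_nan=False),
    quit=st.floats(0, 70, allow_nan=False),
)


class TestMonotonicity:
    @given(
        pats=st.lists(patients_strategy, min_size=1, max_size=30),
        widen_age_lo=st.integers(0, 10),
        widen_age_hi=st.integers(0, 10),
        lower_py=st.floats(0, 10, allow_nan=False),
        drop_quit=st.booleans(),
    )
    def test_widening_never_decreases_detection(
        self, pats, widen_age_lo, widen_age_hi, lower_py, drop_quit
    ):
        base = elig.uspstf_2021()
        wider = elig.ScreeningRule(
            "wider",
            base.age_min - widen_age_lo,
            base.age_max + widen_age_hi,
            base.min_pack_years - lower_py,
            None if drop_quit else base.max_quit_years,
            True,
        )
        assert (
            elig.detection_rate(pats, wider).fraction
            >= elig.detection_rate(pats, base).fraction
        )
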