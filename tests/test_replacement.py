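"""Replacement rates, longevity, and the missing-replacement estimators."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dentinechron.errors import (
    InconsistentFamilyError,
    InvalidInputError,
    InvalidMeasurementError,
    MissingProfileError,
)
from dentinechron.replacement import (
    ApexProfile,
    EstimationMethod,
    JawElement,
    ToothFamily,
    ToothRecord,
    count_lines_from_apex,
    dentine_extent_age,
    estimate_missing_replacement_age,
    estimated_replacement_height,
    functional_period,
    replacement_rate_direct,
    replacement_rate_for_family,
    tooth_longevity,
)
from dentinechron.synthetic import GrowthParams, simulate_family


def tooth(age, position="p1", **kw):
    return ToothRecord(
        taxon="T", specimen_id="s", element=JawElement.MAXILLA,
        position_label=position, age_days=age, **kw,
    )


class TestDirectRate:
    @pytest.mark.parametrize(
        "functional, replacement, expected",
        [(459, 354, 105), (147, 43, 104), (157, 59, 98), (146, 69, 77), (200, 0, 200)],
    )
    def test_subtraction(self, functional, replacement, expected):
        est = replacement_rate_direct(functional, replacement)
        assert est.rate_days == expected
        assert est.method is EstimationMethod.DIRECT
        assert not est.is_minimum

    def test_inconsistent_family(self):
        with pytest.raises(InconsistentFamilyError):
            replacement_rate_direct(100, 100)

    @settings(max_examples=50, derandomize=True)
    @given(a=st.integers(1, 10_000), b=st.integers(0, 9_999))
    def test_integer_conservation(self, a, b):
        if b >= a:
            a, b = b + 1, a - 1 if a > 0 else 0
        est = replacement_rate_direct(a, b)
        assert est.rate_days + b == a


class TestRpHeightEstimator:
    @pytest.mark.parametrize("rp, expected", [(54, 36), (0, 0), (100, 66.667)])
    def test_two_thirds_rule(self, rp, expected):
        assert estimated_replacement_height(rp) == pytest.approx(expected, abs=5e-4)

    def test_negative_rp_rejected(self):
        with pytest.raises(InvalidMeasurementError):
            estimated_replacement_height(-1.0)

    @pytest.mark.parametrize(
        "height, expected", [(25.0, 2), (30.0, 3), (0.0, 0), (1000.0, 4)]
    )
    def test_count_lines_from_apex(self, height, expected):
        profile = ApexProfile((10.0, 20.0, 30.0, 40.0))
        assert count_lines_from_apex(profile, height) == expected

    def test_uniform_profile_direct_count(self):
        profile = ApexProfile(tuple(float(i) for i in range(1, 101)))
        assert count_lines_from_apex(profile, 36.0) == 36
        assert estimate_missing_replacement_age(profile, 54.0) == 36

    def test_composition_gives_reported_rate(self):
        # 171-day functional tooth with a 54-um pit on a 1-um-per-line edge
        profile = ApexProfile(tuple(float(i) for i in range(1, 172)))
        repl_age = estimate_missing_replacement_age(profile, 54.0)
        assert replacement_rate_direct(171, repl_age).rate_days == 135

    @settings(max_examples=30, derandomize=True)
    @given(
        heights=st.lists(st.floats(0.0, 50.0), min_size=1, max_size=60),
        h1=st.floats(0, 3000),
        h2=st.floats(0, 3000),
    )
    def test_monotone_and_bounded(self, heights, h1, h2):
        profile = ApexProfile(tuple(sorted(heights)))
        lo, hi = sorted((h1, h2))
        c_lo, c_hi = count_lines_from_apex(profile, lo), count_lines_from_apex(profile, hi)
        assert c_lo <= c_hi <= len(profile)

    def test_recovery_on_synthetic_families(self, rng):
        # mirrors the calibration on specimens with intact replacement teeth
        params = GrowthParams()
        rel_errors = []
        for _ in range(200):
            obs = params.true_replacement_interval + int(rng.integers(30, 200))
            family, profile, truth = simulate_family(params, obs, rng)
            true_repl = family.replacements[0].age_days
            est = estimate_missing_replacement_age(profile, family.functional.rp_height)
            rel_errors.append(abs(est - true_repl) / true_repl)
        assert np.median(rel_errors) <= 0.15


class TestDentineExtent:
    @pytest.mark.parametrize("extent, width, expected", [(100, 10, 10), (780, 10, 78)])
    def test_arithmetic(self, extent, width, expected):
        assert dentine_extent_age(extent, width) == expected

    def test_invalid_inputs(self):
        with pytest.raises(InvalidMeasurementError):
            dentine_extent_age(0, 10)
        with pytest.raises(InvalidMeasurementError):
            dentine_extent_age(100, 0)


class TestFamilyDispatch:
    def test_minimum_when_no_replacement_or_pit(self):
        fam = ToothFamily(functional=tooth(152))
        est = replacement_rate_for_family(fam)
        assert est.rate_days == 152
        assert est.method is EstimationMethod.MINIMUM
        assert est.is_minimum

    def test_direct_when_replacement_present(self):
        fam = ToothFamily(functional=tooth(157), replacements=(tooth(59, "p1r"),))
        est = replacement_rate_for_family(fam)
        assert est.rate_days == 98
        assert est.method is EstimationMethod.DIRECT

    def test_two_replacements_uses_immediate_successor(self):
        fam = ToothFamily(
            functional=tooth(100),
            replacements=(tooth(60, "r1"), tooth(20, "r2")),
        )
        est = replacement_rate_for_family(fam)
        assert est.rate_days == 40
        assert est.replacement_age_used == 60

    def test_rp_dispatch_requires_profile(self):
        fam = ToothFamily(functional=tooth(171, rp_height=54.0))
        with pytest.raises(MissingProfileError):
            replacement_rate_for_family(fam)
        profile = ApexProfile(tuple(float(i) for i in range(1, 172)))
        est = replacement_rate_for_family(fam, profile)
        assert est.method is EstimationMethod.RP_HEIGHT
        assert est.rate_days == 135

    def test_family_invariants(self):
        with pytest.raises(InconsistentFamilyError):
            ToothFamily(functional=tooth(50), replacements=(tooth(60, "r"),))
        with pytest.raises(InconsistentFamilyError):
            ToothFamily(
                functional=tooth(100),
                replacements=(tooth(20, "r1"), tooth(60, "r2")),
            )


class TestFunctionalPeriodAndLongevity:
    def test_shed_minus_mean_attachment(self):
        assert functional_period(227, [106, 135]) == 107

    def test_single_attachment_baseline(self):
        assert functional_period(227, [135]) == 92

    @settings(max_examples=30, derandomize=True)
    @given(shed=st.integers(2, 1000), k=st.integers(1, 999))
    def test_single_tooth_difference(self, shed, k):
        if k >= shed:
            k = shed - 1
        assert functional_period(shed, [shed - k]) == k

    def test_invalid_inputs(self):
        with pytest.raises(InvalidInputError):
            functional_period(100, [])
        with pytest.raises(InvalidInputError):
            functional_period(100, [100])

    def test_longevity_and_minimum_flag(self):
        fam = ToothFamily(functional=tooth(459))
        assert tooth_longevity(fam) == (459, False)
        fam_min = ToothFamily(functional=tooth(81, age_is_minimum=True))
        assert tooth_longevity(fam_min) == (81, True)

    def test_longevity_bounds_rate(self):
        fam = ToothFamily(functional=tooth(459), replacements=(tooth(354, "r"),))
        longevity, _ = tooth_longevity(fam)
        assert longevity >= replacement_rate_for_family(fam).rate_days
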