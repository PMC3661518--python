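import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad
from scipy.stats import lognorm

from pmslt.risk_model import (
    BMIExposure,
    DiseaseRisk,
    ExposureShift,
    adjust_incidence,
    apply_bmi_trend,
    category_relative_risks,
    kg_to_bmi_units,
    lognormal_from_mean_sd,
    potential_impact_fraction,
    shift_relative_risks,
)

CUTS = [0.0, 25.0, 30.0, 35.0, 40.0, np.inf]


def _scipy_dist(mean, sd):
    mu, sigma = lognormal_from_mean_sd(mean, sd)
    return lognorm(s=sigma, scale=np.exp(mu))


class TestLognormalFromMeanSd:
    def test_round_trip_moments(self):
        mu, sigma = lognormal_from_mean_sd(27.0, 5.0)
        back_mean = math.exp(mu + sigma**2 / 2)
        back_sd = back_mean * math.sqrt(math.exp(sigma**2) - 1)
        assert back_mean == pytest.approx(27.0, rel=1e-10)
        assert back_sd == pytest.approx(5.0, rel=1e-10)

    def test_sd_to_zero_limit(self):
        mu, sigma = lognormal_from_mean_sd(27.0, 1e-12)
        assert sigma == pytest.approx(0.0, abs=1e-10)
        assert mu == pytest.approx(math.log(27.0), abs=1e-10)

    def test_quadrature_mean(self):
        # oracle: numerically integrate b * pdf(b) over the support
        dist = _scipy_dist(27.0, 5.0)
        mean, _ = quad(lambda b: b * dist.pdf(b), 0, np.inf)
        assert mean == pytest.approx(27.0, abs=1e-6)

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(ValueError):
            lognormal_from_mean_sd(0.0, 5.0)
        with pytest.raises(ValueError):
            lognormal_from_mean_sd(27.0, -1.0)


class TestCategoryProportions:
    def test_point_mass_between_25_and_30(self):
        exposure = BMIExposure(27.0, 1e-9)
        np.testing.assert_allclose(
            exposure.proportions, [0, 1, 0, 0, 0], atol=1e-12
        )

    @given(
        mean=st.floats(20.0, 35.0), sd=st.floats(0.5, 8.0)
    )
    @settings(max_examples=50, deadline=None)
    def test_sum_to_one(self, mean, sd):
        assert BMIExposure(mean, sd).proportions.sum() == pytest.approx(
            1.0, abs=1e-12
        )

    def test_matches_quadrature(self):
        dist = _scipy_dist(27.0, 5.0)
        p = BMIExposure(27.0, 5.0).proportions
        for i in range(5):
            hi = 200.0 if np.isinf(CUTS[i + 1]) else CUTS[i + 1]
            expected, _ = quad(dist.pdf, CUTS[i], hi, limit=200)
            if np.isinf(CUTS[i + 1]):
                expected += dist.sf(200.0)
            assert p[i] == pytest.approx(expected, abs=1e-8)

    def test_quadrature_over_100_random_parameter_sets(self):
        rng = np.random.default_rng(2024)
        for _ in range(100):
            mean = rng.uniform(24, 30)
            sd = rng.uniform(3, 6)
            dist = _scipy_dist(mean, sd)
            p = BMIExposure(mean, sd).proportions
            for i in range(5):
                if np.isinf(CUTS[i + 1]):
                    expected = dist.sf(CUTS[i])
                else:
                    expected, _ = quad(dist.pdf, CUTS[i], CUTS[i + 1], limit=200)
                assert p[i] == pytest.approx(expected, abs=1e-8)


class TestCategoryMeans:
    def test_strictly_increasing(self):
        m = BMIExposure(27.0, 5.0).means
        assert np.all(np.diff(m) > 0)

    def test_matches_quadrature(self):
        dist = _scipy_dist(27.0, 5.0)
        exposure = BMIExposure(27.0, 5.0)
        for i in range(4):  # bounded categories
            num, _ = quad(lambda b: b * dist.pdf(b), CUTS[i], CUTS[i + 1], limit=200)
            den, _ = quad(dist.pdf, CUTS[i], CUTS[i + 1], limit=200)
            assert exposure.means[i] == pytest.approx(num / den, rel=1e-8)


class TestCategoryRelativeRisks:
    def test_rr_unit_one_gives_all_ones(self):
        rr = category_relative_risks(1.0, BMIExposure(27.0, 5.0))
        np.testing.assert_allclose(rr, 1.0)

    def test_power_evaluation(self):
        # oracle: if m_5 - m_1 = 20 then RR_5 = 1.05**20 = 2.6532977051...
        exposure = BMIExposure(27.0, 5.0)
        m = exposure.means
        rr = category_relative_risks(1.05, exposure)
        assert rr[4] == pytest.approx(1.05 ** (m[4] - m[0]), rel=1e-12)
        assert 1.05**20 == pytest.approx(2.653297705144420, rel=1e-12)

    def test_monotone_in_category(self):
        for rr_unit in (1.0, 1.05, 1.2, 1.4):
            rr = category_relative_risks(rr_unit, BMIExposure(27.0, 5.0))
            assert np.all(np.diff(rr) >= 0)
            assert rr[0] == 1.0

    def test_protective_rejected(self):
        with pytest.raises(ValueError):
            category_relative_risks(0.9, BMIExposure(27.0, 5.0))


class TestShiftRelativeRisks:
    def test_zero_delta_identity(self):
        exposure = BMIExposure(27.0, 5.0)
        rr = category_relative_risks(1.1, exposure)
        shifted = shift_relative_risks(
            DiseaseRisk(1.1, rr), ExposureShift(0.0, frozenset({4, 5}))
        )
        np.testing.assert_array_equal(shifted, rr)

    def test_direct_evaluation(self):
        # RR_5 = 2.0, rr_unit = 1.05, delta = 10 -> 2.0 * 1.05**-10 = 1.2278...
        rr = np.array([1.0, 1.1, 1.3, 1.6, 2.0])
        shifted = shift_relative_risks(
            DiseaseRisk(1.05, rr), ExposureShift(10.0, frozenset({5}))
        )
        assert shifted[4] == pytest.approx(2.0 * 1.05**-10, rel=1e-12)
        assert shifted[4] == pytest.approx(1.2278265071, rel=1e-9)
        np.testing.assert_array_equal(shifted[:4], rr[:4])

    def test_floor_at_one(self):
        rr = np.array([1.0, 1.1, 1.3, 1.6, 2.0])
        shifted = shift_relative_risks(
            DiseaseRisk(1.05, rr), ExposureShift(100.0, frozenset({4, 5}))
        )
        assert shifted[3] == 1.0
        assert shifted[4] == 1.0


class TestPotentialImpactFraction:
    def test_no_shift_gives_zero(self):
        p = np.array([0.5, 0.3, 0.1, 0.07, 0.03])
        rr = np.array([1.0, 1.2, 1.5, 2.0, 3.0])
        assert potential_impact_fraction(p, rr, rr) == 0.0

    def test_hand_summation(self):
        # (0.8*1 + 0.2*2 - 0.8*1 - 0.2*1.5) / (0.8*1 + 0.2*2) = 0.1/1.2
        pif = potential_impact_fraction([0.8, 0.2], [1.0, 2.0], [1.0, 1.5])
        assert pif == pytest.approx(1.0 / 12.0, rel=1e-12)

    def test_all_mass_at_reference(self):
        p = np.array([1.0, 0.0, 0.0, 0.0, 0.0])
        rr = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        assert potential_impact_fraction(p, rr, np.ones(5)) == 0.0

    def test_zero_denominator_rejected(self):
        with pytest.raises(ValueError):
            potential_impact_fraction([0.0, 0.0], [1.0, 1.0], [1.0, 1.0])

    @given(
        mean=st.floats(24.0, 30.0),
        sd=st.floats(3.0, 6.0),
        rr_unit=st.floats(1.0, 1.4),
        delta=st.floats(0.0, 10.0),
    )
    @settings(max_examples=60, deadline=None)
    def test_bounded_in_unit_interval(self, mean, sd, rr_unit, delta):
        exposure = BMIExposure(mean, sd)
        rr = category_relative_risks(rr_unit, exposure)
        shifted = shift_relative_risks(
            DiseaseRisk(rr_unit, rr), ExposureShift(delta, frozenset({4, 5}))
        )
        pif = potential_impact_fraction(exposure.proportions, rr, shifted)
        assert 0.0 <= pif < 1.0

    def test_monotone_in_delta_and_rr_unit(self):
        exposure = BMIExposure(27.0, 5.0)
        p = exposure.proportions
        for rr_unit in (1.02, 1.1, 1.2, 1.4):
            rr = category_relative_risks(rr_unit, exposure)
            pifs = []
            for delta in (0.0, 1.0, 2.0, 5.0, 10.0):
                shifted = shift_relative_risks(
                    DiseaseRisk(rr_unit, rr), ExposureShift(delta, frozenset({4, 5}))
                )
                pifs.append(potential_impact_fraction(p, rr, shifted))
            assert pifs == sorted(pifs)
        for delta in (1.0, 5.0, 10.0):
            pifs = []
            for rr_unit in (1.0, 1.05, 1.1, 1.2, 1.3, 1.4):
                rr = category_relative_risks(rr_unit, exposure)
                shifted = shift_relative_risks(
                    DiseaseRisk(rr_unit, rr), ExposureShift(delta, frozenset({4, 5}))
                )
                pifs.append(potential_impact_fraction(p, rr, shifted))
            assert pifs == sorted(pifs)

    def test_close_to_continuous_oracle_for_moderate_rr(self):
        # restricted-domain sanity check: for per-unit RRs <= 1.15 the
        # categorical PIF tracks the (support-truncated) continuous PIF
        # closely; the full rr range is exercised in the acceptance suite
        rng = np.random.default_rng(7)
        for _ in range(25):
            mean = rng.uniform(24, 30)
            sd = rng.uniform(3, 6)
            rr_unit = rng.uniform(1.0, 1.15)
            delta = rng.uniform(0, 10)
            pif_cat = _categorical_pif(mean, sd, rr_unit, delta, "bmi35")
            pif_cont = _continuous_pif(mean, sd, rr_unit, delta, 35.0)
            assert pif_cat == pytest.approx(pif_cont, abs=0.02)


def _categorical_pif(mean, sd, rr_unit, delta, scenario):
    from pmslt.risk_model import ELIGIBLE_CATEGORIES

    exposure = BMIExposure(mean, sd)
    rr = category_relative_risks(rr_unit, exposure)
    shifted = shift_relative_risks(
        DiseaseRisk(rr_unit, rr), ExposureShift(delta, ELIGIBLE_CATEGORIES[scenario])
    )
    return potential_impact_fraction(exposure.proportions, rr, shifted)


def _continuous_pif(mean, sd, rr_unit, delta, cutoff, bmax=60.0):
    """Brute-force continuous PIF; BMI support truncated at ``bmax`` because
    the untruncated integral of rr**b against a lognormal diverges."""
    dist = _scipy_dist(mean, sd)
    m1 = BMIExposure(mean, sd).means[0]

    def rr_fn(b):
        return rr_unit ** (b - m1)

    def rr_shifted_fn(b):
        if b > cutoff:
            return max(1.0, rr_unit ** (b - delta - m1))
        return rr_fn(b)

    before = sum(
        quad(lambda b: dist.pdf(b) * rr_fn(b), lo, hi, limit=200)[0]
        for lo, hi in ((0.0, cutoff), (cutoff, bmax))
    )
    after = sum(
        quad(lambda b: dist.pdf(b) * rr_shifted_fn(b), lo, hi, limit=200)[0]
        for lo, hi in ((0.0, cutoff), (cutoff, bmax))
    )
    return 1.0 - after / before


class TestAdjustIncidence:
    def test_identity_at_zero_pif(self):
        assert adjust_incidence(0.01, 0.0) == 0.01

    def test_direct_product(self):
        assert adjust_incidence(0.01, 1.0 / 12.0) == pytest.approx(
            0.01 * 11.0 / 12.0, rel=1e-12
        )

    def test_zero_incidence(self):
        assert adjust_incidence(0.0, 0.5) == 0.0


class TestApplyBMITrend:
    def test_zero_years_unchanged(self):
        exposure = BMIExposure(27.0, 5.0)
        assert apply_bmi_trend(exposure, 0.0, 0.05) == exposure

    def test_capped_at_horizon(self):
        exposure = BMIExposure(27.0, 5.0)
        shifted = apply_bmi_trend(exposure, 25.0, 0.05)
        assert shifted.mean == pytest.approx(28.0)  # min(25, 20) * 0.05 = 1.0
        assert shifted.sd == exposure.sd

    def test_zero_increment_unchanged(self):
        exposure = BMIExposure(27.0, 5.0)
        for years in (1.0, 10.0, 50.0):
            assert apply_bmi_trend(exposure, years, 0.0) == exposure


def test_kg_conversion():
    assert kg_to_bmi_units(32.0) == pytest.approx(10.0, rel=1e-12)
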