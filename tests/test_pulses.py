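"""Binomial pulse construction and excitation-profile physics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from wfmp2rage import (
    PpmConvention,
    band_extremum_efficiency,
    effective_flip,
    excitation_profile,
    make_binomial_pulse,
    resonance_offset,
    small_tip_profile,
)


class TestMakeBinomialPulse:
    @pytest.mark.parametrize(
        "order,target,expected",
        [
            (6, "water", (1, 5, 10, 10, 5, 1)),
            (6, "fat", (1, -5, 10, -10, 5, -1)),
            (2, "water", (1, 1)),
            (4, "fat", (1, -3, 3, -1)),
        ],
    )
    def test_coefficients_follow_binomial_row_with_target_signs(self, order, target, expected):
        assert make_binomial_pulse(order, target).coefficients == expected

    def test_total_duration_of_protocol_pulse(self):
        # 5 centre gaps of 1.15 ms plus one 60 us subpulse
        pulse = make_binomial_pulse(6, "water", 60e-6, 1.15e-3, 4.0)
        assert pulse.total_duration == pytest.approx(5.81e-3, abs=1e-9)

    def test_subpulse_flips_sum_to_nominal_flip(self):
        pulse = make_binomial_pulse(6, "water")
        assert np.abs(pulse.subpulse_flips()).sum() == pytest.approx(math.radians(4.0))

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"order": 1, "target": "water"},
            {"order": 6, "target": "water", "subpulse_duration": -1e-6},
            {"order": 6, "target": "water", "centre_spacing": 0.0},
            {"order": 6, "target": "water", "subpulse_duration": 2e-3, "centre_spacing": 1e-3},
            {"order": 6, "target": "oil"},
        ],
    )
    def test_invalid_parameters_raise(self, kwargs):
        with pytest.raises(ValueError):
            make_binomial_pulse(**kwargs)


class TestExcitationProfile:
    def test_water_on_resonance_is_unity(self, water_pulse):
        eff = excitation_profile(water_pulse, np.array([0.0])).efficiency[0]
        assert eff == pytest.approx(1.0, abs=1e-12)

    def test_water_efficiency_at_200hz(self, water_pulse):
        # ~24% of the intended transverse magnetization survives at 200 Hz
        eff = excitation_profile(water_pulse, np.array([200.0])).efficiency[0]
        assert eff == pytest.approx(0.237, abs=0.005)

    def test_water_null_at_half_precession_period(self, water_pulse):
        f_null = 1.0 / (2.0 * water_pulse.centre_spacing)
        eff = excitation_profile(water_pulse, np.array([f_null])).efficiency[0]
        assert eff < 1e-4

    def test_profile_symmetric_in_frequency_for_water(self, water_pulse):
        f = np.linspace(1.0, 600.0, 40)
        pos = excitation_profile(water_pulse, f).efficiency
        neg = excitation_profile(water_pulse, -f[::-1]).efficiency[::-1]
        np.testing.assert_allclose(pos, neg, atol=1e-10)

    @pytest.mark.parametrize("target", ["water", "fat"])
    def test_efficiency_bounded_in_unit_interval(self, target):
        pulse = make_binomial_pulse(6, target)
        eff = excitation_profile(pulse, np.linspace(-900, 900, 501)).efficiency
        assert np.all(eff >= 0.0) and np.all(eff <= 1.0 + 1e-9)

    @pytest.mark.parametrize("target", ["water", "fat"])
    @pytest.mark.parametrize("mode", ["effective-field", "instantaneous"])
    def test_bloch_matches_small_tip_within_one_percent(self, target, mode):
        pulse = make_binomial_pulse(6, target)
        f = np.linspace(-600.0, 600.0, 241)
        bloch = excitation_profile(pulse, f, subpulse_integration=mode).efficiency
        analytic = small_tip_profile(pulse, f).efficiency
        assert np.max(np.abs(bloch - analytic)) < 0.01

    def test_non_finite_frequencies_rejected(self, water_pulse):
        with pytest.raises(ValueError):
            excitation_profile(water_pulse, np.array([0.0, np.inf]))


class TestSmallTipProfile:
    def test_water_closed_form_value_at_third_of_period(self, water_pulse):
        f = 1.0 / (3.0 * water_pulse.centre_spacing)
        eff = small_tip_profile(water_pulse, np.array([f])).efficiency[0]
        assert eff == pytest.approx(abs(math.cos(math.pi / 3)) ** 5)  # 0.03125

    def test_fat_peak_at_half_period(self, fat_pulse):
        f = 1.0 / (2.0 * fat_pulse.centre_spacing)
        eff = small_tip_profile(fat_pulse, np.array([f])).efficiency[0]
        assert eff == pytest.approx(1.0)

    def test_fat_nulled_on_resonance(self, fat_pulse):
        assert small_tip_profile(fat_pulse, np.array([0.0])).efficiency[0] < 1e-12

    @given(st.floats(-2000, 2000))
    @settings(max_examples=50, deadline=None)
    def test_periodicity_in_inverse_centre_spacing(self, df):
        pulse = make_binomial_pulse(6, "water")
        period = 1.0 / pulse.centre_spacing
        e0 = small_tip_profile(pulse, np.array([df])).efficiency[0]
        e1 = small_tip_profile(pulse, np.array([df + period])).efficiency[0]
        assert e0 == pytest.approx(e1, abs=1e-9)


class TestBandExtremum:
    def test_water_band_minimum_exceeds_90_percent(self, water_pulse):
        assert band_extremum_efficiency(water_pulse, 0.0, 112.0, "min") >= 0.90

    def test_zero_width_band_degenerates_to_point(self, water_pulse):
        point = excitation_profile(water_pulse, np.array([150.0])).efficiency[0]
        assert band_extremum_efficiency(water_pulse, 150.0, 0.0, "min") == pytest.approx(point)

    def test_fat_band_near_sine_peak_is_unity(self, fat_pulse):
        f_peak = 1.0 / (2.0 * fat_pulse.centre_spacing)
        assert band_extremum_efficiency(fat_pulse, f_peak, 10.0, "min") == pytest.approx(1.0, abs=0.005)

    def test_min_monotone_non_increasing_in_width(self, water_pulse):
        widths = [0.0, 50.0, 112.0, 200.0, 400.0]
        mins = [band_extremum_efficiency(water_pulse, 0.0, w, "min") for w in widths]
        assert all(a >= b - 1e-12 for a, b in zip(mins, mins[1:]))

    def test_negative_width_rejected(self, water_pulse):
        with pytest.raises(ValueError):
            band_extremum_efficiency(water_pulse, 0.0, -1.0)


class TestEffectiveFlip:
    def test_on_resonance_identity_and_linear_b1(self, water_pulse):
        assert effective_flip(water_pulse, 0.0, 1.0) == pytest.approx(4.0)
        assert effective_flip(water_pulse, 0.0, 0.8) == pytest.approx(3.2)

    def test_200hz_off_resonance_flip(self, water_pulse):
        # 4 deg scaled by the ~23.8% efficiency
        assert effective_flip(water_pulse, 200.0, 1.0) == pytest.approx(0.95, abs=0.03)

    def test_negative_b1_rejected(self, water_pulse):
        with pytest.raises(ValueError):
            effective_flip(water_pulse, 0.0, -0.1)


class TestPpmConvention:
    def test_water_is_the_carrier(self):
        assert resonance_offset(PpmConvention(), "water") == pytest.approx(0.0)

    @pytest.mark.parametrize(
        "name,expected_hz",
        [("alpha-olefinic", 332.64), ("methylene", 418.88)],
    )
    def test_named_resonance_offsets(self, name, expected_hz):
        assert resonance_offset(PpmConvention(), name) == pytest.approx(expected_hz, abs=0.05)

    def test_numeric_ppm_accepted(self):
        conv = PpmConvention()
        assert resonance_offset(conv, 2.0) == pytest.approx((4.7 - 2.0) * 123.2)

    def test_unknown_name_raises(self):
        with pytest.raises(KeyError):
            resonance_offset(PpmConvention(), "cholesterol")
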