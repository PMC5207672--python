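import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from lakeprod import conversions as cv
from lakeprod import seawater


class TestChlorophyll:
    def test_zero_difference_gives_zero(self):
        extract, lake = cv.chla_from_absorbance(
            cv.ChlaReading(a665=0.25, a750=0.25, extract_volume=3,
                           filtered_volume=5))
        assert extract == 0.0 and lake == 0.0

    def test_hand_computed_example(self):
        # A665-A750 = 0.100, 3 mL extract from 5 mL filtered
        extract, lake = cv.chla_from_absorbance(
            cv.ChlaReading(a665=0.120, a750=0.020, extract_volume=3,
                           filtered_volume=5))
        assert extract == pytest.approx(1.1904, abs=1e-9)
        assert lake == pytest.approx(714.24, abs=1e-6)

    def test_linearity_slope_is_coefficient(self):
        diffs = np.array([0.05, 0.10, 0.20, 0.40])
        extracts = [cv.chla_from_absorbance(
            cv.ChlaReading(a665=d, a750=0.0, extract_volume=1,
                           filtered_volume=1))[0] for d in diffs]
        slopes = np.array(extracts) / diffs
        assert np.allclose(slopes, 11.904)

    def test_dense_lake_value_round_trips(self):
        """An absorbance chosen for a 612 ug/L lake works back exactly."""
        diff = cv.absorbance_for_chla(612.0, 3.0, 5.0)
        _, lake = cv.chla_from_absorbance(
            cv.ChlaReading(a665=diff + 0.02, a750=0.02, extract_volume=3,
                           filtered_volume=5))
        assert lake == pytest.approx(612.0, rel=1e-12)

    def test_negative_difference_clamps_with_warning(self):
        with pytest.warns(cv.ExtrapolationWarning):
            extract, lake = cv.chla_from_absorbance(
                cv.ChlaReading(a665=0.01, a750=0.05, extract_volume=3,
                               filtered_volume=5))
        assert extract == 0.0 and lake == 0.0

    def test_nonpositive_volume_rejected(self):
        with pytest.raises(ValueError):
            cv.ChlaReading(a665=0.1, a750=0.0, extract_volume=0,
                           filtered_volume=5)


class TestOxygenSolubility:
    def test_hypersaline_lake_value(self):
        # warm hypersaline surface water sits near 5.6 mg/L at equilibrium
        assert cv.o2_saturation_concentration(31, 52) == pytest.approx(5.6, abs=0.05)

    def test_freshwater_reference(self):
        # standard freshwater solubility tables: 8.26 mg/L at 25 C
        assert cv.o2_saturation_concentration(25, 0) == pytest.approx(8.26, abs=0.02)

    def test_salting_out_and_warming_out(self):
        assert (cv.o2_saturation_concentration(31, 52)
                < cv.o2_saturation_concentration(31, 0))
        assert (cv.o2_saturation_concentration(31, 52)
                < cv.o2_saturation_concentration(20, 52))

    def test_two_fits_agree_within_2_percent(self):
        """Garcia-Gordon and Weiss are independently coded; they must agree."""
        t = np.linspace(20, 35, 16)[:, None]
        s = np.linspace(0, 55, 23)[None, :]
        gg = seawater.o2_solubility_garcia_gordon(t, s)
        wz = seawater.o2_solubility_weiss(t, s)
        assert np.max(np.abs(gg - wz) / gg) < 0.02

    def test_monotone_decreasing_in_t_and_s(self):
        t = np.linspace(0, 39, 40)
        sol_t = cv.o2_saturation_concentration(t, 30)
        assert np.all(np.diff(sol_t) < 0)
        s = np.linspace(0, 59, 60)
        sol_s = cv.o2_saturation_concentration(25, s)
        assert np.all(np.diff(sol_s) < 0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            cv.o2_saturation_concentration(45, 30)
        with pytest.raises(ValueError):
            cv.o2_saturation_concentration(25, 70)

    @pytest.mark.parametrize("pct,factor", [(100.0, 1.0), (0.0, 0.0),
                                            (200.0, 2.0)])
    def test_percent_saturation_scales_linearly(self, pct, factor):
        base = cv.o2_saturation_concentration(31, 52)
        assert cv.percent_saturation_to_concentration(pct, 31, 52) == \
            pytest.approx(factor * base, rel=1e-12)

    def test_negative_percent_rejected(self):
        with pytest.raises(ValueError):
            cv.percent_saturation_to_concentration(-5, 31, 52)


class TestSalinity:
    def test_pss78_definition_point(self):
        # conductivity ratio 1 at 15 C is 35 psu by construction of PSS-78
        assert cv.salinity_from_conductivity(42.914, 15.0) == \
            pytest.approx(35.000, abs=1e-3)

    @pytest.mark.parametrize("cond,temp,printed", [
        (77.1, 28.5, 52.0),   # 2010 survey conditions
        (79.7, 29.1, 52.7),   # 2011 survey conditions
    ])
    def test_hypersaline_survey_values_within_5pct(self, cond, temp, printed):
        """Survey conductivities land near the reported ~52 psu.

        The conversion temperature the loggers applied is unknown and PSS-78
        is an extrapolation above 42 psu, so a 5% band is the honest check.
        """
        with pytest.warns(cv.ExtrapolationWarning):
            s = cv.salinity_from_conductivity(cond, temp)
        assert abs(s - printed) / printed < 0.05

    def test_extrapolation_flagged_above_42(self):
        with pytest.warns(cv.ExtrapolationWarning):
            cv.salinity_from_conductivity(80.0, 29.0)

    def test_nonpositive_conductivity_rejected(self):
        with pytest.raises(ValueError):
            cv.salinity_from_conductivity(0.0, 15.0)


class TestCarbonConversions:
    def test_daily_gpp_to_carbon(self):
        # 22.2 g O2 at PQ 1 is 8.3 g C (22.2 * 12/32)
        assert cv.oxygen_to_carbon(22.2, 1.0) == pytest.approx(8.3, abs=0.05)

    @pytest.mark.parametrize("o2,pq,expect", [(0.0, 1.0, 0.0),
                                              (32.0, 1.0, 12.0)])
    def test_molar_identities(self, o2, pq, expect):
        assert cv.oxygen_to_carbon(o2, pq) == pytest.approx(expect, rel=1e-12)

    @given(flux=st.floats(0, 100), pq=st.floats(0.5, 2.0))
    @settings(max_examples=50, deadline=None)
    def test_round_trip_is_identity(self, flux, pq):
        back = cv.carbon_to_oxygen(cv.oxygen_to_carbon(flux, pq), pq)
        assert back == pytest.approx(flux, rel=1e-12, abs=1e-12)

    def test_invalid_pq(self):
        with pytest.raises(ValueError):
            cv.oxygen_to_carbon(10.0, 0.0)

    @pytest.mark.parametrize("mg,umol", [(11.76, 367.5), (5.61, 175.3),
                                         (32.0, 1000.0)])
    def test_mass_to_molar_rate(self, mg, umol):
        assert cv.o2_rate_mass_to_molar(mg) == pytest.approx(umol, abs=0.05)


class TestCarbonBudget:
    def test_study_scale_budget(self):
        b = cv.carbon_budget(8.3, 140.0)
        assert b.growth_rate == pytest.approx(0.058, abs=5e-4)
        assert round(b.daily_turnover) == 6
        assert b.annual_fixation == pytest.approx(3029.5, rel=1e-12)

    def test_zero_production(self):
        b = cv.carbon_budget(0.0, 140.0)
        assert b.growth_rate == 0.0 and b.daily_turnover == 0.0
        assert math.isinf(b.doubling_time)

    @given(p=st.floats(0.01, 50), b=st.floats(1.0, 500))
    @settings(max_examples=50, deadline=None)
    def test_log_growth_below_simple_ratio(self, p, b):
        # ln(1+x) < x: exponential rate is always below the turnover fraction
        budget = cv.carbon_budget(p, b)
        assert budget.growth_rate < budget.daily_turnover / 100.0

    def test_nonpositive_stock_rejected(self):
        with pytest.raises(ValueError):
            cv.carbon_budget(1.0, 0.0)


class TestQuantumYield:
    @pytest.mark.parametrize("f0,fmax,qy", [
        (900.0, 900.0, 0.0),
        (0.0, 900.0, 1.0),
        (600.0, 900.0, 1.0 / 3.0),
    ])
    def test_yield_values(self, f0, fmax, qy):
        assert cv.quantum_yield(cv.PamTransient(f0=f0, fmax=fmax)) == \
            pytest.approx(qy, rel=1e-12)

    def test_healthy_bloom_band(self):
        """The illustrative transient sits in a typical field mean band."""
        qy = cv.quantum_yield(cv.PamTransient(f0=600.0, fmax=900.0))
        assert 0.332 - 0.036 <= qy <= 0.332 + 0.036

    def test_invalid_transients(self):
        with pytest.raises(ValueError):
            cv.PamTransient(f0=10.0, fmax=0.0)
        with pytest.raises(ValueError):
            cv.PamTransient(f0=950.0, fmax=900.0)
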