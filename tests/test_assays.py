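import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from eprstab.assays import (
    CalibrationCurve,
    CalibrationRangeWarning,
    absorbance_from_pv,
    absorbance_from_rsa,
    absorbance_from_tpc,
    linear_calibration,
    oil_yield,
    pbn_final_concentration,
    peroxide_value,
    rsa_dpph,
    total_phenolics,
)


@pytest.fixture()
def fe_curve():
    # slope typical of Fe(III)-thiocyanate at 507 nm over the published range
    return CalibrationCurve(slope=2400.0, intercept=0.01, r_squared=0.99,
                            x_unit="M", range=(6.1e-5, 4.6e-4))


@pytest.fixture()
def ca_curve():
    return CalibrationCurve(slope=2.0, intercept=0.02, r_squared=0.99,
                            x_unit="mg/mL", range=(0.05, 0.4))


@pytest.fixture()
def trolox_curve():
    # x = umol trolox in assay, y = inhibition fraction
    return CalibrationCurve(slope=0.5, intercept=0.0, r_squared=1.0,
                            x_unit="umol", y_unit="inhibition", range=(0.0, 2.0))


class TestLinearCalibration:
    def test_exact_line(self):
        standards = [(x, 2.0 * x) for x in (0.05, 0.1, 0.2, 0.4)]
        curve = linear_calibration(standards)
        assert curve.slope == pytest.approx(2.0)
        assert curve.intercept == pytest.approx(0.0, abs=1e-12)
        assert curve.r_squared == pytest.approx(1.0)

    def test_noisy_standards_slope_within_3pct(self, rng):
        x = np.linspace(0.05, 0.4, 8)
        y = 2.0 * x * (1 + rng.normal(0, 0.01, x.size))
        curve = linear_calibration(list(zip(x, y)))
        assert curve.slope == pytest.approx(2.0, rel=0.03)

    def test_constant_absorbance_degenerate(self):
        with pytest.warns(UserWarning):
            curve = linear_calibration([(0.1, 0.5), (0.2, 0.5), (0.3, 0.5)])
        assert curve.r_squared == 0.0

    def test_too_few_standards(self):
        with pytest.raises(ValueError):
            linear_calibration([(0.1, 0.2), (0.2, 0.4)])

    def test_range_recorded(self):
        curve = linear_calibration([(x, x) for x in (0.05, 0.2, 0.4)])
        assert curve.range == (0.05, 0.4)


class TestPeroxideValue:
    def test_blank_equals_sample(self, fe_curve):
        assert peroxide_value(0.5, 0.5, fe_curve, oil_mass=0.01) == 0.0

    def test_round_trip(self, fe_curve):
        pv = 100.0
        absorbance = absorbance_from_pv(pv, fe_curve, oil_mass=0.01, abs_blank=0.05)
        back = peroxide_value(absorbance, 0.05, fe_curve, oil_mass=0.01)
        assert back == pytest.approx(pv, rel=1e-6)

    def test_doubling_mass_halves_pv(self, fe_curve):
        a = absorbance_from_pv(100.0, fe_curve, oil_mass=0.01)
        pv1 = peroxide_value(a, 0.0, fe_curve, oil_mass=0.01)
        pv2 = peroxide_value(a, 0.0, fe_curve, oil_mass=0.02)
        assert pv2 == pytest.approx(pv1 / 2.0, rel=1e-9)

    def test_out_of_range_warns(self, fe_curve):
        with pytest.warns(CalibrationRangeWarning):
            peroxide_value(5.0, 0.0, fe_curve, oil_mass=0.01)

    def test_nonpositive_mass_raises(self, fe_curve):
        with pytest.raises(ValueError):
            peroxide_value(0.5, 0.1, fe_curve, oil_mass=0.0)


class TestTotalPhenolics:
    def test_round_trip(self, ca_curve):
        tpc = 8.87
        absorbance = absorbance_from_tpc(tpc, ca_curve)
        assert total_phenolics(absorbance, ca_curve) == pytest.approx(tpc, rel=1e-6)

    def test_zero_absorbance(self):
        curve = CalibrationCurve(slope=2.0, intercept=0.0, r_squared=1.0, range=(0.0, 1.0))
        assert total_phenolics(0.0, curve) == 0.0

    def test_volume_scaling_consistency(self, ca_curve):
        """Doubling extract volume doubles the result at fixed reading."""
        a = absorbance_from_tpc(10.0, ca_curve)
        base = total_phenolics(a, ca_curve, extract_volume_ml=5.0)
        doubled = total_phenolics(a, ca_curve, extract_volume_ml=10.0)
        assert doubled == pytest.approx(2.0 * base, rel=1e-9)

    def test_nonpositive_volume_raises(self, ca_curve):
        with pytest.raises(ValueError):
            total_phenolics(0.5, ca_curve, aliquot_volume_ml=0.0)


class TestRsaDpph:
    def test_no_quenching_is_zero(self, trolox_curve):
        assert rsa_dpph(1.0, 1.0, trolox_curve, oil_mass=0.01) == 0.0

    def test_round_trip(self, trolox_curve):
        rsa = 25.0
        absorbance = absorbance_from_rsa(rsa, 1.0, trolox_curve, oil_mass=0.01)
        assert rsa_dpph(1.0, absorbance, trolox_curve, oil_mass=0.01) == pytest.approx(
            rsa, rel=1e-6
        )

    def test_monotone_decreasing_in_sample_absorbance(self, trolox_curve):
        values = [
            rsa_dpph(1.0, a, trolox_curve, oil_mass=0.01) for a in (0.2, 0.5, 0.8)
        ]
        assert values[0] > values[1] > values[2]

    def test_sample_above_control_clipped(self, trolox_curve):
        with pytest.warns(UserWarning):
            assert rsa_dpph(1.0, 1.2, trolox_curve, oil_mass=0.01) == 0.0

    def test_zero_control_raises(self, trolox_curve):
        with pytest.raises(ValueError):
            rsa_dpph(0.0, 0.1, trolox_curve, oil_mass=0.01)


class TestPbnFinalConcentration:
    def test_published_amounts_give_125_mm(self):
        assert pbn_final_concentration(5.0, 2.5, 100.0) == pytest.approx(125.0)

    def test_zero_stock_volume(self):
        assert pbn_final_concentration(0.0, 2.5, 100.0) == 0.0

    def test_doubling_oil_volume_halves(self):
        full = pbn_final_concentration(5.0, 2.5, 100.0)
        assert pbn_final_concentration(5.0, 2.5, 200.0) == pytest.approx(full / 2.0)

    def test_nonpositive_oil_volume_raises(self):
        with pytest.raises(ValueError):
            pbn_final_concentration(5.0, 2.5, 0.0)


class TestOilYield:
    def test_hx_yield(self):
        assert oil_yield(9.37, 100.0) == pytest.approx(9.37)

    def test_zero_oil(self):
        assert oil_yield(0.0, 30.0) == 0.0

    def test_full_recovery(self):
        assert oil_yield(30.0, 30.0) == 100.0

    def test_oil_exceeding_seed_raises(self):
        with pytest.raises(ValueError):
            oil_yield(31.0, 30.0)


class TestForwardInverseProperty:
    """Every assay composes forward model + inverse to the identity (1e-6)."""

    @settings(max_examples=50, deadline=None)
    @given(
        pv=st.floats(1.0, 500.0),
        mass=st.floats(0.005, 0.05),
        slope=st.floats(500.0, 5000.0),
    )
    def test_pv_round_trip(self, pv, mass, slope):
        curve = CalibrationCurve(slope=slope, intercept=0.0, r_squared=1.0,
                                 range=(0.0, np.inf))
        a = absorbance_from_pv(pv, curve, oil_mass=mass)
        assert peroxide_value(a, 0.0, curve, oil_mass=mass) == pytest.approx(pv, rel=1e-6)

    @settings(max_examples=50, deadline=None)
    @given(tpc=st.floats(0.01, 20.0), mass=st.floats(0.5, 5.0), slope=st.floats(0.5, 5.0))
    def test_tpc_round_trip(self, tpc, mass, slope):
        curve = CalibrationCurve(slope=slope, intercept=0.0, r_squared=1.0,
                                 range=(0.0, np.inf))
        a = absorbance_from_tpc(tpc, curve, oil_mass=mass)
        assert total_phenolics(a, curve, oil_mass=mass) == pytest.approx(tpc, rel=1e-6)

    @settings(max_examples=50, deadline=None)
    @given(rsa=st.floats(0.1, 50.0), mass=st.floats(0.005, 0.02))
    def test_rsa_round_trip(self, rsa, mass):
        curve = CalibrationCurve(slope=0.8 / (50.0 * 0.02), intercept=0.0, r_squared=1.0,
                                 range=(0.0, np.inf))
        a = absorbance_from_rsa(rsa, 1.0, curve, oil_mass=mass)
        assert rsa_dpph(1.0, a, curve, oil_mass=mass) == pytest.approx(rsa, rel=1e-6)
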