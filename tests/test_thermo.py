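"""Voltage-to-temperature transform, apparent rates, linear diagrams,
ambient extrapolation and instrument-constant calibration."""

import numpy as np
import pytest

import itemfive as i5
from itemfive.reference_data import (
    AMBIENT_TEMPERATURE,
    CALIBRATION_REFERENCE,
    REFERENCE_THERMO,
)

R = 8.314462618
KB = 1.380649e-23
H = 6.62607015e-34


def make_cond(**kw):
    defaults = dict(charge=5, ion_mass=9238.73, gas="argon", T_amb=295.0)
    defaults.update(kw)
    return i5.CollisionConditions(**defaults)


class TestTemperatureTransform:
    def test_zero_voltage_is_ambient(self):
        cond = make_cond()
        assert i5.dcv_to_temperature(0.0, cond) == 295.0

    def test_affine_in_voltage(self):
        cond = make_cond()
        t1 = i5.dcv_to_temperature(10.0, cond) - cond.T_amb
        t2 = i5.dcv_to_temperature(20.0, cond) - cond.T_amb
        assert t2 == pytest.approx(2 * t1, rel=1e-12)

    def test_center_of_mass_arithmetic_oracle(self):
        # hand-evaluated: 5 e * 13.5 V * 39.948/(39.948+9238.73)
        # / (1.5 k_B) + 295 K, computed outside the library
        cond = make_cond(dof_factor=1.5)
        assert i5.dcv_to_temperature(13.5, cond) == pytest.approx(
            2543.2705021540487, rel=1e-12)

    def test_negative_voltage_rejected(self):
        with pytest.raises(ValueError):
            i5.dcv_to_temperature(-1.0, make_cond())


class TestRateAndFreeEnergy:
    def test_rate_closed_forms(self):
        assert i5.rate_from_survival(1.0) == 0.0
        assert i5.rate_from_survival(1.0 / np.e) == pytest.approx(1.0)
        assert i5.rate_from_survival(0.5) == pytest.approx(np.log(2))

    def test_rate_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            i5.rate_from_survival(0.0)

    def test_barrierless_identity(self):
        cond = make_cond()
        T = 300.0
        k = KB * T / H
        assert i5.free_energy_from_rate(k, T, cond) == pytest.approx(0.0,
                                                                     abs=1e-9)

    def test_log_linearity_factor_e(self):
        cond = make_cond()
        T = 300.0
        g1 = i5.free_energy_from_rate(1.0, T, cond)
        g2 = i5.free_energy_from_rate(1.0 / np.e, T, cond)
        assert g2 - g1 == pytest.approx(R * T / 1e3, rel=1e-9)

    def test_algebraic_round_trip(self):
        cond = make_cond()
        T, k = 412.0, 3.7e5
        dg = i5.free_energy_from_rate(k, T, cond)
        k_back = (KB * T / H) * np.exp(-dg * 1e3 / (R * T))
        assert k_back == pytest.approx(k, rel=1e-9)


class TestLinearFits:
    def test_arrhenius_two_exact_points(self):
        T = np.array([300.0, 400.0])
        k = np.exp(20.0 - 60e3 / (R * T))
        arr = i5.fit_arrhenius(T, k)
        assert arr.ln_a == pytest.approx(20.0, abs=1e-9)
        assert arr.e_a == pytest.approx(60.0, abs=1e-9)
        assert arr.r_squared == pytest.approx(1.0)

    def test_arrhenius_many_noiseless_points(self):
        T = np.linspace(310, 500, 9)
        k = np.exp(20.0 - 60e3 / (R * T))
        arr = i5.fit_arrhenius(T, k)
        assert arr.e_a == pytest.approx(60.0, abs=1e-9)

    def test_arrhenius_singular_design(self):
        with pytest.raises(ValueError):
            i5.fit_arrhenius([300.0, 300.0], [1.0, 2.0])

    def test_ellingham_exact_line(self):
        T = np.linspace(300, 500, 7)
        dG = 60.0 - 0.04 * T
        ell = i5.fit_ellingham(T, dG)
        assert ell.dh == pytest.approx(60.0, abs=1e-9)
        assert ell.ds == pytest.approx(0.04, abs=1e-12)

    def test_ellingham_temperature_shift_keeps_entropy(self):
        T = np.linspace(300, 500, 7)
        dG = 60.0 - 0.04 * T
        base = i5.fit_ellingham(T, dG)
        shifted = i5.fit_ellingham(T + 10.0, dG)
        assert shifted.ds == pytest.approx(base.ds, abs=1e-12)
        assert shifted.dg(310.0) == pytest.approx(dG[0], abs=1e-9)


class TestAmbientExtrapolation:
    def test_printed_reference_triples_satisfy_identity(self):
        """dG# = dH# - T_amb dS# to 0.05 kJ/mol for every published row."""
        for name, (_, _, dg, dh, tds) in REFERENCE_THERMO.items():
            assert dg == pytest.approx(dh - tds, abs=0.05), name

    def test_identity_by_construction(self):
        arr = i5.ArrheniusFit(ln_a=20.0, e_a=60.0, r_squared=1.0)
        ell = i5.EllinghamFit(dh=63.9, ds=40.0 / 295.0, r_squared=1.0)
        res = i5.extrapolate_ambient(arr, ell, make_cond())
        assert res.dg_m0g == pytest.approx(res.dh_m0g - res.tds_m0g, abs=1e-12)
        assert res.dg_m0g == pytest.approx(23.9, abs=1e-9)
        assert res.kd_m0g == pytest.approx(
            np.exp(-23.9e3 / (R * 295.0)), rel=1e-9)

    def test_kd_order_of_magnitude_at_reference_free_energy(self):
        # dG# = 23.9 kJ/mol at 295 K -> KD ~ 5.9e-5
        kd = np.exp(-23.9e3 / (R * 295.0))
        assert kd == pytest.approx(5.81e-5, rel=0.15)


class TestPipelineAndCalibration:
    def test_noiseless_pipeline_diagrams_are_linear(self, noiseless_fit):
        cond = make_cond(ion_mass=3 * 3079.57672)
        analysis = i5.analyze_boltzmann_fit(noiseless_fit, cond)
        assert analysis.arrhenius.r_squared >= 0.99
        assert analysis.ellingham.r_squared >= 0.999

    def test_calibration_reproduces_reference_row(self, noiseless_fit):
        _, ref_dh, ref_tds = CALIBRATION_REFERENCE
        cond = make_cond(ion_mass=3 * 3079.57672, T_amb=AMBIENT_TEMPERATURE)
        calibrated = i5.calibrate_conditions(noiseless_fit, cond,
                                             ref_dh, ref_tds)
        res = i5.analyze_boltzmann_fit(noiseless_fit, calibrated).result
        assert res.dh_m0g == pytest.approx(ref_dh, abs=1e-6)
        assert res.tds_m0g == pytest.approx(ref_tds, abs=1e-6)
        assert res.dg_m0g == pytest.approx(ref_dh - ref_tds, abs=1e-6)
        # the two extrapolation routes stay Eyring-consistent to ~order one
        k_eyring = (KB * 295.0 / H) * np.exp(-res.dg_m0g * 1e3 / (R * 295.0))
        assert res.k_m0g == pytest.approx(k_eyring, rel=0.5)

    def test_calibrated_constants_rank_variants(self, noiseless_fit):
        """A variant with a lower midpoint yields a smaller barrier."""
        _, ref_dh, ref_tds = CALIBRATION_REFERENCE
        cond = make_cond(ion_mass=3 * 3079.57672, T_amb=AMBIENT_TEMPERATURE)
        calibrated = i5.calibrate_conditions(noiseless_fit, cond, ref_dh,
                                             ref_tds)
        weak_fit = i5.BoltzmannFit(a1=noiseless_fit.a1, a2=noiseless_fit.a2,
                                   x0=11.0, dx=noiseless_fit.dx,
                                   r_squared=1.0)
        from dataclasses import replace
        weak_cond = replace(calibrated, ion_mass=3 * 3124.64983)
        weak = i5.analyze_boltzmann_fit(weak_fit, weak_cond).result
        strong = i5.analyze_boltzmann_fit(noiseless_fit, calibrated).result
        assert weak.dh_m0g < strong.dh_m0g
        assert weak.dg_m0g < strong.dg_m0g
        assert weak.k_m0g > strong.k_m0g
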