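"""LSSE radiation field: limiting angles, local and volume-averaged LVRPA."""

import math

import numpy as np
import pytest

from photofenton import radiation as rad
from photofenton.chem import M_FE


def mg_L_to_M(c):
    return c / (1000.0 * M_FE)


class TestGeometry:
    def test_annular_volume_matches_nominal(self):
        geo = rad.default_geometry()
        assert geo.annular_volume_L == pytest.approx(1.5, rel=5e-3)
        assert geo.v_ratio == pytest.approx(0.10)

    def test_invalid_geometries_rejected(self):
        with pytest.raises(ValueError):
            rad.ReactorGeometry(r_int=7.0, r_ext=3.5)
        with pytest.raises(ValueError):
            rad.ReactorGeometry(v_irr=2.5)  # inconsistent with the radii

    def test_centered_offset(self):
        geo = rad.default_geometry()
        assert geo.offset == pytest.approx((58.98 - 13.0) / 2)


class TestLimitingAngles:
    def test_midpoint_symmetry(self):
        t1, t2 = rad.limiting_angles(5.0, 29.49, 58.98)
        assert t1 == pytest.approx(math.atan(5 / 29.49))
        assert t1 == pytest.approx(0.1679, rel=1e-3)
        assert t2 == pytest.approx(-t1)

    def test_boundary_limits(self):
        assert rad.limiting_angles(5.0, 0.0, 58.98)[1] == pytest.approx(-math.pi / 2)
        assert rad.limiting_angles(5.0, 58.98, 58.98)[0] == pytest.approx(math.pi / 2)

    def test_nonpositive_radius_rejected(self):
        with pytest.raises(ValueError):
            rad.limiting_angles(0.0, 10.0, 58.98)


class TestSpectrumAndAbsorptivity:
    def test_synthetic_spectrum_normalization(self, spectrum):
        assert spectrum.total_photon_power == pytest.approx(3.36e-4, rel=1e-3)
        assert spectrum.wavelengths[0] == 300.0 and spectrum.wavelengths[-1] == 420.0

    def test_csv_round_trip(self, tmp_path, spectrum, absorptivity):
        sp = tmp_path / "spectrum.csv"
        ap = tmp_path / "alpha.csv"
        spectrum.to_csv(str(sp))
        absorptivity.to_csv(str(ap))
        s2 = rad.LampSpectrum.from_csv(str(sp))
        a2 = rad.AbsorptivityTable.from_csv(str(ap))
        np.testing.assert_allclose(s2.spectral_photon_power, spectrum.spectral_photon_power)
        np.testing.assert_allclose(a2.molar_absorptivity, absorptivity.molar_absorptivity)

    def test_out_of_range_wavelength_rejected(self, absorptivity):
        with pytest.raises(ValueError):
            absorptivity.absorptivity_at(250.0)


class TestAbsorptionCoefficient:
    def test_zero_iron_zero_kappa(self, absorptivity):
        for lam in (300.0, 360.0, 420.0):
            assert rad.total_absorption_coeff(0.0, lam, absorptivity) == 0.0

    def test_linear_in_iron(self, absorptivity):
        c = mg_L_to_M(5.0)
        k1 = rad.total_absorption_coeff(c, 340.0, absorptivity)
        k2 = rad.total_absorption_coeff(2 * c, 340.0, absorptivity)
        assert k2 == pytest.approx(2 * k1, rel=1e-12)

    def test_grid_node_is_exact_lookup(self, absorptivity):
        lam = float(absorptivity.wavelengths[3])
        alpha = float(absorptivity.molar_absorptivity[3])
        c = mg_L_to_M(7.5)
        assert rad.total_absorption_coeff(c, lam, absorptivity) == pytest.approx(
            alpha * c, rel=1e-14
        )


class TestLocalLvrpa:
    def test_no_absorber_no_absorption(self, geometry, spectrum):
        assert rad.lvrpa_local(5.0, 6.5, 360.0, 0.0, 0.0, geometry, spectrum) == 0.0

    def test_optically_thin_closed_form(self, geometry, spectrum):
        r, z, lam, kappa = 5.0, 6.5, 360.0, 1e-3
        got = rad.lvrpa_local(r, z, lam, kappa, 0.0, geometry, spectrum)
        t1, t2 = rad.limiting_angles(r, z + geometry.offset, geometry.lamp_length)
        p_s = spectrum.spectral_power_at(lam) / 60.0
        expected = kappa * p_s * (t1 - t2) / (2 * math.pi * geometry.lamp_length)
        assert got == pytest.approx(expected, rel=1e-12)

    def test_agrees_with_midpoint_rule_brute_force(self, geometry, spectrum):
        r, z, lam = 5.5, 3.0, 330.0
        kappa = kappa_T = 0.15  # strongly attenuating medium
        got = rad.lvrpa_local(r, z, lam, kappa, kappa_T, geometry, spectrum)
        t1, t2 = rad.limiting_angles(r, z + geometry.offset, geometry.lamp_length)
        theta = np.linspace(t2, t1, 2_000_001)[:-1] + (t1 - t2) / 2_000_001 / 2
        integral = np.mean(np.exp(-kappa_T * (r - geometry.r_int) / np.cos(theta))) * (
            t1 - t2
        )
        p_s = spectrum.spectral_power_at(lam) / 60.0
        expected = kappa * p_s * integral / (2 * math.pi * geometry.lamp_length)
        assert got == pytest.approx(expected, rel=1e-6)

    def test_outside_annulus_rejected(self, geometry, spectrum):
        with pytest.raises(ValueError):
            rad.lvrpa_local(2.0, 6.5, 360.0, 0.1, 0.1, geometry, spectrum)


class TestVolumeAverage:
    def test_zero_iron_gives_zero(self, geometry, spectrum, absorptivity):
        assert rad.lvrpa_volume_average(0.0, geometry, spectrum, absorptivity) == 0.0

    def test_monotone_and_concave_over_catalyst_range(self, lvrpa_table):
        idx = [list(lvrpa_table.fe3_grid).index(c) for c in (2.5, 5.0, 7.5, 10.0)]
        vals = lvrpa_table.lvrpa[idx]
        assert np.all(np.diff(vals) > 0)
        slopes = np.diff(vals) / np.diff(lvrpa_table.fe3_grid[idx])
        assert np.all(np.diff(slopes) < 0)

    def test_optically_thin_closed_form(self, geometry, spectrum, absorptivity):
        # kappa_T * (r_ext - r_int) < 1e-3 at every wavelength
        c = 1e-7  # mol/L
        got = rad.lvrpa_volume_average(c, geometry, spectrum, absorptivity)
        lam = spectrum.wavelengths
        w = np.empty_like(lam)
        w[0] = (lam[1] - lam[0]) / 2
        w[-1] = (lam[-1] - lam[-2]) / 2
        w[1:-1] = (lam[2:] - lam[:-2]) / 2
        kappa = np.interp(lam, absorptivity.wavelengths, absorptivity.molar_absorptivity) * c
        p_s = spectrum.spectral_photon_power / 60.0
        spectral_sum = float(np.sum(kappa * p_s * w))
        # closed form: exponential -> 1, theta integral -> angle span
        r = np.linspace(geometry.r_int, geometry.r_ext, 2001)
        z = np.linspace(0.0, geometry.h_irr, 1001) + geometry.offset
        t1 = np.arctan(r[:, None] / (geometry.lamp_length - z)[None, :])
        t2 = np.arctan(-r[:, None] / z[None, :])
        inner = np.trapezoid(
            np.trapezoid((t1 - t2) * r[:, None], z - geometry.offset, axis=1), r
        )
        expected = (
            spectral_sum
            / (2 * math.pi * geometry.lamp_length)
            * 2
            * math.pi
            / (geometry.v_irr * 1000.0)
            * inner
        )
        assert got == pytest.approx(expected, rel=1e-4)

    def test_energy_bound(self, geometry, spectrum, absorptivity):
        # even at heavy iron loading the absorbed power cannot exceed emission
        val = rad.lvrpa_volume_average(mg_L_to_M(50.0), geometry, spectrum, absorptivity)
        absorbed = val * geometry.v_irr * 1000.0  # Einstein/s
        assert absorbed <= spectrum.total_photon_power / 60.0

    def test_quadrature_halving_stable(self, geometry, spectrum, absorptivity):
        from photofenton.radiation import _volume_average_fixed

        c = mg_L_to_M(10.0)
        coarse = _volume_average_fixed(c, geometry, spectrum, absorptivity, 16, 16, 32)
        fine = _volume_average_fixed(c, geometry, spectrum, absorptivity, 32, 32, 64)
        assert abs(fine - coarse) / fine < 0.005


class TestLvrpaTable:
    def test_trivial_table(self):
        t = rad.build_lvrpa_table(
            [0.0], rad.default_geometry(), rad.synthetic_spectrum(), rad.synthetic_absorptivity()
        )
        assert t.lvrpa[0] == 0.0 and t(0.0) == 0.0

    def test_nodes_reproduced_exactly(self, lvrpa_table):
        for c, v in zip(lvrpa_table.fe3_grid, lvrpa_table.lvrpa):
            assert lvrpa_table(float(c)) == pytest.approx(float(v), rel=1e-14)

    def test_self_shielding_efficiency_decreases(self, lvrpa_table):
        grid, vals = lvrpa_table.fe3_grid, lvrpa_table.lvrpa
        eff = vals[1:] / grid[1:]  # per-mg efficiency
        assert np.all(np.diff(eff) < 0)

    def test_unit_conversion_to_per_liter(self, lvrpa_table):
        assert lvrpa_table.in_einstein_per_L_s(5.0) == pytest.approx(
            1000.0 * lvrpa_table(5.0)
        )

    def test_extrapolation_clamps_to_end_slope(self, lvrpa_table):
        g = lvrpa_table.fe3_grid
        end, beyond = float(g[-1]), float(g[-1]) + 2.0
        slope = (lvrpa_table(beyond) - lvrpa_table(end)) / 2.0
        further = lvrpa_table(beyond + 1.0)
        assert further == pytest.approx(lvrpa_table(beyond) + slope, rel=1e-9)

    def test_invalid_tables_rejected(self):
        with pytest.raises(ValueError):
            rad.LvrpaTable(np.array([0.0, 5.0]), np.array([1e-10, 1e-10]))  # not increasing
        with pytest.raises(ValueError):
            rad.LvrpaTable(np.array([0.0, 5.0]), np.array([1e-12, 2e-10]))  # nonzero at 0

    def test_csv_round_trip(self, tmp_path, lvrpa_table):
        p = tmp_path / "lvrpa.csv"
        lvrpa_table.to_csv(str(p))
        t2 = rad.LvrpaTable.from_csv(str(p))
        np.testing.assert_allclose(t2.lvrpa, lvrpa_table.lvrpa)
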