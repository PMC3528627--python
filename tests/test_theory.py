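"""Closed-form equilibria, the 1D coordinate transform, transients, and FRAP
half-time predictions."""

import numpy as np
import pytest
from scipy import integrate

from nhdsim import (GaussianWellSpec, coordinate_transform, equilibrium_density,
                    equilibrium_flux, frap_half_time_prediction,
                    make_constant_profile, make_gaussian_profile,
                    overconcentration_ratio, transient_density_1d)
from nhdsim.profiles import DiffusionProfile, InvalidParameterError


def _trapz_periodic(y, x, L):
    return integrate.trapezoid(y, x)


class TestEquilibriumDensity:
    def test_constant_profile_is_uniform(self, flat_profile_1d):
        eq = equilibrium_density(flat_profile_1d)
        assert np.allclose(eq.rho, 0.5)  # (2L)^-1 with L=1

    @pytest.mark.parametrize("formalism", ["stratonovich", "ito"])
    def test_normalization(self, well_profile_1d, formalism):
        eq = equilibrium_density(well_profile_1d, formalism)
        assert integrate.trapezoid(eq.rho, eq.grid) == pytest.approx(1.0, abs=1e-6)

    def test_peak_to_edge_ratio_against_independent_quadrature(self, well_profile_1d):
        # oracle: adaptive quadrature of the normalization constant plus
        # pointwise division, entirely outside equilibrium_density
        amp = lambda x: float(well_profile_1d.amplitude(np.array([x]))[0])
        I, _ = integrate.quad(lambda x: 1.0 / amp(x), -1, 1, limit=400)
        expect = (1.0 / amp(0.0)) / (1.0 / amp(1.0))
        eq = equilibrium_density(well_profile_1d, n_grid=4096)
        rho0 = eq.interpolate(np.array([0.0]))[0]
        rhoL = eq.interpolate(np.array([-1.0]))[0]
        assert rho0 / rhoL == pytest.approx(expect, rel=1e-5)
        assert eq.Omega == pytest.approx(1.0 / I, rel=1e-8)

    def test_2d_density_peaks_where_amplitude_dips(self):
        spec = GaussianWellSpec(centers=((0.25, -0.4), (-0.55, 0.3),
                                         (0.7, 0.75), (-0.2, -0.85)))
        prof = make_gaussian_profile(spec, L=1.0)
        eq = equilibrium_density(prof, n_grid=256)
        ax = eq.grid[0]
        X, Y = np.meshgrid(ax, ax, indexing="ij")
        amp = prof.amplitude(np.stack([X, Y], axis=-1))
        assert np.unravel_index(np.argmax(eq.rho), eq.rho.shape) == \
            np.unravel_index(np.argmin(amp), amp.shape)
        # cross-section comparison: along any fixed x the density maximum
        # colocates with the amplitude minimum
        i = np.searchsorted(ax, 0.25)
        assert np.argmax(eq.rho[i]) == np.argmin(amp[i])

    def test_flux_diagnostic_vanishes_on_equilibrium(self, well_profile_1d):
        eq = equilibrium_density(well_profile_1d)
        assert np.max(np.abs(equilibrium_flux(well_profile_1d, eq))) < 1e-8

    def test_formalisms_coincide_iff_profile_constant(self, well_profile_1d,
                                                      flat_profile_1d):
        for prof, same in [(flat_profile_1d, True), (well_profile_1d, False)]:
            s = equilibrium_density(prof, "stratonovich")
            i = equilibrium_density(prof, "ito")
            close = np.allclose(s.rho, i.rho, rtol=1e-8)
            assert close is same

    def test_resolution_error_on_coarse_grid(self):
        # an extremely narrow well cannot converge on a 64-point grid
        prof = make_gaussian_profile(GaussianWellSpec(omega=1e-8), L=1.0)
        from nhdsim.theory import ResolutionError
        with pytest.raises(ResolutionError):
            equilibrium_density(prof, n_grid=64)


class TestOverconcentration:
    def test_square_root_law(self):
        assert overconcentration_ratio(0.1, 1.0) == pytest.approx(np.sqrt(10), rel=1e-12)
        assert overconcentration_ratio(1.0, 1.0) == 1.0

    def test_ito_is_plain_ratio(self):
        assert overconcentration_ratio(0.1, 1.0, "ito") == pytest.approx(10.0)

    def test_rejects_nonpositive(self):
        with pytest.raises(InvalidParameterError):
            overconcentration_ratio(0.0, 1.0)


class TestCoordinateTransform:
    def test_constant_profile_is_linear(self):
        prof = make_constant_profile(2.0, L=1.0, dim=1)
        ct = coordinate_transform(prof)
        x = np.linspace(-1, 1, 33)
        assert np.allclose(ct.forward(x), (x + 1) / 2.0, atol=1e-10)

    def test_total_length_matches_quadrature(self, well_profile_1d):
        ct = coordinate_transform(well_profile_1d)
        amp = lambda x: float(well_profile_1d.amplitude(np.array([x]))[0])
        I, _ = integrate.quad(lambda x: 1.0 / amp(x), -1, 1, limit=400)
        assert ct.circumference == pytest.approx(I, rel=1e-8)

    def test_round_trip_identity(self, well_profile_1d, rng):
        ct = coordinate_transform(well_profile_1d)
        x = rng.uniform(-1, 1, 1000)
        assert np.max(np.abs(ct.inverse(ct.forward(x)) - x)) < 1e-8

    def test_strictly_increasing(self, well_profile_1d):
        ct = coordinate_transform(well_profile_1d)
        x = np.linspace(-1, 1, 500)
        assert np.all(np.diff(ct.forward(x)) > 0)
        assert ct.forward(-1.0) == pytest.approx(0.0, abs=1e-12)


class TestTransient1D:
    def test_homogeneous_dirac_is_wrapped_gaussian(self):
        prof = make_constant_profile(1.0, L=1.0, dim=1)
        t = 0.05
        x, rho = transient_density_1d(prof, ("dirac", 0.0), t)
        # classical result: variance D0 * t, wrapped on circumference 2L
        direct = np.zeros_like(x)
        for mimg in range(-8, 9):
            direct += np.exp(-((x + 2 * mimg) ** 2) / (2 * t)) / np.sqrt(2 * np.pi * t)
        assert np.max(np.abs(rho - direct)) < 1e-9

    def test_long_time_limit_reaches_equilibrium(self, well_profile_1d):
        eq = equilibrium_density(well_profile_1d)
        x, rho = transient_density_1d(well_profile_1d, ("dirac", 0.5), 12.0)
        assert np.max(np.abs(rho - eq.interpolate(x))) < 1e-3
        # near t=5 the distribution is already visually indistinguishable
        x5, rho5 = transient_density_1d(well_profile_1d, ("dirac", 0.5), 5.0)
        assert np.max(np.abs(rho5 - eq.interpolate(x5))) < 0.05

    def test_slow_zone_transiently_underpopulated(self, well_profile_1d):
        eq = equilibrium_density(well_profile_1d)
        rho_eq0 = eq.interpolate(np.array([0.0]))[0]
        x, rho = transient_density_1d(well_profile_1d, ("dirac", 0.5), 1.0)
        rho0 = np.interp(0.0, x, rho)
        assert rho0 < rho_eq0

    @pytest.mark.parametrize("t", [0.05, 0.5, 2.0, 8.0])
    def test_mass_conserved(self, well_profile_1d, t):
        # grid chosen fine enough to resolve the narrowest kernel tested
        x, rho = transient_density_1d(well_profile_1d, ("dirac", 0.5), t,
                                      n_grid=8192)
        mass = integrate.trapezoid(np.append(rho, rho[0]), np.append(x, 1.0))
        assert mass == pytest.approx(1.0, abs=1e-8)

    def test_smooth_initial_density_and_error_paths(self, well_profile_1d):
        rho0 = lambda x: (1.0 + 0.3 * np.cos(np.pi * x)) / 2.0
        x, rho = transient_density_1d(well_profile_1d, rho0, 0.3)
        mass = integrate.trapezoid(np.append(rho, rho[0]), np.append(x, 1.0))
        assert mass == pytest.approx(1.0, abs=1e-6)
        with pytest.raises(InvalidParameterError):
            transient_density_1d(well_profile_1d, lambda x: np.full_like(x, 2.0), 0.3)


class TestFrapPrediction:
    def test_homogeneous_reduction_to_r_squared(self):
        prof = make_constant_profile(2.0, L=1.0, dim=1)
        for r_b in (0.1, 0.25, 0.4):
            tau = frap_half_time_prediction(prof, r_b).tau
            assert tau == pytest.approx(4 * r_b ** 2 / 4.0, rel=1e-8)  # (2 r_b / D0)^2

    def test_profile_ordering_wide_well_slowest(self, well_profile_1d,
                                                narrow_well_1d, flat_profile_1d):
        for r_b in (0.1, 0.2, 0.3):
            t_wide = frap_half_time_prediction(well_profile_1d, r_b).tau
            t_narrow = frap_half_time_prediction(narrow_well_1d, r_b).tau
            t_flat = frap_half_time_prediction(flat_profile_1d, r_b).tau
            assert t_wide > t_narrow > t_flat

    def test_two_step_piecewise_profile_hand_integral(self):
        # a(x) = 0.5 on [-0.5, 0), 1.0 elsewhere (smoothed steps are
        # irrelevant here: build directly from callables)
        def amp(x):
            x = np.asarray(x, dtype=float)
            return np.where((x >= -0.5) & (x < 0.0), 0.5, 1.0)

        prof = DiffusionProfile(dim=1, L=1.0, amplitude=amp,
                                gradient=lambda x: np.zeros_like(np.asarray(x, float)))
        # int_{-0.3}^{0.3} du/a = 0.3/0.5 + 0.3/1.0 = 0.9  ->  tau = 0.81
        tau = frap_half_time_prediction(prof, 0.3).tau
        assert tau == pytest.approx(0.81, rel=1e-6)

    def test_monotone_in_radius_and_validation(self, well_profile_1d):
        taus = [frap_half_time_prediction(well_profile_1d, r).tau
                for r in (0.1, 0.2, 0.3, 0.6)]
        assert np.all(np.diff(taus) > 0)
        with pytest.raises(InvalidParameterError):
            frap_half_time_prediction(well_profile_1d, 1.0)
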