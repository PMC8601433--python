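"""Single-particle cross sections: Rayleigh scaling laws, Mie benchmarks,
ensemble linearity."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import spherical_jn, spherical_yn

from pdmsphantom.particle_optics import (
    NotRayleighRegimeError,
    ParticleSpec,
    ensemble_coefficients,
    gaussian_size_bins,
    log_spaced_size_bins,
    mie_cross_section,
    mie_efficiencies,
    number_density,
    polydisperse_coefficients,
    rayleigh_cross_section,
)
from pdmsphantom.spectral_fit import fit_scattering

SMALL_TDP = ParticleSpec(diameter_um=0.02, n_particle=2.87, n_medium=1.41)


def mie_oracle(m: float, x: float):
    """Independent Mie computation via scipy spherical Bessel functions."""
    nmax = int(np.ceil(x + 4 * x ** (1 / 3) + 2))
    n = np.arange(1, nmax + 1)
    mx = m * x
    psi = x * spherical_jn(n, x)
    psi1 = x * spherical_jn(n - 1, x)
    chi = -x * spherical_yn(n, x)
    chi1 = -x * spherical_yn(n - 1, x)
    xi, xi1 = psi - 1j * chi, psi1 - 1j * chi1
    psim = mx * spherical_jn(n, mx)
    psim1 = mx * spherical_jn(n - 1, mx)
    dpsi, dchi = psi1 - n / x * psi, chi1 - n / x * chi
    dxi = dpsi - 1j * dchi
    dpsim = psim1 - n / mx * psim
    a = (m * psim * dpsi - psi * dpsim) / (m * psim * dxi - xi * dpsim)
    b = (psim * dpsi - m * psi * dpsim) / (psim * dxi - m * xi * dpsim)
    qsca = 2 / x**2 * np.sum((2 * n + 1) * (abs(a) ** 2 + abs(b) ** 2))
    qext = 2 / x**2 * np.sum((2 * n + 1) * (a + b).real)
    return float(qext), float(qsca)


class TestRayleigh:
    def test_inverse_fourth_power_in_wavelength(self):
        s1 = rayleigh_cross_section(SMALL_TDP, 400.0).sigma_s
        s2 = rayleigh_cross_section(SMALL_TDP, 800.0).sigma_s
        assert s1 / s2 == pytest.approx(16.0, rel=1e-12)

    def test_sixth_power_in_diameter(self):
        p2 = ParticleSpec(diameter_um=0.04, n_particle=2.87, n_medium=1.41)
        s1 = rayleigh_cross_section(SMALL_TDP, 700.0).sigma_s
        s2 = rayleigh_cross_section(p2, 700.0).sigma_s
        assert s2 / s1 == pytest.approx(64.0, rel=1e-12)

    def test_sigma_lambda4_constant_across_band(self, default_grid):
        lam = default_grid.wavelengths
        prod = np.array(
            [rayleigh_cross_section(SMALL_TDP, l).sigma_s * l**4 for l in lam]
        )
        assert np.ptp(prod) / prod.mean() < 1e-12

    def test_large_particle_rejected(self):
        big = ParticleSpec(diameter_um=1.0, n_particle=2.87, n_medium=1.41)
        with pytest.raises(NotRayleighRegimeError, match="Rayleigh regime"):
            rayleigh_cross_section(big, 700.0)

    def test_rayleigh_ensemble_fits_b_equals_4(self, default_grid):
        spec = ParticleSpec(
            diameter_um=0.02, n_particle=2.87, n_medium=1.41,
            mass_density=4.23, mass_fraction_pct=0.1,
        )
        _, mu_sp, _ = ensemble_coefficients(spec, default_grid.wavelengths, model="rayleigh")
        fit = fit_scattering(default_grid.wavelengths, mu_sp)
        assert fit.b == pytest.approx(4.0, abs=0.02)


class TestMie:
    @pytest.mark.parametrize(
        "m,x",
        [(1.5, 10.0), (1.33, 1.0), (2.0355, 3.0), (1.1206, 6.3), (1.5, 55.0)],
    )
    def test_matches_independent_bessel_oracle(self, m, x):
        qext, qsca, _ = mie_efficiencies(m, x)
        oext, osca = mie_oracle(m, x)
        assert qext == pytest.approx(oext, rel=1e-10)
        assert qsca == pytest.approx(osca, rel=1e-10)

    def test_wiscombe_benchmark_x10_m1p5(self):
        # published nonabsorbing benchmark: m = 1.5, x = 10 -> Qext = 2.8820
        qext, qsca, _ = mie_efficiencies(1.5, 10.0)
        assert qext == pytest.approx(2.8820, abs=1e-4)
        assert qsca == pytest.approx(qext, rel=1e-12)  # real index: no absorption

    def test_rayleigh_limit(self):
        r = rayleigh_cross_section(SMALL_TDP, 700.0)
        m = mie_cross_section(SMALL_TDP, 700.0)
        assert m.sigma_s == pytest.approx(r.sigma_s, rel=0.01)

    def test_fitted_b_decreases_with_diameter(self, default_grid):
        """b falls from ~4 as particles grow toward the wavelength.

        Strict monotonicity holds on the sub-resonance branch (here up to
        0.3 um for the high-index scatterer); beyond it Mie interference
        structure makes b oscillate around small values, so for larger
        particles only the coarse ordering (big-particle b far below
        small-particle b) is asserted. A modest 15% size spread mimics a
        real powder.
        """
        lam = default_grid.wavelengths

        def b_of(d):
            spec = ParticleSpec(
                diameter_um=d, n_particle=2.87, n_medium=1.41,
                mass_density=4.23, mass_fraction_pct=0.01,
            )
            dd, ww = gaussian_size_bins(d, 0.15 * d)
            _, mu_sp, _ = polydisperse_coefficients(spec, lam, dd, ww)
            return fit_scattering(lam, mu_sp).b

        branch = [b_of(d) for d in (0.05, 0.1, 0.15, 0.2, 0.25, 0.3)]
        assert all(b2 <= b1 + 1e-9 for b1, b2 in zip(branch, branch[1:]))
        assert branch[0] == pytest.approx(4.0, abs=0.1)
        large = [b_of(d) for d in (0.6, 1.0, 2.0)]
        assert max(large) < min(branch[:2]) - 2.0

    def test_ps_bead_b_below_sub_wavelength_high_index_particle(self, default_grid):
        lam = default_grid.wavelengths
        ps = ParticleSpec(diameter_um=1.0, n_particle=1.58, n_medium=1.41,
                          mass_density=1.05, mass_fraction_pct=1.0)
        tdp = ParticleSpec(diameter_um=0.1, n_particle=2.87, n_medium=1.41,
                           mass_density=4.23, mass_fraction_pct=0.1)
        _, sp_ps, _ = ensemble_coefficients(ps, lam)
        _, sp_tdp, _ = ensemble_coefficients(tdp, lam)
        assert fit_scattering(lam, sp_ps).b < fit_scattering(lam, sp_tdp).b


class TestEnsemble:
    def test_zero_mass_fraction_gives_zero(self, default_grid):
        spec = ParticleSpec(diameter_um=0.5, n_particle=2.87, mass_density=4.23)
        mu_s, mu_sp, mu_a = ensemble_coefficients(spec, default_grid.wavelengths)
        assert not mu_s.any() and not mu_sp.any() and not mu_a.any()

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(w=st.floats(min_value=1e-4, max_value=1.0))
    def test_linear_in_mass_fraction(self, w):
        lam = np.array([500.0, 700.0, 850.0])
        base = ParticleSpec(diameter_um=0.5, n_particle=2.87, n_medium=1.41,
                            mass_density=4.23, mass_fraction_pct=w)
        double = ParticleSpec(diameter_um=0.5, n_particle=2.87, n_medium=1.41,
                              mass_density=4.23, mass_fraction_pct=2 * w)
        s1, _, _ = ensemble_coefficients(base, lam)
        s2, _, _ = ensemble_coefficients(double, lam)
        np.testing.assert_allclose(s2, 2 * s1, rtol=1e-12)

    def test_rayleigh_ensemble_equals_rho_sigma(self):
        spec = ParticleSpec(diameter_um=0.02, n_particle=2.87, n_medium=1.41,
                            mass_density=4.23, mass_fraction_pct=0.1)
        lam = np.array([600.0])
        mu_s, mu_sp, _ = ensemble_coefficients(spec, lam, model="rayleigh")
        rho = number_density(spec)
        sigma_cm2 = rayleigh_cross_section(spec, 600.0).sigma_s * 1e-8
        assert mu_s[0] == pytest.approx(rho * sigma_cm2, rel=1e-12)
        assert mu_sp[0] == pytest.approx(mu_s[0], rel=1e-12)  # g = 0

    def test_volume_fraction_warning(self):
        heavy = ParticleSpec(diameter_um=0.5, n_particle=1.58, n_medium=1.41,
                             mass_density=1.05, mass_fraction_pct=8.0)
        with pytest.warns(UserWarning, match="independent-scattering"):
            ensemble_coefficients(heavy, np.array([700.0]))

    def test_polydisperse_mixture_is_mass_weighted_sum(self):
        lam = np.array([600.0, 750.0])
        spec = ParticleSpec(diameter_um=0.5, n_particle=2.87, n_medium=1.41,
                            mass_density=4.23, mass_fraction_pct=0.1)
        d, w = log_spaced_size_bins(0.3, 1.0, n=3)
        mix_s, _, _ = polydisperse_coefficients(spec, lam, d, w)
        manual = np.zeros_like(lam)
        for dk, wk in zip(d, w):
            sub = ParticleSpec(diameter_um=dk, n_particle=2.87, n_medium=1.41,
                               mass_density=4.23, mass_fraction_pct=0.1 * wk)
            s, _, _ = ensemble_coefficients(sub, lam)
            manual += s
        np.testing.assert_allclose(mix_s, manual, rtol=1e-12)

    def test_gaussian_size_bins_normalized(self):
        d, w = gaussian_size_bins(1.0, 0.05)
        assert w.sum() == pytest.approx(1.0)
        assert np.all(d > 0)
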