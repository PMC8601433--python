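"""Recipe-to-truth calibration: anchors, linearity, design round trips."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pdmsphantom.phantom_model import (
    CalibrationConfig,
    PhantomRecipe,
    SpectralGrid,
    design_recipe,
    pdms_background,
    pdms_refractive_index,
    recipe_to_truth,
)
from pdmsphantom.spectral_fit import fit_absorption, fit_scattering


class TestBackground:
    def test_740nm_peak_present(self, default_grid):
        bg = pdms_background(default_grid)
        at = lambda l: float(np.interp(l, bg.wavelengths, bg.mu_a))
        assert at(740.0) - at(650.0) > 0

    def test_zero_amplitude_gives_flat_baseline(self, default_grid):
        cal = CalibrationConfig(peak_amplitude=0.0)
        bg = pdms_background(default_grid, cal)
        assert np.ptp(bg.mu_a) == 0

    def test_index_within_pdms_range(self, default_grid):
        cal = CalibrationConfig(cauchy_b_nm2=5000.0)
        n = pdms_refractive_index(default_grid.wavelengths, cal.n_pdms, cal.cauchy_b_nm2)
        assert np.all((n >= 1.40) & (n <= 1.45))
        bg = pdms_background(default_grid)
        assert np.all((bg.n >= 1.40) & (bg.n <= 1.45))


class TestRecipeToTruth:
    def test_scattering_anchor_0p1_tdp_gives_10_at_700(self, default_grid):
        truth = recipe_to_truth(PhantomRecipe(tdp_pct=0.1), default_grid)
        assert truth.at(700.0)["mu_s_prime"] == pytest.approx(10.0, rel=1e-12)

    def test_absorption_anchor_0p04_cbp_gives_3_at_800(self, default_grid):
        cal = CalibrationConfig()
        truth = recipe_to_truth(PhantomRecipe(cbp_pct=0.04), default_grid, cal)
        bg = pdms_background(default_grid, cal)
        above_bg = truth.at(800.0)["mu_a"] - float(
            np.interp(800.0, bg.wavelengths, bg.mu_a)
        )
        assert above_bg == pytest.approx(3.0, rel=1e-12)

    def test_empty_recipe_is_pure_background(self, default_grid):
        truth = recipe_to_truth(PhantomRecipe(), default_grid)
        bg = pdms_background(default_grid)
        np.testing.assert_array_equal(truth.mu_a, bg.mu_a)
        assert not truth.mu_s.any()

    def test_doubling_tdp_doubles_scattering(self, default_grid):
        t1 = recipe_to_truth(PhantomRecipe(tdp_pct=0.05), default_grid)
        t2 = recipe_to_truth(PhantomRecipe(tdp_pct=0.10), default_grid)
        np.testing.assert_allclose(t2.mu_s_prime, 2 * t1.mu_s_prime, rtol=1e-12)

    def test_mu_a_invariant_to_tdp_and_mu_sp_to_cbp(self, default_grid):
        a = recipe_to_truth(PhantomRecipe(tdp_pct=0.05, cbp_pct=0.01), default_grid)
        b = recipe_to_truth(PhantomRecipe(tdp_pct=0.15, cbp_pct=0.01), default_grid)
        c = recipe_to_truth(PhantomRecipe(tdp_pct=0.05, cbp_pct=0.04), default_grid)
        np.testing.assert_array_equal(a.mu_a, b.mu_a)
        np.testing.assert_array_equal(a.mu_s_prime, c.mu_s_prime)

    def test_tdp_truth_is_exact_power_law(self, default_grid):
        truth = recipe_to_truth(PhantomRecipe(tdp_pct=0.12), default_grid)
        fit = fit_scattering(default_grid.wavelengths, truth.mu_s_prime)
        cal = CalibrationConfig()
        assert fit.b == pytest.approx(cal.b_tdp, abs=1e-10)
        assert fit.a == pytest.approx(0.12 * cal.k_sca_per_pct, rel=1e-10)
        assert fit.cod == pytest.approx(1.0, abs=1e-12)

    def test_cbp_truth_is_exact_affine(self, default_grid):
        cal = CalibrationConfig(peak_amplitude=0.0, baseline_mu_a=0.0)
        truth = recipe_to_truth(PhantomRecipe(cbp_pct=0.02), default_grid, cal)
        fit = fit_absorption(default_grid.wavelengths, truth.mu_a)
        assert fit.c == pytest.approx(0.02 * cal.cbp_slope_per_pct, rel=1e-10)
        assert fit.d == pytest.approx(0.02 * cal.k_abs_intercept_per_pct, rel=1e-10)
        assert fit.cod == pytest.approx(1.0, abs=1e-12)

    def test_negative_fraction_rejected(self):
        with pytest.raises(ValueError):
            PhantomRecipe(tdp_pct=-0.1)


class TestDesignRecipe:
    def test_anchor_target_recovers_anchor_recipe(self, default_grid):
        bg = pdms_background(default_grid).at(700.0)["mu_a"] if False else None
        cal = CalibrationConfig()
        bg700 = pdms_background(SpectralGrid(np.array([700.0])), cal).mu_a[0]
        r = design_recipe(bg700, 10.0, wavelength_nm=700.0)
        assert r.tdp_pct == pytest.approx(0.1, rel=1e-12)
        assert r.cbp_pct == pytest.approx(0.0, abs=1e-15)

    def test_known_recipe_round_trip(self, default_grid):
        src = PhantomRecipe(tdp_pct=0.08, cbp_pct=0.015)
        truth = recipe_to_truth(src, default_grid)
        at = truth.at(800.0)
        r = design_recipe(at["mu_a"], at["mu_s_prime"], 800.0)
        assert r.tdp_pct == pytest.approx(src.tdp_pct, rel=1e-9)
        assert r.cbp_pct == pytest.approx(src.cbp_pct, rel=1e-9)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(
        mu_a=st.floats(min_value=0.1, max_value=3.0),
        mu_sp=st.floats(min_value=1.0, max_value=40.0),
    )
    def test_random_targets_round_trip(self, mu_a, mu_sp):
        grid = SpectralGrid(np.array([600.0, 800.0, 850.0]))
        r = design_recipe(mu_a, mu_sp, wavelength_nm=800.0)
        truth = recipe_to_truth(r, grid)
        at = truth.at(800.0)
        assert at["mu_a"] == pytest.approx(mu_a, rel=1e-6)
        assert at["mu_s_prime"] == pytest.approx(mu_sp, rel=1e-6)

    def test_unreachable_absorption_names_bound(self):
        with pytest.raises(ValueError, match="below the PDMS background"):
            design_recipe(1e-6, 10.0)
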