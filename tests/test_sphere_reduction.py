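"""Substitution reduction, repeat statistics and the k=1 uncertainty budget."""

import numpy as np
import pytest

from pdmsphantom.rt_forward import SlabGeometry
from pdmsphantom.rt_inverse import invert_spectrum
from pdmsphantom.sphere_reduction import (
    RawSpectra,
    coefficient_of_variation,
    invert_repeats,
    propagate_uncertainty,
    substitution_reduce,
)

GEOM = SlabGeometry(thickness_cm=0.25, n_slab=1.41)
LAM = np.array([600.0, 700.0, 800.0])


def make_raw(R, T, gain=1.0, repeats=1):
    R = np.broadcast_to(R, LAM.shape)
    T = np.broadcast_to(T, LAM.shape)
    return RawSpectra(
        wavelengths=LAM,
        sample_refl=np.tile(gain * R, (repeats, 1)),
        standard_refl=gain * 0.99 * np.ones_like(LAM),
        sample_trans=np.tile(gain * T, (repeats, 1)),
        open_trans=gain * np.ones_like(LAM),
    )


class TestSubstitutionReduce:
    def test_sample_identical_to_standard_gives_rho_std(self):
        raw = RawSpectra(
            wavelengths=LAM,
            sample_refl=0.7 * np.ones_like(LAM),
            standard_refl=0.7 * np.ones_like(LAM),
            sample_trans=0.5 * np.ones_like(LAM),
            open_trans=np.ones_like(LAM),
        )
        rec = substitution_reduce(raw, GEOM, rho_std=0.99)
        np.testing.assert_allclose(rec.R_d, 0.99, rtol=1e-12)

    def test_open_beam_identity_gives_unit_transmittance(self):
        raw = make_raw(0.3, 1.0)
        rec = substitution_reduce(raw, GEOM)
        np.testing.assert_allclose(rec.T_d, 1.0, rtol=1e-12)

    def test_round_trips_generating_values(self):
        rec = substitution_reduce(make_raw(0.43, 0.22), GEOM)
        np.testing.assert_allclose(rec.R_d, 0.43, rtol=1e-12)
        np.testing.assert_allclose(rec.T_d, 0.22, rtol=1e-12)

    def test_scale_invariance_under_common_gain(self):
        a = substitution_reduce(make_raw(0.43, 0.22, gain=1.0), GEOM)
        b = substitution_reduce(make_raw(0.43, 0.22, gain=137.5), GEOM)
        np.testing.assert_allclose(a.R_d, b.R_d, rtol=1e-12)
        np.testing.assert_allclose(a.T_d, b.T_d, rtol=1e-12)

    def test_out_of_range_clipped_with_warning(self):
        raw = make_raw(1.2, 0.2)
        rec = substitution_reduce(raw, GEOM)
        assert np.all(rec.R_d <= 1.0)
        assert any("clipped" in w for w in rec.warnings)

    def test_zero_reference_rejected(self):
        raw = make_raw(0.4, 0.2)
        raw.standard_refl = np.zeros_like(LAM)
        with pytest.raises(ValueError):
            substitution_reduce(raw, GEOM)

    def test_dark_subtraction(self):
        dark = 0.05 * np.ones_like(LAM)
        raw = RawSpectra(
            wavelengths=LAM,
            sample_refl=0.99 * 0.4 + dark,
            standard_refl=0.99 + dark,
            sample_trans=0.2 + dark,
            open_trans=1.0 + dark,
            dark=dark,
        )
        rec = substitution_reduce(raw, GEOM)
        np.testing.assert_allclose(rec.R_d, 0.4 * 0.99, rtol=1e-12)
        np.testing.assert_allclose(rec.T_d, 0.2, rtol=1e-12)


class TestCoefficientOfVariation:
    def _results_from(self, values_a, values_s):
        from pdmsphantom.rt_inverse import InversionResult

        out = []
        for va, vs in zip(values_a, values_s):
            out.append(
                InversionResult(
                    wavelengths=LAM,
                    mu_a=np.full_like(LAM, va),
                    mu_s_prime=np.full_like(LAM, vs),
                    residual=np.zeros_like(LAM),
                    converged=np.ones_like(LAM, dtype=bool),
                )
            )
        return out

    def test_identical_repeats_zero(self):
        cov_a, cov_s = coefficient_of_variation(self._results_from([1, 1, 1], [9, 9, 9]))
        assert np.all(cov_a == 0) and np.all(cov_s == 0)

    def test_two_point_hand_computation(self):
        # repeats (9, 11): sd = sqrt(2), mean = 10 -> CoV = 14.14%
        _, cov_s = coefficient_of_variation(self._results_from([1, 1], [9, 11]))
        assert cov_s[0] == pytest.approx(100 * np.sqrt(2) / 10, rel=1e-12)

    def test_single_repeat_rejected(self):
        with pytest.raises(ValueError):
            coefficient_of_variation(self._results_from([1], [9]))


class TestUncertaintyBudget:
    @pytest.fixture(scope="class")
    def noiseless_record(self):
        """Noiseless 3-wavelength measurement of a known slab."""
        from pdmsphantom.rt_forward import adding_doubling

        R = np.empty_like(LAM)
        T = np.empty_like(LAM)
        for i in range(LAM.size):
            res = adding_doubling(0.5, 20.0, 0.5, GEOM)
            R[i], T[i] = res.R_total, res.T_total
        raw = make_raw(R[0], T[0], repeats=3)
        return substitution_reduce(raw, GEOM)

    def test_degenerate_budget_is_zero(self, noiseless_record):
        bud = propagate_uncertainty(
            noiseless_record, g=0.5, u_thickness_cm=0.0, u_rho=0.0, u_n=0.0
        )
        np.testing.assert_allclose(bud.combined_k1_mu_a, 0.0, atol=1e-12)
        np.testing.assert_allclose(bud.combined_k1_mu_s_prime, 0.0, atol=1e-12)

    def test_thickness_component_linear_in_u(self, noiseless_record):
        b1 = propagate_uncertainty(
            noiseless_record, u_thickness_cm=0.005, u_rho=0.0, u_n=0.0
        )
        b2 = propagate_uncertainty(
            noiseless_record, u_thickness_cm=0.010, u_rho=0.0, u_n=0.0
        )
        np.testing.assert_allclose(
            b2.components_mu_a["thickness"],
            2.0 * b1.components_mu_a["thickness"],
            rtol=1e-9,
        )

    def test_combined_is_quadrature_sum(self, noiseless_record):
        bud = propagate_uncertainty(noiseless_record)
        manual = np.sqrt(
            np.sum([c**2 for c in bud.components_mu_a.values()], axis=0)
        )
        np.testing.assert_allclose(bud.combined_k1_mu_a, manual, rtol=1e-12)

    def test_fd_step_halving_stable(self, noiseless_record):
        b1 = propagate_uncertainty(noiseless_record, u_rho=0.0, u_n=0.0)
        b2 = propagate_uncertainty(
            noiseless_record, u_rho=0.0, u_n=0.0, fd_rel_step=0.005
        )
        rel = np.abs(
            b2.components_mu_s_prime["thickness"]
            / b1.components_mu_s_prime["thickness"]
            - 1.0
        )
        assert np.max(rel) < 0.01
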