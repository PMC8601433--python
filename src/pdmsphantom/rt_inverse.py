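"""Inverse adding--doubling: (mu_a, mu_s') from measured (R, T).

At each wavelength the measured total reflectance and transmittance are
matched by iteratively re-running the forward adding--doubling solver with
trial coefficients, searching over (log mu_a, log mu_s'). The anisotropy g
and the refractive index n are fixed inputs, never fitted — comparability
across instruments requires every laboratory to invert with the same g.

The search is a coarse 6x6 log-spaced grid (to land in the right basin)
followed by Levenberg--Marquardt polishing; convergence requires the forward
model to reproduce the measurement to 1e-6 in max-norm. Spectra are inverted
wavelength by wavelength with the previous wavelength's solution as a warm
start.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .rt_forward import SlabGeometry, adding_doubling

__all__ = ["InversionResult", "invert_rt", "invert_spectrum", "MU_A_FLOOR"]

#: lower clamp keeping log(mu_a) finite; converged values at the floor are flagged
MU_A_FLOOR = 1e-5

#: residual tolerance (max-norm on R and T) declaring convergence
TOLERANCE = 1e-6

#: mu_s' * t below which collimated transmission dominates the measurement
COLLIMATED_REGIME_TAU = 0.1

#: calibrated search box for the coarse grid (1/cm)
GRID_MU_A = (1e-3, 5.0)
GRID_MU_SP = (0.3, 60.0)


@dataclass
class InversionResult:
    """Recovered spectra with per-wavelength diagnostics."""

    wavelengths: np.ndarray
    mu_a: np.ndarray
    mu_s_prime: np.ndarray
    residual: np.ndarray
    converged: np.ndarray
    warnings: list[str] = field(default_factory=list)


class UnphysicalMeasurementError(ValueError):
    """Raised when R + T exceeds unity beyond tolerance."""


_LOG_BOUNDS = (np.log(1e-7), np.log(1e4))  # keeps the unbounded LM search sane


def _forward(log_mua: float, log_musp: float, g: float, geom: SlabGeometry):
    mu_a = np.exp(np.clip(log_mua, *_LOG_BOUNDS))
    mu_sp = np.exp(np.clip(log_musp, *_LOG_BOUNDS))
    mu_s = mu_sp / (1.0 - g)
    res = adding_doubling(mu_a, mu_s, g, geom)
    return res.R_total, res.T_total


def invert_rt(
    R: float,
    T: float,
    geom: SlabGeometry,
    g: float = 0.5,
    n: float | None = None,
    x0: tuple[float, float] | None = None,
) -> tuple[float, float, dict]:
    """Recover (mu_a, mu_s') in 1/cm from one (R_total, T_total) pair.

    Parameters
    ----------
    R, T : float
        Measured total reflectance and transmittance fractions.
    geom : SlabGeometry
        Slab geometry; ``n`` overrides ``geom.n_slab`` when given (the
        per-wavelength index of a spectrum).
    g : float
        Fixed anisotropy used in the forward model.
    x0 : optional (mu_a, mu_s') warm start.

    Returns ``(mu_a, mu_s_prime, diagnostics)`` where diagnostics carries
    ``residual``, ``converged`` and ``warnings``.
    """
    if R < 0 or T < 0:
        raise UnphysicalMeasurementError(f"negative measurement R={R}, T={T}")
    if R + T > 1.0 + 1e-3:
        raise UnphysicalMeasurementError(
            f"unphysical measurement: R + T = {R + T:.6f} > 1"
        )
    if n is not None:
        geom = SlabGeometry(
            thickness_cm=geom.thickness_cm,
            n_slab=float(n),
            n_outside=geom.n_outside,
            beam_diameter_mm=geom.beam_diameter_mm,
        )

    def resid(x):
        Rm, Tm = _forward(x[0], x[1], g, geom)
        return np.array([Rm - R, Tm - T])

    starts: list[np.ndarray] = []
    if x0 is not None:
        starts.append(np.log([max(x0[0], MU_A_FLOOR), max(x0[1], 1e-6)]))

    best = None
    for attempt, start in enumerate(starts + [None]):
        if start is None:
            # coarse 6x6 log-spaced grid initialization
            la = np.log(np.geomspace(*GRID_MU_A, 6))
            ls = np.log(np.geomspace(*GRID_MU_SP, 6))
            grid_best, grid_val = None, np.inf
            for a in la:
                for s in ls:
                    r = resid((a, s))
                    v = np.max(np.abs(r))
                    if v < grid_val:
                        grid_val, grid_best = v, np.array([a, s])
            start = grid_best
        sol = least_squares(
            resid, start, method="lm", xtol=1e-14, ftol=1e-14, gtol=1e-14,
            max_nfev=200,
        )
        res_norm = float(np.max(np.abs(sol.fun)))
        if best is None or res_norm < best[1]:
            best = (sol.x, res_norm)
        if res_norm < TOLERANCE:
            break

    x, res_norm = best
    mu_a = float(np.exp(x[0]))
    mu_sp = float(np.exp(x[1]))
    converged = res_norm < TOLERANCE
    warns: list[str] = []
    if mu_a <= MU_A_FLOOR * 1.01:
        mu_a = max(mu_a, MU_A_FLOOR)
        warns.append("mu_a at floor")
    if mu_sp * geom.thickness_cm < COLLIMATED_REGIME_TAU:
        warns.append("collimated-transmission regime (mu_s'*t < 0.1)")
    if not converged:
        warns.append(f"non-convergence: residual {res_norm:.2e}")
    return mu_a, mu_sp, {
        "residual": res_norm,
        "converged": converged,
        "warnings": warns,
    }


def invert_spectrum(
    wavelengths: np.ndarray,
    R: np.ndarray,
    T: np.ndarray,
    geom: SlabGeometry,
    g: float = 0.5,
    n: np.ndarray | float | None = None,
) -> InversionResult:
    """Per-wavelength inversion of aligned R(lambda), T(lambda) spectra.

    Uses the previous wavelength's solution as a warm start; an unphysical
    wavelength is flagged (NaN coefficients) without aborting the rest.
    """
    lam = np.asarray(wavelengths, dtype=float)
    R = np.asarray(R, dtype=float)
    T = np.asarray(T, dtype=float)
    if not (lam.shape == R.shape == T.shape):
        raise ValueError("wavelengths, R, T must be aligned")
    n_arr = np.broadcast_to(
        np.asarray(geom.n_slab if n is None else n, dtype=float), lam.shape
    )

    mu_a = np.full_like(lam, np.nan)
    mu_sp = np.full_like(lam, np.nan)
    residual = np.full_like(lam, np.nan)
    converged = np.zeros(lam.shape, dtype=bool)
    warnings_all: list[str] = []
    prev: tuple[float, float] | None = None
    for i in range(lam.size):
        try:
            a, s, diag = invert_rt(
                float(R[i]), float(T[i]), geom, g=g, n=float(n_arr[i]), x0=prev
            )
        except UnphysicalMeasurementError as exc:
            warnings_all.append(f"{lam[i]:.1f} nm: {exc}")
            prev = None
            continue
        mu_a[i], mu_sp[i] = a, s
        residual[i] = diag["residual"]
        converged[i] = diag["converged"]
        for w in diag["warnings"]:
            warnings_all.append(f"{lam[i]:.1f} nm: {w}")
        prev = (a, s) if diag["converged"] else None
    return InversionResult(
        wavelengths=lam,
        mu_a=mu_a,
        mu_s_prime=mu_sp,
        residual=residual,
        converged=converged,
        warnings=warnings_all,
    )
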