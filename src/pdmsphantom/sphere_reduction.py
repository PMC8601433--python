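"""Integrating-sphere signal reduction and the k=1 uncertainty budget.

The single-sphere substitution method ratios the dark-subtracted,
monitor-normalized sample signal against a reference: a calibrated
reflectance standard (nominally 99% reflectance) for the reflectance channel
and the empty beam for the transmittance channel,

    R_d = rho_std * (S_sample/M_sample) / (S_std/M_std)
    T_d = (S_sample/M_sample) / (S_open/M_open)

Sphere-wall interreflection changes between sample and standard (the
classical single-sphere substitution error) are deliberately not modeled.

The uncertainty budget combines, in quadrature at coverage factor k = 1:

* type A — the spread of the coefficients inverted from each of the
  repeated acquisitions (sd / sqrt(n_repeats));
* type B — central-finite-difference sensitivities of the inversion to the
  slab thickness, the standard's reflectance, and the refractive index,
  each scaled by its standard uncertainty.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .rt_forward import SlabGeometry
from .rt_inverse import InversionResult, invert_spectrum

__all__ = [
    "RawSpectra",
    "MeasurementRecord",
    "UncertaintyBudget",
    "substitution_reduce",
    "propagate_uncertainty",
    "coefficient_of_variation",
    "invert_repeats",
]

DEFAULT_RHO_STD = 0.99
DEFAULT_U_THICKNESS_CM = 0.005
DEFAULT_U_RHO = 0.005
DEFAULT_U_N = 0.005
FD_RELATIVE_STEP = 1e-2


@dataclass
class RawSpectra:
    """One acquisition's raw detector signals on a common wavelength grid.

    ``sample_refl``/``sample_trans`` may be 2-D (repeats x wavelengths).
    Monitors default to unity (perfectly stable source), darks to zero.
    """

    wavelengths: np.ndarray
    sample_refl: np.ndarray
    standard_refl: np.ndarray
    sample_trans: np.ndarray
    open_trans: np.ndarray
    monitor_sample_refl: np.ndarray | None = None
    monitor_standard: np.ndarray | None = None
    monitor_sample_trans: np.ndarray | None = None
    monitor_open: np.ndarray | None = None
    dark: np.ndarray | None = None


@dataclass
class MeasurementRecord:
    """Reduced diffuse reflectance/transmittance with per-repeat values."""

    wavelengths: np.ndarray
    R_d: np.ndarray  # mean over repeats
    T_d: np.ndarray
    R_repeats: np.ndarray  # (n_repeats, n_wavelengths)
    T_repeats: np.ndarray
    rho_std: float
    geom: SlabGeometry
    warnings: list[str] = field(default_factory=list)

    @property
    def n_repeats(self) -> int:
        return self.R_repeats.shape[0]


@dataclass
class UncertaintyBudget:
    """Named per-wavelength k=1 components and their quadrature sum."""

    wavelengths: np.ndarray
    components_mu_a: dict[str, np.ndarray]
    components_mu_s_prime: dict[str, np.ndarray]
    combined_k1_mu_a: np.ndarray
    combined_k1_mu_s_prime: np.ndarray
    warnings: list[str] = field(default_factory=list)


def _norm(signal, monitor, dark):
    sig = np.asarray(signal, dtype=float)
    mon = np.ones_like(sig) if monitor is None else np.asarray(monitor, dtype=float)
    drk = np.zeros_like(sig) if dark is None else np.asarray(dark, dtype=float)
    if np.any(mon - drk <= 0):
        raise ValueError("zero or negative monitor signal after dark subtraction")
    return (sig - drk) / (mon - drk)


def substitution_reduce(
    raw: RawSpectra,
    geom: SlabGeometry,
    rho_std: float | np.ndarray = DEFAULT_RHO_STD,
) -> MeasurementRecord:
    """Reduce raw sphere signals to calibrated (R_d, T_d) per repeat.

    Out-of-range values are clipped to [0, 1] with a warning. A scalar or
    per-wavelength standard reflectance is accepted.
    """
    lam = np.asarray(raw.wavelengths, dtype=float)
    rho = np.asarray(rho_std, dtype=float)
    if np.any(rho <= 0) or np.any(rho > 1):
        raise ValueError("standard reflectance must be in (0, 1]")
    s_std = _norm(raw.standard_refl, raw.monitor_standard, raw.dark)
    s_open = _norm(raw.open_trans, raw.monitor_open, raw.dark)
    if np.any(s_std <= 0) or np.any(s_open <= 0):
        raise ValueError("non-positive reference signal")
    s_refl = np.atleast_2d(_norm(raw.sample_refl, raw.monitor_sample_refl, raw.dark))
    s_trans = np.atleast_2d(_norm(raw.sample_trans, raw.monitor_sample_trans, raw.dark))

    R_rep = rho * s_refl / s_std
    T_rep = s_trans / s_open
    warns: list[str] = []
    for name, arr in (("R_d", R_rep), ("T_d", T_rep)):
        bad = (arr < 0) | (arr > 1)
        if bad.any():
            warns.append(f"{name}: {int(bad.sum())} values clipped to [0, 1]")
            np.clip(arr, 0.0, 1.0, out=arr)
    return MeasurementRecord(
        wavelengths=lam,
        R_d=R_rep.mean(axis=0),
        T_d=T_rep.mean(axis=0),
        R_repeats=R_rep,
        T_repeats=T_rep,
        rho_std=float(np.mean(rho)),
        geom=geom,
        warnings=warns,
    )


def invert_repeats(
    m: MeasurementRecord,
    g: float = 0.5,
    n: np.ndarray | float | None = None,
) -> list[InversionResult]:
    """Invert each repeated acquisition separately."""
    return [
        invert_spectrum(m.wavelengths, m.R_repeats[k], m.T_repeats[k], m.geom, g=g, n=n)
        for k in range(m.n_repeats)
    ]


def coefficient_of_variation(results: list[InversionResult]):
    """Per-wavelength CoV (%) of mu_a and mu_s' across repeated inversions.

    Wavelengths where the mean vanishes yield NaN (flagged undefined).
    """
    if len(results) < 2:
        raise ValueError("need at least 2 repeats for a coefficient of variation")
    mu_a = np.vstack([r.mu_a for r in results])
    mu_sp = np.vstack([r.mu_s_prime for r in results])

    def cov(x):
        import warnings

        out = np.full(x.shape[1], np.nan)
        ok = np.sum(np.isfinite(x), axis=0) >= 2
        if ok.any():
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                mean = np.nanmean(x[:, ok], axis=0)
                sd = np.nanstd(x[:, ok], axis=0, ddof=1)
            with np.errstate(divide="ignore", invalid="ignore"):
                out[ok] = np.where(mean != 0, sd / mean * 100.0, np.nan)
        return out

    return cov(mu_a), cov(mu_sp)


def propagate_uncertainty(
    m: MeasurementRecord,
    g: float = 0.5,
    n: np.ndarray | float | None = None,
    u_thickness_cm: float = DEFAULT_U_THICKNESS_CM,
    u_rho: float = DEFAULT_U_RHO,
    u_n: float = DEFAULT_U_N,
    repeat_results: list[InversionResult] | None = None,
    fd_rel_step: float = FD_RELATIVE_STEP,
) -> UncertaintyBudget:
    """k=1 uncertainty budget for the inverted (mu_a, mu_s') spectra.

    Type A from the repeat spread (sd/sqrt(n)); type B via central finite
    differences of the full inversion with respect to thickness, standard
    reflectance and refractive index. Non-finite sensitivities are excluded
    with a warning.
    """
    lam = m.wavelengths
    if n is None:
        n = m.geom.n_slab
    n_arr = np.broadcast_to(np.asarray(n, dtype=float), lam.shape)
    warns: list[str] = []

    comps_a: dict[str, np.ndarray] = {}
    comps_s: dict[str, np.ndarray] = {}

    # --- type A: repeatability
    if m.n_repeats >= 2:
        if repeat_results is None:
            repeat_results = invert_repeats(m, g=g, n=n_arr)
        mu_a_rep = np.vstack([r.mu_a for r in repeat_results])
        mu_sp_rep = np.vstack([r.mu_s_prime for r in repeat_results])
        comps_a["repeatability"] = mu_a_rep.std(axis=0, ddof=1) / np.sqrt(m.n_repeats)
        comps_s["repeatability"] = mu_sp_rep.std(axis=0, ddof=1) / np.sqrt(m.n_repeats)
    else:
        warns.append("single acquisition: budget lacks repeatability component")

    # --- type B: central differences of the mean-spectrum inversion
    def inv_mean(geom: SlabGeometry, R=None, n_use=None):
        res = invert_spectrum(
            lam,
            m.R_d if R is None else R,
            m.T_d,
            geom,
            g=g,
            n=n_arr if n_use is None else n_use,
        )
        return res.mu_a, res.mu_s_prime

    def central(name, u, plus, minus, delta):
        if u == 0:
            return
        (a_p, s_p), (a_m, s_m) = plus, minus
        sens_a = (a_p - a_m) / (2.0 * delta)
        sens_s = (s_p - s_m) / (2.0 * delta)
        ca, cs = np.abs(sens_a) * u, np.abs(sens_s) * u
        bad = ~np.isfinite(ca) | ~np.isfinite(cs)
        if bad.any():
            warns.append(
                f"{name}: non-finite sensitivity at {int(bad.sum())} wavelengths; "
                "component excluded there"
            )
            ca = np.where(bad, 0.0, ca)
            cs = np.where(bad, 0.0, cs)
        comps_a[name] = ca
        comps_s[name] = cs

    t = m.geom.thickness_cm
    dt = fd_rel_step * t
    central(
        "thickness", u_thickness_cm,
        inv_mean(SlabGeometry(t + dt, m.geom.n_slab, m.geom.n_outside, m.geom.beam_diameter_mm)),
        inv_mean(SlabGeometry(t - dt, m.geom.n_slab, m.geom.n_outside, m.geom.beam_diameter_mm)),
        dt,
    )
    drho = fd_rel_step * m.rho_std
    # rho_std rescales the reduced reflectance: R_d proportional to rho_std
    central(
        "rho_std", u_rho,
        inv_mean(m.geom, R=m.R_d * (1 + drho / m.rho_std)),
        inv_mean(m.geom, R=m.R_d * (1 - drho / m.rho_std)),
        drho,
    )
    dn = fd_rel_step * float(np.mean(n_arr))
    central(
        "refractive_index", u_n,
        inv_mean(m.geom, n_use=n_arr + dn),
        inv_mean(m.geom, n_use=n_arr - dn),
        dn,
    )

    def combine(comps):
        if not comps:
            return np.zeros_like(lam)
        return np.sqrt(np.sum([c**2 for c in comps.values()], axis=0))

    return UncertaintyBudget(
        wavelengths=lam,
        components_mu_a=comps_a,
        components_mu_s_prime=comps_s,
        combined_k1_mu_a=combine(comps_a),
        combined_k1_mu_s_prime=combine(comps_s),
        warnings=warns,
    )
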