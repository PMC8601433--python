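"""Single-particle scattering optics and ensemble coefficients.

Computes scattering/absorption cross sections and the anisotropy factor of
spherical particles from either the classical Rayleigh formula (particle much
smaller than the wavelength) or the full Lorenz--Mie partial-wave series, and
assembles bulk coefficients ``mu_s``, ``mu_s_prime`` for an ensemble of such
particles dispersed at a known mass fraction in a polymer matrix.

Conventions
-----------
* Diameters in micrometres, wavelengths in nanometres (vacuum), mass
  densities in g/cm^3, coefficients in 1/cm.
* ``n_medium`` is the (real) refractive index of the host matrix; the size
  parameter uses the wavelength *in the medium*.
* The Mie implementation here is restricted to real relative indices: the
  carbon-black absorber in these phantoms is calibrated empirically at the
  phantom-model level, never predicted from carbon optics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import spherical_jn, spherical_yn

__all__ = [
    "ParticleSpec",
    "CrossSections",
    "rayleigh_cross_section",
    "mie_cross_section",
    "mie_efficiencies",
    "ensemble_coefficients",
    "polydisperse_coefficients",
    "log_spaced_size_bins",
    "gaussian_size_bins",
    "number_density",
]

#: handbook mass density of the PDMS matrix, g/cm^3
PDMS_DENSITY = 1.03

#: size-parameter bound below which the Rayleigh formula is accepted
RAYLEIGH_SIZE_PARAMETER_MAX = 0.3

#: volume fraction above which independent scattering is considered strained
INDEPENDENT_SCATTERING_VOLUME_FRACTION = 0.05


@dataclass(frozen=True)
class ParticleSpec:
    """A monodisperse spherical particle species dispersed in a matrix.

    Parameters
    ----------
    diameter_um : float
        Sphere diameter in micrometres.
    n_particle : float
        Real refractive index of the particle material.
    n_medium : float
        Real refractive index of the host matrix (PDMS ~ 1.41).
    mass_density : float
        Particle material density, g/cm^3.
    mass_fraction_pct : float
        Mass of particles per mass of matrix, in percent (w/w).
    matrix_density : float
        Host matrix density, g/cm^3 (default: PDMS).
    """

    diameter_um: float
    n_particle: float
    n_medium: float = 1.41
    mass_density: float = 1.0
    mass_fraction_pct: float = 0.0
    matrix_density: float = PDMS_DENSITY

    def __post_init__(self) -> None:
        if self.diameter_um <= 0:
            raise ValueError("particle diameter must be positive")
        if self.n_particle < 1 or self.n_medium < 1:
            raise ValueError("refractive indices must be >= 1")
        if self.mass_fraction_pct < 0:
            raise ValueError("mass fraction must be non-negative")
        if self.mass_density <= 0 or self.matrix_density <= 0:
            raise ValueError("densities must be positive")

    def size_parameter(self, wavelength_nm: float) -> float:
        """Size parameter x = pi d n_medium / lambda (lambda in vacuum)."""
        d_nm = self.diameter_um * 1e3
        return float(np.pi * d_nm * self.n_medium / wavelength_nm)

    @property
    def relative_index(self) -> float:
        return self.n_particle / self.n_medium

    @property
    def volume_um3(self) -> float:
        return float(np.pi / 6.0 * self.diameter_um**3)


@dataclass(frozen=True)
class CrossSections:
    """Single-particle cross sections (um^2) and anisotropy."""

    sigma_s: float
    sigma_a: float = 0.0
    g: float = 0.0

    def __post_init__(self) -> None:
        if self.sigma_s < 0 or self.sigma_a < 0:
            raise ValueError("cross sections must be non-negative")
        if not -1 < self.g < 1:
            raise ValueError("anisotropy must satisfy |g| < 1")


class NotRayleighRegimeError(ValueError):
    """Raised when a particle is too large for the Rayleigh approximation."""


class MieConvergenceError(RuntimeError):
    """Raised when the partial-wave series fails to produce finite terms."""


def rayleigh_cross_section(p: ParticleSpec, wavelength_nm: float) -> CrossSections:
    """Rayleigh scattering cross section of a small dielectric sphere.

    sigma_s = (2/3) pi^5 d^6 / lambda_med^4 * ((m^2-1)/(m^2+2))^2 with the
    exact lambda^-4 dependence; scattering is symmetric (g = 0) and a real
    index gives no absorption.

    Raises
    ------
    NotRayleighRegimeError
        If the size parameter exceeds ``RAYLEIGH_SIZE_PARAMETER_MAX``.
    """
    x = p.size_parameter(wavelength_nm)
    if x >= RAYLEIGH_SIZE_PARAMETER_MAX:
        raise NotRayleighRegimeError(
            f"particle not in Rayleigh regime: size parameter {x:.3f} >= "
            f"{RAYLEIGH_SIZE_PARAMETER_MAX} (diameter {p.diameter_um} um at "
            f"{wavelength_nm} nm)"
        )
    m = p.relative_index
    lam_med_um = wavelength_nm * 1e-3 / p.n_medium
    lorentz = (m**2 - 1.0) / (m**2 + 2.0)
    sigma_s = (2.0 / 3.0) * np.pi**5 * p.diameter_um**6 / lam_med_um**4 * lorentz**2
    return CrossSections(sigma_s=float(sigma_s), sigma_a=0.0, g=0.0)


def _mie_ab(m: float, x: float) -> tuple[np.ndarray, np.ndarray]:
    """Mie coefficients a_n, b_n for a real relative index m and size param x.

    Logarithmic derivative D_n(mx) by downward recurrence (stable), Riccati-
    Bessel psi/chi by upward recurrence; series truncated after
    nmax = x + 4 x^(1/3) + 2 terms (the standard criterion).
    """
    if x <= 0:
        raise ValueError("size parameter must be positive")
    if m <= 0:
        raise ValueError("relative index must be positive")
    nmax = int(np.ceil(x + 4.0 * x ** (1.0 / 3.0) + 2.0))
    mx = m * x
    # downward recurrence for D_n(mx), started well above nmax
    nstart = int(max(nmax, np.ceil(abs(mx))) + 50)
    D = np.zeros(nstart + 1)
    for n in range(nstart, 0, -1):
        D[n - 1] = n / mx - 1.0 / (D[n] + n / mx)
    D = D[1 : nmax + 1]  # D_1 .. D_nmax

    n = np.arange(1, nmax + 1)
    # Riccati-Bessel psi_n(x) = x j_n(x), chi_n(x) = -x y_n(x); upward
    # recurrence for psi is unstable once n > x, so use library Bessels
    orders = np.arange(0, nmax + 1)
    psi = x * spherical_jn(orders, x)
    chi = -x * spherical_yn(orders, x)
    psi_n, psi_nm1 = psi[1:], psi[:-1]
    chi_n, chi_nm1 = chi[1:], chi[:-1]

    xi_n = psi_n - 1j * chi_n
    xi_nm1 = psi_nm1 - 1j * chi_nm1

    da = D / m + n / x
    db = D * m + n / x
    a = (da * psi_n - psi_nm1) / (da * xi_n - xi_nm1)
    b = (db * psi_n - psi_nm1) / (db * xi_n - xi_nm1)
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise MieConvergenceError(
            f"Mie series produced non-finite terms (nmax={nmax}, m={m}, x={x})"
        )
    return a, b


def mie_efficiencies(m: float, x: float) -> tuple[float, float, float]:
    """Return (Qext, Qsca, g) for a homogeneous sphere, real index.

    Standard Bohren & Huffman sums:
      Qsca = (2/x^2) sum (2n+1)(|a_n|^2+|b_n|^2)
      Qext = (2/x^2) sum (2n+1) Re(a_n+b_n)
      g Qsca = (4/x^2) sum [ n(n+2)/(n+1) Re(a_n a*_{n+1} + b_n b*_{n+1})
                             + (2n+1)/(n(n+1)) Re(a_n b*_n) ]
    """
    a, b = _mie_ab(m, x)
    n = np.arange(1, len(a) + 1, dtype=float)
    qsca = 2.0 / x**2 * np.sum((2 * n + 1) * (np.abs(a) ** 2 + np.abs(b) ** 2))
    qext = 2.0 / x**2 * np.sum((2 * n + 1) * (a + b).real)
    asym = np.sum(
        n[:-1] * (n[:-1] + 2) / (n[:-1] + 1)
        * (a[:-1] * np.conj(a[1:]) + b[:-1] * np.conj(b[1:])).real
    )
    asym += np.sum((2 * n + 1) / (n * (n + 1)) * (a * np.conj(b)).real)
    g = 4.0 / x**2 * asym / qsca if qsca > 0 else 0.0
    return float(qext), float(qsca), float(g)


def mie_cross_section(p: ParticleSpec, wavelength_nm: float) -> CrossSections:
    """Lorenz--Mie cross sections of a sphere in a non-absorbing medium.

    For the real relative indices handled here sigma_a = 0 and
    sigma_s = Qsca * pi (d/2)^2.
    """
    x = p.size_parameter(wavelength_nm)
    m = p.relative_index
    _, qsca, g = mie_efficiencies(m, x)
    geom = np.pi * (p.diameter_um / 2.0) ** 2
    # clip |g| strictly inside (-1, 1); Mie g can approach but not reach 1
    g = float(np.clip(g, -1 + 1e-12, 1 - 1e-12))
    return CrossSections(sigma_s=float(qsca * geom), sigma_a=0.0, g=g)


def number_density(p: ParticleSpec) -> float:
    """Particle number density in 1/cm^3 from the mass fraction.

    In the dilute limit one cm^3 of composite contains ~``matrix_density``
    grams of matrix, hence ``mass_fraction * matrix_density`` grams of
    particles.
    """
    w = p.mass_fraction_pct / 100.0
    particle_mass_g = p.mass_density * p.volume_um3 * 1e-12  # um^3 -> cm^3
    return w * p.matrix_density / particle_mass_g


def ensemble_coefficients(
    p: ParticleSpec,
    wavelengths_nm: np.ndarray,
    model: str = "mie",
):
    """Bulk coefficients of an independent-scattering particle ensemble.

    Returns arrays ``(mu_s, mu_s_prime, mu_a)`` in 1/cm over the wavelength
    grid, with mu_s = rho_s * sigma_s and mu_s_prime = mu_s (1 - g).

    A volume fraction above ~5% strains the independent-scattering
    assumption and triggers a warning (the computation still proceeds).
    """
    wavelengths_nm = np.asarray(wavelengths_nm, dtype=float)
    if p.mass_fraction_pct == 0:
        z = np.zeros_like(wavelengths_nm)
        return z, z.copy(), z.copy()
    vol_frac = (p.mass_fraction_pct / 100.0) * p.matrix_density / p.mass_density
    if vol_frac > INDEPENDENT_SCATTERING_VOLUME_FRACTION:
        warnings.warn(
            f"volume fraction {vol_frac:.3f} exceeds "
            f"{INDEPENDENT_SCATTERING_VOLUME_FRACTION}: independent-scattering "
            "assumption strained",
            stacklevel=2,
        )
    rho = number_density(p)  # 1/cm^3
    xs = {"mie": mie_cross_section, "rayleigh": rayleigh_cross_section}[model]
    mu_s = np.empty_like(wavelengths_nm)
    mu_sp = np.empty_like(wavelengths_nm)
    for i, lam in enumerate(wavelengths_nm):
        cs = xs(p, float(lam))
        sigma_cm2 = cs.sigma_s * 1e-8  # um^2 -> cm^2
        mu_s[i] = rho * sigma_cm2
        mu_sp[i] = mu_s[i] * (1.0 - cs.g)
    mu_a = np.zeros_like(mu_s)
    return mu_s, mu_sp, mu_a


def log_spaced_size_bins(d_min_um: float, d_max_um: float, n: int = 5):
    """Discrete size mixture for a stated diameter range: n log-spaced
    diameters with equal mass per bin."""
    d = np.geomspace(d_min_um, d_max_um, n)
    return d, np.full(n, 1.0 / n)


def gaussian_size_bins(mean_um: float, sd_um: float, n: int = 7):
    """Discrete size mixture for a nominal d = mean +/- sd bead population.

    Gauss-Hermite nodes of the number-weighted Gaussian diameter
    distribution; returned weights are mass weights (number weight * d^3,
    normalized).
    """
    x, w = np.polynomial.hermite.hermgauss(n)
    d = mean_um + np.sqrt(2.0) * sd_um * x
    if np.any(d <= 0):
        raise ValueError("size distribution extends to non-positive diameters")
    mass_w = w * d**3
    return d, mass_w / mass_w.sum()


def polydisperse_coefficients(
    p: ParticleSpec,
    wavelengths_nm: np.ndarray,
    diameters_um: np.ndarray,
    mass_weights: np.ndarray,
    model: str = "mie",
):
    """Ensemble coefficients of a discrete size mixture.

    The total mass fraction of ``p`` is split across the diameter bins
    according to ``mass_weights`` (normalized internally); bulk coefficients
    are the sums over bins.
    """
    from dataclasses import replace as _replace

    diameters_um = np.asarray(diameters_um, dtype=float)
    w = np.asarray(mass_weights, dtype=float)
    if diameters_um.shape != w.shape:
        raise ValueError("diameters and mass weights must align")
    w = w / w.sum()
    lam = np.asarray(wavelengths_nm, dtype=float)
    mu_s = np.zeros_like(lam)
    mu_sp = np.zeros_like(lam)
    mu_a = np.zeros_like(lam)
    for d, wk in zip(diameters_um, w):
        spec = _replace(p, diameter_um=float(d),
                        mass_fraction_pct=p.mass_fraction_pct * float(wk))
        s, sp, a = ensemble_coefficients(spec, lam, model=model)
        mu_s += s
        mu_sp += sp
        mu_a += a
    return mu_s, mu_sp, mu_a
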