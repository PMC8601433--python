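"""Phantom recipes and their ground-truth optical properties.

A phantom is a cured PDMS slab loaded with up to three additives:

* TDP — titanium-dioxide powder, the scatterer (0.3–1.0 um, n ~ 2.87);
* CBP — carbon-black powder, the absorber (calibrated empirically);
* PS  — 1.0-um polystyrene microbeads (n ~ 1.58), added to shift the
  power-law exponent of the reduced scattering spectrum downward.

``recipe_to_truth`` maps mass fractions to per-wavelength (mu_a, mu_s, g, n)
using a linear-in-concentration calibration: absorption is affine in
wavelength per unit CBP (so a CBP-only phantom obeys mu_a = c*lambda + d
exactly, above the PDMS background), and TDP scattering is a pure power law
a (lambda/500)^-b per unit TDP. PS-bead scattering is computed from the
Lorenz--Mie series. The anisotropy is fixed at g = 0.5, the conventional
wavelength-averaged value for sub-micrometre TiO2, and is used consistently
by the forward and inverse solvers.

Default calibration anchors (all overridable via :class:`CalibrationConfig`):
0.1% TDP gives mu_s' = 10 1/cm at 700 nm; 0.04% CBP gives mu_a = 3 1/cm at
800 nm. The PDMS matrix itself contributes a small, nearly flat background
absorption with a weak peak near 740 nm (a methyl-group vibrational
overtone); its default magnitude here is a synthetic stand-in.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .particle_optics import (
    ParticleSpec,
    ensemble_coefficients,
    gaussian_size_bins,
    polydisperse_coefficients,
)

__all__ = [
    "SpectralGrid",
    "PhantomRecipe",
    "OpticalProperties",
    "CalibrationConfig",
    "pdms_background",
    "recipe_to_truth",
    "design_recipe",
    "pdms_refractive_index",
]


@dataclass(frozen=True)
class SpectralGrid:
    """Strictly increasing wavelength grid in nm (default 500–850, 5-nm step)."""

    wavelengths: np.ndarray = field(
        default_factory=lambda: np.arange(500.0, 850.0 + 1e-9, 5.0)
    )

    def __post_init__(self) -> None:
        lam = np.asarray(self.wavelengths, dtype=float)
        if lam.ndim != 1 or lam.size < 1:
            raise ValueError("wavelength grid must be a 1-D array")
        if lam.size > 1 and not np.all(np.diff(lam) > 0):
            raise ValueError("wavelengths must be strictly increasing")
        object.__setattr__(self, "wavelengths", lam)

    def __len__(self) -> int:
        return self.wavelengths.size


@dataclass(frozen=True)
class PhantomRecipe:
    """Additive mass fractions (% w/w in PDMS) and slab geometry."""

    tdp_pct: float = 0.0
    cbp_pct: float = 0.0
    ps_pct: float = 0.0
    thickness_cm: float = 0.25
    diameter_mm: float = 87.0

    def __post_init__(self) -> None:
        for name in ("tdp_pct", "cbp_pct", "ps_pct"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.thickness_cm <= 0:
            raise ValueError("thickness must be positive")


@dataclass(frozen=True)
class OpticalProperties:
    """Per-wavelength slab optical properties.

    Arrays are aligned with ``wavelengths`` (nm); coefficients in 1/cm.
    """

    wavelengths: np.ndarray
    mu_a: np.ndarray
    mu_s: np.ndarray
    g: np.ndarray
    n: np.ndarray

    def __post_init__(self) -> None:
        lam = np.asarray(self.wavelengths, dtype=float)
        for name in ("mu_a", "mu_s", "g", "n"):
            arr = np.broadcast_to(
                np.asarray(getattr(self, name), dtype=float), lam.shape
            ).copy()
            object.__setattr__(self, name, arr)
        object.__setattr__(self, "wavelengths", lam)
        if np.any(self.mu_a < 0) or np.any(self.mu_s < 0):
            raise ValueError("coefficients must be non-negative")
        if np.any(np.abs(self.g) >= 1):
            raise ValueError("|g| must be < 1")
        if np.any(self.n < 1):
            raise ValueError("refractive index must be >= 1")

    @property
    def mu_s_prime(self) -> np.ndarray:
        return self.mu_s * (1.0 - self.g)

    def at(self, wavelength_nm: float) -> dict[str, float]:
        """Linearly interpolated properties at one wavelength."""
        lam = self.wavelengths
        return {
            name: float(np.interp(wavelength_nm, lam, getattr(self, name)))
            for name in ("mu_a", "mu_s", "g", "n")
        } | {"mu_s_prime": float(np.interp(wavelength_nm, lam, self.mu_s_prime))}


def pdms_refractive_index(
    wavelengths_nm: np.ndarray,
    n_constant: float = 1.41,
    cauchy_b_nm2: float = 0.0,
) -> np.ndarray:
    """PDMS refractive index; constant by default, optional Cauchy A + B/lambda^2.

    With a Cauchy term the constant is interpreted as the value at 700 nm so
    the mid-band index is unchanged.
    """
    lam = np.asarray(wavelengths_nm, dtype=float)
    if cauchy_b_nm2 == 0.0:
        return np.full_like(lam, n_constant)
    a = n_constant - cauchy_b_nm2 / 700.0**2
    return a + cauchy_b_nm2 / lam**2


@dataclass(frozen=True)
class CalibrationConfig:
    """Concentration-to-optics calibration and matrix background model.

    Scattering: one percent TDP contributes
    ``k_sca * (lambda/500)^-b_tdp`` 1/cm of reduced scattering, with k_sca
    chosen so that 0.1% TDP gives 10 1/cm at 700 nm and the exponent b_tdp
    set to 1.15, the midpoint of the empirically observed 1.02–1.28 spread.

    Absorption: one percent CBP contributes ``c1*lambda + d1`` 1/cm, anchored
    so 0.04% CBP gives 3 1/cm at 800 nm with a small positive slope (spectra
    stay almost flat).

    Background: baseline + Gaussian peak at 740 nm (FWHM 25 nm); magnitudes
    are synthetic stand-ins for the weak PDMS absorption.
    """

    b_tdp: float = 1.15
    musp700_at_0p1_tdp: float = 10.0  # 1/cm at 700 nm for 0.1% TDP
    mua800_at_0p04_cbp: float = 3.0  # 1/cm at 800 nm for 0.04% CBP
    cbp_slope_per_pct: float = 0.005  # 1/cm per nm per % CBP
    baseline_mu_a: float = 0.005  # 1/cm, flat PDMS background
    peak_amplitude: float = 0.02  # 1/cm at 740 nm
    peak_center_nm: float = 740.0
    peak_fwhm_nm: float = 25.0
    g: float = 0.5
    n_pdms: float = 1.41
    cauchy_b_nm2: float = 0.0
    ps_diameter_um: float = 1.0
    ps_diameter_sd_um: float = 0.05  # nominal 1.00 +/- 0.05 um beads
    ps_index: float = 1.58
    ps_density: float = 1.05

    @property
    def k_sca_per_pct(self) -> float:
        """Reduced scattering at 500 nm per % TDP, 1/cm."""
        anchor_pct = 0.1
        return (
            self.musp700_at_0p1_tdp / anchor_pct * (700.0 / 500.0) ** self.b_tdp
        )

    @property
    def k_abs_intercept_per_pct(self) -> float:
        """d1 so that c1*800 + d1 equals the 800-nm absorption anchor per %."""
        anchor_pct = 0.04
        return self.mua800_at_0p04_cbp / anchor_pct - self.cbp_slope_per_pct * 800.0

    def k_abs(self, wavelengths_nm: np.ndarray) -> np.ndarray:
        """Absorption per % CBP: affine in wavelength, 1/cm."""
        lam = np.asarray(wavelengths_nm, dtype=float)
        return self.cbp_slope_per_pct * lam + self.k_abs_intercept_per_pct


DEFAULT_CALIBRATION = CalibrationConfig()


def pdms_background(
    grid: SpectralGrid, cal: CalibrationConfig = DEFAULT_CALIBRATION
) -> OpticalProperties:
    """Optical properties of the bare PDMS matrix (no additives)."""
    lam = grid.wavelengths
    sigma = cal.peak_fwhm_nm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    mu_a = cal.baseline_mu_a + cal.peak_amplitude * np.exp(
        -0.5 * ((lam - cal.peak_center_nm) / sigma) ** 2
    )
    n = pdms_refractive_index(lam, cal.n_pdms, cal.cauchy_b_nm2)
    return OpticalProperties(
        wavelengths=lam,
        mu_a=mu_a,
        mu_s=np.zeros_like(lam),
        g=np.full_like(lam, cal.g),
        n=n,
    )


def _ps_mu_s_prime(
    ps_pct: float, grid: SpectralGrid, cal: CalibrationConfig
) -> np.ndarray:
    if ps_pct == 0:
        return np.zeros(len(grid))
    spec = ParticleSpec(
        diameter_um=cal.ps_diameter_um,
        n_particle=cal.ps_index,
        n_medium=cal.n_pdms,
        mass_density=cal.ps_density,
        mass_fraction_pct=ps_pct,
    )
    if cal.ps_diameter_sd_um > 0:
        d, w = gaussian_size_bins(cal.ps_diameter_um, cal.ps_diameter_sd_um)
        _, mu_sp, _ = polydisperse_coefficients(
            spec, grid.wavelengths, d, w, model="mie"
        )
    else:
        _, mu_sp, _ = ensemble_coefficients(spec, grid.wavelengths, model="mie")
    return mu_sp


def recipe_to_truth(
    r: PhantomRecipe,
    grid: SpectralGrid | None = None,
    cal: CalibrationConfig = DEFAULT_CALIBRATION,
) -> OpticalProperties:
    """Ground-truth optical properties of a phantom recipe.

    mu_a = background + k_abs(lambda) * cbp_pct,
    mu_s' = k_sca * tdp_pct * (lambda/500)^-b_tdp + PS Mie contribution,
    g fixed, mu_s = mu_s'/(1-g).
    """
    if grid is None:
        grid = SpectralGrid()
    lam = grid.wavelengths
    bg = pdms_background(grid, cal)
    mu_a = bg.mu_a + cal.k_abs(lam) * r.cbp_pct
    mu_sp = cal.k_sca_per_pct * r.tdp_pct * (lam / 500.0) ** (-cal.b_tdp)
    mu_sp = mu_sp + _ps_mu_s_prime(r.ps_pct, grid, cal)
    if np.any(mu_a < 0) or np.any(mu_sp < 0):
        raise ValueError("calibration produced a negative coefficient")
    mu_s = mu_sp / (1.0 - cal.g)
    return OpticalProperties(
        wavelengths=lam, mu_a=mu_a, mu_s=mu_s, g=np.full_like(lam, cal.g), n=bg.n
    )


def design_recipe(
    mu_a_target: float,
    mu_s_prime_target: float,
    wavelength_nm: float = 800.0,
    cal: CalibrationConfig = DEFAULT_CALIBRATION,
    thickness_cm: float = 0.25,
) -> PhantomRecipe:
    """Invert the calibration: recipe achieving the targets at one wavelength.

    Only TDP and CBP are used (no PS beads). Raises ``ValueError`` naming the
    violated bound when a target is unreachable (absorption below the PDMS
    background, or negative scattering).
    """
    grid = SpectralGrid(np.asarray([wavelength_nm]))
    bg = pdms_background(grid, cal).mu_a[0]
    if mu_a_target < bg:
        raise ValueError(
            f"target mu_a {mu_a_target:.4g} 1/cm is below the PDMS background "
            f"{bg:.4g} 1/cm at {wavelength_nm} nm"
        )
    if mu_s_prime_target < 0:
        raise ValueError("target mu_s' must be non-negative")
    cbp = (mu_a_target - bg) / cal.k_abs(np.asarray([wavelength_nm]))[0]
    tdp = mu_s_prime_target / (
        cal.k_sca_per_pct * (wavelength_nm / 500.0) ** (-cal.b_tdp)
    )
    return PhantomRecipe(tdp_pct=float(tdp), cbp_pct=float(cbp), thickness_cm=thickness_cm)
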