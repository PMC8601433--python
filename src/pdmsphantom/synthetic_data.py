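"""End-to-end synthetic integrating-sphere measurements.

Emulates the measurement chain for any phantom recipe so the full analysis
(reduction → inversion → fitting → regression) is testable without
laboratory data: ground-truth optical properties from the recipe
calibration, exact forward adding--doubling reflectance/transmittance,
spectrometer resolution as a Gaussian convolution (8.5-nm FWHM), raw
detector signals for the substitution method (sample, 99%-reflectance
standard, open beam, monitors), and multiplicative Gaussian detector noise
whose standard deviation rises smoothly toward the band edges where a real
supercontinuum/spectrometer chain loses signal-to-noise.

The emulator reproduces the statistical structure the analysis assumes —
five repeated acquisitions, edge-heavy noise, strict linearity of the truth
in additive concentrations — not any particular instrument's systematics
(stray light, dark drift, and sphere substitution error are out of scope).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .phantom_model import (
    CalibrationConfig,
    DEFAULT_CALIBRATION,
    OpticalProperties,
    PhantomRecipe,
    SpectralGrid,
    recipe_to_truth,
)
from .rt_forward import SlabGeometry, adding_doubling
from .sphere_reduction import MeasurementRecord, RawSpectra, substitution_reduce

__all__ = [
    "InstrumentConfig",
    "simulate_phantom_measurement",
    "simulate_phantom_grid",
    "simulate_ps_bead_set",
    "DEFAULT_TDP_LEVELS",
    "DEFAULT_CBP_LEVELS",
]

#: default concentration grid (% w/w), spanning the studied recipe ranges
DEFAULT_TDP_LEVELS = (0.05, 0.10, 0.15)
DEFAULT_CBP_LEVELS = (0.0025, 0.01, 0.04)


@dataclass(frozen=True)
class InstrumentConfig:
    """Synthetic instrument settings.

    ``noise_floor`` is the mid-band relative standard deviation of each raw
    detector spectrum; toward the band edges it is multiplied by a cosine
    taper reaching ``edge_noise_factor`` at the extreme wavelengths over
    ``edge_width_nm``. ``resolution_fwhm_nm = 0`` disables smoothing.
    """

    grid: SpectralGrid = field(default_factory=SpectralGrid)
    resolution_fwhm_nm: float = 8.5
    n_repeats: int = 5
    noise_floor: float = 0.01
    edge_noise_factor: float = 3.0
    edge_width_nm: float = 50.0
    rho_std: float = 0.99
    seed: int = 20211118

    def edge_factor(self, wavelengths_nm: np.ndarray) -> np.ndarray:
        """Smooth noise multiplier: 1 mid-band, ``edge_noise_factor`` at edges."""
        lam = np.asarray(wavelengths_nm, dtype=float)
        lo, hi = lam[0], lam[-1]
        dist = np.minimum(lam - lo, hi - lam)
        taper = np.where(
            dist < self.edge_width_nm,
            0.5 * (1.0 + np.cos(np.pi * dist / self.edge_width_nm)),
            0.0,
        )
        return 1.0 + (self.edge_noise_factor - 1.0) * taper


def _smooth(y: np.ndarray, lam: np.ndarray, fwhm_nm: float) -> np.ndarray:
    """Gaussian spectral-resolution convolution with edge renormalization."""
    if fwhm_nm <= 0:
        return y
    sigma = fwhm_nm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    K = np.exp(-0.5 * ((lam[:, None] - lam[None, :]) / sigma) ** 2)
    K /= K.sum(axis=1, keepdims=True)
    return K @ y


def _forward_spectra(truth: OpticalProperties, geom: SlabGeometry):
    lam = truth.wavelengths
    R = np.empty_like(lam)
    T = np.empty_like(lam)
    for i in range(lam.size):
        res = adding_doubling(
            float(truth.mu_a[i]), float(truth.mu_s[i]), float(truth.g[i]),
            SlabGeometry(geom.thickness_cm, float(truth.n[i]), geom.n_outside,
                         geom.beam_diameter_mm),
        )
        R[i], T[i] = res.R_total, res.T_total
    return R, T


def simulate_phantom_measurement(
    recipe: PhantomRecipe,
    cfg: InstrumentConfig | None = None,
    cal: CalibrationConfig = DEFAULT_CALIBRATION,
    seed: int | None = None,
) -> tuple[MeasurementRecord, OpticalProperties]:
    """Simulate one phantom's raw acquisition and reduce it.

    Returns the reduced :class:`MeasurementRecord` (with per-repeat values)
    and the attached ground-truth :class:`OpticalProperties` for recovery
    scoring. Bitwise-reproducible for a fixed seed.
    """
    if cfg is None:
        cfg = InstrumentConfig()
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    lam = cfg.grid.wavelengths
    truth = recipe_to_truth(recipe, cfg.grid, cal)
    geom = SlabGeometry(thickness_cm=recipe.thickness_cm, n_slab=float(truth.n.mean()))
    R_true, T_true = _forward_spectra(truth, geom)
    R_meas = _smooth(R_true, lam, cfg.resolution_fwhm_nm)
    T_meas = _smooth(T_true, lam, cfg.resolution_fwhm_nm)

    sd = cfg.noise_floor * cfg.edge_factor(lam)

    def noisy(clean, size=None):
        shape = clean.shape if size is None else (size,) + clean.shape
        return clean * (1.0 + sd * rng.standard_normal(shape))

    gain = 1.0  # arbitrary detector gain; the reduction is scale-invariant
    raw = RawSpectra(
        wavelengths=lam,
        standard_refl=noisy(gain * cfg.rho_std * np.ones_like(lam)),
        open_trans=noisy(gain * np.ones_like(lam)),
        sample_refl=noisy(gain * R_meas, size=cfg.n_repeats),
        sample_trans=noisy(gain * T_meas, size=cfg.n_repeats),
        monitor_sample_refl=noisy(np.ones((cfg.n_repeats, lam.size))) if cfg.noise_floor else None,
        monitor_sample_trans=noisy(np.ones((cfg.n_repeats, lam.size))) if cfg.noise_floor else None,
        monitor_standard=noisy(np.ones_like(lam)) if cfg.noise_floor else None,
        monitor_open=noisy(np.ones_like(lam)) if cfg.noise_floor else None,
    )
    record = substitution_reduce(raw, geom, rho_std=cfg.rho_std)
    return record, truth


def simulate_phantom_grid(
    tdp_levels=DEFAULT_TDP_LEVELS,
    cbp_levels=DEFAULT_CBP_LEVELS,
    cfg: InstrumentConfig | None = None,
    cal: CalibrationConfig = DEFAULT_CALIBRATION,
    pairs: list[tuple[float, float]] | None = None,
) -> list[dict]:
    """Simulate a factorial (or explicit pair list) TDP x CBP phantom grid.

    Returns one dict per phantom: recipe, reduced record, truth, seed. Child
    seeds are spawned deterministically from the config seed.
    """
    if cfg is None:
        cfg = InstrumentConfig()
    if pairs is None:
        if not len(tdp_levels) or not len(cbp_levels):
            raise ValueError("concentration lists must be non-empty")
        pairs = [(t, c) for t in tdp_levels for c in cbp_levels]
    seeds = np.random.SeedSequence(cfg.seed).generate_state(len(pairs)) % (2**31)
    out = []
    for (tdp, cbp), s in zip(pairs, seeds):
        recipe = PhantomRecipe(tdp_pct=tdp, cbp_pct=cbp)
        record, truth = simulate_phantom_measurement(recipe, cfg, cal, seed=int(s))
        out.append(
            {"recipe": recipe, "record": record, "truth": truth, "seed": int(s)}
        )
    return out


#: the three PS-bead/TDP recipes used to demonstrate the b-value shift
PS_BEAD_RECIPES = (
    PhantomRecipe(tdp_pct=0.0, ps_pct=1.25),
    PhantomRecipe(tdp_pct=0.1, ps_pct=0.625),
    PhantomRecipe(tdp_pct=0.2, ps_pct=0.0),
)


def simulate_ps_bead_set(
    cfg: InstrumentConfig | None = None,
    cal: CalibrationConfig = DEFAULT_CALIBRATION,
) -> list[dict]:
    """Simulate the three-phantom polystyrene-bead series.

    Sample (i) scatters only via 1-um PS beads (Mie), (iii) only via TDP
    (power law), (ii) is the mixture; the fitted power-law exponent b rises
    from (i) to (iii).
    """
    if cfg is None:
        cfg = InstrumentConfig()
    seeds = np.random.SeedSequence(cfg.seed + 1).generate_state(3) % (2**31)
    out = []
    for recipe, s in zip(PS_BEAD_RECIPES, seeds):
        record, truth = simulate_phantom_measurement(recipe, cfg, cal, seed=int(s))
        out.append({"recipe": recipe, "record": record, "truth": truth, "seed": int(s)})
    return out
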