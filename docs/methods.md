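# Methods

This note documents the models, numerics and design choices behind
`pdmsphantom`: what each stage computes, what the synthetic instrument does
and does not emulate, and which knobs matter.

## Phantom optical model

A phantom is a homogeneous PDMS slab (default 2.5 mm thick, 87 mm diameter)
whose per-wavelength properties over 500–850 nm are

* absorption `mu_a(λ) = background(λ) + k_abs(λ) · CBP%`, with
  `k_abs(λ) = c₁λ + d₁` affine in wavelength, so a carbon-black-only phantom
  obeys the linear characterization function exactly;
* reduced scattering `mu_s'(λ) = k_sca · TDP% · (λ/500)^(−b_t) + PS(λ)`,
  so a titania-only phantom obeys the power-law characterization exactly,
  with the polystyrene-bead term `PS(λ)` computed from Lorenz–Mie theory;
* fixed anisotropy `g = 0.5` (the conventional wavelength-averaged value for
  sub-micrometre TiO₂) and refractive index `n = 1.41` (an optional Cauchy
  `A + B/λ²` term is available; cured PDMS spans roughly 1.405–1.445).

Calibration anchors (defaults, all overridable): 0.1 % w/w TDP gives
`mu_s'(700 nm) = 10 cm⁻¹`; 0.04 % w/w CBP gives `mu_a(800 nm) = 3 cm⁻¹`
above background; `b_t = 1.15`, the midpoint of the empirically observed
1.02–1.28 spread for titania-loaded PDMS; the CBP spectral slope is
`c₁ = 0.005 cm⁻¹ nm⁻¹` per percent, keeping absorption spectra nearly flat.
The calibration is linear through the origin in each concentration, which is
what makes the closed-form `design_recipe` inverse possible.

The carbon-black term is deliberately empirical. Titania in PDMS is likewise
not modeled from first principles: a Lorenz–Mie computation for a 0.3–1.0 µm
TiO₂ size mixture (n ≈ 2.87) predicts a nearly flat, resonance-structured
spectrum (fitted exponent near −0.3), far from the b ≈ 1.0–1.3 observed for
real dispersed powders — aggregation and effective-index effects dominate,
so a calibrated power law is the right level of description. Mie theory is
used where it is quantitative: monodisperse polystyrene spheres
(1.00 ± 0.05 µm, n = 1.58). The ±0.05 µm bead-size spread is represented by
a 7-node Gauss–Hermite quadrature over the diameter distribution; it damps
the Mie ripple enough that the bead spectrum still fits a power law with
COD ≈ 0.996 while lowering the exponent to b ≈ 0.5.

The PDMS background absorption is a flat 0.005 cm⁻¹ baseline plus a Gaussian
peak at 740 nm (FWHM 25 nm, amplitude 0.02 cm⁻¹) representing the weak
methyl-overtone absorption of the polymer. These magnitudes are synthetic
stand-ins — chosen small relative to any carbon-black loading — since only
the peak's existence and position are established.

## Forward solver: adding–doubling

`adding_doubling` solves the azimuthally averaged radiative transfer
equation for the slab with collimated normal incidence:

* **Quadrature.** 20 ordinates per hemisphere (default). With an index
  mismatch the hemisphere is split at the critical-angle cosine
  `μ_c = √(1 − (n_out/n_slab)²)`: Gauss–Legendre below it, Gauss–Radau above
  it with a node pinned at μ = 1 so the collimated beam travels on an exact
  ordinate. Doubling the order changes R and T by < 10⁻⁴.
* **Phase function.** Henyey–Greenstein, expanded in Legendre polynomials to
  order 2N−1 and then symmetrically balanced (Sinkhorn iteration) so that
  discrete scattering conserves energy exactly for every ordinate; this is
  what keeps `R + T = 1` at zero absorption to better than 10⁻⁹ even for
  g = 0.8–0.9 where the truncated series alone would leak ~10⁻⁵.
* **Initialization and doubling.** A diamond (Crank–Nicolson) step builds
  the reflection/transmission operators of a starting layer of optical
  thickness ≤ 10⁻⁵; repeated doubling reaches the slab's optical thickness;
  Fresnel interface layers (diagonal in the flux representation, total
  internal reflection included) are added on both faces. All operators act
  on per-ordinate fluxes, which makes the adding equations compose energy
  directly.
* **Degenerate media.** `mu_s = 0` is evaluated analytically
  (Beer–Lambert with multiple Fresnel passes).

The specular component is included in both totals, matching hemispherical
collection by a single integrating sphere. The beam diameter is carried as
metadata only; no finite-beam lateral-loss correction is applied.

`mc_oracle` is an independent check: a vectorized photon random walk with
Henyey–Greenstein sampling, Fresnel reflection/escape decisions at the
boundaries, implicit-capture absorption weighting and Russian roulette below
weight 10⁻⁴. The deterministic solver agrees with it within Monte-Carlo
error (3 SE at 10⁶ photons) across the calibrated property range.

## Inverse solver

`invert_rt` searches (log mu_a, log mu_s') so the forward model reproduces a
measured (R, T) pair to 10⁻⁶ in max-norm: a 6×6 log-spaced coarse grid
locates the basin, Levenberg–Marquardt polishes (warm-started from the
previous wavelength inside `invert_spectrum`). `g` and `n` are fixed inputs
— cross-laboratory comparability requires every inversion to use the same
`g`, so model mismatch for bead-loaded phantoms is observed, not corrected.
Numerical guards: log-parameters clipped to [ln 10⁻⁷, ln 10⁴] during the
search; `mu_a` floored at 10⁻⁵ cm⁻¹ (flagged); `R + T` up to 1.001 is
accepted (noise), beyond that the wavelength is flagged unphysical and
skipped without aborting the spectrum; `mu_s'·t < 0.1` raises a
collimated-transmission-regime warning, mirroring the known artifact when a
thin, weakly scattering sample transmits unscattered light.

In the near-transparent regime (no absorber: `mu_a` ~ background only,
R + T ≈ 0.99) the inversion is intrinsically fragile under measurement
noise: noisy repeats whose R + T exceeds unity cannot converge and are
flagged, and the surviving repeats are a selected sample, so recovered
spectra scatter by a few percent there. Downstream statistics therefore use
only converged repeat inversions per wavelength.

## Integrating-sphere reduction and uncertainty

The substitution method ratios dark-subtracted, monitor-normalized signals:
`R_d = ρ_std (S_sam/M_sam)/(S_std/M_std)` against a 99 %-reflectance
standard, `T_d = (S_sam/M_sam)/(S_open/M_open)` against the empty beam.
Reduction is invariant to any common detector gain. Single-sphere
substitution error (the change in sphere throughput between sample and
standard) is a known simplification and is not modeled.

The k = 1 budget combines in quadrature: type A, the spread of coefficients
inverted from each repeat (sd/√n); type B, central finite differences
(relative step 10⁻², step-halving stable to < 1 %) of the inversion with
respect to thickness, standard reflectance and refractive index, scaled by
`u(t) = 0.005 cm`, `u(ρ_std) = 0.005`, `u(n) = 0.005`. These magnitudes are
configuration defaults of plausible size; they are not measured values.

## Four-parameter characterization

`mu_a(λ) = cλ + d` is fitted by (optionally inverse-variance weighted)
linear least squares; `mu_s'(λ) = a(λ/500)^(−b)` by Levenberg–Marquardt with
an analytic Jacobian, initialized from a log–log regression. The COD
(R²) is always computed unweighted, `1 − SS_res/SS_tot` about the mean, for
comparability with conventionally printed CODs. `b` is scale-invariant and
`a` scales proportionally under any rescaling of the spectrum.

Concentration diagnostics: ordinary least squares of `d` on CBP% and `a` on
TDP% (the linearity claims), plus independence cross-checks. The headline
cross-statistic is the *pooled partial slope*: `a` and CBP% are centered
within each fixed-TDP group and a single slope is fitted through all
phantoms, with the residual-based standard error at the pooled degrees of
freedom (n − groups − 1). Per-level 3-point regressions are also reported
but carry a single degree of freedom, which makes their standard errors
unreliable as test statistics.

## Synthetic instrument

The emulator composes: truth spectra → forward adding–doubling per
wavelength → Gaussian spectral-resolution convolution (FWHM 8.5 nm,
edge-renormalized) → raw detector signals (sample reflectance/transmittance
per repeat, one standard and one open-beam acquisition, unit monitors) →
multiplicative Gaussian noise → substitution reduction. Noise has relative
standard deviation 1 % per raw spectrum mid-band, rising by a cosine taper
to 3× within 50 nm of the band edges — a synthetic stand-in for the
supercontinuum/spectrometer signal-to-noise roll-off whose true shape is not
documented. Under these defaults the coefficient of variation of the
inverted coefficients across five repeats stays below ~6 % at mid-band
wavelengths and grows toward the edges, reproducing the statistical
structure the analysis assumes. Defaults: 5-nm grid, 5 repeats, seed
20211118.

What the emulator does *not* contain: stray light, dark drift, detector
nonlinearity, sphere-throughput substitution error, sample heterogeneity or
sedimentation. Passing end-to-end tests therefore demonstrates correctness
of the analysis chain under the assumed noise model, not robustness to
instrument systematics.

## Problem sizes

Defaults were chosen so a full run is interactive: the nine-phantom grid
with five repeats performs ~3200 per-wavelength inversions in a few minutes
on one core; Monte-Carlo cross-validation uses 10⁶ photons per
configuration. The acceptance script runs the same default sizes.

## Known limitations

* The concentration calibration is linear by construction; real phantoms
  show mild nonlinearity at high loadings (clumping, multiple-scattering
  onset) that the model intentionally omits.
* The low-concentration collimated-transmission artifact is flagged, never
  corrected.
* Tissue (a, b) comparison values are consumed from user-supplied tables;
  the bundled example table is marked synthetic and illustrative.
* Mie machinery covers real relative indices only (non-absorbing spheres);
  the absorbing carbon black is calibrated, not computed.
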