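"""Design a phantom recipe for target optical properties.

Given a target absorption and reduced scattering coefficient at one
wavelength, invert the concentration calibration to get the additive mass
fractions, then check the resulting truth spectra.
"""

from pdmsphantom import design_recipe, recipe_to_truth

# Target: mu_a = 0.5 1/cm and mu_s' = 10 1/cm at 800 nm — mid-range values
# for soft tissue in the NIR window.
recipe = design_recipe(mu_a_target=0.5, mu_s_prime_target=10.0, wavelength_nm=800.0)
print(f"recipe: TDP {recipe.tdp_pct:.4f}% w/w, CBP {recipe.cbp_pct:.5f}% w/w")

truth = recipe_to_truth(recipe)
for lam in (500.0, 700.0, 800.0, 850.0):
    at = truth.at(lam)
    print(
        f"  {lam:5.0f} nm: mu_a = {at['mu_a']:.3f} 1/cm, "
        f"mu_s' = {at['mu_s_prime']:.2f} 1/cm"
    )

# The 800-nm values reproduce the design targets exactly (the calibration is
# linear in concentration, so the inverse is closed-form); absorption is
# nearly flat with wavelength while scattering falls as (lambda/500)^-1.15.
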