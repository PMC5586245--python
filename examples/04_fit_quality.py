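"""Judging fits and curve similarity: reduced chi^2 with a fitted scale,
the correlation-map (longest-run) test, smearing, and mixture decomposition.
"""

import numpy as np

from saskit.fitting import chi2_fit, cormap_test, fit_mixture, smear_model
from saskit.profiles import Profile
from saskit.synthetic import sphere_intensity

rng = np.random.default_rng(5)
q = np.linspace(0.01, 0.5, 500)
truth = sphere_intensity(q, 30.0)
sigma = 0.03 * truth + 1e-7
data = Profile(q=q, intensity=truth + rng.normal(0, sigma), sigma=sigma)

# 1. correct model: chi2 ~ 1 and a CORMAP p-value that is not significant
fit = chi2_fit(data, truth)
cm = cormap_test(data.intensity, fit.c * truth)
print(f"correct model:  chi2 = {fit.chi2:.2f}, scale = {fit.c:.3f}, "
      f"longest run = {cm.L}, p = {cm.p_value:.3f}")

# 2. wrong model (radius off by 5%): chi2 explodes and, independently of the
#    error estimates, the run of same-sign residuals is far longer than a
#    fair coin allows
wrong = sphere_intensity(q, 31.5)
fitw = chi2_fit(data, wrong)
cmw = cormap_test(data.intensity, fitw.c * wrong)
print(f"wrong model:    chi2 = {fitw.chi2:.2f}, "
      f"longest run = {cmw.L}, p = {cmw.p_value:.2e}")

# 3. instrument smearing (SANS wavelength spread) fills in the sharp minima
smeared = smear_model(q, truth, dlambda_over_lambda=0.1)
j = np.argmin(truth[q < 0.2])
print(f"first minimum:  ideal {truth[j]:.2e} -> smeared {smeared[j]:.2e}")

# 4. a 70/30 two-component mixture decomposed by non-negative least squares
c1, c2 = sphere_intensity(q, 20.0), 3.0 * sphere_intensity(q, 45.0)
mixture = 0.7 * c1 + 0.3 * c2
msig = 0.01 * mixture + 1e-7
mdata = Profile(q=q, intensity=mixture + rng.normal(0, msig), sigma=msig)
mix = fit_mixture(mdata, [c1, c2])
print(f"mixture fit:    weights = {mix.weights[0]:.3f} / {mix.weights[1]:.3f} "
      f"(truth 0.700 / 0.300), chi2 = {mix.chi2:.2f}")
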