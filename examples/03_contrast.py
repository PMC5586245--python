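"""Contrast and composition: mass and scattering-length density from a
sequence, solvent SLDs, extinction coefficient, and a synthetic SANS
contrast-variation series analysed for its match point and Stuhrmann plot.
"""

import numpy as np

from saskit.contrast import (
    ContrastPoint, ContrastSeries, composition_from_sequence, contrast_context,
    extinction_coefficient, match_point, solvent_sld, stuhrmann,
)
from saskit.guinier import GuinierResult

# 1. composition-derived quantities for a short synthetic test sequence
seq = "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQAPILSRVGDGTQDNLSGAEKAVQVKVKALP"
comp = composition_from_sequence(seq)
print(f"sequence: M = {comp.mass:.1f} Da, vbar = {comp.vbar:.3f} cm^3/g, "
      f"labile H = {comp.labile_H:.0f}")
print(f"A280 extinction: {extinction_coefficient(seq):.3f} (g/l)^-1 cm^-1")

# 2. solvent scattering-length densities
print(f"water (X-ray):      {solvent_sld(probe='xray'):.3e} cm^-2")
print(f"H2O (neutron):      {solvent_sld(probe='neutron'):.3e} cm^-2")
print(f"D2O (neutron):      {solvent_sld(probe='neutron', f_d2o=1.0):.3e} cm^-2")

# 3. particle contrast in H2O and D2O (with H/D exchange of labile sites)
for f in (0.0, 1.0):
    ctx = contrast_context(comp, probe="neutron", f_d2o=f)
    print(f"f_D2O = {f:.0f}: delta_rho = {ctx.delta_rho:+.3e} cm^-2")

# 4. a synthetic contrast series around the protein match point (~40% D2O):
#    signed sqrt(I0/C) versus solvent SLD is linear; its root is the match point
points = []
for f in (0.0, 0.2, 0.6, 0.8, 1.0):
    ctx = contrast_context(comp, probe="neutron", f_d2o=f)
    i0 = (ctx.delta_rho * 1e-10) ** 2 * 2.0    # synthetic, exact
    g = GuinierResult(Rg=20.0, Rg_err=0.05, I0=i0, I0_err=0.01 * i0 + 1e-9,
                      q_range=(0.01, 0.06), qRg_window=(0.2, 1.2),
                      r2=1.0, n_points=20)
    points.append(ContrastPoint(f_d2o=f, profile=None, concentration=1.0,
                                guinier=g, context=ctx))
mp = match_point(ContrastSeries(points))
print(f"match point: f_D2O = {mp['f_d2o_match']:.3f} "
      f"(extrapolated: {mp['extrapolated']})")

# 5. Stuhrmann analysis of a synthetic Rg-vs-contrast series
rm2, alpha, beta = 400.0, 8.0e11, 0.0
stu_points = []
for f, g0 in zip((0.0, 0.2, 0.8), points[:3]):
    ctx = g0.context
    rg = np.sqrt(rm2 + alpha / ctx.delta_rho)
    g = GuinierResult(Rg=rg, Rg_err=0.05, I0=g0.guinier.I0,
                      I0_err=g0.guinier.I0_err, q_range=(0.01, 0.06),
                      qRg_window=(0.2, 1.2), r2=1.0, n_points=20)
    stu_points.append(ContrastPoint(f_d2o=f, profile=None, concentration=1.0,
                                    guinier=g, context=ctx))
stu = stuhrmann(ContrastSeries(stu_points), pin_beta=True)
print(f"Stuhrmann: Rm = {np.sqrt(stu['Rm2']):.2f} A, "
      f"alpha = {stu['alpha']:.2e} (positive: denser shell outside)")
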