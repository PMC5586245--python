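# Methods and numerical choices

This note records the models behind each module, the non-obvious parameter
choices, what the synthetic generators do and do not cover, and the known
limitations. Empirical statements here are limited to what the test suite
actually computes.

## Guinier analysis (`saskit.guinier`)

Weighted least squares of ln I versus q² with weights (I/σ)², so the fit is
performed in the space where counting errors are approximately Gaussian.
Rg = √(−3·slope); errors follow from the covariance of the linear fit.

The automatic window is a fixed-point iteration: fit on the current window,
re-truncate to qRg ≤ `qrg_limit` (default 1.3, the conventional bound for
globular particles), repeat. Because the qRg cutoff is discrete in the data
grid, the iteration can enter a two-cycle between adjacent windows; a
revisited window length terminates the iteration and the current window is
accepted. The q_min adequacy check tests q_min ≤ π/d_max when d_max is known.

Bias: the Guinier approximation is only the leading term. For a sphere,
ln I = −(qR)²/5 − (qR)⁴/350 − …, concave down in q², so the fitted Rg
*over*-estimates, by more as the window widens (the suite measures this
monotone growth).

## Indirect transform (`saskit.prtransform`)

P(r) is expanded in the Moore sine basis P(r) = r·Σ aₙ sin(nπr/d_max), whose
Fourier transform has a closed form (with the removable singularities at
q = nπ/d_max handled by their analytic limits). The number of basis functions
is ceil(q_max·d_max/π) + 4 — the Shannon channel count plus a small margin.
The solution minimizes χ² + α·∫(P″)², i.e. a curvature (smoothness) penalty;
α is chosen by maximum Menger curvature of the discrete L-curve unless given
explicitly. Rg, I(0) and their errors come from closed-form moments of the
basis and the sandwich covariance of the penalized solve. Note the penalty is
not scale-free: data scaled by c are reproduced exactly by α/c² (tests assert
this equivariance).

`dmax_scan` refits over a d_max grid and suggests the smallest d_max whose
fit χ² is within 5% of the best — treating all χ² ≤ 1 as indistinguishable
from the best, since fits at or below the noise floor cannot be ranked — and
whose P(r) has no negative dip near d_max. On noise-free synthetic data the
χ² floors at different d_max differ by orders of magnitude for numerical
rather than physical reasons; the χ² ≤ 1 rule keeps the suggestion at the
physical value.

## Invariants and mass (`saskit.invariants`)

The Porod invariant Qi = ∫q²I dq is computed in three pieces: the regularized
back-transform extended analytically over [0, q_min]; the regularized curve
over the measured range; and a K/q⁴ Porod tail beyond q_max, with K estimated
from the last 40% of the measured q range. The wide tail window averages over
form-factor oscillations — a narrow (e.g. 10%) window can land on an
oscillation extremum and bias Vp by tens of percent for compact shapes.

- Porod volume: Vp = 2π²·I(0)/Qi.
- Corrected-volume mass: the apparent Porod volume truncated at q_max is
  mapped through a linear q_max-dependent correction V′ = A + B·V_ap (the
  shipped table is self-calibrated on the package's own sphere generator and
  labelled as such), then M = V′ · 1.37 g/cm³ · N_A · 10⁻²⁴.
- Volume of correlation: Vc = I(0)/∫qI dq, with M from the molecule-class
  power law (protein: M = (Vc²/Rg / 0.1231)^1.0).
- Absolute scale: M = I(0)·N_A / (C·Δρ_M²) with Δρ_M the contrast per unit
  mass from the contrast context. The suite reproduces two published worked
  examples (glucose isomerase 178 312 Da, calmodulin 21 944 Da) to within 1%
  from the printed inputs alone.

`mass_consistency` compares all available routes against each other and an
expected mass when given. The volume-based calibrations assume protein-like
internal density; for non-protein particles (including the uniform spheres of
the synthetic generator) the routes legitimately disagree and are flagged,
not silently reconciled.

## Contrast and composition (`saskit.contrast`)

Residue composition tables (amino acids, nucleotides) and element scattering
lengths ship as package data. Mass is the average (isotope-abundance) mass;
vbar comes from residue partial volumes; labile hydrogens exchange with the
solvent D₂O fraction at 90% completeness by default. Solvent SLDs place
water at 9.39·10¹⁰ cm⁻² (X-ray), −0.56·10¹⁰ (H₂O) and 6.36·10¹⁰ cm⁻² (D₂O)
for neutrons; solutes displace water by their partial molar volumes. A280
extinction uses the Gill–von Hippel composition rule, returned per g/l.

Contrast-series analyses: the match point fits signed √(I(0)/C) versus
solvent SLD (the sign restored from the computed contrast); the Stuhrmann fit
is weighted least squares of Rg² versus 1/Δρ with explicit column scaling —
the design columns (1, 1/Δρ, 1/Δρ²) span ~20 orders of magnitude and the
unscaled normal equations are numerically singular. Component extraction
solves the per-q 3-component linear system (I₁₁, I₁₂, I₂₂) across the series
and reports the design condition number.

## Flexibility plots (`saskit.flexplots`)

The dimensionless Kratky curve (qRg)²·I/I(0) of a pure Guinier law peaks at
exactly (√3, 3/e ≈ 1.104); the "globular" flag tests the located peak against
the windows x ∈ [1.5, 2.2], y ∈ [0.9, 1.3]. Peaks are refined by a parabola
through the three bracketing samples. A Gaussian coil instead rises to the
plateau of 2. Porod–Debye plateau detection (q⁴I vs q⁴) requires the tail
window to be both low-scatter (std < 20% of the level) *and* trend-free
(linear drift < 20% of the level across the window): a coil's q⁴I grows
steadily ∝ q² and can pass a scatter-only criterion.

## Fit quality (`saskit.fitting`)

χ² uses the (1/N) convention with the analytic optimal multiplicative scale
(and optionally a fitted additive constant); the suite verifies calibration
(mean χ² = 1.00 ± 0.01 over 200 replicates of N = 500). The correlation-map
test uses the exact null distribution of the longest same-sign run of paired
differences, computed by a composition recursion in exact rational
arithmetic; ties inherit the previous sign. Resolution smearing is a Gaussian
kernel combining geometric σ_q and wavelength spread
σ = q·(Δλ/λ)/√(8 ln 2), integrated by Gauss–Hermite quadrature with the model
reflected about q = 0. Mixtures are decomposed by non-negative least squares
on error-weighted curves.

## SEC-SAS (`saskit.secsas`)

Frame traces (Rg, I(0) via the automatic Guinier fit, integrated intensity)
are computed against a provisional solvent estimate, then recomputed against
the selected buffer. Buffer selection takes the longest window on an
*explicitly chosen* side of the elution peak whose frames are pairwise
compatible under the longest-run test at the Bonferroni-corrected level
α/n_pairs, shrinking from the peak-adjacent side; drift is never healed by
silently switching sides. Sample selection grows a contiguous window around
the I(0) maximum subject to (a) Rg stability and (b) pairwise compatibility
of *buffer-subtracted*, optimally scaled frames — on raw frames the constant
solvent background makes ordinary concentration variation across the peak
look like a shape change. Rg stability allows, in quadrature with the
statistical errors, a 1% of Rg systematic floor: the per-frame automatic
Guinier window length changes discretely between frames, which moves the
fitted Rg of a compact particle by about that much. Averaging uses
σ_avg = rms(σ)/√N. The UV delay is estimated by maximizing the correlation
between the I(0) trace and the A280 trace; concentration is A/(ε·path), e.g.
×3.23 for a 0.31 cm cell.

## Synthetic generators (`saskit.synthetic`)

Exactly solvable form factors only: solid sphere, ellipsoid of revolution,
two-sphere dumbbell, Gaussian (Debye) coil, and a pure Guinier-law profile.
Optional hard-sphere (Percus–Yevick) structure factor, large-aggregate
contamination, solvent-mismatch offset, and Gaussian counting noise with
σ = I/√counts (or true Poisson sampling). Every generated profile carries a
truth record (Rg, d_max, volume, I(0)) computed from the geometry, never from
the curve. The SEC simulator elutes Gaussian concentration peaks of such
components and produces a matching delayed A280 trace. The generators are
deliberately *not* models of real macromolecules: uniform density, no
hydration shell, no interparticle interference beyond PY. They exist to give
the analysis code inputs with exactly known answers.

## Limitations

- No bead or atomistic modelling, no ensemble methods, no desmearing and no
  sasCIF I/O.
- Volume-to-mass calibrations (corrected volume, volume of correlation) are
  protein-specific power laws applied outside their derivation when used on
  the uniform-sphere synthetics; the tests therefore assert factor-level
  agreement only, and the consistency battery reports rather than hides the
  spread.
- The corrected-volume (A, B) table is calibrated on this package's own
  sphere generator, not on experimental data.
- The longest-run test's exact null assumes independent points; oversampled
  (interpolated) profiles violate that and make it anticonservative.
- SEC frame selection assumes a single dominant species per window and
  Gaussian-ish errors; radiation damage appears only as whatever drift it
  causes in the traces.
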