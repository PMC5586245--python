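{
  "_comment": "Empirical constants relating scattering volumes/invariants to molecular mass.",
  "volume_of_correlation": {
    "_comment": "Rambo & Tainer (2013, Nature 496:477) power law M = (QR / c)^k with QR = Vc^2 / Rg (A^3).",
    "protein": {"c": 0.1231, "k": 1.0},
    "nucleic_acid": {"c": 0.00934, "k": 0.808}
  },
  "fischer_porod": {
    "_comment": "Volume-to-mass conversion for the corrected Porod volume: protein mass density 1.37 g/cm^3 (Fischer et al. 2010, J. Appl. Cryst. 43:101), i.e. M [Da] = V [A^3] * 1.37 * 0.602214.",
    "mass_density_g_cm3": 1.37
  },
  "porod_rule_of_thumb": {
    "_comment": "Typical Vp/M ratio for hydrated folded proteins; values far outside [1.3, 1.7] warrant a flag.",
    "low": 1.3,
    "high": 1.7,
    "nominal": [1.45, 1.50]
  }
}
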