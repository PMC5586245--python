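{
  "_comment": "Element properties used for composition-based scattering-length densities. mass: average atomic weight (g/mol, IUPAC 2021 abridged); electrons: atomic number Z; b_coh: bound coherent neutron scattering length (fm, Sears 1992 compilation, Neutron News 3(3):26).",
  "H":  {"mass": 1.008,   "electrons": 1,  "b_coh": -3.7390},
  "D":  {"mass": 2.01410, "electrons": 1,  "b_coh": 6.671},
  "C":  {"mass": 12.011,  "electrons": 6,  "b_coh": 6.6460},
  "N":  {"mass": 14.007,  "electrons": 7,  "b_coh": 9.36},
  "O":  {"mass": 15.999,  "electrons": 8,  "b_coh": 5.803},
  "S":  {"mass": 32.06,   "electrons": 16, "b_coh": 2.847},
  "P":  {"mass": 30.974,  "electrons": 15, "b_coh": 5.13},
  "Na": {"mass": 22.990,  "electrons": 11, "b_coh": 3.63},
  "Cl": {"mass": 35.45,   "electrons": 17, "b_coh": 9.577},
  "K":  {"mass": 39.098,  "electrons": 19, "b_coh": 3.67},
  "Mg": {"mass": 24.305,  "electrons": 12, "b_coh": 5.375},
  "Ca": {"mass": 40.078,  "electrons": 20, "b_coh": 4.70},
  "Fe": {"mass": 55.845,  "electrons": 26, "b_coh": 9.45},
  "Zn": {"mass": 65.38,   "electrons": 30, "b_coh": 5.680}
}
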