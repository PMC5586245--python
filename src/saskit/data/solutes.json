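{
  "_comment": "Built-in solvent solute table: elemental formula and (approximate) partial molar volume in cm^3/mol used to correct for displaced water. Users may supply their own entries in the same shape.",
  "NaCl":  {"formula": {"Na": 1, "Cl": 1}, "molar_volume": 16.6},
  "KCl":   {"formula": {"K": 1, "Cl": 1},  "molar_volume": 26.8},
  "MgCl2": {"formula": {"Mg": 1, "Cl": 2}, "molar_volume": 14.5},
  "CaCl2": {"formula": {"Ca": 1, "Cl": 2}, "molar_volume": 17.8},
  "MOPS":  {"formula": {"C": 7, "H": 15, "N": 1, "O": 4, "S": 1}, "molar_volume": 158.0},
  "HEPES": {"formula": {"C": 8, "H": 18, "N": 2, "O": 4, "S": 1}, "molar_volume": 180.0},
  "TRIS":  {"formula": {"C": 4, "H": 11, "N": 1, "O": 3}, "molar_volume": 89.0},
  "TCEP":  {"formula": {"C": 9, "H": 15, "O": 6, "P": 1}, "molar_volume": 160.0},
  "DTT":   {"formula": {"C": 4, "H": 10, "O": 2, "S": 2}, "molar_volume": 118.0},
  "NaN3":  {"formula": {"Na": 1, "N": 3}, "molar_volume": 27.0},
  "glycerol": {"formula": {"C": 3, "H": 8, "O": 3}, "molar_volume": 73.0},
  "urea":  {"formula": {"C": 1, "H": 4, "N": 2, "O": 1}, "molar_volume": 44.2},
  "EDTA":  {"formula": {"C": 10, "H": 16, "N": 2, "O": 8}, "molar_volume": 195.0}
}
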