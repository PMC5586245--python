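{
  "_comment": "Per-nucleotide (nucleoside monophosphate minus water) elemental composition for chain residues; volumes in A^3 are approximate per-nucleotide partial volumes (Voss & Gerstein 2005 scale, ~0.29-0.33 nm^3); exch_H counts base NH/NH2 protons (plus the 2'-OH for RNA). Chain termini add one H2O and 2 further labile H (handled in code).",
  "dna": {
    "A": {"formula": {"C": 10, "H": 12, "N": 5, "O": 5, "P": 1}, "volume": 314.0, "exch_H": 2},
    "T": {"formula": {"C": 10, "H": 13, "N": 2, "O": 7, "P": 1}, "volume": 307.0, "exch_H": 1},
    "G": {"formula": {"C": 10, "H": 12, "N": 5, "O": 6, "P": 1}, "volume": 323.0, "exch_H": 3},
    "C": {"formula": {"C": 9,  "H": 12, "N": 3, "O": 6, "P": 1}, "volume": 288.0, "exch_H": 2}
  },
  "rna": {
    "A": {"formula": {"C": 10, "H": 12, "N": 5, "O": 6, "P": 1}, "volume": 315.0, "exch_H": 3},
    "U": {"formula": {"C": 9,  "H": 11, "N": 2, "O": 8, "P": 1}, "volume": 286.0, "exch_H": 2},
    "G": {"formula": {"C": 10, "H": 12, "N": 5, "O": 7, "P": 1}, "volume": 324.0, "exch_H": 4},
    "C": {"formula": {"C": 9,  "H": 12, "N": 3, "O": 7, "P": 1}, "volume": 291.0, "exch_H": 3}
  }
}
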