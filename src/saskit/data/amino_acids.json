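{
  "_comment": "Per-residue (amino acid minus water) elemental composition; residue volumes in A^3 from the Zamyatnin (1972, Prog. Biophys. Mol. Biol. 24:107) compilation; exch_H: exchangeable (labile) hydrogens including the backbone amide, side chains counted in their pH ~7 protonation state. Chain termini add one H2O and 3 further labile H (handled in code).",
  "A": {"formula": {"C": 3,  "H": 5,  "N": 1, "O": 1, "S": 0}, "volume": 88.6,  "exch_H": 1},
  "R": {"formula": {"C": 6,  "H": 12, "N": 4, "O": 1, "S": 0}, "volume": 173.4, "exch_H": 6},
  "N": {"formula": {"C": 4,  "H": 6,  "N": 2, "O": 2, "S": 0}, "volume": 114.1, "exch_H": 3},
  "D": {"formula": {"C": 4,  "H": 5,  "N": 1, "O": 3, "S": 0}, "volume": 111.1, "exch_H": 1},
  "C": {"formula": {"C": 3,  "H": 5,  "N": 1, "O": 1, "S": 1}, "volume": 108.5, "exch_H": 2},
  "Q": {"formula": {"C": 5,  "H": 8,  "N": 2, "O": 2, "S": 0}, "volume": 143.8, "exch_H": 3},
  "E": {"formula": {"C": 5,  "H": 7,  "N": 1, "O": 3, "S": 0}, "volume": 138.4, "exch_H": 1},
  "G": {"formula": {"C": 2,  "H": 3,  "N": 1, "O": 1, "S": 0}, "volume": 60.1,  "exch_H": 1},
  "H": {"formula": {"C": 6,  "H": 7,  "N": 3, "O": 1, "S": 0}, "volume": 153.2, "exch_H": 2},
  "I": {"formula": {"C": 6,  "H": 11, "N": 1, "O": 1, "S": 0}, "volume": 166.7, "exch_H": 1},
  "L": {"formula": {"C": 6,  "H": 11, "N": 1, "O": 1, "S": 0}, "volume": 166.7, "exch_H": 1},
  "K": {"formula": {"C": 6,  "H": 12, "N": 2, "O": 1, "S": 0}, "volume": 168.6, "exch_H": 4},
  "M": {"formula": {"C": 5,  "H": 9,  "N": 1, "O": 1, "S": 1}, "volume": 162.9, "exch_H": 1},
  "F": {"formula": {"C": 9,  "H": 9,  "N": 1, "O": 1, "S": 0}, "volume": 189.9, "exch_H": 1},
  "P": {"formula": {"C": 5,  "H": 7,  "N": 1, "O": 1, "S": 0}, "volume": 112.7, "exch_H": 0},
  "S": {"formula": {"C": 3,  "H": 5,  "N": 1, "O": 2, "S": 0}, "volume": 89.0,  "exch_H": 2},
  "T": {"formula": {"C": 4,  "H": 7,  "N": 1, "O": 2, "S": 0}, "volume": 116.1, "exch_H": 2},
  "W": {"formula": {"C": 11, "H": 10, "N": 2, "O": 1, "S": 0}, "volume": 227.8, "exch_H": 2},
  "Y": {"formula": {"C": 9,  "H": 9,  "N": 1, "O": 2, "S": 0}, "volume": 193.6, "exch_H": 2},
  "V": {"formula": {"C": 5,  "H": 9,  "N": 1, "O": 1, "S": 0}, "volume": 140.0, "exch_H": 1}
}
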