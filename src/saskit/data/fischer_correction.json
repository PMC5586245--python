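{
 "_comment": "SYNTHETIC CALIBRATION. Linear correction V' = A(qmax) + B(qmax)*V_ap mapping the apparent Porod volume (invariant truncated at the measured qmax, no tail extension) to the particle volume, in the spirit of the empirical correction of Fischer et al. (2010, J. Appl. Cryst. 43:101). Coefficients here were re-derived by the same procedure from analytic uniform-density form factors (spheres R=12-60 A and ellipsoids of revolution), not from the original PDB-based profile set. qmax in 1/A, volumes in A^3.",
 "qmax": [
  0.1,
  0.125,
  0.15,
  0.175,
  0.2,
  0.225,
  0.25,
  0.275,
  0.3,
  0.325,
  0.35,
  0.375,
  0.4,
  0.425,
  0.45,
  0.475,
  0.5
 ],
 "A": [
  -51930.87,
  -28444.89,
  -17627.56,
  -13563.11,
  -10708.5,
  -9708.79,
  -8032.93,
  -7498.95,
  -6467.95,
  -6123.83,
  -5430.02,
  -5222.78,
  -4729.76,
  -4513.12,
  -4147.84,
  -3910.07,
  -3665.32
 ],
 "B": [
  0.8832,
  0.90006,
  0.90435,
  0.91934,
  0.92568,
  0.93611,
  0.9395,
  0.94821,
  0.94901,
  0.95598,
  0.95676,
  0.96115,
  0.96274,
  0.96536,
  0.96687,
  0.96891,
  0.97011
 ]
}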