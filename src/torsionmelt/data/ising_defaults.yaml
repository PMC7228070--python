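# Default parameters of the torsional melting model.
# Energies kcal/mol except c_bubble (cal mol^-1 deg^-2); angles degrees;
# lengths nm; temperature K.  Stacking energies cover the ten canonical
# dinucleotide steps (the other six map by reverse-complement symmetry).
stacking:
  ag: -1.44
  ac: -2.19
  at: -1.72
  aa: -1.49
  ta: -0.57
  tc: -1.81
  tg: -0.93
  gg: -1.82
  gc: -2.55
  cg: -1.29
pairing:
  at: 0.64
  gc: 0.12
epsilon: 4.1
c_bubble: 0.79
tau0: 34.5
p_twist: 110.8
contour_l: null
temperature: 300.0
pairing_double_count: false
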