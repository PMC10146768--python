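# Criteria parameters for alpha-HCH.
# The published parameter table truncates this chemical's row; the BAFs
# here are reconstructed from the published BAF table and the exposure
# block is shared with p-p'DDE.  The adopted (one-significant-figure)
# RfD 0.0002 mg/kg/d is used, matching the published worked example.
# BCF back-solved from the trophic-level-2 baseline BAF (1.97e4 L/kg,
# f_l 0.019, f_fd 0.9753).
chemical:
  id: "alpha-HCH"
  lg_kow: 3.69
  rfd: 0.0002         # adopted RfD, mg/kg/d
water:
  poc: 4.0e-6         # kg/L
  doc: 1.5e-5         # kg/L
trophic_levels:
  2: {f_l: 0.019, fcm: 1.000, bcf: 366.03}
  3: {f_l: 0.026, fcm: 24.70, bcf: 366.03}
  4: {f_l: 0.030, fcm: 1.003, bcf: 366.03}
bafs:                 # published final BAFs, L/kg
  2: 365.0
  3: 9000.0           # 9.00e3
  4: 366.0
exposure:
  bw: 60.6
  di: 1.85
  fi2: 0.0126
  fi3: 0.0100
  fi4: 0.0075
  rsc: 0.2
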