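# Criteria parameters for p-p'DDE.
# The `bafs` block encodes the published final-BAF table verbatim and
# therefore overrides the BCF-derived chain; remove it to exercise the
# full f_fd -> baseline-BAF -> final-BAF derivation.  The BCF below is
# back-solved from the published trophic-level-2 baseline BAF
# (5.33e7 L/kg, f_l 0.019, f_fd 0.0319); POC/DOC are a back-solved pair
# satisfying POC + 0.08*DOC = 5.2e-6 kg/L (only the combined term is
# recoverable from the published dissolved fractions).
chemical:
  id: "p-p'DDE"
  lg_kow: 6.76
  rfd: 0.01271        # unrounded model prediction, mg/kg/d
water:
  poc: 4.0e-6         # kg/L
  doc: 1.5e-5         # kg/L
trophic_levels:
  2: {f_l: 0.019, fcm: 1.000, bcf: 32305.2}
  3: {f_l: 0.026, fcm: 13.30, bcf: 32305.2}
  4: {f_l: 0.030, fcm: 1.128, bcf: 32305.2}
bafs:                 # published final BAFs, L/kg
  2: 32400.0          # 3.24e4
  3: 430000.0         # 4.30e5
  4: 36500.0          # 3.65e4
exposure:
  bw: 60.6            # kg
  di: 1.85            # L/d
  fi2: 0.0126         # kg/d
  fi3: 0.0100
  fi4: 0.0075
  rsc: 0.2
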