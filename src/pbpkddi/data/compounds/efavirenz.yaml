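version: 1
name: efavirenz
mw: 315.7
logp: 4.6
compound_type: neutral
bp_ratio: 0.74
fu_plasma: 0.01
fa: 0.96
ka: 0.4
fu_gut: 1.0
q_gut: 20.0
vss_target: 3.5
kp_scalar: 1.0
enzyme_kinetics: []
cl_additional: 1200.0
cl_renal: 0.01
interaction:
  ind_max: 3.2
  ind_c50: 0.012
  fu_mic: 1.0
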