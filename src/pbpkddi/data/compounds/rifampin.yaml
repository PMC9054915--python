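version: 1
name: rifampin
mw: 822.9
logp: 2.7
compound_type: neutral
bp_ratio: 0.9
fu_plasma: 0.15
fa: 0.95
ka: 1.0
fu_gut: 1.0
q_gut: 25.0
vss_target: 0.66
kp_scalar: 1.0
enzyme_kinetics: []
cl_additional: 60.0
cl_renal: 1.0
interaction:
  ki: 18.5
  ind_max: 12.0
  ind_c50: 0.32
  fu_mic: 1.0
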