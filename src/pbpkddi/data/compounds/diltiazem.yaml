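version: 1
name: diltiazem
mw: 414.5
logp: 2.8
compound_type: monoprotic base
pka1: 7.7
bp_ratio: 1.0
fu_plasma: 0.22
fa: 0.9
ka: 1.5
fu_gut: 1.0
q_gut: 14.0
vss_target: 4.0
kp_scalar: 1.0
enzyme_kinetics:
- enzyme: CYP3A4
  vmax: 26.0
  km: 30.0
  fu_mic: 1.0
cl_additional: 30.0
cl_renal: 2.0
interaction:
  kapp: 2.2
  kinact: 0.7
  fu_mic: 1.0
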