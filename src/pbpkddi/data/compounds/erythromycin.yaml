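version: 1
name: erythromycin
mw: 733.9
logp: 3.06
compound_type: monoprotic base
pka1: 8.9
bp_ratio: 0.9
fu_plasma: 0.28
fa: 0.5
ka: 1.0
fu_gut: 1.0
q_gut: 13.0
vss_target: 0.75
kp_scalar: 1.0
enzyme_kinetics:
- enzyme: CYP3A4
  vmax: 19.0
  km: 44.0
  fu_mic: 1.0
cl_additional: 50.0
cl_renal: 5.0
interaction:
  kapp: 10.0
  kinact: 1.6
  fu_mic: 1.0
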