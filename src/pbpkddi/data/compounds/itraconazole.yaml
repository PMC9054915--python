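version: 1
name: itraconazole
mw: 705.6
logp: 4.35
compound_type: monoprotic base
pka1: 3.7
bp_ratio: 0.58
fu_plasma: 0.016
fa: 1.0
ka: 1.4
fu_gut: 1.0
q_gut: 15.0
vss_target: 7.0
kp_scalar: 1.0
enzyme_kinetics:
- enzyme: CYP3A4
  vmax: 0.03
  km: 0.0039
  fu_mic: 1.0
cl_additional: 1.0
cl_renal: 0.01
interaction:
  ki: 0.0003
  fu_mic: 1.0
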