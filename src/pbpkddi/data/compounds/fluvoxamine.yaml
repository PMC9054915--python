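# Weak CYP3A4 inhibitor (potent against CYP1A2/2C19, which are not part of
# this system; only the weak competitive CYP3A4 component is carried).
# Literature basis: fu ~0.23, Vd large (~15 L/kg), CL ~40 L/h non-CYP3A4;
# unbound CYP3A4 Ki of order 10 uM.
version: 1
name: fluvoxamine
mw: 318.3
logp: 2.9
compound_type: monoprotic base
pka1: 9.4
bp_ratio: 1.0
fu_plasma: 0.23
fa: 0.94
ka: 0.8
fu_gut: 1.0
q_gut: 15.0
vss_target: 15.0
kp_scalar: 1.0
enzyme_kinetics: []
cl_additional: 300.0
cl_renal: 1.0
interaction:
  ki: 10.0
  fu_mic: 1.0
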