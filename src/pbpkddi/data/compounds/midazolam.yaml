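# Sensitive CYP3A4 index substrate.
# Literature basis: fu ~0.032, B/P 0.66, weak base (pKa 6.0), Vss ~1 L/kg;
# CYP3A4 Vmax/Km from recombinant-enzyme kinetics giving CL ~25 L/h and a
# gut first-pass extraction of ~0.4-0.5; small non-CYP3A4 intrinsic
# clearance so that fm,CYP3A4 > 0.9.
version: 1
name: midazolam
mw: 325.8
logp: 3.53
compound_type: monoprotic base
pka1: 6.01
bp_ratio: 0.66
fu_plasma: 0.032
fa: 1.0
ka: 3.0
fu_gut: 1.0
q_gut: 14.4
vss_target: 1.0
kp_scalar: 1.0
enzyme_kinetics:
  - enzyme: CYP3A4
    vmax: 5.23
    km: 2.16
    fu_mic: 1.0
cl_additional: 70.0
cl_renal: 0.07
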