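# Final ipatasertib model: physicochemistry and absorption from in-house /
# predicted values; CYP3A4 Vmax, Km, CL_additional and kinact are the
# optimized values from the stepwise calibration (Km fixed at 0.195 uM,
# Vmax/CL_additional anchored to the itraconazole DDI, kinact anchored to
# the midazolam DDI); Ki and Kapp are the in vitro values.
version: 1
name: ipatasertib
mw: 458.0
logp: 3.0
compound_type: diprotic base
pka1: 9.0
pka2: 4.9
bp_ratio: 1.43
fu_plasma: 0.63
fa: 0.76
ka: 0.76          # 1/h
fu_gut: 1.0
q_gut: 9.28       # L/h
papp_mdck: 3.55   # 1e-6 cm/s
perm_scalar: 3.89
peff: 1.74        # 1e-4 cm/s
vss_target: 39.13 # L/kg
kp_scalar: 1.0    # resolved against vss_target at model build
enzyme_kinetics:
  - enzyme: CYP3A4
    vmax: 0.135   # pmol/min/pmol
    km: 0.195     # uM, fu_mic = 1
    fu_mic: 1.0
cl_additional: 2.7  # L/h
cl_renal: 19.3      # L/h
interaction:
  ki: 4.4        # uM, competitive
  kapp: 9.66     # uM
  kinact: 0.17   # 1/h, optimized (in vitro 2.6)
  fu_mic: 1.0
provenance: >
  Final fit-for-purpose model parameters for the AKT inhibitor ipatasertib
  (GDC-0068): saturable CYP3A4 metabolism with additional hepatic and renal
  clearance; competitive + time-dependent CYP3A4 inhibition.
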