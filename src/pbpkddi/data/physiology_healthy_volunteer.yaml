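# Virtual healthy-volunteer system for whole-body PBPK simulation.
#
# Values are the widely published population-simulator healthy-volunteer
# defaults for a 70-kg adult (organ weights/flows from standard reference-man
# compilations; CYP3A4 abundance, MPPGL and turnover from the compound-DDI
# modelling literature).  They live in this one editable file so the virtual
# subject can be audited and versioned independently of the code.
#
# Units are stated per key.  Flows are arterial-side blood flows; gut and
# spleen drain through the liver (portal vein), so the sum of all entries in
# tissue_blood_flows equals venous return = cardiac output.
version: 1
body_weight_kg: 70.0
hematocrit: 0.45

tissue_volumes_L:
  lung: 0.53
  adipose: 13.5
  bone: 7.9
  brain: 1.45
  gut: 1.65
  heart: 0.33
  kidney: 0.31
  liver: 1.65
  muscle: 29.0
  skin: 3.4
  spleen: 0.15
  arterial_blood: 1.7
  venous_blood: 3.9

# L/h; liver entry is the hepatic artery only (portal inflow = gut + spleen).
tissue_blood_flows_L_per_h:
  adipose: 19.5
  bone: 19.5
  brain: 46.8
  gut: 58.5
  heart: 15.6
  kidney: 74.1
  liver: 25.35
  muscle: 66.3
  skin: 19.5
  spleen: 11.7

cardiac_output_L_per_h: 356.85

liver_weight_g: 1650.0
mppgl_mg_per_g: 40.0                  # microsomal protein per g liver
cyp3a4_hepatic_abundance_pmol_per_mg: 137.0
cyp3a4_gut_total_nmol: 66.2
kdeg_hepatic_per_h: 0.0193            # hepatic CYP3A4 degradation rate
kdeg_gut_per_h: 0.03                  # enterocyte CYP3A4 degradation rate
q_villi_L_per_h: 18.0                 # mucosal villous flow (Qgut model)
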