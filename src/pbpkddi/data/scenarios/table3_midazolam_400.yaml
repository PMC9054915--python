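# Application scenario: midazolam 2 mg single dose on day 8 of ipatasertib 400 mg QD x8.
name: table3_midazolam_400
victim: {compound: midazolam, dose: 2, route: oral, start_time: 168, n_doses: 1}
perpetrator: {compound: ipatasertib, dose: 400, route: oral, interval: 24, n_doses: 8}
trial: {n_trials: 10, n_subjects: 10, seed: 0}
metric: auc_inf_post_dose
follow_up_h: 48
metadata: {age_range: [20, 95], proportion_female: 0.5, auc_type: "AUC0-inf"}
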