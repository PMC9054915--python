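# Calibration anchor study: midazolam 2 mg single dose on day 8 of
# ipatasertib 600 mg QD x8.
name: calibration_midazolam_600mg
victim: {compound: midazolam, dose: 2, route: oral, start_time: 168, n_doses: 1}
perpetrator: {compound: ipatasertib, dose: 600, route: oral, interval: 24, n_doses: 8}
trial: {n_trials: 10, n_subjects: 13, seed: 0}
metric: auc_inf_post_dose
follow_up_h: 48
metadata: {age_range: [37, 76], proportion_female: 0.69, auc_type: "AUC0-inf"}
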