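# Calibration anchor study: ipatasertib 100 mg single dose on day 5,
# itraconazole 200 mg QD days 1-9, simulated over 12 days.
name: calibration_itraconazole_100mg
victim: {compound: ipatasertib, dose: 100, route: oral, start_time: 96, n_doses: 1}
perpetrator: {compound: itraconazole, dose: 200, route: oral, interval: 24, n_doses: 9}
trial: {n_trials: 10, n_subjects: 15, seed: 0}
metric: auc_inf_post_dose
follow_up_h: 192
metadata: {age_range: [22, 52], proportion_female: 0.67, auc_type: "AUC0-inf"}
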