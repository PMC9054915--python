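# Application scenario: ipatasertib 400 mg QD x21 with/without efavirenz.
name: table3_efavirenz
victim: {compound: ipatasertib, dose: 400, route: oral, interval: 24, n_doses: 21}
perpetrator: {compound: efavirenz, dose: 600, route: oral, interval: 24, n_doses: 21}
trial: {n_trials: 10, n_subjects: 10, seed: 0}
metric: auc_0_24_last_dose
metadata: {age_range: [20, 95], proportion_female: 0.5, auc_type: "AUC0-24h day 21"}
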