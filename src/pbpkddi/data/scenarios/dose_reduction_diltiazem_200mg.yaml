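# Dose-reduction scenario: ipatasertib 200 mg QD x21 with diltiazem 120 mg BID.
name: dose_reduction_diltiazem_200mg
victim: {compound: ipatasertib, dose: 200, route: oral, interval: 24, n_doses: 21}
perpetrator: {compound: diltiazem, dose: 120, route: oral, interval: 12, n_doses: 42}
trial: {n_trials: 10, n_subjects: 10, seed: 0}
metric: auc_0_24_last_dose
metadata: {auc_type: "AUC0-24h day 21"}
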