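#!/usr/bin/env python
"""Dose–exposure nonlinearity of the calibrated final model.

Simulates apparent oral clearance (dose/AUC) across 25–800 mg after a
single dose and at day-8 steady state, plus a synthetic escalation dataset
with residual error, and contrasts the final model with and without TDI to
show the low-dose nonlinearity is saturation-driven.
"""

from pathlib import Path

import pandas as pd

from pbpkddi import calibration as cal
from pbpkddi import physiology, synthetic_data

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)
phys = physiology.default_healthy_volunteer()
final = cal.calibrated_final_model().apply()

table = cal.simulate_cl_over_f(final, phys)
table.to_csv(OUT / "dose_escalation_clf.csv", index=False)
wide = table.pivot(index="dose", columns="phase", values="cl_over_f").round(1)
print("apparent oral clearance (L/h) by dose:\n", wide, sep="")
lo, hi = wide["single"].loc[400.0], wide["single"].loc[25.0]
print(f"\nCL/F falls {100*(1-lo/hi):.0f}% from 25 to 400 mg "
      f"(more-than-dose-proportional exposure at low doses).")

no_tdi = cal.simulate_cl_over_f(final.without_tdi(), phys, doses=(25.0, 400.0), day8=False)
r_tdi = wide["single"].loc[25.0] / wide["single"].loc[400.0]
r_no = no_tdi["cl_over_f"].iloc[0] / no_tdi["cl_over_f"].iloc[1]
print(f"CL/F(25)/CL/F(400): {r_tdi:.2f} with TDI vs {r_no:.2f} without "
      f"→ saturation, not inactivation, drives the nonlinearity.")

study = synthetic_data.generate_dose_escalation(final, n_per_dose=6, residual_cv=0.2, seed=11)
study.observations.to_csv(OUT / "dose_escalation_synthetic_obs.csv", index=False)
print("wrote results/dose_escalation_clf.csv, dose_escalation_synthetic_obs.csv")
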