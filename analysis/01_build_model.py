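#!/usr/bin/env python
"""Initial model build: distribution and the clearance backbone.

Predicts tissue partition coefficients for ipatasertib (diprotic base,
acidic-phospholipid mechanism), solves the Kp scalar against the observed
Vss of 39.13 L/kg, and translates the record's enzyme kinetics into the
implied IV plasma clearance via the well-stirred liver (the forward view of
the retrograde calculation).
"""

from pathlib import Path

import pandas as pd

from pbpkddi import calibration, compounds, partition, physiology
from pbpkddi.scenarios import fm_cyp3a4_at_trace

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)

phys = physiology.default_healthy_volunteer()
ipa = compounds.ipatasertib_final()

kps = partition.predict_kp_set(ipa, phys)
scalar = partition.find_kp_scalar(ipa, phys, ipa.vss_target, kps=kps)
vss = partition.compute_vss(kps, phys, ipa, scalar)

df = pd.DataFrame(
    [{"tissue": t, "kp_unscaled": round(kp, 3), "kp_scaled": round(scalar * kp, 3)}
     for t, kp in sorted(kps.items())]
)
df.to_csv(OUT / "model_build_kp.csv", index=False)

pw = ipa.cyp3a4
clint = pw.vmax / pw.km  # µL/min/pmol
cl_iv = calibration.forward_iv_clearance(
    clint, ipa.cl_renal, ipa.cl_additional, ipa.fu_plasma, ipa.bp_ratio, phys
)
fm = fm_cyp3a4_at_trace(ipa, phys)

summary = pd.DataFrame([
    {"quantity": "kp_scalar", "value": round(scalar, 4), "units": "-"},
    {"quantity": "vss_check", "value": round(vss, 4), "units": "L/kg"},
    {"quantity": "clint_cyp3a4", "value": round(clint, 4), "units": "uL/min/pmol"},
    {"quantity": "implied_iv_plasma_clearance", "value": round(cl_iv, 2), "units": "L/h"},
    {"quantity": "fm_cyp3a4_trace", "value": round(fm, 3), "units": "fraction"},
])
summary.to_csv(OUT / "model_build_summary.csv", index=False)

print(f"Kp scalar matching Vss {ipa.vss_target} L/kg: {scalar:.3f} (Vss check {vss:.3f})")
print(f"adipose Kp {kps['adipose']:.2f} < muscle Kp {kps['muscle']:.2f} (ionized base)")
print(f"CLint,CYP3A4 = Vmax/Km = {clint:.3f} uL/min/pmol "
      f"→ implied IV plasma clearance {cl_iv:.1f} L/h; fm,CYP3A4(trace) = {fm:.2f}")
print("wrote results/model_build_kp.csv, results/model_build_summary.csv")
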