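#!/usr/bin/env python
"""Dose-reduction question: is 200 mg with a moderate inhibitor comparable
to 400 mg alone?

Compares steady-state exposure of ipatasertib 200 mg QD co-administered with
erythromycin or diltiazem against 400 mg QD alone on the same virtual
population, reporting the geometric-mean ratio with a 90% CI.
"""

from pathlib import Path

import pandas as pd

from pbpkddi import calibration as cal
from pbpkddi import scenarios

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)
SEED = 20260929 % (2**31)

record_final = cal.calibrated_final_model().apply()
ref = scenarios.load_scenario("reference_400mg_alone", seed=SEED).model_copy(
    update={"victim": record_final}
)
rows = []
for name in ("dose_reduction_erythromycin_200mg", "dose_reduction_diltiazem_200mg"):
    red = scenarios.load_scenario(name, seed=SEED).model_copy(
        update={"victim": record_final}
    )
    out = scenarios.dose_reduction_analysis(red, ref)
    g = out["auc_ratio"]
    comparable = 0.7 <= g.geo_mean_ratio <= 1.43
    rows.append(dict(comparison=name, auc_ratio=round(g.geo_mean_ratio, 3),
                     ci90=f"{g.ci90_low:.2f}-{g.ci90_high:.2f}",
                     n=g.n, comparable=comparable))
    print(f"{name}: (200 mg + inhibitor)/(400 mg alone) AUC ratio "
          f"{g.geo_mean_ratio:.2f} (90% CI {g.ci90_low:.2f}-{g.ci90_high:.2f}) "
          f"→ {'comparable' if comparable else 'NOT comparable'}")

pd.DataFrame(rows).to_csv(OUT / "dose_reduction.csv", index=False)
print("wrote results/dose_reduction.csv")
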