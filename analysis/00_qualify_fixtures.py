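#!/usr/bin/env python
"""Gate the perpetrator/substrate fixture library before any analysis.

The perpetrator compound files are assembled from literature, not from the
study itself, so each one must first reproduce its interaction-class
behaviour against an index substrate (midazolam probe for inhibitors and
inducers; structural fm check for midazolam itself).
"""

from pathlib import Path

import pandas as pd

from pbpkddi.scenarios import qualify_fixture

OUT = Path(__file__).resolve().parents[1] / "results"

rows = []
for name in ("itraconazole", "erythromycin", "diltiazem", "fluvoxamine",
             "rifampin", "efavirenz", "midazolam"):
    report = qualify_fixture(name)
    for check in report.checks:
        rows.append(dict(fixture=name, check=check.description,
                         value=round(check.value, 4), passed=check.passed))
        status = "PASS" if check.passed else "FAIL"
        print(f"{status}  {name}: {check.description} = {check.value:.3f}")

df = pd.DataFrame(rows)
OUT.mkdir(exist_ok=True)
df.to_csv(OUT / "fixture_qualification.csv", index=False)
n_fail = int((~df["passed"]).sum())
print(f"\n{len(df)} checks, {n_fail} failures → results/fixture_qualification.csv")
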