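#!/usr/bin/env python
"""1:1 complexation diffusion model vs the measured β-CD table.

Predicts the four mutual-diffusion coefficients from the 1:1 binding
model at the table compositions for the literature Ka = 80 dm³ mol⁻¹,
then estimates Ka from the measured cross coefficients (default
D12-only objective).  Writes results/binding_model.json and
results/dik_predicted_Ka80.csv.
"""

import json
from pathlib import Path

import pandas as pd

from hgdiff.binding import (
    BindingSystem,
    combine_complex_diffusivity,
    fit_association_constant,
    predict_dik_1to1,
)
from hgdiff.core import dik_rows, load_fixture
from hgdiff.io import write_report

OUT = Path(__file__).resolve().parents[1] / "results"

t3 = load_fixture("table3").set_index("species")["D"]
D_G, D_H = float(t3["Sal-"]), float(t3["beta-CD"])
D_GH = combine_complex_diffusivity(D_G, D_H)
rows = dik_rows(load_fixture("table2"))

system80 = BindingSystem(Ka=80.0, D_guest=D_G, D_host=D_H, D_complex=D_GH)
pred = pd.DataFrame([
    {"X1": comp.X1,
     **{f"{c}_pred": getattr(predict_dik_1to1(system80, comp), c)
        for c in ("D11", "D12", "D21", "D22")},
     **{f"{c}_meas": getattr(m, c) for c in ("D11", "D12", "D21", "D22")}}
    for comp, m in rows
])
pred.to_csv(OUT / "dik_predicted_Ka80.csv", index=False)
print("1:1 model at Ka=80 vs measurement:")
print(pred.round(3).to_string(index=False))

fit = fit_association_constant(rows, D_G, D_H, D_GH)
report = {
    "D_complex_used": D_GH,
    "Ka_estimate": fit.Ka,
    "Ka_sd": fit.Ka_sd,
    "objective": list(fit.subset),
    "rss": fit.rss,
    "residuals": fit.residuals,
    "literature_Ka": 80.0,
}
write_report(report, OUT / "binding_model.json")
print(f"\nD12-only Ka estimate: {fit.Ka:.0f} ± {fit.Ka_sd:.0f} dm3/mol "
      f"(literature value 80).")
print("The global estimate is statistically compatible with the literature "
      "80, but the per-row residuals are structured: at Ka=80 the model "
      "underpredicts |D12| at X1>=0.5 (matching the X1=0.5 row alone would "
      "need Ka of several hundred), so the estimate carries a large "
      "uncertainty. With the tabulated free-species diffusivities the model "
      "also cannot reach the measured D11 at X1=1 (electrolyte coupling is "
      "outside the complexation-only model), which is why D11 is excluded "
      "from the default objective.")
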