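#!/usr/bin/env python
"""Job continuous-variation analysis and synthetic NMR titration.

Simulates a noiseless 1:1 Job curve at the study conditions (Ka = 80,
C_total = 0.010 mol dm⁻³) and locates its maximum; contrasts it with a
1:2 curve; then generates a noisy fast-exchange titration at the
published concentrations (2.9 mM drug, host added to ratio ~2.75) and
refits Ka globally across three proton columns.
Writes results/stoichiometry.json and results/job_curve_1to1.csv.
"""

import argparse
from pathlib import Path

import pandas as pd

from hgdiff.io import write_report
from hgdiff.stoichiometry import estimate_stoichiometry, fit_titration, job_curve
from hgdiff.synthetic import generate_titration_dataset

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=5)
args = parser.parse_args()

OUT = Path(__file__).resolve().parents[1] / "results"

series = job_curve(Ka=80.0, C_total=0.010, n=201)
est11 = estimate_stoichiometry(series)
pd.DataFrame({"x": series.x, "response": series.y}).to_csv(
    OUT / "job_curve_1to1.csv", index=False)
est12 = estimate_stoichiometry(job_curve(Ka=1e4, C_total=0.010, n=401,
                                         stoich=(1, 2)))

ddmax_true = {"H3": 0.31, "H4": -0.12, "H6": 0.22}
tit, record = generate_titration_dataset(80.0, ddmax_true, C_guest=0.0029,
                                         sigma=0.002, seed=args.seed)
fit = fit_titration(tit)

report = {
    "job_1to1": est11,
    "job_1to2": est12,
    "titration_truth": record.truth,
    "titration_fit": {"Ka": fit.Ka, "Ka_sd": fit.Ka_sd,
                      "ddelta_max": fit.ddelta_max, "rss": fit.rss},
}
write_report(report, OUT / "stoichiometry.json")

print(f"1:1 Job maximum at x = {est11['x_max']:.4f} "
      f"(inferred guest:host ratio {est11['ratio']:.2f}) — a maximum at "
      "~0.5 is the continuous-variation signature of 1:1 binding.")
print(f"1:2 control curve peaks at x = {est12['x_max']:.3f} (ratio "
      f"{est12['ratio']:.2f}), confirming the estimator distinguishes "
      "stoichiometries.")
print(f"Titration refit: Ka = {fit.Ka:.1f} ± {fit.Ka_sd:.1f} dm3/mol "
      f"(truth 80); limiting shifts {dict((k, round(v, 3)) for k, v in fit.ddelta_max.items())} "
      f"(truth {ddmax_true}); signed shifts preserved.")
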