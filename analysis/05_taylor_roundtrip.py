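#!/usr/bin/env python
"""Taylor dispersion chain: simulate, fit, and invert dispersion peaks.

Demonstrates the full measurement model on the strongly coupled midpoint
composition of the β-CD system, then runs a replicate study on random
valid matrices at peak SNR 10³ to quantify how precisely the chain
recovers a diffusion matrix.  Writes results/taylor_roundtrip.json.
"""

import argparse
import warnings
from pathlib import Path

import numpy as np

from hgdiff.core import DiffusionMatrix
from hgdiff.io import write_report
from hgdiff.synthetic import generate_peak_dataset, taylor_roundtrip_study
from hgdiff.taylor import InjectionProfile, default_instrument, fit_peak, refine_dik

warnings.filterwarnings("ignore", message=".*Covariance.*")

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=7)
parser.add_argument("--replicates", type=int, default=40)
args = parser.parse_args()

OUT = Path(__file__).resolve().parents[1] / "results"
inst = default_instrument()
injs = [InjectionProfile(1e-3, 0.0), InjectionProfile(0.0, 1e-3)]

truth = DiffusionMatrix(D11=1.009, D12=-0.220, D21=0.050, D22=0.446)
peaks, record = generate_peak_dataset(truth, inst, injs, sigma=1e-6,
                                      seed=args.seed)
fits = [fit_peak(p) for p in peaks]
rec = refine_dik(peaks, injs, fits=fits)
print(f"Instrument: tube L={inst.L} m, r={inst.r*1e3:.3f} mm, "
      f"geometric tR={inst.tR:.0f} s, {peaks[0].t.size} samples/peak")
print("Truth matrix (1e-9 m2/s):\n", truth.as_array().round(4))
print("Recovered from two noisy peaks:\n", rec.as_array().round(4))

study = taylor_roundtrip_study(args.replicates, seed=args.seed, snr=1e3,
                               instrument=inst)
errs = np.array([r["max_rel_err"] for r in study])
frac = float(np.mean(errs <= 0.01))
summary = {
    "demo": {"truth": record.truth["matrix"],
             "recovered": {"D11": rec.D11, "D12": rec.D12,
                           "D21": rec.D21, "D22": rec.D22}},
    "replicates": args.replicates,
    "snr": 1e3,
    "fraction_within_1pc_of_scale": frac,
    "median_max_rel_err": float(np.median(errs[np.isfinite(errs)])),
}
write_report(summary, OUT / "taylor_roundtrip.json")
print(f"\nReplicate study ({args.replicates} matrices, SNR 1e3): "
      f"{100*frac:.0f}% recovered within 1% of the largest coefficient; "
      f"median worst-element error {summary['median_max_rel_err']*100:.2f}%.")
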