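#!/usr/bin/env python
"""Perfusion analysis: max-slope MBF and the summed stress score.

Simulates a stress acquisition with three hypoperfused segments and
writes the per-segment MBF/score table plus recovery diagnostics.

Outputs (under results/): perfusion_segments.csv, perfusion_summary.json
"""

import argparse
import json
from pathlib import Path

import numpy as np

from ctecv import phantom as ph
from ctecv.perfusion import analyze_perfusion

parser = argparse.ArgumentParser(description=__doc__)
parser.add_argument("--seed", type=int, default=0)
parser.add_argument("--noise-sd", type=float, default=0.0,
                    help="HU noise on the curves")
parser.add_argument("--out", type=Path, default=Path("results"))
args = parser.parse_args()
args.out.mkdir(parents=True, exist_ok=True)

true_mbf = np.full(16, 110.0)
true_mbf[3] = 78.0    # normalized 0.71 -> score 1
true_mbf[8] = 70.0    # 0.64 -> score 2
true_mbf[13] = 50.0   # 0.45 -> score 3

spec = ph.PhantomSpec(seed=args.seed)
t, arterial, tissue, truth = ph.generate_perfusion_series(
    spec, true_mbf, noise_sd=args.noise_sd)
res = analyze_perfusion(tissue, arterial, t[1] - t[0])

df = res.segments.copy()
df["true_mbf"] = true_mbf
df["rel_error"] = (df["mbf"] - true_mbf) / true_mbf
df.to_csv(args.out / "perfusion_segments.csv")

summary = {
    "global_mbf": res.global_mbf,
    "true_global_mbf": float(true_mbf.mean()),
    "sss": res.sss,
    "true_sss": 6,
    "max_rel_error": float(np.abs(df["rel_error"]).max()),
    "noise_sd": args.noise_sd,
}
(args.out / "perfusion_summary.json").write_text(json.dumps(summary, indent=1))
print(f"global MBF {res.global_mbf:.1f} (truth {true_mbf.mean():.1f}) "
      f"mL/100mL/min; SSS = {res.sss}; "
      f"max relative MBF error {summary['max_rel_error']:.3%}")
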