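#!/usr/bin/env python
"""Bootstrap mediation: does the ALPS index carry part of the association
between putamen PVS volume fraction and global cognition (MoCA) in the
patient group?  Covariates: demographics and vascular risk factors.

Run:  python analysis/05_mediation.py [--seed 1]
"""

import argparse
from pathlib import Path

from glymphkit.pipeline import PipelineConfig, run_pipeline

ap = argparse.ArgumentParser()
ap.add_argument("--seed", type=int, default=1)
ap.add_argument("--n-boot", type=int, default=5000)
args = ap.parse_args()

cfg = PipelineConfig(seed=args.seed, n_boot=args.n_boot, write_volumes=False)
summary = run_pipeline(cfg, Path("results"), stages=("simulate", "mediate", "report"))

m = summary["mediate"]
print(f"paths (n={m['n']}, {m['n_boot']} bootstrap replicates):")
print(f"  a  (X->M):        {m['a']:+.4f}")
print(f"  b  (M->Y | X):    {m['b']:+.4f}")
print(f"  c' (X->Y | M):    {m['c_prime']:+.4f}")
print(f"  c  (total X->Y):  {m['c']:+.4f}")
print(f"  indirect a*b:     {m['indirect']:+.4f}  "
      f"95% CI [{m['ci_low']:.4f}, {m['ci_high']:.4f}]")
verdict = "significant" if m["significant"] else "not significant"
pct = f"{m['mediation_percent']:.1f}%" if m["mediation_percent"] is not None else "undefined"
print(f"  -> indirect effect {verdict} (CI excludes 0: {m['significant']}); "
      f"mediated share {pct}")
print("-> results/mediation.json, results/summary.json")
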