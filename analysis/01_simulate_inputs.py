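#!/usr/bin/env python
"""Generate the study inputs: a three-group cohort with planted mediation
structure, plus DWI and structural PVS phantoms with ground truth.

Tables and sidecars go to results/; NIfTI volumes go to scratch/ (large,
regenerable).  Run:  python analysis/01_simulate_inputs.py [--seed 1]
"""

import argparse
from pathlib import Path

from glymphkit import io as gio
from glymphkit.pipeline import PipelineConfig, run_pipeline
from glymphkit.synthetic import (
    alps_phantom_spec,
    make_dwi_phantom,
    make_pvs_phantom,
    standard_pvs_phantom_spec,
)

ap = argparse.ArgumentParser()
ap.add_argument("--seed", type=int, default=1)
args = ap.parse_args()

results = Path("results")
scratch = Path("scratch/volumes")
scratch.mkdir(parents=True, exist_ok=True)

cfg = PipelineConfig(seed=args.seed, write_volumes=False)
summary = run_pipeline(cfg, results, stages=("simulate",))
print(f"cohort: {summary['simulate']['n_subjects']} subjects "
      f"(planted indirect effect {summary['simulate']['planted_indirect']:.3f}) "
      f"-> results/cohort.csv")

dwi_spec = alps_phantom_spec(snr=None, seed=args.seed)
dwi, _ = make_dwi_phantom(dwi_spec)
gio.save_dwi(scratch / "alps_phantom", dwi)
print(f"DWI phantom: grid {dwi.signal.shape}, {dwi.n_b0} b0 + "
      f"{len(dwi.bvalues) - dwi.n_b0} diffusion volumes -> scratch/volumes/")

from glymphkit.atlas import write_region_lookup

write_region_lookup(results / "region_codes.json")

pvs_spec = standard_pvs_phantom_spec(noise_fraction=0.05, seed=args.seed)
t1w, t2w, atlas, gt = make_pvs_phantom(pvs_spec)
gio.save_nifti(scratch / "pvs_t1w.nii.gz", t1w, pvs_spec.affine)
gio.save_nifti(scratch / "pvs_t2w.nii.gz", t2w, pvs_spec.affine)
gio.save_nifti(scratch / "pvs_truth.nii.gz", gt.astype("uint8"), pvs_spec.affine)
print(f"PVS phantom: {len(pvs_spec.tubes)} tubes, {int(gt.sum())} ground-truth "
      f"voxels -> scratch/volumes/")
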