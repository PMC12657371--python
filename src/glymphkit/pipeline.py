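"""End-to-end orchestration: simulate -> ALPS -> PVS -> statistics -> report.

The pipeline reproduces the result structure of a glymphatic-function
study on fully synthetic inputs: phantom-derived ALPS indices and PVS
volume fractions with ground truth, and a cohort-level statistical report
(group-comparison table, partial-correlation matrix with FDR, and a
bootstrap mediation decomposition).  Every output is a pure function of
the configuration and seed; the config hash and seed are embedded in the
JSON summary.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as gio
from .dti_alps import RoiSpec, compute_alps, fit_tensors
from .pvs import FrangiParams, StructuralPair, quantify_pvs
from .stats import (
    fdr_adjust,
    group_compare,
    mediate,
    partial_correlation,
    zscore_cognition,
)
from .synthetic import (
    CohortSpec,
    alps_phantom_spec,
    default_alps_rois,
    isotropic_phantom_spec,
    make_cohort,
    make_dwi_phantom,
    make_pvs_phantom,
    standard_pvs_phantom_spec,
)

logger = logging.getLogger("glymphkit")

STAGES = ("simulate", "alps", "pvs", "zscore", "compare", "correlate", "mediate", "report")

#: covariate set for ALPS ~ PVS partial correlations (demographics + VRFs)
ALPS_PVS_COVARIATES = (
    "age",
    "sex",
    "education",
    "hypertension",
    "diabetes",
    "hypercholesterolemia",
    "smoking",
    "bmi",
)
#: ALPS ~ cognition adds the imaging markers
ALPS_COGNITION_COVARIATES = ALPS_PVS_COVARIATES + (
    "fazekas",
    "lacunes",
    "cmbs",
    "bg_epvs_grade",
)

_PVS_VF_COLUMNS = (
    "pvs_vf_bg",
    "pvs_vf_caudate",
    "pvs_vf_putamen",
    "pvs_vf_pallidum",
    "pvs_vf_amygdala",
    "pvs_vf_thalamus",
    "pvs_vf_hippocampus",
)
_COGNITION_COLUMNS = (
    "moca",
    "z_memory",
    "z_executive",
    "z_processing_speed",
    "z_visuospatial",
    "z_language",
)


@dataclass
class PipelineConfig:
    """Validated configuration of the end-to-end pipeline."""

    seed: int = 1
    # cohort
    n_hc: int = 40
    n_nci: int = 52
    n_mci: int = 68
    # DWI phantom
    dwi_grid: tuple[int, int, int] = (32, 32, 32)
    dwi_snr: float | None = None
    roi_diameter: float = 5.0
    rois: list[dict] | None = None  # explicit ROI table overrides phantom defaults
    # PVS phantom + quantification
    pvs_noise_fraction: float = 0.05
    pvs_contrast: float = 0.3
    frangi: FrangiParams = field(default_factory=FrangiParams)
    threshold: float = 0.1
    min_cluster_voxels: int = 3
    # statistics
    covariates_alps_pvs: tuple[str, ...] = ALPS_PVS_COVARIATES
    covariates_alps_cognition: tuple[str, ...] = ALPS_COGNITION_COVARIATES
    mediation_x: str = "pvs_vf_putamen"
    mediation_m: str = "alps"
    mediation_y: str = "moca"
    n_boot: int = 5000
    ci: float = 95.0
    write_volumes: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = gio.load_yaml(path) or {}
        frangi = FrangiParams(**raw.pop("frangi", {}))
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(frangi=frangi, **raw)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if self.rois is not None:
            for r in self.rois:
                RoiSpec(**r)  # raises on malformed entries
        if not 0 < self.threshold <= 1:
            raise ValueError("threshold must lie in (0, 1]")
        for c in self.covariates_alps_pvs + self.covariates_alps_cognition:
            if not isinstance(c, str):
                raise ValueError("covariate names must be strings")

    def config_hash(self) -> str:
        payload = asdict(self)
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def _derived_seed(seed: int, offset: int) -> int:
    return (seed * 1000 + offset) % (2**31 - 1)


def run_pipeline(
    config: PipelineConfig, out_dir: str | Path, stages: tuple[str, ...] = STAGES
) -> dict:
    """Execute the requested stages in order and write their outputs.

    Returns the machine-readable summary (also written to summary.json
    when the ``report`` stage runs).  Stage failures raise with the stage
    name attached; outputs of completed stages remain on disk.
    """
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stages": list(stages),
    }
    state: dict = {}
    for stage in stages:
        if stage not in STAGES:
            raise ValueError(f"unknown stage {stage!r}")
    t_all = time.time()
    try:
        if "simulate" in stages or {"alps", "pvs", "zscore", "compare", "correlate", "mediate"} & set(stages):
            _stage_simulate(config, out, state, summary)
        if "alps" in stages:
            _stage_alps(config, out, state, summary)
        if "pvs" in stages:
            _stage_pvs(config, out, state, summary)
        if "zscore" in stages:
            _stage_zscore(config, out, state, summary)
        if "compare" in stages:
            _stage_compare(config, out, state, summary)
        if "correlate" in stages:
            _stage_correlate(config, out, state, summary)
        if "mediate" in stages:
            _stage_mediate(config, out, state, summary)
    except Exception as exc:  # annotate with the failing stage
        raise RuntimeError(f"pipeline stage failed: {exc}") from exc
    summary["runtime_s"] = round(time.time() - t_all, 3)
    if "report" in stages:
        gio.save_json(out / "summary.json", _without_runtime(summary))
    return summary


def _without_runtime(summary: dict) -> dict:
    """Summary without wall-clock fields, so repeated runs are byte-identical."""
    return {k: v for k, v in summary.items() if k != "runtime_s"}


def _stage_simulate(config, out, state, summary) -> None:
    t0 = time.time()
    cohort, truth = make_cohort(
        CohortSpec(
            n_hc=config.n_hc,
            n_nci=config.n_nci,
            n_mci=config.n_mci,
            seed=_derived_seed(config.seed, 1),
        )
    )
    cohort.to_csv(out / "cohort.csv", index=False, float_format="%.6g")
    gio.save_json(out / "cohort_truth.json", truth)
    state["cohort"] = cohort
    state["truth"] = truth
    summary["simulate"] = {
        "n_subjects": len(cohort),
        "planted_indirect": truth["indirect"],
    }
    logger.info("simulate: %d subjects in %.2fs", len(cohort), time.time() - t0)


def _stage_alps(config, out, state, summary) -> None:
    t0 = time.time()
    results = {}
    for name, spec in (
        ("fiber_phantom", alps_phantom_spec(
            grid_shape=config.dwi_grid, snr=config.dwi_snr,
            seed=_derived_seed(config.seed, 2))),
        ("isotropic_phantom", isotropic_phantom_spec(
            grid_shape=config.dwi_grid, snr=config.dwi_snr,
            seed=_derived_seed(config.seed, 3))),
    ):
        dwi, gt = make_dwi_phantom(spec)
        field_ = fit_tensors(dwi)
        if config.rois:
            rois = [RoiSpec(**r) for r in config.rois]
            roi_p = next(r for r in rois if r.fiber_type == "projection")
            roi_a = next(r for r in rois if r.fiber_type == "association")
        else:
            roi_p, roi_a = default_alps_rois(spec, diameter=config.roi_diameter)
        res = compute_alps(field_, roi_p, roi_a)
        results[name] = res.as_dict()
        results[name]["max_tensor_error_mm2_s"] = float(
            np.abs(field_.tensor - gt.tensor).max()
        )
        if config.write_volumes:
            gio.save_nifti(out / f"{name}_fa.nii.gz", field_.fa, dwi.affine)
            gio.save_nifti(out / f"{name}_color_fa.nii.gz", field_.color_fa, dwi.affine)
    gio.save_json(out / "alps_phantom.json", results)
    summary["alps"] = results
    logger.info("alps: index=%.4f in %.2fs", results["fiber_phantom"]["alps_index"], time.time() - t0)


def _stage_pvs(config, out, state, summary) -> None:
    t0 = time.time()
    spec = standard_pvs_phantom_spec(
        noise_fraction=config.pvs_noise_fraction,
        contrast=config.pvs_contrast,
        seed=_derived_seed(config.seed, 4),
    )
    t1w, t2w, atlas, gt = make_pvs_phantom(spec)
    pair = StructuralPair(t1w, t2w, spec.voxel_size, spec.affine)
    table, mask, vmap = quantify_pvs(
        pair,
        atlas,
        frangi=config.frangi,
        threshold=config.threshold,
        min_cluster_voxels=config.min_cluster_voxels,
        denoise=config.pvs_noise_fraction > 0,
    )
    table.to_csv(out / "pvs_results.csv", index=False)
    inter = int((mask & gt).sum())
    stats = {
        "dice": 2.0 * inter / max(int(mask.sum()) + int(gt.sum()), 1),
        "sensitivity": inter / max(int(gt.sum()), 1),
        "gt_voxels": int(gt.sum()),
        "segmented_voxels": int(mask.sum()),
        "total_vf_percent": float(
            table.query("region == 'bg' and hemisphere == 'total'")["vf_percent"].iloc[0]
        ),
    }
    if config.write_volumes:
        gio.save_nifti(out / "pvs_vesselness.nii.gz", vmap.v, spec.affine)
        gio.save_nifti(out / "pvs_mask.nii.gz", mask.astype(np.uint8), spec.affine)
    gio.save_json(out / "pvs_phantom.json", stats)
    summary["pvs"] = stats
    logger.info("pvs: dice=%.3f in %.2fs", stats["dice"], time.time() - t0)


def _stage_zscore(config, out, state, summary) -> None:
    cohort = state["cohort"]
    z = zscore_cognition(cohort)
    cohort = pd.concat([cohort, z], axis=1)
    cohort.to_csv(out / "cohort_with_z.csv", index=False, float_format="%.6g")
    state["cohort"] = cohort
    hc = z[cohort["group"] == "HC"]
    summary["zscore"] = {
        "hc_means": {c: round(float(hc[c].mean()), 10) for c in z.columns},
        "hc_sds": {c: round(float(hc[c].std(ddof=1)), 10) for c in z.columns},
    }


def _stage_compare(config, out, state, summary) -> None:
    cohort = state["cohort"]
    continuous = ["age", "education", "bmi", "moca", "alps", *list(_PVS_VF_COLUMNS)]
    categorical = [
        "sex",
        "hypertension",
        "diabetes",
        "hypercholesterolemia",
        "smoking",
        "lacunes",
        "cmbs",
        "bg_epvs_grade",
    ]
    rows = []
    for var in continuous + categorical:
        kind = "categorical" if var in categorical else "continuous"
        gc = group_compare(cohort[var].to_numpy(), cohort["group"].to_numpy(), kind=kind)
        row = {"variable": var, "test": gc.test, "statistic": gc.statistic, "p": gc.p}
        if gc.pairwise_p:
            for (a, b), p in gc.pairwise_p.items():
                row[f"p_{a}_vs_{b}"] = p
        rows.append(row)
    table = pd.DataFrame(rows)
    table.to_csv(out / "group_comparison.csv", index=False)
    summary["compare"] = {
        r["variable"]: {"test": r["test"], "p": r["p"]} for r in rows
    }


def _stage_correlate(config, out, state, summary) -> None:
    cohort = state["cohort"]
    csvd = cohort[cohort["group"] != "HC"]
    rows = []
    for y in _PVS_VF_COLUMNS:
        pr = partial_correlation(
            csvd["alps"], csvd[y],
            csvd[list(config.covariates_alps_pvs)], names=("alps", y),
        )
        rows.append({"family": "alps_vs_pvs", "x": "alps", "y": y, "r": pr.r,
                     "dof": pr.dof, "p": pr.p})
    for y in _COGNITION_COLUMNS:
        if y not in csvd.columns:
            continue
        pr = partial_correlation(
            csvd["alps"], csvd[y],
            csvd[list(config.covariates_alps_cognition)], names=("alps", y),
        )
        rows.append({"family": "alps_vs_cognition", "x": "alps", "y": y, "r": pr.r,
                     "dof": pr.dof, "p": pr.p})
    table = pd.DataFrame(rows)
    table["q"] = fdr_adjust(table["p"].to_numpy(), table["family"].to_numpy())
    table.to_csv(out / "correlations.csv", index=False)
    summary["correlate"] = {
        f"{r.family}:{r.y}": {"r": round(r.r, 6), "p": round(r.p, 6), "q": round(r.q, 6)}
        for r in table.itertuples()
    }


def _stage_mediate(config, out, state, summary) -> None:
    cohort = state["cohort"]
    csvd = cohort[cohort["group"] != "HC"]
    res = mediate(
        csvd,
        config.mediation_x,
        config.mediation_m,
        config.mediation_y,
        covariates=config.covariates_alps_pvs,
        n_boot=config.n_boot,
        ci=config.ci,
        seed=_derived_seed(config.seed, 5),
    )
    payload = {
        "x": config.mediation_x,
        "m": config.mediation_m,
        "y": config.mediation_y,
        "a": res.a,
        "b": res.b,
        "c": res.c,
        "c_prime": res.c_prime,
        "indirect": res.indirect,
        "ci_low": res.ci_low,
        "ci_high": res.ci_high,
        "significant": res.significant,
        "mediation_percent": None if np.isnan(res.mediation_percent) else res.mediation_percent,
        "standardized": res.standardized,
        "n": res.n,
        "n_boot": res.n_boot,
    }
    gio.save_json(out / "mediation.json", payload)
    summary["mediate"] = payload
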