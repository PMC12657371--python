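"""File-format plumbing: NIfTI volumes, FSL-style bval/bvec text, YAML
configs and JSON sidecars."""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import yaml

from .dti_alps import DiffusionVolume

__all__ = [
    "save_nifti",
    "load_nifti",
    "save_dwi",
    "load_dwi",
    "read_bvals_bvecs",
    "write_bvals_bvecs",
    "load_yaml",
    "save_json",
]


def save_nifti(path: str | Path, data: np.ndarray, affine: np.ndarray) -> None:
    nib.save(nib.Nifti1Image(np.asarray(data), np.asarray(affine)), str(path))


def load_nifti(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    img = nib.load(str(path))
    return np.asarray(img.get_fdata()), np.asarray(img.affine)


def write_bvals_bvecs(prefix: str | Path, bvals: np.ndarray, bvecs: np.ndarray) -> None:
    """FSL convention: one row of b-values; bvecs as 3 rows (x, y, z)."""
    prefix = Path(prefix)
    np.savetxt(prefix.with_suffix(".bval"), np.atleast_2d(bvals), fmt="%.6g")
    np.savetxt(prefix.with_suffix(".bvec"), np.asarray(bvecs).T, fmt="%.8f")


def read_bvals_bvecs(prefix: str | Path) -> tuple[np.ndarray, np.ndarray]:
    prefix = Path(prefix)
    bvals = np.loadtxt(prefix.with_suffix(".bval")).ravel()
    bvecs = np.loadtxt(prefix.with_suffix(".bvec")).T
    return bvals, bvecs


def save_dwi(prefix: str | Path, dwi: DiffusionVolume) -> None:
    """Write <prefix>.nii.gz plus <prefix>.bval/.bvec."""
    prefix = Path(prefix)
    save_nifti(prefix.with_suffix(".nii.gz"), dwi.signal, dwi.affine)
    write_bvals_bvecs(prefix, dwi.bvalues, dwi.bvecs)


def load_dwi(prefix: str | Path) -> DiffusionVolume:
    prefix = Path(prefix)
    data, affine = load_nifti(prefix.with_suffix(".nii.gz"))
    bvals, bvecs = read_bvals_bvecs(prefix)
    voxel_size = tuple(np.linalg.norm(affine[:3, :3], axis=0))
    return DiffusionVolume(
        signal=data, bvalues=bvals, bvecs=bvecs, voxel_size=voxel_size, affine=affine
    )


def load_yaml(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def save_json(path: str | Path, payload: dict) -> None:
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
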