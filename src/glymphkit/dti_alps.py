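"""Diffusion-tensor fitting and the DTI-ALPS glymphatic index.

The ALPS (Analysis aLong the Perivascular Space) index summarises water
diffusivity along the perivascular direction (the scanner x-axis, at the
level of the lateral-ventricle body) relative to diffusivity perpendicular
to it inside two fiber systems:

    ALPS = mean(Dxx_proj, Dxx_assoc) / mean(Dyy_proj, Dzz_assoc)

where ``proj`` is a spherical ROI in the projection-fiber bundle (fibers
along z) and ``assoc`` one in the association-fiber bundle (fibers along
y).  Diagonal diffusivities are read off the tensor in the native image
axes: no reorientation is applied, which assumes an axial acquisition
aligned with the scanner frame.

The tensor itself is estimated voxel-wise from the mono-exponential DTI
signal model ``S = S0 * exp(-b g^T D g)`` by (weighted) log-linear least
squares.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DiffusionVolume",
    "TensorField",
    "RoiSpec",
    "AlpsResult",
    "fit_tensors",
    "sphere_roi",
    "extract_diffusivities",
    "alps_index",
    "compute_alps",
    "fractional_anisotropy",
    "tensor_field_from_tensors",
]

_B0_TOL = 1e-6


# ---------------------------------------------------------------------------
# containers


@dataclass
class DiffusionVolume:
    """A 4D diffusion-weighted acquisition plus its gradient table.

    Parameters
    ----------
    signal : ndarray, shape (x, y, z, n_volumes)
        Non-negative magnitude signal.
    bvalues : ndarray, shape (n_volumes,)
        b-values in s/mm^2; at least one must be zero.
    bvecs : ndarray, shape (n_volumes, 3)
        Unit gradient directions for b > 0 volumes (b = 0 rows may be zero).
    voxel_size : tuple of float
        Voxel edge lengths in mm.
    affine : ndarray, shape (4, 4)
        Voxel-to-world transform (RAS mm).
    """

    signal: np.ndarray
    bvalues: np.ndarray
    bvecs: np.ndarray
    voxel_size: tuple[float, float, float]
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        self.bvalues = np.asarray(self.bvalues, dtype=float).ravel()
        self.bvecs = np.asarray(self.bvecs, dtype=float).reshape(-1, 3)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.signal.ndim != 4:
            raise ValueError("signal must be 4D (x, y, z, volume)")
        n = self.signal.shape[-1]
        if len(self.bvalues) != n or len(self.bvecs) != n:
            raise ValueError("bvalues/bvecs length must match the number of volumes")
        if np.any(self.signal < 0):
            raise ValueError("signal must be non-negative")
        if not np.any(self.bvalues <= _B0_TOL):
            raise ValueError("at least one b=0 volume is required")
        dwi = self.bvalues > _B0_TOL
        norms = np.linalg.norm(self.bvecs[dwi], axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-8):
            raise ValueError("all b>0 gradient directions must have unit norm")

    @property
    def n_b0(self) -> int:
        return int(np.sum(self.bvalues <= _B0_TOL))


@dataclass
class TensorField:
    """Per-voxel diffusion tensor with derived eigensystem, FA and color-FA.

    ``flagged`` marks voxels where the fit was impossible (all-zero signal);
    those tensors are identically zero and are excluded from ROI statistics.
    Negative eigenvalues are clamped to zero for FA/color-FA only; the raw
    tensor (and hence the diagonal diffusivities entering the ALPS ratio)
    is retained as fitted.
    """

    tensor: np.ndarray              # (..., 3, 3) symmetric, mm^2/s
    eigenvalues: np.ndarray         # (..., 3) sorted descending
    principal_direction: np.ndarray  # (..., 3) eigenvector of lambda_1
    fa: np.ndarray                  # (...,) in [0, 1]
    color_fa: np.ndarray            # (..., 3) RGB = |e1| * FA
    flagged: np.ndarray             # (...,) bool
    voxel_size: tuple[float, float, float]
    affine: np.ndarray

    @property
    def shape(self) -> tuple[int, ...]:
        return self.tensor.shape[:-2]


@dataclass
class RoiSpec:
    """A spherical region of interest in world (mm) coordinates."""

    center: tuple[float, float, float]
    diameter: float = 5.0
    fiber_type: str = "projection"
    hemisphere: str = "left"

    def __post_init__(self) -> None:
        if self.diameter <= 0:
            raise ValueError("ROI diameter must be positive")
        if self.fiber_type not in ("projection", "association"):
            raise ValueError("fiber_type must be 'projection' or 'association'")


@dataclass
class AlpsResult:
    """ALPS index with the four ROI-mean diagonal diffusivities behind it."""

    dxx_proj: float
    dxx_assoc: float
    dyy_proj: float
    dzz_assoc: float
    alps_index: float
    hemisphere: str = "left"

    def as_dict(self) -> dict:
        return {
            "dxx_proj": self.dxx_proj,
            "dxx_assoc": self.dxx_assoc,
            "dyy_proj": self.dyy_proj,
            "dzz_assoc": self.dzz_assoc,
            "alps_index": self.alps_index,
            "hemisphere": self.hemisphere,
        }


# ---------------------------------------------------------------------------
# tensor math


def fractional_anisotropy(eigenvalues: np.ndarray) -> np.ndarray:
    """FA from eigenvalues (last axis), negatives clamped to zero.

    FA = sqrt(3/2) * ||lambda - mean(lambda)|| / ||lambda||, zero where the
    tensor is zero.
    """
    lam = np.clip(np.asarray(eigenvalues, dtype=float), 0.0, None)
    mean = lam.mean(axis=-1, keepdims=True)
    num = np.sqrt(((lam - mean) ** 2).sum(axis=-1))
    den = np.sqrt((lam**2).sum(axis=-1))
    with np.errstate(invalid="ignore", divide="ignore"):
        fa = np.sqrt(1.5) * num / den
    fa = np.where(den > 0, fa, 0.0)
    return np.clip(fa, 0.0, 1.0)


def tensor_field_from_tensors(
    tensor: np.ndarray,
    voxel_size: tuple[float, float, float],
    affine: np.ndarray,
    flagged: np.ndarray | None = None,
) -> TensorField:
    """Build a :class:`TensorField` (eigensystem, FA, color-FA) from raw tensors."""
    tensor = np.asarray(tensor, dtype=float)
    if flagged is None:
        flagged = np.zeros(tensor.shape[:-2], dtype=bool)
    evals, evecs = np.linalg.eigh(tensor)  # ascending
    evals = evals[..., ::-1]
    principal = evecs[..., :, ::-1][..., :, 0]
    fa = fractional_anisotropy(evals)
    color = np.abs(principal) * fa[..., None]
    fa = np.where(flagged, 0.0, fa)
    color = np.where(flagged[..., None], 0.0, color)
    return TensorField(
        tensor=tensor,
        eigenvalues=evals,
        principal_direction=principal,
        fa=fa,
        color_fa=np.clip(color, 0.0, 1.0),
        flagged=flagged,
        voxel_size=tuple(voxel_size),
        affine=np.asarray(affine, dtype=float),
    )


def _design_matrix(bvalues: np.ndarray, bvecs: np.ndarray) -> np.ndarray:
    """Rows map the 6 unique tensor components (xx, yy, zz, xy, xz, yz)
    to -b * g^T D g."""
    g = bvecs
    b = bvalues[:, None]
    return -b * np.column_stack(
        [
            g[:, 0] ** 2,
            g[:, 1] ** 2,
            g[:, 2] ** 2,
            2 * g[:, 0] * g[:, 1],
            2 * g[:, 0] * g[:, 2],
            2 * g[:, 1] * g[:, 2],
        ]
    )


def _components_to_tensor(d6: np.ndarray) -> np.ndarray:
    """(..., 6) -> (..., 3, 3) symmetric."""
    t = np.empty(d6.shape[:-1] + (3, 3), dtype=float)
    t[..., 0, 0] = d6[..., 0]
    t[..., 1, 1] = d6[..., 1]
    t[..., 2, 2] = d6[..., 2]
    t[..., 0, 1] = t[..., 1, 0] = d6[..., 3]
    t[..., 0, 2] = t[..., 2, 0] = d6[..., 4]
    t[..., 1, 2] = t[..., 2, 1] = d6[..., 5]
    return t


def fit_tensors(dwi: DiffusionVolume, method: str = "wls") -> TensorField:
    """Voxel-wise (weighted) log-linear diffusion-tensor fit.

    Per voxel solves ``ln(S/S0) = -b g^T D g`` over the b > 0 volumes with
    S0 the mean of all b = 0 volumes.  ``method='ols'`` is the ordinary
    log-linear fit; ``method='wls'`` (default) re-weights once with the
    squared predicted signal, the standard correction for the
    log-transformed noise.

    Voxels with non-positive S0 or signal are flagged and get a zero tensor.

    Raises
    ------
    ValueError
        If fewer than 6 independent gradient directions are available.
    """
    if method not in ("ols", "wls"):
        raise ValueError("method must be 'ols' or 'wls'")
    b0_mask = dwi.bvalues <= _B0_TOL
    dwi_mask = ~b0_mask
    if dwi_mask.sum() < 6:
        raise ValueError("tensor fit requires at least 6 b>0 volumes")
    A = _design_matrix(dwi.bvalues[dwi_mask], dwi.bvecs[dwi_mask])
    if np.linalg.matrix_rank(A) < 6:
        raise ValueError(
            "gradient scheme is degenerate: fewer than 6 independent directions"
        )

    shape = dwi.signal.shape[:3]
    s0 = dwi.signal[..., b0_mask].mean(axis=-1)
    s = dwi.signal[..., dwi_mask]

    flagged = (s0 <= 0) | np.any(s <= 0, axis=-1)
    valid = ~flagged
    d6 = np.zeros(shape + (6,), dtype=float)
    if np.any(valid):
        y = np.log(s[valid] / s0[valid][:, None])  # (nvox, nvol)
        sol = np.linalg.lstsq(A, y.T, rcond=None)[0].T  # (nvox, 6)
        if method == "wls":
            pred = np.exp(sol @ A.T)  # predicted S/S0 from the OLS pass
            w = pred**2
            # batched weighted normal equations: (A^T W A) d = A^T W y
            lhs = np.einsum("nj,vn,nk->vjk", A, w, A)
            rhs = np.einsum("nj,vn,vn->vj", A, w, y)
            sol = np.linalg.solve(lhs, rhs[..., None])[..., 0]
        d6[valid] = sol
    tensor = _components_to_tensor(d6)
    tensor[flagged] = 0.0
    return tensor_field_from_tensors(tensor, dwi.voxel_size, dwi.affine, flagged)


# ---------------------------------------------------------------------------
# ROI extraction and the ALPS ratio


def _voxel_centers_world(shape: tuple[int, ...], affine: np.ndarray) -> np.ndarray:
    idx = np.indices(shape).reshape(3, -1).T.astype(float)
    return idx @ affine[:3, :3].T + affine[:3, 3]


def sphere_roi(roi: RoiSpec, fieldlike: TensorField) -> np.ndarray:
    """Boolean mask of voxels whose centers lie within the ROI sphere.

    Raises ``ValueError`` if the center is outside the volume or no voxel
    center falls inside the sphere.
    """
    shape = fieldlike.shape
    affine = fieldlike.affine
    center = np.asarray(roi.center, dtype=float)
    # volume bounds in world coordinates (voxel-center convention)
    corners_vox = np.array(
        [[i, j, k] for i in (0, shape[0] - 1) for j in (0, shape[1] - 1) for k in (0, shape[2] - 1)],
        dtype=float,
    )
    corners = corners_vox @ affine[:3, :3].T + affine[:3, 3]
    lo, hi = corners.min(axis=0), corners.max(axis=0)
    if np.any(center < lo) or np.any(center > hi):
        raise ValueError(f"ROI center {tuple(center)} lies outside the volume")
    centers = _voxel_centers_world(shape, affine)
    dist = np.linalg.norm(centers - center, axis=1)
    mask = (dist <= roi.diameter / 2.0).reshape(shape)
    if not mask.any():
        raise ValueError("ROI does not contain any voxel center")
    return mask


def extract_diffusivities(
    field: TensorField, roi_mask: np.ndarray
) -> tuple[float, float, float]:
    """Arithmetic mean of (Dxx, Dyy, Dzz) over unflagged ROI voxels.

    Diagonal elements are taken in the native image axes; no rotation into
    the local fiber frame is applied.
    """
    roi_mask = np.asarray(roi_mask, dtype=bool)
    if not roi_mask.any():
        raise ValueError("empty ROI")
    use = roi_mask & ~field.flagged
    if not use.any():
        raise ValueError("all ROI voxels are flagged (no valid tensor fit)")
    diag = field.tensor[use][:, (0, 1, 2), (0, 1, 2)]
    means = diag.mean(axis=0)
    return float(means[0]), float(means[1]), float(means[2])


def alps_index(
    dxx_proj: float,
    dxx_assoc: float,
    dyy_proj: float,
    dzz_assoc: float,
    hemisphere: str = "left",
) -> AlpsResult:
    """ALPS = mean(Dxx_proj, Dxx_assoc) / mean(Dyy_proj, Dzz_assoc)."""
    vals = (dxx_proj, dxx_assoc, dyy_proj, dzz_assoc)
    if not all(np.isfinite(vals)):
        raise ValueError("all four diffusivities must be finite")
    denom = (dyy_proj + dzz_assoc) / 2.0
    if denom <= 0:
        raise ValueError(
            f"non-positive ALPS denominator mean(Dyy_proj={dyy_proj:g}, "
            f"Dzz_assoc={dzz_assoc:g}) = {denom:g}"
        )
    num = (dxx_proj + dxx_assoc) / 2.0
    return AlpsResult(
        dxx_proj=float(dxx_proj),
        dxx_assoc=float(dxx_assoc),
        dyy_proj=float(dyy_proj),
        dzz_assoc=float(dzz_assoc),
        alps_index=float(num / denom),
        hemisphere=hemisphere,
    )


def compute_alps(
    field: TensorField, roi_projection: RoiSpec, roi_association: RoiSpec
) -> AlpsResult:
    """Full ROI protocol: sphere ROIs -> diagonal diffusivities -> ALPS ratio."""
    if roi_projection.fiber_type != "projection":
        raise ValueError("first ROI must have fiber_type='projection'")
    if roi_association.fiber_type != "association":
        raise ValueError("second ROI must have fiber_type='association'")
    dxx_p, dyy_p, _ = extract_diffusivities(field, sphere_roi(roi_projection, field))
    dxx_a, _, dzz_a = extract_diffusivities(field, sphere_roi(roi_association, field))
    return alps_index(
        dxx_p, dxx_a, dyy_p, dzz_a, hemisphere=roi_projection.hemisphere
    )
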