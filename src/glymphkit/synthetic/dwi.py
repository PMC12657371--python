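"""Ground-truthed diffusion-weighted phantoms.

Each phantom is a block layout of regions with known diffusion tensors.
The signal follows the mono-exponential forward model
``S = S0 * exp(-b g^T D g)``; optional Rician noise models MR magnitude
statistics (sigma = S0 / SNR, applied per volume).

The default ALPS demonstration layout contains a projection-fiber block,
an association-fiber block and an isotropic background.  In both fiber
blocks the dominant diffusivity lies along the image x-axis — the
perivascular direction, which runs perpendicular to both fiber systems —
so the noiseless end-to-end ALPS index equals the eigenvalue ratio
lambda_parallel / lambda_perp exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..dti_alps import DiffusionVolume, TensorField, tensor_field_from_tensors

__all__ = [
    "FiberRegion",
    "DwiPhantomSpec",
    "make_dwi_phantom",
    "fibonacci_directions",
    "default_gradient_scheme",
    "alps_phantom_spec",
    "isotropic_phantom_spec",
    "default_alps_rois",
]

# canonical white-matter single-fiber diffusivities, mm^2/s
LAMBDA_PARALLEL = 1.7e-3
LAMBDA_PERP = 0.3e-3
ISO_DIFFUSIVITY = 0.8e-3


@dataclass
class FiberRegion:
    """Diffusion tensor of one phantom region.

    ``eigenvalues`` (mm^2/s, first entry along ``principal_axis``); for
    axially symmetric tensors the orientation of the two minor axes is
    immaterial.
    """

    eigenvalues: tuple[float, float, float]
    principal_axis: tuple[float, float, float] = (0.0, 0.0, 1.0)

    def tensor(self) -> np.ndarray:
        lam = np.asarray(self.eigenvalues, dtype=float)
        if np.any(lam < 0):
            raise ValueError("eigenvalues must be non-negative")
        e1 = np.asarray(self.principal_axis, dtype=float)
        n = np.linalg.norm(e1)
        if n == 0:
            raise ValueError("principal_axis must be non-zero")
        e1 = e1 / n
        # complete an orthonormal basis
        helper = np.array([1.0, 0.0, 0.0])
        if abs(e1 @ helper) > 0.9:
            helper = np.array([0.0, 1.0, 0.0])
        e2 = np.cross(e1, helper)
        e2 /= np.linalg.norm(e2)
        e3 = np.cross(e1, e2)
        basis = np.column_stack([e1, e2, e3])
        return basis @ np.diag(lam) @ basis.T


@dataclass
class DwiPhantomSpec:
    """Specification of a block DWI phantom.

    ``region_labels`` is an integer label volume; ``regions`` maps each
    label appearing in it to a :class:`FiberRegion`.  ``snr`` is the
    S0-referenced signal-to-noise ratio; ``None`` means noiseless.
    """

    region_labels: np.ndarray
    regions: dict[int, FiberRegion]
    voxel_size: tuple[float, float, float] = (2.0, 2.0, 2.0)
    bvalues: np.ndarray | None = None
    bvecs: np.ndarray | None = None
    s0: float = 1000.0
    snr: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        self.region_labels = np.asarray(self.region_labels)
        if self.region_labels.ndim != 3:
            raise ValueError("region_labels must be a 3D label volume")
        present = set(np.unique(self.region_labels).tolist())
        missing = present - set(self.regions)
        if missing:
            raise ValueError(f"labels {sorted(missing)} have no region definition")
        if self.bvalues is None or self.bvecs is None:
            self.bvalues, self.bvecs = default_gradient_scheme()
        self.bvalues = np.asarray(self.bvalues, dtype=float).ravel()
        self.bvecs = np.asarray(self.bvecs, dtype=float).reshape(-1, 3)
        if not np.any(self.bvalues <= 1e-6):
            raise ValueError("at least one b=0 entry is required")
        dwi = self.bvalues > 1e-6
        norms = np.linalg.norm(self.bvecs[dwi], axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-8):
            raise ValueError("non-unit b>0 gradient direction")
        for reg in self.regions.values():
            if np.any(np.asarray(reg.eigenvalues) < 0):
                raise ValueError("negative eigenvalue in region definition")
        if self.snr is not None and not np.isfinite(self.snr):
            self.snr = None

    @property
    def affine(self) -> np.ndarray:
        aff = np.eye(4)
        aff[0, 0], aff[1, 1], aff[2, 2] = self.voxel_size
        return aff


def fibonacci_directions(n: int) -> np.ndarray:
    """n approximately uniform unit vectors on the sphere (deterministic)."""
    i = np.arange(n) + 0.5
    phi = np.pi * (1.0 + np.sqrt(5.0)) * i
    z = 1.0 - 2.0 * i / n
    r = np.sqrt(np.clip(1.0 - z**2, 0.0, None))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def default_gradient_scheme(
    n_directions: int = 64, n_b0: int = 5, b: float = 1000.0
) -> tuple[np.ndarray, np.ndarray]:
    """64-direction single-shell scheme at b = 1000 s/mm^2 plus five b = 0."""
    bvals = np.concatenate([np.zeros(n_b0), np.full(n_directions, b)])
    bvecs = np.vstack([np.zeros((n_b0, 3)), fibonacci_directions(n_directions)])
    return bvals, bvecs


def make_dwi_phantom(spec: DwiPhantomSpec) -> tuple[DiffusionVolume, TensorField]:
    """Generate the phantom signal and its exact ground-truth tensor field."""
    labels = spec.region_labels
    shape = labels.shape
    n_vol = len(spec.bvalues)

    # per-region attenuation profile across volumes
    codes = sorted(spec.regions)
    tensors = {c: spec.regions[c].tensor() for c in codes}
    atten = {}
    for c in codes:
        quad = np.einsum("ni,ij,nj->n", spec.bvecs, tensors[c], spec.bvecs)
        atten[c] = np.exp(-spec.bvalues * quad)

    signal = np.empty(shape + (n_vol,), dtype=float)
    truth = np.empty(shape + (3, 3), dtype=float)
    for c in codes:
        m = labels == c
        signal[m] = spec.s0 * atten[c]
        truth[m] = tensors[c]

    if spec.snr is not None:
        if spec.snr <= 0:
            raise ValueError("snr must be positive")
        rng = np.random.default_rng(spec.seed)
        sigma = spec.s0 / spec.snr
        n1 = rng.normal(0.0, sigma, signal.shape)
        n2 = rng.normal(0.0, sigma, signal.shape)
        signal = np.sqrt((signal + n1) ** 2 + n2**2)

    dwi = DiffusionVolume(
        signal=signal,
        bvalues=spec.bvalues,
        bvecs=spec.bvecs,
        voxel_size=spec.voxel_size,
        affine=spec.affine,
    )
    gt = tensor_field_from_tensors(truth, spec.voxel_size, spec.affine)
    return dwi, gt


# ---------------------------------------------------------------------------
# standard layouts

BACKGROUND, PROJECTION, ASSOCIATION = 0, 1, 2


def _block_layout(grid_shape: tuple[int, int, int]) -> np.ndarray:
    """Two fiber blocks split along y, inset from the volume edge."""
    labels = np.zeros(grid_shape, dtype=int)
    nx, ny, nz = grid_shape
    x0, x1 = nx // 4, 3 * nx // 4
    z0, z1 = nz // 4, 3 * nz // 4
    labels[x0:x1, ny // 8 : ny // 2 - ny // 8, z0:z1] = PROJECTION
    labels[x0:x1, ny // 2 + ny // 8 : ny - ny // 8, z0:z1] = ASSOCIATION
    return labels


def alps_phantom_spec(
    grid_shape: tuple[int, int, int] = (32, 32, 32),
    voxel_size: tuple[float, float, float] = (2.0, 2.0, 2.0),
    lambda_parallel: float = LAMBDA_PARALLEL,
    lambda_perp: float = LAMBDA_PERP,
    snr: float | None = None,
    seed: int = 0,
) -> DwiPhantomSpec:
    """ALPS demonstration phantom.

    Both fiber blocks carry eigenvalues (lambda_parallel, lambda_perp,
    lambda_perp) with the dominant axis along x (the perivascular
    direction), so ALPS = lambda_parallel / lambda_perp by construction.
    The background is isotropic.
    """
    x_axis = (1.0, 0.0, 0.0)
    regions = {
        BACKGROUND: FiberRegion((ISO_DIFFUSIVITY,) * 3),
        PROJECTION: FiberRegion((lambda_parallel, lambda_perp, lambda_perp), x_axis),
        ASSOCIATION: FiberRegion((lambda_parallel, lambda_perp, lambda_perp), x_axis),
    }
    return DwiPhantomSpec(
        region_labels=_block_layout(grid_shape),
        regions=regions,
        voxel_size=voxel_size,
        snr=snr,
        seed=seed,
    )


def isotropic_phantom_spec(
    grid_shape: tuple[int, int, int] = (32, 32, 32),
    voxel_size: tuple[float, float, float] = (2.0, 2.0, 2.0),
    diffusivity: float = ISO_DIFFUSIVITY,
    snr: float | None = None,
    seed: int = 0,
) -> DwiPhantomSpec:
    """Phantom with the block layout but an identical isotropic tensor everywhere."""
    iso = FiberRegion((diffusivity,) * 3)
    return DwiPhantomSpec(
        region_labels=_block_layout(grid_shape),
        regions={BACKGROUND: iso, PROJECTION: iso, ASSOCIATION: iso},
        voxel_size=voxel_size,
        snr=snr,
        seed=seed,
    )


def default_alps_rois(spec: DwiPhantomSpec, diameter: float = 5.0):
    """Projection/association sphere ROIs centered in the phantom's fiber blocks."""
    from ..dti_alps import RoiSpec

    affine = spec.affine
    rois = []
    for label, fiber in ((PROJECTION, "projection"), (ASSOCIATION, "association")):
        idx = np.argwhere(spec.region_labels == label)
        if idx.size == 0:
            raise ValueError(f"phantom has no voxels with label {label}")
        center_vox = idx.mean(axis=0)
        # snap to the nearest voxel center so tiny ROIs are non-empty
        center_vox = np.round(center_vox)
        center = center_vox @ affine[:3, :3].T + affine[:3, 3]
        rois.append(RoiSpec(center=tuple(center), diameter=diameter, fiber_type=fiber))
    return tuple(rois)
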