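"""T1w/T2w structural phantoms with tubular perivascular spaces.

Perivascular spaces are fluid-filled, so they appear dark on T1-weighted
and bright on T2-weighted images.  The phantom plants cylinders of known
geometry inside labeled subcortical nuclei, lowers T1 and raises T2
intensity inside them, and adds Gaussian noise (appropriate for
structural magnitude images at typical SNR).  Cylinders are voxelized by
the center-of-voxel membership rule, so the ground-truth mask is exactly
reproducible by a brute-force point-in-cylinder test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..atlas import REGION_CODES, RegionAtlas

__all__ = [
    "Tube",
    "IntensityModel",
    "PvsPhantomSpec",
    "make_pvs_phantom",
    "default_subcortical_atlas",
    "standard_pvs_phantom_spec",
    "voxelize_cylinder",
]


@dataclass
class Tube:
    """A straight cylindrical PVS: centerline endpoints (mm, world), radius (mm)."""

    start: tuple[float, float, float]
    end: tuple[float, float, float]
    radius: float
    region: str  # atlas region name the tube belongs to


@dataclass
class IntensityModel:
    """Background means and tube contrast of the structural pair.

    ``t1_drop``/``t2_gain`` are fractional: inside a tube
    T1 = background * (1 - t1_drop), T2 = background * (1 + t2_gain).
    ``noise_sd`` is the absolute Gaussian noise SD (same units as the
    background means).
    """

    t1_background: float = 100.0
    t2_background: float = 100.0
    t1_drop: float = 0.3
    t2_gain: float = 0.3
    noise_sd: float = 0.0


@dataclass
class PvsPhantomSpec:
    grid_shape: tuple[int, int, int] = (48, 56, 48)
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    tubes: list[Tube] = field(default_factory=list)
    intensity: IntensityModel = field(default_factory=IntensityModel)
    atlas: RegionAtlas | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.atlas is None:
            self.atlas = default_subcortical_atlas(self.grid_shape, self.voxel_size)
        min_vox = min(self.voxel_size)
        for t in self.tubes:
            if t.radius < 0.5 * min_vox:
                raise ValueError(
                    f"tube radius {t.radius} mm below half the minimum voxel size"
                )

    @property
    def affine(self) -> np.ndarray:
        aff = np.eye(4)
        aff[0, 0], aff[1, 1], aff[2, 2] = self.voxel_size
        return aff


def _voxel_centers(shape, affine) -> np.ndarray:
    idx = np.indices(shape).reshape(3, -1).T.astype(float)
    return idx @ affine[:3, :3].T + affine[:3, 3]


def voxelize_cylinder(
    start, end, radius, grid_shape, affine
) -> np.ndarray:
    """Boolean mask of voxels whose centers lie inside the finite cylinder."""
    p0 = np.asarray(start, dtype=float)
    p1 = np.asarray(end, dtype=float)
    axis = p1 - p0
    length = np.linalg.norm(axis)
    if length == 0:
        raise ValueError("degenerate cylinder: start == end")
    axis = axis / length
    pts = _voxel_centers(grid_shape, affine)
    rel = pts - p0
    t = rel @ axis
    radial = np.linalg.norm(rel - t[:, None] * axis[None, :], axis=1)
    inside = (t >= 0) & (t <= length) & (radial <= radius)
    return inside.reshape(grid_shape)


def default_subcortical_atlas(
    grid_shape: tuple[int, int, int] = (48, 56, 48),
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> RegionAtlas:
    """Simplified block atlas: box-shaped nuclei mirrored across the midline
    inside an ellipsoidal GM+WM tissue mask."""
    nx, ny, nz = grid_shape
    affine = np.eye(4)
    affine[0, 0], affine[1, 1], affine[2, 2] = voxel_size

    labels = np.zeros(grid_shape, dtype=int)
    # structure -> (y fraction range, z fraction range); boxes are pairwise
    # disjoint; x placed per hemisphere
    spans = {
        "caudate": ((0.28, 0.42), (0.50, 0.70)),
        "putamen": ((0.30, 0.55), (0.22, 0.46)),
        "pallidum": ((0.44, 0.56), (0.50, 0.66)),
        "amygdala": ((0.60, 0.72), (0.22, 0.38)),
        "thalamus": ((0.58, 0.75), (0.45, 0.68)),
        "hippocampus": ((0.78, 0.92), (0.45, 0.70)),
    }
    # left hemisphere: lower x indices; right: mirrored
    left_x = (int(0.12 * nx), int(0.42 * nx))
    for name, ((y0f, y1f), (z0f, z1f)) in spans.items():
        y0, y1 = int(y0f * ny), int(y1f * ny)
        z0, z1 = int(z0f * nz), int(z1f * nz)
        lx0, lx1 = left_x
        for sl in (
            (slice(lx0, lx1), slice(y0, y1), slice(z0, z1)),
            (slice(nx - lx1, nx - lx0), slice(y0, y1), slice(z0, z1)),
        ):
            if np.any(labels[sl] != 0):
                raise RuntimeError(f"atlas boxes overlap at structure {name}")
        labels[lx0:lx1, y0:y1, z0:z1] = REGION_CODES[f"{name}_left"]
        labels[nx - lx1 : nx - lx0, y0:y1, z0:z1] = REGION_CODES[f"{name}_right"]

    # ellipsoidal tissue mask covering the labeled structures
    ii, jj, kk = np.indices(grid_shape).astype(float)
    cx, cy, cz = (nx - 1) / 2, (ny - 1) / 2, (nz - 1) / 2
    tissue = (
        ((ii - cx) / (0.48 * nx)) ** 2
        + ((jj - cy) / (0.48 * ny)) ** 2
        + ((kk - cz) / (0.48 * nz)) ** 2
    ) <= 1.0
    tissue |= labels > 0
    return RegionAtlas(
        labels=labels, tissue_mask=tissue, voxel_size=voxel_size, affine=affine
    )


def make_pvs_phantom(
    spec: PvsPhantomSpec,
) -> tuple[np.ndarray, np.ndarray, RegionAtlas, np.ndarray]:
    """Generate (t1w, t2w, atlas, ground-truth PVS mask).

    Raises ``ValueError`` if a tube extends outside the atlas volume or
    outside its declared region.
    """
    atlas = spec.atlas
    shape = spec.grid_shape
    affine = spec.affine

    gt = np.zeros(shape, dtype=bool)
    corners = _voxel_centers(shape, affine)
    lo, hi = corners.min(axis=0), corners.max(axis=0)
    for t in spec.tubes:
        for p in (t.start, t.end):
            p = np.asarray(p, dtype=float)
            if np.any(p < lo) or np.any(p > hi):
                raise ValueError(f"tube endpoint {tuple(p)} outside atlas extent")
        mask = voxelize_cylinder(t.start, t.end, t.radius, shape, affine)
        region_mask = atlas.mask(t.region)
        if mask.any() and not np.all(region_mask[mask]):
            raise ValueError(
                f"tube in {t.region!r} has voxels outside its declared region"
            )
        gt |= mask

    im = spec.intensity
    t1w = np.full(shape, im.t1_background, dtype=float)
    t2w = np.full(shape, im.t2_background, dtype=float)
    t1w[gt] = im.t1_background * (1.0 - im.t1_drop)
    t2w[gt] = im.t2_background * (1.0 + im.t2_gain)

    if im.noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    if im.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        t1w = t1w + rng.normal(0.0, im.noise_sd, shape)
        t2w = t2w + rng.normal(0.0, im.noise_sd, shape)

    return t1w, t2w, atlas, gt


def standard_pvs_phantom_spec(
    noise_fraction: float = 0.05,
    contrast: float = 0.3,
    seed: int = 0,
    grid_shape: tuple[int, int, int] = (48, 56, 48),
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> PvsPhantomSpec:
    """The standard test phantom: tubes of radius 1-2 mm in putamen, caudate
    and thalamus of both hemispheres, 30% T1/T2 contrast, noise SD given as
    a fraction of the background intensity."""
    atlas = default_subcortical_atlas(grid_shape, voxel_size)
    vs = np.asarray(voxel_size)

    def _tube_in(region: str, radius: float, axis: int, offset: tuple[float, float]):
        """Axis-aligned tube through the interior of ``region``."""
        idx = np.argwhere(atlas.mask(region))
        lo_v, hi_v = idx.min(axis=0), idx.max(axis=0)
        center = (lo_v + hi_v) / 2.0
        margin = radius / vs[axis] + 2.0
        start_v, end_v = center.copy(), center.copy()
        start_v[axis] = lo_v[axis] + margin
        end_v[axis] = hi_v[axis] - margin
        # offset perpendicular axes (voxel units) to decorrelate tube positions
        perp = [a for a in range(3) if a != axis]
        start_v[perp[0]] += offset[0]
        end_v[perp[0]] += offset[0]
        start_v[perp[1]] += offset[1]
        end_v[perp[1]] += offset[1]
        return Tube(
            start=tuple(start_v * vs),
            end=tuple(end_v * vs),
            radius=radius,
            region=region,
        )

    tubes = [
        _tube_in("putamen_left", 1.0, 2, (-2.0, 0.0)),
        _tube_in("putamen_left", 1.5, 1, (2.5, 0.0)),
        _tube_in("putamen_right", 1.0, 2, (2.0, 0.0)),
        _tube_in("caudate_left", 1.0, 2, (0.0, 0.0)),
        _tube_in("caudate_right", 2.0, 1, (0.0, 0.0)),
        _tube_in("thalamus_left", 1.5, 2, (0.0, 0.0)),
    ]
    intensity = IntensityModel(
        t1_drop=contrast, t2_gain=contrast, noise_sd=100.0 * noise_fraction
    )
    return PvsPhantomSpec(
        grid_shape=grid_shape,
        voxel_size=voxel_size,
        tubes=tubes,
        intensity=intensity,
        atlas=atlas,
        seed=seed,
    )
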