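"""EPC construction, Frangi vesselness, segmentation and volume fractions."""

import numpy as np
import pytest

from glymphkit.atlas import BG_SUBDIVISIONS
from glymphkit.pvs import (
    EpcVolume,
    FrangiParams,
    StructuralPair,
    compute_epc,
    frangi_vesselness,
    nlm_filter,
    pvs_volume_fraction,
    quantify_pvs,
    segment_pvs,
)
from glymphkit.synthetic import (
    default_subcortical_atlas,
    make_pvs_phantom,
    standard_pvs_phantom_spec,
)

EYE = np.eye(4)
VS = (1.0, 1.0, 1.0)


def _epc(arr):
    return EpcVolume(epc=np.asarray(arr, float), mask=np.ones(np.shape(arr), bool),
                     voxel_size=VS, affine=EYE)


def _dark_cylinder(shape=(24, 24, 24), radius=1.0, drop=0.3):
    """EPC-like volume with a dark z-axis cylinder through the center."""
    vol = np.ones(shape)
    ii, jj = np.indices(shape[:2]).astype(float)
    c = (shape[0] - 1) / 2
    inside = (ii - c) ** 2 + (jj - c) ** 2 <= radius**2
    vol[inside, :] = 1.0 - drop
    gt = np.zeros(shape, bool)
    gt[inside, :] = True
    return vol, gt


# ---------------------------------------------------------------------------
# NLM + EPC


def test_nlm_constant_volume_unchanged():
    vol = np.full((10, 10, 10), 7.0)
    assert np.allclose(nlm_filter(vol), vol)


def test_nlm_h_zero_is_identity():
    rng = np.random.default_rng(0)
    vol = rng.normal(10, 1, (8, 8, 8))
    assert np.array_equal(nlm_filter(vol, h=0), vol)


def test_nlm_reduces_noise_on_piecewise_constant_phantom():
    rng = np.random.default_rng(1)
    clean = np.zeros((16, 16, 16))
    clean[8:] = 10.0
    noisy = clean + rng.normal(0, 1.0, clean.shape)
    den = nlm_filter(noisy)
    assert np.sqrt(((den - clean) ** 2).mean()) < np.sqrt(((noisy - clean) ** 2).mean())
    assert den.min() >= noisy.min() and den.max() <= noisy.max()


def test_nlm_rejects_non_finite():
    vol = np.ones((4, 4, 4))
    vol[0, 0, 0] = np.nan
    with pytest.raises(ValueError, match="finite"):
        nlm_filter(vol)


def test_epc_is_pointwise_ratio():
    t2 = np.full((5, 5, 5), 3.0)
    pair = StructuralPair(t1w=2 * t2, t2w=t2, voxel_size=VS, affine=EYE)
    out = compute_epc(pair)
    assert np.allclose(out.epc, 2.0)
    assert out.mask.all()


def test_epc_masks_zero_divider_without_infinities():
    t1 = np.ones((4, 4, 4))
    t2 = np.ones((4, 4, 4))
    t2[0] = 0.0
    out = compute_epc(StructuralPair(t1w=t1, t2w=t2, voxel_size=VS, affine=EYE))
    assert not out.mask[0].any()
    assert np.all(np.isfinite(out.epc))


def test_epc_is_lower_inside_tubes(noiseless_pvs_phantom):
    spec, t1w, t2w, atlas, gt = noiseless_pvs_phantom
    out = compute_epc(StructuralPair(t1w=t1w, t2w=t2w, voxel_size=VS, affine=EYE))
    assert out.epc[gt].mean() < out.epc[(atlas.labels > 0) & ~gt].mean()


def test_epc_mismatched_grids_rejected():
    with pytest.raises(ValueError, match="grid"):
        StructuralPair(t1w=np.ones((4, 4, 4)), t2w=np.ones((4, 4, 5)),
                       voxel_size=VS, affine=EYE)


# ---------------------------------------------------------------------------
# Frangi


def test_vesselness_zero_on_uniform_volume():
    v = frangi_vesselness(_epc(np.full((12, 12, 12), 5.0)))
    assert np.all(v.v == 0)


def test_vesselness_bounded_and_high_on_dark_tube():
    vol, gt = _dark_cylinder()
    v = frangi_vesselness(_epc(vol)).v
    assert v.min() >= 0 and v.max() <= 1
    core = gt.copy()
    core[..., :4] = core[..., -4:] = False  # avoid end caps
    on_axis = v[core].mean()
    background = v[~gt].mean()
    assert on_axis / max(background, 1e-12) >= 10


def test_bright_tube_gives_zero_response_with_dark_polarity():
    vol, gt = _dark_cylinder()
    bright = 2.0 - vol  # invert contrast
    v = frangi_vesselness(_epc(bright), FrangiParams(polarity="dark")).v
    core = gt.copy()
    core[..., :4] = core[..., -4:] = False
    assert np.allclose(v[core], 0.0)
    # and the bright-polarity setting recovers it
    v2 = frangi_vesselness(_epc(bright), FrangiParams(polarity="bright")).v
    assert v2[core].mean() > 0.05


def test_vesselness_monotone_in_added_scales():
    vol, _ = _dark_cylinder()
    sub = frangi_vesselness(_epc(vol), FrangiParams(scales=(0.8, 1.2), c=0.05)).v
    sup = frangi_vesselness(_epc(vol), FrangiParams(scales=(0.4, 0.8, 1.2, 1.6), c=0.05)).v
    assert np.all(sup >= sub - 1e-12)


def test_vesselness_rotation_robustness():
    """A tube rotated 90 deg (axis swap) keeps its on-axis response within 5%."""
    vol, gt = _dark_cylinder()
    vz = frangi_vesselness(_epc(vol)).v
    vy = frangi_vesselness(_epc(np.swapaxes(vol, 1, 2))).v
    core = gt.copy()
    core[..., :4] = core[..., -4:] = False
    r1 = vz[core].mean()
    r2 = vy[np.swapaxes(core, 1, 2)].mean()
    assert abs(r1 - r2) / r1 < 0.05


def test_empty_scale_list_rejected():
    with pytest.raises(ValueError, match="scale"):
        FrangiParams(scales=())


# ---------------------------------------------------------------------------
# segmentation + volume fraction


def test_threshold_one_on_submaximal_map_gives_empty_mask():
    vol, _ = _dark_cylinder()
    v = frangi_vesselness(_epc(vol))
    assert v.v.max() < 1
    mask = segment_pvs(v, np.ones(v.v.shape, bool), threshold=1.0)
    assert not mask.any()


def test_min_cluster_larger_than_any_component_empties_mask():
    v = np.zeros((10, 10, 10))
    v[2:4, 2, 2] = 0.9  # two-voxel component
    mask = segment_pvs(v, np.ones(v.shape, bool), threshold=0.5, min_cluster_voxels=5)
    assert not mask.any()


def test_empty_region_mask_rejected():
    with pytest.raises(ValueError, match="empty region"):
        segment_pvs(np.zeros((4, 4, 4)), np.zeros((4, 4, 4), bool))


def test_segmentation_dice_on_noiseless_phantom(noiseless_pvs_phantom):
    spec, t1w, t2w, atlas, gt = noiseless_pvs_phantom
    pair = StructuralPair(t1w=t1w, t2w=t2w, voxel_size=spec.voxel_size, affine=spec.affine)
    _, mask, _ = quantify_pvs(pair, atlas, denoise=False)
    inter = (mask & gt).sum()
    dice = 2 * inter / (mask.sum() + gt.sum())
    assert dice >= 0.7


def test_vf_arithmetic_ten_in_a_thousand():
    atlas = default_subcortical_atlas((20, 20, 20))
    # shrink tissue mask to exactly 1000 voxels for the arithmetic check
    tissue = np.zeros((20, 20, 20), bool)
    tissue.ravel()[:1000] = True
    atlas.tissue_mask = tissue
    pvs = np.zeros((20, 20, 20), bool)
    put = np.argwhere(atlas.mask("putamen_left"))[:10]
    pvs[tuple(put.T)] = True
    table = pvs_volume_fraction(pvs, atlas)
    total = table.query("region == 'putamen' and hemisphere == 'left'").iloc[0]
    assert total["pvs_volume_mm3"] == pytest.approx(10.0)
    assert total["tissue_volume_mm3"] == pytest.approx(1000.0)
    assert total["vf_percent"] == pytest.approx(1.0)


def test_empty_pvs_mask_gives_zero_vf_everywhere():
    atlas = default_subcortical_atlas((20, 20, 20))
    table = pvs_volume_fraction(np.zeros((20, 20, 20), bool), atlas)
    assert np.allclose(table["vf_percent"], 0.0)


def test_bg_vf_is_sum_of_subdivisions(noiseless_pvs_phantom):
    spec, t1w, t2w, atlas, gt = noiseless_pvs_phantom
    table = pvs_volume_fraction(gt, atlas)
    tot = table[table.hemisphere == "total"].set_index("region")
    bg_from_parts = sum(tot.loc[s, "pvs_volume_mm3"] for s in BG_SUBDIVISIONS)
    assert tot.loc["bg", "pvs_volume_mm3"] == pytest.approx(bg_from_parts)
    assert tot.loc["bg", "vf_percent"] == pytest.approx(
        100 * bg_from_parts / tot.loc["bg", "tissue_volume_mm3"]
    )


def test_phantom_vf_close_to_analytic_cylinder_ratio(noiseless_pvs_phantom):
    """Ground-truth VF agrees with pi r^2 L / tissue volume within the
    voxelization error of ~1-mm tubes."""
    spec, _, _, atlas, gt = noiseless_pvs_phantom
    analytic = sum(
        np.pi * t.radius**2 * np.linalg.norm(np.subtract(t.end, t.start))
        for t in spec.tubes
    )
    voxelized = gt.sum() * atlas.voxel_volume
    assert voxelized == pytest.approx(analytic, rel=0.35)
    table = pvs_volume_fraction(gt, atlas)
    vf = table.query("region == 'bg' and hemisphere == 'total'")["vf_percent"].iloc[0]
    tissue = atlas.tissue_mask.sum() * atlas.voxel_volume
    # bg aggregate excludes the thalamic tube
    assert 0 < vf < 100 * analytic / tissue * 1.5


def test_region_local_denominator_option():
    atlas = default_subcortical_atlas((20, 20, 20))
    pvs = np.zeros((20, 20, 20), bool)
    put = np.argwhere(atlas.mask("putamen_left"))[:10]
    pvs[tuple(put.T)] = True
    table = pvs_volume_fraction(pvs, atlas, denominator="region")
    row = table.query("region == 'putamen' and hemisphere == 'left'").iloc[0]
    assert row["tissue_volume_mm3"] == pytest.approx(atlas.mask("putamen_left").sum())
    assert row["vf_percent"] == pytest.approx(1000.0 / atlas.mask("putamen_left").sum())
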