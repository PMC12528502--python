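"""Preprocessing: normalisation, cropping, masks, paired augmentation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import ndimage

from orthosyn.preprocess import (AugmentParams, apply_mask, augment_pair,
                                 build_unified_mask, center_crop,
                                 central_region_mask, truncate_normalize)
from orthosyn.volume import StructureMaskSet, VolumeImage, read_nifti, write_nifti

SPACING = (1.0, 1.0, 1.0)


def vol(data, domain="HU"):
    return VolumeImage(np.asarray(data, float), SPACING, domain)


def test_truncate_normalize_clips_then_rescales():
    v = vol(np.array([-2000.0, -1000.0, 500.0, 3000.0]).reshape(1, 2, 2))
    out = truncate_normalize(v)
    assert np.allclose(out.data.ravel(), [0.0, 0.0, 0.5, 1.0])
    assert out.norm_bounds == (-1000.0, 2000.0)
    assert out.intensity_domain == "normalized01"


def test_truncate_normalize_rejects_wrong_domain():
    with pytest.raises(ValueError):
        truncate_normalize(vol(np.zeros((2, 2, 2)), domain="normalized01"))


def test_constant_volume_normalises_to_zeros_with_warning(caplog):
    out = truncate_normalize(vol(np.full((2, 2, 2), 100.0)))
    assert np.all(out.data == 0.0)


@settings(max_examples=20, derandomize=True)
@given(st.integers(0, 2**31 - 1))
def test_normalisation_spans_unit_interval(seed):
    rng = np.random.default_rng(seed)
    v = vol(rng.uniform(-1500, 2500, size=(4, 4, 4)))
    out = truncate_normalize(v)
    assert out.data.min() == 0.0 and out.data.max() == 1.0
    # idempotence: renormalising a [0,1] volume by its own min/max is identity
    again = (out.data - out.data.min()) / (out.data.max() - out.data.min())
    assert np.allclose(again, out.data)


def test_center_crop_index_oracle():
    big = np.zeros((256, 256, 64))
    big[64:192, 64:192, :] = np.arange(128 * 128 * 64).reshape(128, 128, 64)
    out = center_crop(vol(big), (128, 128, 64))
    assert np.array_equal(out.data, big[64:192, 64:192, 0:64])


def test_center_crop_identity_and_errors():
    data = np.random.default_rng(0).random((8, 6, 4))
    assert np.array_equal(center_crop(vol(data), (8, 6, 4)).data, data)
    hot = np.zeros((9, 9, 9))
    hot[4, 4, 4] = 1.0
    assert center_crop(vol(hot), (3, 3, 3)).data[1, 1, 1] == 1.0
    with pytest.raises(ValueError):
        center_crop(vol(data), (10, 6, 4))


def test_central_region_mask_counts():
    m = central_region_mask((128, 128, 64), (128, 64, 64))
    assert m.sum() == 128 * 64 * 64  # 524288 ones in the default core
    assert central_region_mask((4, 4, 4), (4, 4, 4)).all()
    small = central_region_mask((4, 4, 4), (2, 2, 2))
    expected = np.zeros((4, 4, 4), np.uint8)
    expected[1:3, 1:3, 1:3] = 1
    assert np.array_equal(small, expected)
    # default core halves the anterior-posterior axis
    assert central_region_mask((128, 128, 64)).sum() == 128 * 64 * 64


def _mask_set(shape, rng):
    interior = np.zeros(shape, np.uint8)
    interior[8:12, 8:12, 6:10] = 1
    return StructureMaskSet(
        ptv=interior,
        bladder=np.roll(interior, 3, axis=0),
        rectum=np.roll(interior, -3, axis=1),
        body=(rng.random(shape) < 2.0).astype(np.uint8),
    )


def test_augment_identity_is_exact():
    rng = np.random.default_rng(0)
    masks = _mask_set((24, 24, 16), rng)
    v = vol(rng.random((24, 24, 16)), domain="normalized01")
    out_v, out_m = augment_pair(v, masks, AugmentParams())
    assert np.array_equal(out_v.data, v.data)
    assert np.array_equal(out_m.ptv, masks.ptv)


def test_integer_translations_invert_exactly_on_interior_masks():
    rng = np.random.default_rng(1)
    masks = _mask_set((24, 24, 16), rng)
    v = vol(rng.random((24, 24, 16)), domain="normalized01")
    fwd_v, fwd_m = augment_pair(v, masks, AugmentParams(translation_px=(5, 0, 0)))
    back_v, back_m = augment_pair(fwd_v, fwd_m, AugmentParams(translation_px=(-5, 0, 0)))
    assert np.array_equal(back_m.ptv, masks.ptv)
    assert np.array_equal(back_m.bladder, masks.bladder)


def test_rotated_masks_stay_binary_and_params_validate():
    rng = np.random.default_rng(2)
    masks = _mask_set((24, 24, 16), rng)
    v = vol(rng.random((24, 24, 16)), domain="normalized01")
    _, out_m = augment_pair(v, masks, AugmentParams(rotation_deg=3.5))
    for _, m in out_m.items():
        assert set(np.unique(m)) <= {0, 1}
    with pytest.raises(ValueError):
        AugmentParams(translation_px=(6, 0, 0))
    with pytest.raises(ValueError):
        AugmentParams(rotation_deg=4.5)


def test_hu_fill_value_for_translation():
    v = vol(np.full((8, 8, 8), 500.0))
    masks = StructureMaskSet(*[np.ones((8, 8, 8), np.uint8)] * 4)
    out_v, _ = augment_pair(v, masks, AugmentParams(translation_px=(2, 0, 0)))
    assert np.all(out_v.data[:2] == -1000.0)  # air fill in HU domain


def brute_force_dilation(mask, iterations):
    out = mask.astype(bool)
    for _ in range(iterations):
        nxt = out.copy()
        idx = np.argwhere(out)
        for i, j, k in idx:
            nxt[max(0, i - 1):i + 2, max(0, j - 1):j + 2, max(0, k - 1):k + 2] = True
        out = nxt
    return out


def test_unified_mask_single_voxel_dilation_oracle():
    shape = (16, 16, 16)
    ptv = np.zeros(shape, np.uint8)
    ptv[8, 8, 8] = 1
    masks = StructureMaskSet(ptv=ptv, bladder=np.zeros(shape, np.uint8),
                             rectum=np.zeros(shape, np.uint8), body=np.ones(shape, np.uint8))
    um = build_unified_mask(masks, dilation_px=3)
    assert um.data.sum() == 7 ** 3  # 26-connected cube grows by 1 voxel per pass
    assert np.array_equal(um.data.astype(bool), brute_force_dilation(ptv, 3))


def test_unified_mask_union_and_errors():
    shape = (12, 12, 12)
    rng = np.random.default_rng(3)
    a = (rng.random(shape) < 0.2).astype(np.uint8)
    b = (rng.random(shape) < 0.2).astype(np.uint8)
    masks = StructureMaskSet(ptv=a, bladder=b, rectum=a, body=np.ones(shape, np.uint8))
    um0 = build_unified_mask(masks, dilation_px=0)
    assert np.array_equal(um0.data, (a | b))  # overlap counted once, no growth
    empty = StructureMaskSet(*[np.zeros(shape, np.uint8)] * 3, body=np.ones(shape, np.uint8))
    with pytest.raises(ValueError):
        build_unified_mask(empty)


def test_apply_mask_contract():
    rng = np.random.default_rng(4)
    v = vol(rng.random((6, 6, 6)), domain="normalized01")
    ones = np.ones((6, 6, 6))
    assert np.array_equal(apply_mask(v, ones).data, v.data)
    assert np.all(apply_mask(v, np.zeros((6, 6, 6))).data == 0)
    m = (rng.random((6, 6, 6)) < 0.5).astype(float)
    assert np.isclose(apply_mask(v, m).data.sum(), v.data[m.astype(bool)].sum())
    with pytest.raises(ValueError):
        apply_mask(v, np.ones((5, 6, 6)))


def test_nifti_round_trip(tmp_path):
    rng = np.random.default_rng(5)
    v = VolumeImage(rng.normal(0, 300, size=(10, 12, 8)), (1.98, 1.98, 3.0))
    path = tmp_path / "vol.nii"
    write_nifti(v, path)
    back = read_nifti(path)
    assert np.abs(back.data - v.data).max() <= 1e-3  # float32 storage
    assert np.allclose(back.spacing_mm, (1.98, 1.98, 3.0), atol=1e-6)


def test_nifti_rejects_4d(tmp_path):
    import nibabel as nib

    path = tmp_path / "vol4d.nii"
    nib.save(nib.Nifti1Image(np.zeros((4, 4, 4, 2), np.float32), np.eye(4)), str(path))
    with pytest.raises(ValueError):
        read_nifti(path)
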