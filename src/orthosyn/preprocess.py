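"""Intensity and geometry preprocessing for volume/mask pairs.

Covers the online preprocessing stage of the reconstruction pipeline:
HU truncation to [-1000, 2000] with per-case min-max normalisation,
central cropping, construction of the central-region mask and of the
dilated unified structure mask, paired augmentation (integer translations
and small axial rotations applied identically to a volume and its masks),
and elementwise masking.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .volume import HU_AIR, StructureMaskSet, UnifiedMask, VolumeImage

log = logging.getLogger(__name__)

HU_CLIP = (-1000.0, 2000.0)

__all__ = [
    "AugmentParams", "truncate_normalize", "center_crop", "central_region_mask",
    "augment_pair", "build_unified_mask", "apply_mask", "crop_masks",
]


@dataclass(frozen=True)
class AugmentParams:
    """Rigid paired augmentation: integer voxel translation plus an axial rotation."""

    translation_px: tuple[int, int, int] = (0, 0, 0)
    rotation_deg: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if any(abs(t) > 5 for t in self.translation_px):
            raise ValueError(f"|translation| must be <= 5 px per axis, got {self.translation_px}")
        if abs(self.rotation_deg) > 4.0:
            raise ValueError(f"|rotation| must be <= 4 deg, got {self.rotation_deg}")

    @classmethod
    def sample(cls, rng: np.random.Generator, max_translation_px: int = 5,
               max_rotation_deg: float = 4.0) -> "AugmentParams":
        """Draw a random augmentation.  The ±5 px / ±4° envelope is defined
        at the reference 1.98 mm raster; pass a smaller translation range on
        coarser grids to keep the physical magnitude (~±10 mm) comparable."""
        t = int(max_translation_px)
        return cls(
            translation_px=tuple(int(v) for v in rng.integers(-t, t + 1, size=3)),
            rotation_deg=float(rng.uniform(-max_rotation_deg, max_rotation_deg)),
            seed=int(rng.integers(0, 2**31 - 1)),
        )


def truncate_normalize(v: VolumeImage) -> VolumeImage:
    """Clip to [-1000, 2000] HU then per-case min-max rescale to [0, 1].

    The clipped (min, max) pair is stored on the result so evaluation can
    map back to HU.  A constant volume normalises to all zeros (degenerate
    input; logged, not raised, so a bad case cannot poison a training run).
    """
    if v.intensity_domain != "HU":
        raise ValueError("truncate_normalize expects an HU-domain volume")
    clipped = np.clip(v.data, *HU_CLIP)
    lo, hi = float(clipped.min()), float(clipped.max())
    if hi == lo:
        log.warning("constant volume after clipping; returning zeros")
        out = np.zeros_like(clipped)
        hi = lo + 1.0
    else:
        out = (clipped - lo) / (hi - lo)
    return VolumeImage(out, v.spacing_mm, "normalized01", norm_bounds=(lo, hi))


def center_crop(v: VolumeImage, target_shape: tuple[int, int, int]) -> VolumeImage:
    """Centred crop to `target_shape`; odd margins floor toward the origin."""
    sl = _center_slices(v.shape, target_shape)
    out = VolumeImage(v.data[sl], v.spacing_mm, v.intensity_domain)
    out.norm_bounds = v.norm_bounds
    return out


def _center_slices(shape, target) -> tuple[slice, ...]:
    if len(target) != len(shape):
        raise ValueError("target rank mismatch")
    sls = []
    for s, t in zip(shape, target):
        if t > s:
            raise ValueError(f"crop target {target} exceeds input shape {shape}")
        start = (s - t) // 2
        sls.append(slice(start, start + t))
    return tuple(sls)


def crop_masks(masks: StructureMaskSet, target_shape) -> StructureMaskSet:
    sl = _center_slices(masks.shape, target_shape)
    return StructureMaskSet(**{name: m[sl] for name, m in masks.items()})


def central_region_mask(shape: tuple[int, int, int],
                        core_shape: tuple[int, int, int] | None = None) -> np.ndarray:
    """Binary box mask: ones in the centred core, zeros elsewhere.

    The default core keeps the full left-right and superior-inferior extent
    and the central half of the anterior-posterior axis, which for a
    128x128x64 grid is the 128x64x64 treatment-region box.
    """
    if core_shape is None:
        core_shape = (shape[0], shape[1] // 2, shape[2])
    mask = np.zeros(shape, dtype=np.uint8)
    mask[_center_slices(shape, core_shape)] = 1
    return mask


def _translate(arr: np.ndarray, t: tuple[int, int, int], fill: float) -> np.ndarray:
    """Integer-voxel translation with constant fill (exact, no interpolation)."""
    out = np.full_like(arr, fill)
    src = []
    dst = []
    for size, shift in zip(arr.shape, t):
        if abs(shift) >= size:
            return out
        if shift >= 0:
            src.append(slice(0, size - shift))
            dst.append(slice(shift, size))
        else:
            src.append(slice(-shift, size))
            dst.append(slice(0, size + shift))
    out[tuple(dst)] = arr[tuple(src)]
    return out


def augment_pair(cbct: VolumeImage, masks: StructureMaskSet,
                 params: AugmentParams) -> tuple[VolumeImage, StructureMaskSet]:
    """Apply the same translation and axial (x-y plane) rotation to a CBCT
    and its structures: linear interpolation for the volume, nearest
    neighbour with re-binarisation for masks.

    Out-of-field voxels fill with -1000 HU for HU-domain volumes and 0 for
    normalised ones; masks fill with 0.
    """
    if cbct.shape != masks.shape:
        raise ValueError("volume and masks must be aligned")
    fill = HU_AIR if cbct.intensity_domain == "HU" else 0.0

    def _xform(arr: np.ndarray, fill_value: float, order: int) -> np.ndarray:
        out = arr.astype(np.float64)
        if params.rotation_deg != 0.0:
            out = ndimage.rotate(out, params.rotation_deg, axes=(0, 1), reshape=False,
                                 order=order, mode="constant", cval=fill_value)
        out = _translate(out, params.translation_px, fill_value)
        return out

    vol = _xform(cbct.data, fill, order=1)
    if cbct.intensity_domain == "normalized01":
        vol = np.clip(vol, 0.0, 1.0)
    new_masks = StructureMaskSet(**{
        name: (_xform(m, 0.0, order=0) > 0.5).astype(np.uint8) for name, m in masks.items()
    })
    out = VolumeImage(vol, cbct.spacing_mm, cbct.intensity_domain)
    out.norm_bounds = cbct.norm_bounds
    return out, new_masks


def build_unified_mask(masks: StructureMaskSet, dilation_px: int = 3) -> UnifiedMask:
    """Union of PTV, bladder and rectum, dilated `dilation_px` times with a
    26-connected 3x3x3 element to include boundary context."""
    union = (masks.ptv | masks.bladder | masks.rectum).astype(bool)
    if not union.any():
        raise ValueError("cannot build a unified mask from all-empty structures")
    if dilation_px > 0:
        union = ndimage.binary_dilation(union, structure=np.ones((3, 3, 3), bool),
                                        iterations=dilation_px)
    return UnifiedMask(union.astype(np.uint8), dilation_px)


def apply_mask(v: VolumeImage, mask: np.ndarray) -> VolumeImage:
    """Elementwise product of a volume with a binary mask."""
    if v.shape != mask.shape:
        raise ValueError(f"shape mismatch: volume {v.shape} vs mask {mask.shape}")
    out = VolumeImage(v.data * mask, v.spacing_mm, v.intensity_domain)
    out.norm_bounds = v.norm_bounds
    return out
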