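"""Case-to-training-sample preparation shared by training and evaluation.

For one phantom fraction this performs, in order: HU truncation and
per-volume min-max normalisation, optional central cropping, optional
paired augmentation of the CBCT and its structures (training only), DRR
rendering from the augmented CBCT, unified-mask construction, and central
region masking of the pCT/CBCT working volumes.  DRRs are rendered after
augmentation (so they reflect the augmented anatomy) and before the
central-region masking.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .phantom import PhantomCase
from .preprocess import (AugmentParams, augment_pair, build_unified_mask,
                         center_crop, central_region_mask, crop_masks,
                         truncate_normalize)
from .projection import ProjectionPair, render_pair
from .volume import StructureMaskSet, UnifiedMask, VolumeImage

__all__ = ["PrepSettings", "Sample", "prepare_fraction"]


@dataclass(frozen=True)
class PrepSettings:
    """Preprocessing knobs; ``None`` leaves the corresponding step out."""

    crop_shape: tuple[int, int, int] | None = None
    #: central-region core; None -> (X, Y//2, Z) default box, False-like empty tuple disables
    core_shape: tuple[int, int, int] | None = None
    use_central_mask: bool = True
    raster: tuple[int, int] | None = None  # default: (X, Y) of the working grid
    dilation_px: int = 3
    augment: bool = True
    #: translation draw range in voxels; keep ~10 mm physical on coarse grids
    max_translation_px: int = 5
    max_rotation_deg: float = 4.0


@dataclass
class Sample:
    """One (inputs, target) training/evaluation pair in normalised domain."""

    case_id: str
    fraction: int
    drrs: ProjectionPair
    pct01: VolumeImage
    target01: VolumeImage
    umask: UnifiedMask
    body: np.ndarray
    eval_mask: np.ndarray  # body (intersected with the core box when masking is on)


def prepare_fraction(case: PhantomCase, idx: int, prep: PrepSettings,
                     augment_params: AugmentParams | None = None) -> Sample:
    """Build the model inputs and target for fraction `idx` of a case."""
    cbct, fmasks, _ = case.fractions[idx]
    pct01 = truncate_normalize(case.pct)
    cbct01 = truncate_normalize(cbct)
    masks = fmasks

    if prep.crop_shape is not None:
        pct01 = center_crop(pct01, prep.crop_shape)
        cbct01 = center_crop(cbct01, prep.crop_shape)
        masks = crop_masks(masks, prep.crop_shape)

    if augment_params is not None and prep.augment:
        cbct01, masks = augment_pair(cbct01, masks, augment_params)

    shape = cbct01.shape
    raster = prep.raster or (shape[0], shape[1])
    drrs = render_pair(cbct01, raster=raster)
    umask = build_unified_mask(masks, dilation_px=prep.dilation_px)

    body = masks.body.copy()
    eval_mask = body
    if prep.use_central_mask:
        core = central_region_mask(shape, prep.core_shape)
        pct01 = VolumeImage(pct01.data * core, pct01.spacing_mm, "normalized01",
                            norm_bounds=pct01.norm_bounds)
        cbct01 = VolumeImage(cbct01.data * core, cbct01.spacing_mm, "normalized01",
                             norm_bounds=cbct01.norm_bounds)
        umask = UnifiedMask((umask.data & core).astype(np.uint8), umask.dilation_px)
        eval_mask = (body & core).astype(np.uint8)
        if not umask.data.any() or not eval_mask.any():
            raise ValueError(f"central-region mask removed all structures for {case.case_id}")

    return Sample(case.case_id, idx, drrs, pct01, cbct01, umask, body, eval_mask)
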