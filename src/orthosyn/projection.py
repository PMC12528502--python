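"""Digitally reconstructed radiographs (DRRs) by orthogonal parallel projection.

Two views are rendered, matching the setup-imaging geometry the framework
assumes: gantry 0 deg (source anterior, rays along the anterior-posterior
axis) and 270 deg (left lateral, rays along the left-right axis), IEC
convention for a supine patient.  The ray operator is the *mean* of voxel
values along the ray axis, which keeps DRR magnitudes comparable across
grid sizes; each view is then bilinearly resized to the output raster and
min-max normalised to [0, 1] independently.

The same numerics run in two modes: :func:`render_pair` on plain arrays for
data generation, and :func:`differentiable_project` on autodiff tensors so
the DRR-consistency loss can propagate gradients into the synthesised
volume.  Both call one tensor-path implementation, so they agree
bit-for-float.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .grad import Tensor, axis_linear, interp_matrix
from .volume import VolumeImage

log = logging.getLogger(__name__)

ANGLES = (0, 270)
AXIS_OF_ANGLE = {0: 1, 270: 0}  # 0 deg: integrate along y; 270 deg: along x

__all__ = ["ProjectionPair", "parallel_project", "render_pair",
           "differentiable_project", "project_tensor", "export_png"]


@dataclass
class ProjectionPair:
    """Two orthogonal DRRs on a common raster, values in [0, 1]."""

    img_0deg: np.ndarray
    img_270deg: np.ndarray
    pixel_spacing_mm: tuple[float, float] = (1.98, 1.98)

    def __post_init__(self):
        if self.img_0deg.shape != self.img_270deg.shape:
            raise ValueError("the two projections must share a raster")

    @property
    def raster(self) -> tuple[int, int]:
        return self.img_0deg.shape

    def stacked(self) -> np.ndarray:
        """(2, H, W) channel stack, network-input layout."""
        return np.stack([self.img_0deg, self.img_270deg])


def parallel_project(v: VolumeImage | np.ndarray, angle: int) -> np.ndarray:
    """Raw parallel projection: mean along the ray axis, no resize/normalise.

    Angle 0 yields an (x, z) image, angle 270 a (y, z) image.
    """
    if angle not in ANGLES:
        raise ValueError(f"unsupported projection angle {angle}; only {ANGLES}")
    data = v.data if isinstance(v, VolumeImage) else np.asarray(v)
    if data.ndim != 3:
        raise ValueError("projection input must be 3-D")
    return data.mean(axis=AXIS_OF_ANGLE[angle])


def project_tensor(v: Tensor, angle: int, raster: tuple[int, int] = (128, 128)) -> Tensor:
    """Tensor-path DRR: mean projection, bilinear resize to `raster`,
    then per-image min-max normalisation (resize first, normalise last,
    so the result spans exactly [0, 1])."""
    if angle not in ANGLES:
        raise ValueError(f"unsupported projection angle {angle}; only {ANGLES}")
    img = v.mean(axis=AXIS_OF_ANGLE[angle])
    img = axis_linear(img, interp_matrix(img.shape[0], raster[0]), 0)
    img = axis_linear(img, interp_matrix(img.shape[1], raster[1]), 1)
    lo, hi = img.min(), img.max()
    if hi.item() == lo.item():
        log.warning("constant projection; returning zeros")
        return img * 0.0
    return (img - lo) / (hi - lo)


def _pixel_spacing(v: VolumeImage, raster: tuple[int, int]) -> tuple[float, float]:
    # both views share z as second image axis; first axis is x (0 deg) / y (270 deg)
    ext0 = v.shape[0] * v.spacing_mm[0]
    extz = v.shape[2] * v.spacing_mm[2]
    return (ext0 / raster[0], extz / raster[1])


def render_pair(v: VolumeImage, raster: tuple[int, int] = (128, 128)) -> ProjectionPair:
    """Render the 0/270-degree DRR pair of a volume (plain-array output)."""
    t = Tensor(v.data)
    return ProjectionPair(
        img_0deg=project_tensor(t, 0, raster).data,
        img_270deg=project_tensor(t, 270, raster).data,
        pixel_spacing_mm=_pixel_spacing(v, raster),
    )


def differentiable_project(v: Tensor, raster: tuple[int, int] = (128, 128)) -> tuple[Tensor, Tensor]:
    """DRR pair of a volume inside the computation graph (for the loss)."""
    return project_tensor(v, 0, raster), project_tensor(v, 270, raster)


def export_png(img: np.ndarray, path) -> None:
    """8-bit PNG export of a [0, 1] projection, for visual inspection."""
    from PIL import Image

    arr = np.clip(img, 0.0, 1.0)
    # image row 0 at superior edge: transpose (first-axis, z) -> (z, first-axis), flip z
    Image.fromarray((arr.T[::-1] * 255).astype(np.uint8)).save(str(path))
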