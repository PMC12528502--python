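"""Volumetric containers and NIfTI input/output.

A :class:`VolumeImage` carries a 3-D scalar field either in Hounsfield
units (HU) or min-max normalised to [0, 1], together with its voxel
spacing.  When a volume is normalised, the clipped HU bounds used for the
rescaling are kept on the object so HU-domain evaluation metrics can map
model outputs back to physical units.

Axis convention: index order (x, y, z) = (left-right, anterior-posterior,
superior-inferior), 0-based, crop windows half-open.  Files are written in
canonical RAS orientation with spacing on the affine diagonal.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import nibabel as nib
import numpy as np

HU_AIR = -1000.0

__all__ = ["VolumeImage", "StructureMaskSet", "UnifiedMask", "read_nifti", "write_nifti"]


@dataclass
class VolumeImage:
    """3-D scalar field with voxel spacing and an intensity-domain tag."""

    data: np.ndarray
    spacing_mm: tuple[float, float, float]
    intensity_domain: str = "HU"  # "HU" | "normalized01"
    #: (min, max) HU bounds recorded by truncate_normalize; None while in HU
    norm_bounds: tuple[float, float] | None = None

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError(f"VolumeImage requires a 3-D array, got ndim={self.data.ndim}")
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        if len(self.spacing_mm) != 3 or any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"spacing must be three positive values, got {self.spacing_mm}")
        if self.intensity_domain not in ("HU", "normalized01"):
            raise ValueError(f"unknown intensity domain {self.intensity_domain!r}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def copy(self) -> "VolumeImage":
        return replace(self, data=self.data.copy())

    def to_hu(self) -> "VolumeImage":
        """Invert the per-case min-max normalisation using the stored bounds."""
        if self.intensity_domain == "HU":
            return self.copy()
        if self.norm_bounds is None:
            raise ValueError("normalized volume has no stored HU bounds to invert")
        lo, hi = self.norm_bounds
        return VolumeImage(self.data * (hi - lo) + lo, self.spacing_mm, "HU")


def _check_binary(arr: np.ndarray, name: str) -> np.ndarray:
    arr = np.asarray(arr)
    if not np.isin(arr, (0, 1)).all():
        raise ValueError(f"mask {name!r} must be binary (0/1)")
    return arr.astype(np.uint8)


@dataclass
class StructureMaskSet:
    """Binary masks of the four delineated radiotherapy structures."""

    ptv: np.ndarray
    bladder: np.ndarray
    rectum: np.ndarray
    body: np.ndarray

    def __post_init__(self):
        shapes = set()
        for name in ("ptv", "bladder", "rectum", "body"):
            arr = _check_binary(getattr(self, name), name)
            setattr(self, name, arr)
            shapes.add(arr.shape)
        if len(shapes) != 1:
            raise ValueError(f"mask shapes disagree: {sorted(shapes)}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.body.shape

    def items(self):
        return (("ptv", self.ptv), ("bladder", self.bladder),
                ("rectum", self.rectum), ("body", self.body))

    def copy(self) -> "StructureMaskSet":
        return StructureMaskSet(self.ptv.copy(), self.bladder.copy(),
                                self.rectum.copy(), self.body.copy())


@dataclass
class UnifiedMask:
    """Union of PTV/bladder/rectum dilated by a few voxels; used only in the loss."""

    data: np.ndarray
    dilation_px: int

    def __post_init__(self):
        self.data = _check_binary(self.data, "unified")
        if self.dilation_px < 0:
            raise ValueError("dilation_px must be >= 0")


def write_nifti(v: VolumeImage, path) -> None:
    affine = np.diag(list(v.spacing_mm) + [1.0])
    img = nib.Nifti1Image(v.data.astype(np.float32), affine)
    img.header.set_zooms(v.spacing_mm)
    nib.save(img, str(path))


def read_nifti(path, intensity_domain: str = "HU") -> VolumeImage:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3-D payload, got shape {data.shape}")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return VolumeImage(np.asarray(data, dtype=np.float64), spacing, intensity_domain)
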