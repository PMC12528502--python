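"""Synthetic pelvic phantom cohorts for the reconstruction framework.

Clinical cohorts pairing a planning CT with daily CBCTs are not publicly
shareable, so the package generates anthropomorphic stand-ins: each
"patient" is an elliptical body with a bone ring and ellipsoidal bladder,
prostate (PTV) and rectum, rasterised on a voxel grid.  Per-fraction
volumes replay the dominant sources of day-to-day pelvic variation —
bladder filling, rectal gas, small prostate displacement — plus CBCT-like
additive noise, and come pre-aligned to the planning volume (rigid
registration is assumed already applied).

Organs are analytic primitives, so every structure mask is exactly
consistent with the painted intensities and organ volumes are analytically
checkable.  All generation is a pure function of (spec, seed).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .volume import HU_AIR, StructureMaskSet, VolumeImage, write_nifti

__all__ = [
    "AnatomyState", "PhantomSpec", "PhantomCase", "Cohort",
    "generate_planning_case", "generate_fraction", "sample_state", "make_cohort",
]

DEFAULT_TISSUE_HU = {
    "body": 40.0,      # soft tissue
    "bladder": 10.0,   # urine
    "ptv": 45.0,       # prostate / prostate bed
    "rectum": 25.0,    # rectal wall + content
    "rectal_gas": -950.0,
    "bone": 700.0,
    "air": -1000.0,
}


@dataclass(frozen=True)
class AnatomyState:
    """Per-fraction anatomical state relative to the planning anatomy."""

    bladder_volume_scale: float = 1.0
    rectal_gas_fraction: float = 0.0
    rectum_radius_mm: float = 12.0
    prostate_center_offset_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    seed: int = 0

    def __post_init__(self):
        if not 0.3 <= self.bladder_volume_scale <= 3.0:
            raise ValueError(f"bladder_volume_scale {self.bladder_volume_scale} outside [0.3, 3.0]")
        if not 0.0 <= self.rectal_gas_fraction <= 1.0:
            raise ValueError(f"rectal_gas_fraction {self.rectal_gas_fraction} outside [0, 1]")
        if self.rectum_radius_mm <= 0:
            raise ValueError("rectum_radius_mm must be positive")
        if any(abs(o) > 10.0 for o in self.prostate_center_offset_mm):
            raise ValueError("prostate offsets bounded by +-10 mm")


@dataclass(frozen=True)
class PhantomSpec:
    """Cohort-level generation settings (grid, spacing, tissue HU, noise)."""

    grid_shape: tuple[int, int, int] = (64, 64, 32)
    spacing_mm: tuple[float, float, float] = (4.0, 4.0, 4.0)
    n_fractions: int = 3
    noise_sigma_hu: float = 20.0
    intensity_offset_hu: float = 0.0  # global CBCT-vs-pCT shift inside the body
    tissue_hu_table: dict = field(default_factory=lambda: dict(DEFAULT_TISSUE_HU))

    def __post_init__(self):
        if any(s % 2 for s in self.grid_shape):
            raise ValueError(f"grid_shape must be even per axis, got {self.grid_shape}")
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError("spacing must be positive")
        if self.n_fractions < 1:
            raise ValueError("n_fractions must be >= 1")
        for organ, hu in self.tissue_hu_table.items():
            if not -1000.0 <= hu <= 2000.0:
                raise ValueError(f"HU for {organ} outside [-1000, 2000]")


@dataclass(frozen=True)
class _Anatomy:
    """Planning-anatomy geometric parameters in mm, grid-centre relative.

    +x left, +y posterior, +z superior.  The rectum runs along z posterior
    to the prostate; the bladder sits anterior-superior.
    """

    body_semi_xy: tuple[float, float]
    bone_outer_xy: tuple[float, float]
    bone_thickness: float
    bone_half_z: float
    bladder_center: tuple[float, float, float]
    bladder_semi: tuple[float, float, float]
    ptv_center: tuple[float, float, float]
    ptv_semi: tuple[float, float, float]
    rectum_y: float
    rectum_radius: float


def _default_anatomy(rng: np.random.Generator | None = None) -> _Anatomy:
    """Baseline pelvis with mild per-patient variation when an rng is given."""
    u = (lambda lo, hi: rng.uniform(lo, hi)) if rng is not None else (lambda lo, hi: (lo + hi) / 2)
    return _Anatomy(
        body_semi_xy=(u(100, 118), u(82, 96)),
        bone_outer_xy=(u(82, 92), u(64, 74)),
        bone_thickness=u(7, 10),
        bone_half_z=u(42, 52),
        bladder_center=(u(-4, 4), u(-36, -30), u(12, 18)),
        bladder_semi=(u(24, 28), u(19, 23), u(19, 23)),
        ptv_center=(u(-3, 3), u(8, 12), u(-16, -10)),
        ptv_semi=(u(15, 18), u(13, 16), u(12, 14)),
        rectum_y=u(32, 42),
        rectum_radius=u(10.5, 13.5),
    )


@dataclass
class PhantomCase:
    case_id: str
    spec: PhantomSpec
    pct: VolumeImage
    masks: StructureMaskSet
    anatomy: _Anatomy
    fractions: list[tuple[VolumeImage, StructureMaskSet, AnatomyState]] = field(default_factory=list)


# -- rasterisation ------------------------------------------------------------

def _grid_mm(spec: PhantomSpec):
    """Voxel-centre coordinates in mm, origin at the grid centre."""
    axes = [
        (np.arange(n) - (n - 1) / 2.0) * s
        for n, s in zip(spec.grid_shape, spec.spacing_mm)
    ]
    return np.meshgrid(*axes, indexing="ij")


def _ellipsoid(xx, yy, zz, center, semi):
    return (((xx - center[0]) / semi[0]) ** 2
            + ((yy - center[1]) / semi[1]) ** 2
            + ((zz - center[2]) / semi[2]) ** 2) <= 1.0


def _check_fits(name: str, center, semi, anat: _Anatomy, spec: PhantomSpec):
    """Conservative analytic containment of an ellipsoid in the body cylinder."""
    a_b, b_b = anat.body_semi_xy
    half_z = spec.grid_shape[2] * spec.spacing_mm[2] / 2.0
    in_plane = ((abs(center[0]) + semi[0]) / a_b) ** 2 + ((abs(center[1]) + semi[1]) / b_b) ** 2
    if in_plane > 1.0 or abs(center[2]) + semi[2] > half_z:
        raise ValueError(f"grid/body too small to contain organ {name!r}")
    if min(semi) < min(spec.spacing_mm):
        raise ValueError(f"grid too coarse: organ {name!r} below one voxel radius")


def _rasterize(spec: PhantomSpec, anat: _Anatomy, state: AnatomyState | None):
    """Paint the phantom and derive priority-disjoint structure masks.

    Priority PTV > bladder > rectum > bone > body keeps each painted organ's
    HU exactly equal to its table entry inside its mask.
    """
    xx, yy, zz = _grid_mm(spec)
    hu = spec.tissue_hu_table

    bladder_semi = np.asarray(anat.bladder_semi, dtype=float)
    ptv_center = np.asarray(anat.ptv_center, dtype=float)
    rectum_radius = anat.rectum_radius
    if state is not None:
        bladder_semi = bladder_semi * state.bladder_volume_scale ** (1.0 / 3.0)
        ptv_center = ptv_center + np.asarray(state.prostate_center_offset_mm)
        rectum_radius = state.rectum_radius_mm

    _check_fits("bladder", anat.bladder_center, bladder_semi, anat, spec)
    _check_fits("ptv", ptv_center, anat.ptv_semi, anat, spec)
    _check_fits("rectum", (0.0, anat.rectum_y, 0.0),
                (rectum_radius, rectum_radius, min(spec.spacing_mm)), anat, spec)

    a_b, b_b = anat.body_semi_xy
    body = (xx / a_b) ** 2 + (yy / b_b) ** 2 <= 1.0
    ao, bo = anat.bone_outer_xy
    ai, bi = ao - anat.bone_thickness, bo - anat.bone_thickness
    ring = ((xx / ao) ** 2 + (yy / bo) ** 2 <= 1.0) & ((xx / ai) ** 2 + (yy / bi) ** 2 > 1.0)
    bone = ring & (np.abs(zz) <= anat.bone_half_z) & body

    bladder = _ellipsoid(xx, yy, zz, anat.bladder_center, bladder_semi) & body
    ptv = _ellipsoid(xx, yy, zz, ptv_center, anat.ptv_semi) & body
    rectum = (((xx / rectum_radius) ** 2 + ((yy - anat.rectum_y) / rectum_radius) ** 2) <= 1.0) & body

    # priority-disjoint masks
    bladder_m = bladder & ~ptv
    rectum_m = rectum & ~ptv & ~bladder_m
    bone_m = bone & ~ptv & ~bladder_m & ~rectum_m

    vol = np.full(spec.grid_shape, hu["air"])
    vol[body] = hu["body"]
    vol[bone_m] = hu["bone"]
    vol[rectum_m] = hu["rectum"]
    vol[bladder_m] = hu["bladder"]
    vol[ptv] = hu["ptv"]

    if state is not None and state.rectal_gas_fraction > 0 and rectum_m.any():
        # gas collects anteriorly (lowest y) in a supine patient
        idx = np.argwhere(rectum_m)
        order = np.lexsort((idx[:, 2], idx[:, 0], idx[:, 1]))  # y major
        n_gas = int(round(state.rectal_gas_fraction * len(idx)))
        gas_idx = idx[order[:n_gas]]
        vol[tuple(gas_idx.T)] = hu["rectal_gas"]

    masks = StructureMaskSet(ptv=ptv.astype(np.uint8), bladder=bladder_m.astype(np.uint8),
                             rectum=rectum_m.astype(np.uint8), body=body.astype(np.uint8))
    return vol, masks


# -- public operations --------------------------------------------------------

def generate_planning_case(spec: PhantomSpec, seed: int, case_id: str | None = None) -> PhantomCase:
    """Build a planning volume (pCT) and its structure set; no fractions yet."""
    rng = np.random.default_rng(seed)
    anatomy = _default_anatomy(rng)
    vol, masks = _rasterize(spec, anatomy, state=None)
    pct = VolumeImage(vol, spec.spacing_mm, "HU")
    return PhantomCase(case_id or f"case_{seed:04d}", spec, pct, masks, anatomy)


def generate_fraction(case: PhantomCase, state: AnatomyState) -> tuple[VolumeImage, StructureMaskSet]:
    """Per-fraction CBCT-like volume under `state`, masks updated to match.

    The identity state (scale 1, no gas, planning rectum radius, zero
    offsets) with zero noise/offset reproduces the planning volume exactly.
    """
    spec = case.spec
    vol, masks = _rasterize(spec, case.anatomy, state=state)
    body = masks.body.astype(bool)
    if spec.intensity_offset_hu:
        vol = vol + spec.intensity_offset_hu * body
    if spec.noise_sigma_hu > 0:
        rng = np.random.default_rng(state.seed)
        noise = rng.normal(0.0, spec.noise_sigma_hu, size=vol.shape)
        vol = vol + noise * body
    vol = np.clip(vol, -1000.0, 2000.0)
    return VolumeImage(vol, spec.spacing_mm, "HU"), masks


def sample_state(rng: np.random.Generator, base_rectum_radius_mm: float) -> AnatomyState:
    """Draw a plausible inter-fraction anatomy: bladder filling varies by
    roughly a factor two, rectal gas appears in about 60% of fractions,
    and the prostate shifts by a few millimetres."""
    scale = float(np.clip(np.exp(rng.normal(0.0, 0.25)), 0.5, 2.0))
    gas = 0.0 if rng.random() < 0.4 else float(rng.uniform(0.1, 0.6))
    radius = float(base_rectum_radius_mm * rng.uniform(0.85, 1.25))
    offset = tuple(float(np.clip(o, -6, 6)) for o in rng.normal(0.0, 2.0, size=3))
    return AnatomyState(scale, gas, radius, offset, seed=int(rng.integers(0, 2**31 - 1)))


@dataclass
class Cohort:
    """Generated cases plus the patient-wise split assignment."""

    cases: list[PhantomCase]
    split_of: dict[str, str]  # case_id -> "train" | "val" | "test"

    def split(self, name: str) -> list[PhantomCase]:
        return [c for c in self.cases if self.split_of[c.case_id] == name]

    def manifest(self) -> dict:
        return {
            "cases": [
                {
                    "case_id": c.case_id,
                    "split": self.split_of[c.case_id],
                    "n_fractions": len(c.fractions),
                    "states": [dataclasses.asdict(s) for _, _, s in c.fractions],
                }
                for c in self.cases
            ]
        }


def _split_counts(n: int, fractions: tuple[float, float, float]) -> tuple[int, int, int]:
    """Largest-remainder apportionment; nonzero shares get at least one patient."""
    raw = [f * n for f in fractions]
    counts = [int(np.floor(r)) for r in raw]
    for f, i in ((f, i) for i, f in enumerate(fractions)):
        if f > 0 and counts[i] == 0:
            counts[i] = 1
    while sum(counts) > n:
        i = int(np.argmax(counts))
        counts[i] -= 1
    rema = [r - c for r, c in zip(raw, counts)]
    while sum(counts) < n:
        i = int(np.argmax(rema))
        counts[i] += 1
        rema[i] = -1
    return tuple(counts)


def make_cohort(spec: PhantomSpec, n_patients: int,
                split_fractions: tuple[float, float, float] = (0.6, 0.2, 0.2),
                seed: int = 0, out_dir: str | Path | None = None) -> Cohort:
    """Generate `n_patients` cases with per-fraction variation and a
    patient-wise train/val/test partition (no patient in two splits)."""
    if abs(sum(split_fractions) - 1.0) > 1e-9:
        raise ValueError("split fractions must sum to 1")
    n_nonzero = sum(1 for f in split_fractions if f > 0)
    if n_patients < n_nonzero:
        raise ValueError(f"{n_patients} patients cannot fill {n_nonzero} nonempty splits")

    ss = np.random.SeedSequence(seed)
    case_seeds = [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(n_patients)]
    cases: list[PhantomCase] = []
    for p, cseed in enumerate(case_seeds):
        case = generate_planning_case(spec, cseed, case_id=f"case_{p:03d}")
        rng = np.random.default_rng(cseed + 1)
        for _ in range(spec.n_fractions):
            state = sample_state(rng, case.anatomy.rectum_radius)
            cbct, fmasks = generate_fraction(case, state)
            case.fractions.append((cbct, fmasks, state))
        cases.append(case)

    counts = _split_counts(n_patients, split_fractions)
    labels = ["train"] * counts[0] + ["val"] * counts[1] + ["test"] * counts[2]
    split_of = {c.case_id: lab for c, lab in zip(cases, labels)}
    cohort = Cohort(cases, split_of)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for c in cases:
            cdir = out / c.case_id
            cdir.mkdir(exist_ok=True)
            write_nifti(c.pct, cdir / "pct.nii")
            for name, m in c.masks.items():
                write_nifti(VolumeImage(m.astype(float), spec.spacing_mm, "HU"),
                            cdir / f"mask_{name}.nii")
            for k, (cbct, fmasks, _) in enumerate(c.fractions):
                write_nifti(cbct, cdir / f"fraction_{k:02d}.nii")
                for name, m in fmasks.items():
                    write_nifti(VolumeImage(m.astype(float), spec.spacing_mm, "HU"),
                                cdir / f"fraction_{k:02d}_mask_{name}.nii")
        (out / "manifest.json").write_text(json.dumps(cohort.manifest(), indent=2))
    return cohort
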