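"""Training losses: voxel MAE, 2.5D perceptual loss, DRR-consistency loss,
structure-masked perceptual loss, and their anatomically informed
combination (ALF).

The anatomically informed loss is

    L = alpha * MAE + beta * PL + gamma * PL_DRR + omega * PL_structures

where PL is a feature-space mean-squared error evaluated slice-wise
(all axial and all sagittal slices, "2.5D") through a VGG19-style
convolutional feature extractor at layer indices 3, 8, 15 and 22;
PL_DRR compares the projections of the synthesised volume against the
input DRRs through the differentiable projector; and PL_structures
applies PL after multiplying both volumes by the dilated unified
structure mask.  The four ablation configurations are pure weight
settings of the same function (see :data:`ABLATION_WEIGHTS`).

Feature backbones are pluggable.  The default is a seeded random-weight
CNN with the VGG19 layer topology (width-scaled): random-feature
perceptual losses are a recognised deterministic choice and need no
downloaded weights.  A pretrained VGG19 can be plugged in where torch /
torchvision are available.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .grad import Tensor, as_tensor
from .projection import ProjectionPair, differentiable_project
from .volume import UnifiedMask

__all__ = [
    "LossWeights", "FeatureExtractorSpec", "ABLATION_WEIGHTS",
    "mae_loss", "extract_features", "perceptual_loss", "pl_drr",
    "pl_structures", "alf_total",
]

#: The four loss-ablation configurations (alpha, beta, gamma, omega).
ABLATION_WEIGHTS = {
    "onlyMAE": (1.0, 0.0, 0.0, 0.0),
    "onlyPL": (0.0, 1.0, 0.0, 0.0),
    "MAE&PL": (1.0, 0.02, 0.0, 0.0),
    "ALF": (1.0, 0.05, 0.01, 0.04),
}


@dataclass(frozen=True)
class LossWeights:
    alpha: float = 1.0
    beta: float = 0.05
    gamma: float = 0.01
    omega: float = 0.04

    def __post_init__(self):
        vals = (self.alpha, self.beta, self.gamma, self.omega)
        if any(w < 0 for w in vals):
            raise ValueError(f"loss weights must be >= 0, got {vals}")
        if not any(w > 0 for w in vals):
            raise ValueError("at least one loss weight must be positive")

    @classmethod
    def preset(cls, name: str) -> "LossWeights":
        return cls(*ABLATION_WEIGHTS[name])

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.alpha, self.beta, self.gamma, self.omega)


@dataclass(frozen=True)
class FeatureExtractorSpec:
    """Which feature backbone to use and where to tap it.

    ``width`` scales the channel schedule of the seeded backbone
    (64/128/256/512 in the full-width network -> width * 1/2/4/8).
    """

    backbone: str = "seeded_random_cnn"  # or "pretrained_vgg19"
    layer_ids: tuple[int, ...] = (3, 8, 15, 22)
    seed: int = 0
    width: int = 8

    def __post_init__(self):
        if self.backbone not in ("seeded_random_cnn", "pretrained_vgg19"):
            raise ValueError(f"unknown backbone {self.backbone!r}")
        if list(self.layer_ids) != sorted(set(self.layer_ids)):
            raise ValueError("layer_ids must be strictly increasing")


# VGG19 feature-stage topology: (op, channels) per index; "M" = 2x2 max pool.
_VGG19_LAYOUT = [64, 64, "M", 128, 128, "M", 256, 256, 256, 256, "M", 512, 512, 512, 512, "M", 512, 512, 512, 512]


class _Backbone(nn.Module):
    """Feature stack following the VGG19 layout, taps at conv/ReLU indices.

    Index convention matches the canonical enumeration of the VGG19 feature
    stage, where each conv is followed by a ReLU that shares the next index:
    0 conv, 1 relu, 2 conv, 3 relu, 4 pool, 5 conv, ...  Taps at indices
    3, 8, 15, 22 therefore fall on the ReLU outputs of stages 1-4.
    """

    def __init__(self, width_map, max_index: int):
        super().__init__()
        self.ops: list[tuple[str, int]] = []  # (kind, conv-slot index)
        convs = []
        c_in = 3
        idx = 0
        for entry in _VGG19_LAYOUT:
            if idx > max_index:
                break
            if entry == "M":
                self.ops.append(("pool", -1))
                idx += 1
            else:
                c_out = width_map(entry)
                convs.append(nn.Conv2d(c_in, c_out, 3, stride=1, padding=1))
                self.ops.append(("conv", len(convs) - 1))
                self.ops.append(("relu", -1))
                c_in = c_out
                idx += 2
        for i, conv in enumerate(convs):
            setattr(self, f"conv{i}", conv)
        self.convs = convs

    def features(self, x: Tensor, layer_ids: tuple[int, ...]) -> list[Tensor]:
        wanted = set(layer_ids)
        out: dict[int, Tensor] = {}
        idx = 0
        for kind, slot in self.ops:
            if kind == "conv":
                x = self.convs[slot](x)
            elif kind == "relu":
                x = x.relu()
            else:
                x = nn.MaxPool2d()(x)
            if idx in wanted:
                out[idx] = x
            idx += 1
            if len(out) == len(wanted):
                break
        missing = wanted - set(out)
        if missing:
            raise ValueError(f"layer ids {sorted(missing)} beyond backbone depth {idx}")
        return [out[i] for i in sorted(layer_ids)]


_BACKBONE_CACHE: dict[tuple, _Backbone] = {}


def get_backbone(spec: FeatureExtractorSpec) -> _Backbone:
    key = (spec.backbone, spec.seed, spec.width, tuple(spec.layer_ids))
    if key not in _BACKBONE_CACHE:
        max_index = max(spec.layer_ids)
        if spec.backbone == "seeded_random_cnn":
            bb = _Backbone(lambda c: max(1, c * spec.width // 64), max_index)
            nn.init_weights(bb, spec.seed)
        else:
            bb = _load_pretrained_vgg19(max_index)
        for p in bb.parameters():  # frozen feature extractor
            p.requires_grad = False
        _BACKBONE_CACHE[key] = bb
    return _BACKBONE_CACHE[key]


def _load_pretrained_vgg19(max_index: int) -> _Backbone:
    """Optional pretrained backbone; requires torch + torchvision at run time."""
    try:
        from torchvision.models import VGG19_Weights, vgg19  # type: ignore
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError(
            "the pretrained_vgg19 backbone requires torchvision; use the "
            "seeded_random_cnn backbone where it is unavailable"
        ) from exc
    net = vgg19(weights=VGG19_Weights.IMAGENET1K_V1).features.eval()
    bb = _Backbone(lambda c: c, max_index)
    conv_slot = 0
    for layer in net:
        if layer.__class__.__name__ == "Conv2d":
            if conv_slot >= len(bb.convs):
                break
            bb.convs[conv_slot].weight.data[...] = layer.weight.detach().numpy()
            bb.convs[conv_slot].bias.data[...] = layer.bias.detach().numpy()
            conv_slot += 1
    return bb


def _pseudo_rgb(batch: Tensor) -> Tensor:
    """(N, H, W) -> (N, 3, H, W) by triplicating the single channel."""
    n, h, w = batch.shape
    x = batch.reshape(n, 1, h, w)
    from .grad import concat

    return concat([x, x, x], axis=1)


def extract_features(img2d, spec: FeatureExtractorSpec) -> list[Tensor]:
    """Feature maps of one [0, 1] grayscale image at the spec's layer taps."""
    t = as_tensor(img2d)
    if t.ndim != 2:
        raise ValueError("extract_features expects a single 2-D image")
    batch = t.reshape(1, *t.shape)
    return get_backbone(spec).features(_pseudo_rgb(batch), tuple(spec.layer_ids))


def _batched_feature_mse(s_batch: Tensor, c_batch: Tensor, spec: FeatureExtractorSpec) -> Tensor:
    """Mean over layers of feature-space MSE for a batch of slice pairs."""
    bb = get_backbone(spec)
    fs = bb.features(_pseudo_rgb(s_batch), tuple(spec.layer_ids))
    fc = bb.features(_pseudo_rgb(c_batch), tuple(spec.layer_ids))
    total = None
    for a, b in zip(fs, fc):
        term = ((a - b) ** 2).mean()
        total = term if total is None else total + term
    return total / float(len(fs))


def mae_loss(s, c) -> Tensor:
    """Mean absolute error over all voxels."""
    s, c = as_tensor(s), as_tensor(c)
    if s.shape != c.shape:
        raise ValueError(f"shape mismatch {s.shape} vs {c.shape}")
    return (s - c).abs().mean()


def _slices(vol: Tensor, orientation: str) -> Tensor:
    """Axial slices -> batch (Z, X, Y); sagittal slices -> batch (X, Y, Z)."""
    if orientation == "axial":
        return vol.moveaxis(2, 0)
    return vol  # sagittal: x already leads


def perceptual_loss(s_vol, c_vol, spec: FeatureExtractorSpec) -> Tensor:
    """2.5D perceptual loss: feature MSE over all axial and all sagittal
    slices of the pair, averaged over slices, layers and feature elements
    (the two orientations weighted equally)."""
    s_vol, c_vol = as_tensor(s_vol), as_tensor(c_vol)
    if s_vol.shape != c_vol.shape:
        raise ValueError(f"shape mismatch {s_vol.shape} vs {c_vol.shape}")
    terms = [
        _batched_feature_mse(_slices(s_vol, o), _slices(c_vol, o), spec)
        for o in ("axial", "sagittal")
    ]
    return (terms[0] + terms[1]) / 2.0


def pl_drr(s_vol, input_drrs: ProjectionPair, spec: FeatureExtractorSpec) -> Tensor:
    """Perceptual loss between the input DRRs and the DRRs re-projected from
    the synthesised volume (both angles, averaged)."""
    s_vol = as_tensor(s_vol)
    sdrr0, sdrr270 = differentiable_project(s_vol, raster=input_drrs.raster)
    total = None
    for sdrr, target in ((sdrr0, input_drrs.img_0deg), (sdrr270, input_drrs.img_270deg)):
        if sdrr.shape != target.shape:
            raise ValueError(f"raster mismatch {sdrr.shape} vs {target.shape}")
        n = sdrr.shape[0]
        term = _batched_feature_mse(sdrr.reshape(1, *sdrr.shape),
                                    Tensor(target).reshape(1, *target.shape), spec)
        total = term if total is None else total + term
    return total / 2.0


def pl_structures(s_vol, c_vol, umask: UnifiedMask, spec: FeatureExtractorSpec) -> Tensor:
    """Perceptual loss restricted to the clinically relevant region: both
    volumes are multiplied by the unified mask before the 2.5D loss."""
    s_vol, c_vol = as_tensor(s_vol), as_tensor(c_vol)
    if umask.data.shape != s_vol.shape:
        raise ValueError("unified mask must be aligned to the volumes")
    if not umask.data.any():
        raise ValueError("empty unified mask")
    m = Tensor(umask.data.astype(np.float64))
    return perceptual_loss(s_vol * m, c_vol * m, spec)


def alf_total(s_vol, c_vol, input_drrs: ProjectionPair | None, umask: UnifiedMask | None,
              w: LossWeights, spec: FeatureExtractorSpec,
              compute_all: bool = True) -> tuple[Tensor, dict[str, float]]:
    """Weighted anatomically informed loss plus its unweighted components.

    Zero-weight components contribute nothing to the gradient; with
    ``compute_all=False`` they are skipped entirely (reported as NaN),
    which the training loop uses to avoid dead work in the ablations.
    """
    s_vol, c_vol = as_tensor(s_vol), as_tensor(c_vol)
    total = Tensor(0.0)
    breakdown: dict[str, float] = {}

    def _term(name: str, weight: float, fn):
        nonlocal total
        if weight > 0 or compute_all:
            comp = fn()
            breakdown[name] = comp.item()
            if weight > 0:
                total = total + weight * comp
        else:
            breakdown[name] = float("nan")

    _term("mae", w.alpha, lambda: mae_loss(s_vol, c_vol))
    _term("pl", w.beta, lambda: perceptual_loss(s_vol, c_vol, spec))
    if input_drrs is None:
        if w.gamma > 0:
            raise ValueError("gamma > 0 requires input DRRs")
        breakdown["pl_drr"] = float("nan")
    else:
        _term("pl_drr", w.gamma, lambda: pl_drr(s_vol, input_drrs, spec))
    if umask is None:
        if w.omega > 0:
            raise ValueError("omega > 0 requires a unified mask")
        breakdown["pl_structures"] = float("nan")
    else:
        _term("pl_structures", w.omega, lambda: pl_structures(s_vol, c_vol, umask, spec))
    return total, breakdown
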