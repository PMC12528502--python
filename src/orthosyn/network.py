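"""Dual-branch encoder-decoder networks for 2-projection volumetric synthesis.

The flagship architecture ("fusion_skip_res") encodes the two orthogonal
DRRs with a 2-D convolutional branch and the planning CT with a mirrored
3-D branch, fuses the two latent representations through a 1x1x1
transformation layer, and decodes a synthetic CBCT with trilinear
upsampling blocks that carry encoder skip connections and residual
additions.  Three ablation variants are realised by switching flags on the
same implementation:

===============  ==========  ===============  =================
variant          3D encoder  skip connections residual decoder
===============  ==========  ===============  =================
drrs_only        no          no               no
fusion           yes         no               no
fusion_skip      yes         yes              no
fusion_skip_res  yes         yes              yes
===============  ==========  ===============  =================

Channel schedule: doubling per level from ``base_channels``; the 2-D latent
is reshaped by splitting its channel axis into (channels, depth) to match
the 3-D latent grid, conserving every element.  The final layer is a
1-channel 1x1x1 convolution with a sigmoid, bounding the output to the
[0, 1] normalised intensity domain of the target.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from . import nn
from .grad import Tensor, concat

VARIANTS = ("drrs_only", "fusion", "fusion_skip", "fusion_skip_res")

__all__ = ["ModelConfig", "ReconModel", "build_model", "VARIANTS"]


@dataclass(frozen=True)
class ModelConfig:
    variant: str = "fusion_skip_res"
    in_shape_3d: tuple[int, int, int] = (128, 128, 64)
    in_raster_2d: tuple[int, int] = (128, 128)
    base_channels: int = 64
    n_levels: int = 4
    latent_fuse_channels: int | None = None

    def __post_init__(self):
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}; choose from {VARIANTS}")
        if self.base_channels < 1 or self.n_levels < 1:
            raise ValueError("base_channels and n_levels must be >= 1")
        f = 2 ** self.n_levels
        if any(s % f for s in self.in_shape_3d):
            raise ValueError(f"in_shape_3d {self.in_shape_3d} must be divisible by {f}")
        if any(r % f for r in self.in_raster_2d):
            raise ValueError(f"in_raster_2d {self.in_raster_2d} must be divisible by {f}")
        if tuple(self.in_raster_2d) != tuple(self.in_shape_3d[:2]):
            raise ValueError(
                "the DRR raster must match the first two volume axes so the "
                f"latent grids align: raster {self.in_raster_2d} vs volume {self.in_shape_3d}"
            )

    @property
    def fuse_channels(self) -> int:
        return self.latent_fuse_channels or self.base_channels * 2 ** (self.n_levels - 1)

    @property
    def latent_depth(self) -> int:
        return self.in_shape_3d[2] // 2 ** self.n_levels

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        d = dict(d)
        for key in ("in_shape_3d", "in_raster_2d"):
            d[key] = tuple(d[key])
        return cls(**d)


class EnconvBlock(nn.Module):
    """Downsampling conv block: strided conv, instance norm, ReLU, conv."""

    def __init__(self, conv_cls, c_in: int, c_out: int):
        super().__init__()
        self.net = nn.Sequential(
            conv_cls(c_in, c_out, 3, stride=2, padding=1),
            nn.InstanceNorm(c_out),
            nn.ReLU(),
            conv_cls(c_out, c_out, 3, stride=1, padding=1),
        )

    def forward(self, x: Tensor) -> Tensor:
        return self.net(x)


class ResDeconvBlock(nn.Module):
    """Trilinear x2 upsampling, optional skip concat, stride-1 conv stack,
    optional residual addition (1x1x1 projection when channels differ)."""

    def __init__(self, c_in: int, c_skip: int, c_out: int, residual: bool):
        super().__init__()
        c_cat = c_in + c_skip
        self.residual = residual
        self.up = nn.Upsample3d()
        self.stack = nn.Sequential(
            nn.Conv3d(c_cat, c_out, 3, stride=1, padding=1),
            nn.InstanceNorm(c_out),
            nn.ReLU(),
            nn.Conv3d(c_out, c_out, 3, stride=1, padding=1),
        )
        if residual and c_cat != c_out:
            self.proj = nn.Conv3d(c_cat, c_out, 1, stride=1, padding=0)
        else:
            self.proj = None

    def forward(self, x: Tensor, skip: Tensor | None) -> Tensor:
        x = self.up(x)
        if skip is not None:
            if skip.shape[2:] != x.shape[2:]:
                raise ValueError(f"skip spatial {skip.shape[2:]} != decoder {x.shape[2:]}")
            x = concat([x, skip], axis=1)
        y = self.stack(x)
        if self.residual:
            y = y + (self.proj(x) if self.proj is not None else x)
        return y


class ReconModel(nn.Module):
    """One implementation, four variants (see module docstring)."""

    def __init__(self, cfg: ModelConfig):
        super().__init__()
        self.cfg = cfg
        self.use_3d = cfg.variant != "drrs_only"
        self.use_skips = cfg.variant in ("fusion_skip", "fusion_skip_res")
        self.use_res = cfg.variant == "fusion_skip_res"

        chs = [cfg.base_channels * 2 ** i for i in range(cfg.n_levels)]
        self.enc2d = nn.Sequential(*[
            EnconvBlock(nn.Conv2d, 2 if i == 0 else chs[i - 1], chs[i])
            for i in range(cfg.n_levels)
        ])
        if self.use_3d:
            self.enc3d_blocks = [
                EnconvBlock(nn.Conv3d, 1 if i == 0 else chs[i - 1], chs[i])
                for i in range(cfg.n_levels)
            ]
            for i, blk in enumerate(self.enc3d_blocks):
                setattr(self, f"enc3d_{i}", blk)

        c2_lat = chs[-1]
        if c2_lat % cfg.latent_depth:
            raise ValueError(
                f"2D latent channels {c2_lat} not divisible by latent depth {cfg.latent_depth}"
            )
        self.c2_reshaped = c2_lat // cfg.latent_depth
        cat_ch = self.c2_reshaped + (chs[-1] if self.use_3d else 0)
        self.transform = nn.Conv3d(cat_ch, cfg.fuse_channels, 1, stride=1, padding=0)

        dec_out = chs[-2::-1] + [chs[0]]  # e.g. 512->256->128->64->64 for n=4
        self.dec_blocks = []
        c_prev = cfg.fuse_channels
        for i, c_out in enumerate(dec_out):
            c_skip = chs[cfg.n_levels - 2 - i] if (self.use_skips and i < cfg.n_levels - 1) else 0
            blk = ResDeconvBlock(c_prev, c_skip, c_out, residual=self.use_res)
            setattr(self, f"dec_{i}", blk)
            self.dec_blocks.append(blk)
            c_prev = c_out
        self.head = nn.Conv3d(c_prev, 1, 1, stride=1, padding=0)
        # start the sigmoid output near 0.5: a saturated head is unrecoverable
        # under the L1 pull toward the mostly-air target median
        self.head.init_scale = 0.01

    def n_parameters(self) -> int:
        return sum(p.size for p in self.parameters())

    def forward(self, drrs, pct) -> Tensor:
        """drrs: (2, H, W) array/Tensor; pct: (X, Y, Z) array/Tensor in [0, 1].

        Returns the synthetic CBCT as an (X, Y, Z) tensor in [0, 1].
        """
        cfg = self.cfg
        drrs = drrs if isinstance(drrs, Tensor) else Tensor(np.asarray(drrs))
        pct = pct if isinstance(pct, Tensor) else Tensor(np.asarray(pct))
        if tuple(drrs.shape) != (2, *cfg.in_raster_2d):
            raise ValueError(f"DRR input {drrs.shape} != (2, {cfg.in_raster_2d})")
        if tuple(pct.shape) != tuple(cfg.in_shape_3d):
            raise ValueError(f"pCT input {pct.shape} != {cfg.in_shape_3d}")

        x2 = drrs.reshape(1, 2, *cfg.in_raster_2d)
        f2 = self.enc2d(x2)  # (1, C2, h, w)
        _, c2, h, w = f2.shape
        dz = cfg.latent_depth
        # split channels into (channels, depth), move depth last: (1, C', h, w, dz)
        f2r = f2.reshape(1, c2 // dz, dz, h, w).moveaxis(2, 4)

        skips: list[Tensor] = []
        if self.use_3d:
            x3 = pct.reshape(1, 1, *cfg.in_shape_3d)
            for blk in self.enc3d_blocks:
                x3 = blk(x3)
                skips.append(x3)
            fused_in = concat([f2r, skips[-1]], axis=1)
        else:
            fused_in = f2r
        z = self.transform(fused_in)

        for i, blk in enumerate(self.dec_blocks):
            skip = None
            if self.use_skips and i < cfg.n_levels - 1:
                skip = skips[cfg.n_levels - 2 - i]
            z = blk(z, skip)
        out = self.head(z).sigmoid()
        return out.reshape(*cfg.in_shape_3d)


def build_model(cfg: ModelConfig, seed: int | None = None) -> ReconModel:
    """Construct a variant; Kaiming-uniform initialised when a seed is given."""
    model = ReconModel(cfg)
    if seed is not None:
        nn.init_weights(model, seed)
    return model
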