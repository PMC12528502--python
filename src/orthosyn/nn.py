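"""Neural-network layers, initialisation and optimisation on the autodiff engine.

Provides exactly the building blocks the reconstruction networks use:
strided 2-D/3-D convolutions, instance normalisation, ReLU/sigmoid,
2x2 max pooling, trilinear x2 upsampling, Kaiming-uniform initialisation,
and a decoupled-weight-decay Adam (AdamW) optimiser.
"""

from __future__ import annotations

import numpy as np

from .grad import Tensor, axis_linear, conv_nd, interp_matrix, maxpool2d

__all__ = [
    "Module", "Sequential", "Conv2d", "Conv3d", "InstanceNorm", "ReLU",
    "Sigmoid", "MaxPool2d", "Upsample3d", "kaiming_uniform_", "init_weights",
    "AdamW",
]


class Module:
    """Base class: children registered by attribute assignment."""

    def __init__(self):
        self._params: dict[str, Tensor] = {}
        self._children: dict[str, "Module"] = {}

    def __setattr__(self, name, value):
        if isinstance(value, Module):
            self.__dict__.setdefault("_children", {})[name] = value
        elif isinstance(value, Tensor) and value.requires_grad:
            self.__dict__.setdefault("_params", {})[name] = value
        object.__setattr__(self, name, value)

    def parameters(self) -> list[Tensor]:
        out = list(self._params.values())
        for child in self._children.values():
            out.extend(child.parameters())
        return out

    def named_parameters(self, prefix: str = "") -> list[tuple[str, Tensor]]:
        out = [(prefix + n, p) for n, p in self._params.items()]
        for cname, child in self._children.items():
            out.extend(child.named_parameters(prefix + cname + "."))
        return out

    def modules(self) -> list["Module"]:
        out = [self]
        for child in self._children.values():
            out.extend(child.modules())
        return out

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    def state_dict(self) -> dict[str, np.ndarray]:
        return {n: p.data.copy() for n, p in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = dict(self.named_parameters())
        if set(own) != set(state):
            missing = sorted(set(own) ^ set(state))
            raise ValueError(f"state dict mismatch: {missing}")
        for n, p in own.items():
            if p.data.shape != state[n].shape:
                raise ValueError(f"shape mismatch for {n}: {p.data.shape} vs {state[n].shape}")
            p.data[...] = state[n]

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Sequential(Module):
    def __init__(self, *layers: Module):
        super().__init__()
        self.layers = list(layers)
        for i, layer in enumerate(layers):
            setattr(self, f"l{i}", layer)

    def forward(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x)
        return x


class _ConvNd(Module):
    nd: int

    def __init__(self, c_in: int, c_out: int, kernel_size: int, stride: int = 1,
                 padding: int = 0, bias: bool = True):
        super().__init__()
        self.c_in, self.c_out = c_in, c_out
        self.kernel_size, self.stride, self.padding = kernel_size, stride, padding
        shape = (c_out, c_in) + (kernel_size,) * self.nd
        # placeholder values; real runs call init_weights() for seeded Kaiming draws
        self.weight = Tensor(np.zeros(shape), requires_grad=True)
        self.bias = Tensor(np.zeros(c_out), requires_grad=True) if bias else None

    @property
    def fan_in(self) -> int:
        return self.c_in * self.kernel_size ** self.nd

    def forward(self, x: Tensor) -> Tensor:
        if self.stride > 1:
            for s in x.shape[2:]:
                if s % self.stride:
                    raise ValueError(
                        f"strided conv requires spatial dims divisible by {self.stride}, got {x.shape[2:]}"
                    )
        return conv_nd(x, self.weight, self.bias, stride=self.stride, padding=self.padding)


class Conv2d(_ConvNd):
    nd = 2


class Conv3d(_ConvNd):
    nd = 3


class InstanceNorm(Module):
    """Per-sample, per-channel normalisation over spatial axes, with affine."""

    def __init__(self, channels: int, eps: float = 1e-5):
        super().__init__()
        self.eps = eps
        self.weight = Tensor(np.ones(channels), requires_grad=True)
        self.bias_p = Tensor(np.zeros(channels), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        sp = tuple(range(2, x.ndim))
        mu = x.mean(axis=sp, keepdims=True)
        var = ((x - mu) ** 2).mean(axis=sp, keepdims=True)
        xhat = (x - mu) / ((var + self.eps) ** 0.5)
        bshape = (1, -1) + (1,) * (x.ndim - 2)
        return xhat * self.weight.reshape(bshape) + self.bias_p.reshape(bshape)


class ReLU(Module):
    def __init__(self):
        super().__init__()

    def forward(self, x: Tensor) -> Tensor:
        return x.relu()


class Sigmoid(Module):
    def __init__(self):
        super().__init__()

    def forward(self, x: Tensor) -> Tensor:
        return x.sigmoid()


class MaxPool2d(Module):
    def __init__(self):
        super().__init__()

    def forward(self, x: Tensor) -> Tensor:
        return maxpool2d(x)


class Upsample3d(Module):
    """Trilinear x2 upsampling of (N, C, X, Y, Z), half-pixel-centred."""

    def __init__(self):
        super().__init__()

    def forward(self, x: Tensor) -> Tensor:
        for ax in (2, 3, 4):
            x = axis_linear(x, interp_matrix(x.shape[ax], 2 * x.shape[ax]), ax)
        return x


def kaiming_uniform_(t: Tensor, fan_in: int, rng: np.random.Generator,
                     gain: float = np.sqrt(2.0)) -> None:
    """Draw U(-b, b) with b = gain * sqrt(3 / fan_in) (He uniform, ReLU gain)."""
    bound = gain * np.sqrt(3.0 / fan_in)
    t.data[...] = rng.uniform(-bound, bound, size=t.data.shape)


def init_weights(model: Module, seed: int) -> Module:
    """Seeded Kaiming-He-uniform initialisation of every conv in `model`.

    Conv biases are drawn from the fan-in uniform customary for that scheme;
    instance-norm affine parameters stay at identity.  Deterministic: the
    module traversal order is the attribute-registration order.
    """
    rng = np.random.default_rng(seed)
    for mod in model.modules():
        if isinstance(mod, _ConvNd):
            kaiming_uniform_(mod.weight, mod.fan_in, rng)
            if mod.bias is not None:
                bound = 1.0 / np.sqrt(mod.fan_in)
                mod.bias.data[...] = rng.uniform(-bound, bound, size=mod.bias.data.shape)
            # layers may request a damped draw (e.g. an output head feeding a
            # sigmoid, which must start on the responsive part of the curve)
            scale = getattr(mod, "init_scale", 1.0)
            if scale != 1.0:
                mod.weight.data *= scale
                if mod.bias is not None:
                    mod.bias.data *= scale
    return model


class AdamW:
    """Adam with decoupled weight decay (applied to conv weights and biases alike)."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 1e-2):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1.0 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1.0 - self.b2) * g * g
            mhat = self.m[i] / b1t
            vhat = self.v[i] / b2t
            p.data -= self.lr * self.weight_decay * p.data
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
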