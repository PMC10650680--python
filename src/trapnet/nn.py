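"""Neural-network building blocks on top of the autodiff engine.

Layers hold their parameters as `Tensor`s with `requires_grad=True` and
expose them through `named_parameters()` with slash-free dotted names, which
is also the key scheme used in checkpoints (`backbone.*`, `classifier.*`,
`discriminator.*`, `transformer.*`).
"""

from __future__ import annotations

from typing import Iterator

import numpy as np

from .autograd import Tensor, conv2d3x3

__all__ = ["Module", "Linear", "Conv3x3", "LayerNorm", "SGD", "he_normal"]


def he_normal(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int, dtype=np.float32) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape).astype(dtype)


class Module:
    """Minimal container: submodules and parameters are plain attributes."""

    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Tensor]]:
        for name, value in vars(self).items():
            full = f"{prefix}{name}"
            if isinstance(value, Tensor) and value.requires_grad:
                yield full, value
            elif isinstance(value, Module):
                yield from value.named_parameters(f"{full}.")
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{full}.{i}.")
                    elif isinstance(item, Tensor) and item.requires_grad:
                        yield f"{full}.{i}", item

    def parameters(self) -> list[Tensor]:
        return [p for _, p in self.named_parameters()]

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    def state_dict(self, prefix: str = "") -> dict[str, np.ndarray]:
        return {name: p.data.copy() for name, p in self.named_parameters(prefix)}

    def load_state_dict(self, state: dict[str, np.ndarray], prefix: str = "") -> None:
        own = dict(self.named_parameters(prefix))
        missing = set(own) - set(state)
        if missing:
            raise KeyError(f"checkpoint is missing parameters: {sorted(missing)[:5]}...")
        for name, p in own.items():
            arr = np.asarray(state[name])
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for {name}: {arr.shape} vs {p.data.shape}")
            p.data = arr.astype(p.data.dtype)


class Linear(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator, dtype=np.float32, zero_init: bool = False):
        if zero_init:
            w = np.zeros((n_in, n_out), dtype=dtype)
        else:
            w = he_normal(rng, (n_in, n_out), fan_in=n_in, dtype=dtype)
        self.weight = Tensor(w, requires_grad=True)
        self.bias = Tensor(np.zeros(n_out, dtype=dtype), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class Conv3x3(Module):
    """3x3 convolution, padding 1, configurable stride."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator, stride: int = 1, dtype=np.float32):
        self.stride = stride
        self.weight = Tensor(he_normal(rng, (c_out, c_in, 3, 3), fan_in=c_in * 9, dtype=dtype), requires_grad=True)
        self.bias = Tensor(np.zeros(c_out, dtype=dtype), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return conv2d3x3(x, self.weight, self.bias, stride=self.stride)

    def named_parameters(self, prefix: str = ""):
        yield f"{prefix}weight", self.weight
        yield f"{prefix}bias", self.bias


class LayerNorm(Module):
    def __init__(self, dim: int, dtype=np.float32, eps: float = 1e-5):
        self.eps = eps
        self.gain = Tensor(np.ones(dim, dtype=dtype), requires_grad=True)
        self.shift = Tensor(np.zeros(dim, dtype=dtype), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        centered = x - mu
        var = (centered * centered).mean(axis=-1, keepdims=True)
        inv = (var + self.eps) ** -0.5
        return centered * inv * self.gain + self.shift


class SGD:
    """Stochastic gradient descent with classical momentum and lr groups.

    Each group is a dict with keys `params` (list of Tensors) and `lr_scale`
    (multiplier applied to the base rate passed to `step`), mirroring the
    1x backbone / 10x new-layers convention of fine-tuning protocols.
    """

    def __init__(self, groups: list[dict], momentum: float = 0.9, weight_decay: float = 0.0):
        self.groups = groups
        self.momentum = momentum
        self.weight_decay = weight_decay
        self._velocity = [[np.zeros_like(p.data) for p in g["params"]] for g in groups]

    def step(self, base_lr: float) -> None:
        for group, vel in zip(self.groups, self._velocity):
            lr = base_lr * group.get("lr_scale", 1.0)
            for p, v in zip(group["params"], vel):
                if p.grad is None:
                    continue
                g = p.grad
                if self.weight_decay:
                    g = g + self.weight_decay * p.data
                v *= self.momentum
                v += g
                p.data = p.data - lr * v

    def zero_grad(self) -> None:
        for g in self.groups:
            for p in g["params"]:
                p.zero_grad()
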