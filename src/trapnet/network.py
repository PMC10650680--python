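"""Network components: feature extractor G, label classifier C, domain
discriminator D, the gradient reversal layer, and the conditional join
h = (f, g).

The adversarial game is the usual one: D is trained to tell source features
from target features, while G — receiving D's gradient through the reversal
layer — is trained to make them indistinguishable.  Conditioning the
discriminator on the classifier output g (the join h) lets the alignment
respect class structure instead of blindly matching marginals.

The feature extractor is pluggable.  The default is a small 4-stage
stride-2 CNN that maps a 64x64 image to a 4x4 spatial map (the "local"
features X_L) and its spatial mean (the "global" vector X_G = f), which is
what the classifier, the discriminator join, and the transformer token head
consume.  Deeper backbones are reachable through the same interface by
widening/deepening the stage list.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import autograd as ag
from .autograd import Tensor
from .nn import Conv3x3, LayerNorm, Linear, Module

__all__ = [
    "FeatureBundle",
    "GRLContext",
    "SmallCNN",
    "LabelClassifier",
    "DomainDiscriminator",
    "join_features",
    "grl_apply",
    "save_checkpoint",
    "load_checkpoint",
    "SCORE_EPS",
]

# domain scores are clamped to [SCORE_EPS, 1 - SCORE_EPS] before the
# adversarial loss so log(D) and log(1-D) stay finite
SCORE_EPS = 1e-6


@dataclass
class FeatureBundle:
    """Backbone outputs for a batch of images.

    local_map: (B, H, W, C_f) spatial features from the last stage.
    global_vec: (B, C_f) spatial mean of local_map.
    f: the vector fed to the classifier and to the discriminator join;
       defaults to global_vec.
    """

    local_map: Tensor
    global_vec: Tensor
    f: Tensor

    @property
    def grid_shape(self) -> tuple[int, int]:
        return self.local_map.shape[1], self.local_map.shape[2]


@dataclass(frozen=True)
class GRLContext:
    """Gradient reversal coefficient; forward is the identity."""

    lam: float = 1.0

    def __post_init__(self):
        if self.lam < 0:
            raise ValueError("reversal coefficient must be >= 0")


def grl_apply(x: Tensor, ctx: GRLContext) -> Tensor:
    """Identity forward; backward multiplies the upstream gradient by -lam."""
    return ag.grl(x, ctx.lam)


def join_features(f: Tensor, g: Tensor, mode: str = "concat", detach_g: bool = True) -> Tensor:
    """Conditional feature join h = (f, g) fed to the domain discriminator.

    concat mode returns [f || g] (length d_f + d); multilinear mode returns
    vec(f g^T) (length d_f * d).  g is a conditioning signal, not a gradient
    path to the classifier head, so it is detached by default.
    """
    if f.size == 0 or g.size == 0:
        raise ValueError("cannot join empty feature vectors")
    if detach_g:
        g = g.detach()
    single = f.ndim == 1
    if single:
        f = f.reshape(1, -1)
        g = g.reshape(1, -1)
    if mode == "concat":
        h = ag.concat([f, g], axis=1)
    elif mode == "multilinear":
        b, df = f.shape
        d = g.shape[1]
        h = (f.reshape(b, df, 1) * g.reshape(b, 1, d)).reshape(b, df * d)
    else:
        raise ValueError(f"unknown join mode: {mode!r}")
    return h.reshape(-1) if single else h


class SmallCNN(Module):
    """4-stage stride-2 CNN feature extractor.

    Each stage halves the spatial resolution with a 3x3 stride-2 convolution
    followed by ReLU, so a 64x64 input yields a 4x4 local map.  Images enter
    channels-last (B, H, W, 3), already normalized.
    """

    def __init__(
        self,
        rng: np.random.Generator,
        channels: tuple[int, ...] = (8, 16, 32, 64),
        in_channels: int = 3,
        final_norm: bool = True,
        dtype=np.float32,
    ):
        self.in_channels = in_channels
        self.stages = []
        c_prev = in_channels
        for c in channels:
            self.stages.append(Conv3x3(c_prev, c, rng, stride=2, dtype=dtype))
            c_prev = c
        self.out_channels = c_prev
        # channel-wise normalization of the last stage keeps the feature
        # scale bounded — without it the adversarial gradient can inflate
        # feature norms without limit and destabilize the minimax game
        self.norm = LayerNorm(c_prev, dtype=dtype) if final_norm else None

    def __call__(self, images: Tensor) -> FeatureBundle:
        if images.ndim != 4 or images.shape[-1] != self.in_channels:
            raise ValueError(
                f"expected (B, H, W, {self.in_channels}) channels-last images, got {images.shape}"
            )
        x = images.transpose(0, 3, 1, 2)
        for conv in self.stages:
            # leaky activations keep a recovery gradient if the adversarial
            # pressure drives a stage toward all-dead units
            x = conv(x).leaky_relu(0.1)
        local = x.transpose(0, 2, 3, 1)  # (B, H, W, C)
        if self.norm is not None:
            local = self.norm(local)
        global_vec = local.mean(axis=(1, 2))
        return FeatureBundle(local_map=local, global_vec=global_vec, f=global_vec)


class LabelClassifier(Module):
    """Linear classification head C on top of the pooled feature f."""

    def __init__(self, d_f: int, n_classes: int, rng: np.random.Generator, dtype=np.float32):
        self.head = Linear(d_f, n_classes, rng, dtype=dtype)

    def __call__(self, f: Tensor) -> Tensor:
        return self.head(f)


class DomainDiscriminator(Module):
    """MLP mapping the join h to a source-probability in (0, 1).

    Two hidden layers (default width 256) with LeakyReLU, sigmoid output,
    clamped away from {0, 1} so the adversarial loss stays finite.
    """

    def __init__(
        self,
        d_in: int,
        rng: np.random.Generator,
        hidden: tuple[int, ...] = (256, 256),
        negative_slope: float = 0.2,
        eps: float = SCORE_EPS,
        dtype=np.float32,
    ):
        self.negative_slope = negative_slope
        self.eps = eps
        self.layers = []
        prev = d_in
        for width in hidden:
            self.layers.append(Linear(prev, width, rng, dtype=dtype))
            prev = width
        self.out = Linear(prev, 1, rng, dtype=dtype)

    def forward_logits(self, h: Tensor) -> Tensor:
        """Pre-sigmoid scores; the stable path for the adversarial loss."""
        single = h.ndim == 1
        x = h.reshape(1, -1) if single else h
        for layer in self.layers:
            x = layer(x).leaky_relu(self.negative_slope)
        z = self.out(x).reshape(-1)
        return z[0] if single else z

    def __call__(self, h: Tensor) -> Tensor:
        score = self.forward_logits(h).sigmoid()
        return score.clip(self.eps, 1.0 - self.eps)


# -- checkpoints ---------------------------------------------------------------


def config_hash(config: dict) -> str:
    return hashlib.sha256(json.dumps(config, sort_keys=True).encode()).hexdigest()[:16]


def save_checkpoint(path, state: dict[str, np.ndarray], config: dict) -> None:
    """Write all parameter tensors plus the config and its hash.

    Keys follow the ``backbone.* / classifier.* / discriminator.* /
    transformer.*`` naming scheme.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    meta = json.dumps({"config": config, "config_hash": config_hash(config)})
    np.savez(path, __meta__=np.frombuffer(meta.encode(), dtype=np.uint8), **state)


def load_checkpoint(path) -> tuple[dict[str, np.ndarray], dict]:
    with np.load(Path(path), allow_pickle=False) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        state = {k: data[k] for k in data.files if k != "__meta__"}
    return state, meta["config"]
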