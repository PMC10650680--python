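"""Transformer token head over backbone features.

The last-stage spatial map X_L is read as a sequence of H*W local patch
tokens and the pooled vector X_G as one global token (position 0).  Each is
linearly projected to the model width, learned positional embeddings are
added, and the sequence runs through standard transformer encoder blocks
(multi-head self-attention + feed-forward, residual + layer norm).  Class
scores Z are read from the output global token, and their cross-entropy on
labeled source samples is the transfer term L_T of the training objective:
it forces the long-range local/global structure of the image, not just the
pooled feature, to be class-discriminative.
"""

from __future__ import annotations

import numpy as np

from . import autograd as ag
from .autograd import Tensor
from .losses import transformer_loss
from .network import FeatureBundle
from .nn import LayerNorm, Linear, Module

__all__ = ["EncoderBlock", "TokenHead"]


class EncoderBlock(Module):
    """Post-norm transformer encoder block."""

    def __init__(self, d_model: int, n_heads: int, d_ff: int, rng: np.random.Generator, dtype=np.float32):
        if d_model % n_heads:
            raise ValueError("d_model must be divisible by n_heads")
        self.n_heads = n_heads
        self.d_head = d_model // n_heads
        self.qkv = Linear(d_model, 3 * d_model, rng, dtype=dtype)
        self.proj = Linear(d_model, d_model, rng, dtype=dtype)
        self.norm1 = LayerNorm(d_model, dtype=dtype)
        self.norm2 = LayerNorm(d_model, dtype=dtype)
        self.ff1 = Linear(d_model, d_ff, rng, dtype=dtype)
        self.ff2 = Linear(d_ff, d_model, rng, dtype=dtype)
        self.last_attention: np.ndarray | None = None  # (B, heads, T, T), diagnostics

    def _attend(self, x: Tensor) -> Tensor:
        b, t, d = x.shape
        qkv = self.qkv(x).reshape(b, t, 3, self.n_heads, self.d_head)
        qkv = qkv.transpose(2, 0, 3, 1, 4)  # (3, B, heads, T, d_head)
        q, k, v = qkv[0], qkv[1], qkv[2]
        scores = ag.matmul(q, k.transpose(0, 1, 3, 2)) * (1.0 / np.sqrt(self.d_head))
        attn = ag.softmax(scores, axis=-1)
        self.last_attention = attn.data.copy()
        out = ag.matmul(attn, v)  # (B, heads, T, d_head)
        out = out.transpose(0, 2, 1, 3).reshape(b, t, d)
        return self.proj(out)

    def __call__(self, x: Tensor) -> Tensor:
        x = self.norm1(x + self._attend(x))
        ff = self.ff2(self.ff1(x).relu())
        return self.norm2(x + ff)


class TokenHead(Module):
    """Tokenization + encoder stack + linear class head on the global token."""

    def __init__(
        self,
        c_f: int,
        grid: tuple[int, int],
        n_classes: int,
        rng: np.random.Generator,
        d_model: int = 256,
        n_heads: int = 4,
        d_ff: int = 512,
        n_layers: int = 1,
        pos_init_std: float = 0.02,
        dtype=np.float32,
    ):
        self.grid = tuple(grid)
        n_tokens = self.grid[0] * self.grid[1] + 1
        self.proj_local = Linear(c_f, d_model, rng, dtype=dtype)
        self.proj_global = Linear(c_f, d_model, rng, dtype=dtype)
        self.pos = Tensor(rng.normal(0.0, pos_init_std, size=(n_tokens, d_model)).astype(dtype), requires_grad=True)
        self.blocks = [EncoderBlock(d_model, n_heads, d_ff, rng, dtype=dtype) for _ in range(n_layers)]
        self.head = Linear(d_model, n_classes, rng, dtype=dtype)

    def tokenize(self, bundle: FeatureBundle, include_local: bool = True) -> Tensor:
        """Build the (B, H*W + 1, d_model) token sequence.

        Position 0 is the global token (projected X_G); positions 1..H*W are
        the spatial cells of X_L in row-major order.  ``include_local=False``
        is a degenerate-sequence ablation keeping only the global token.
        """
        b, h, w, c = bundle.local_map.shape
        g_tok = self.proj_global(bundle.global_vec).reshape(b, 1, -1)
        if include_local:
            local = bundle.local_map.reshape(b, h * w, c)
            l_tok = self.proj_local(local)
            seq = ag.concat([g_tok, l_tok], axis=1)
            return seq + self.pos
        return g_tok + self.pos[0:1]

    def forward_tokens(self, seq: Tensor) -> Tensor:
        """Run the encoder stack; return class scores Z from the global token."""
        x = seq
        for block in self.blocks:
            x = block(x)
        return self.head(x[:, 0, :])

    def __call__(self, bundle: FeatureBundle) -> Tensor:
        return self.forward_tokens(self.tokenize(bundle))

    def branch_loss(self, bundle: FeatureBundle, y: np.ndarray) -> Tensor:
        """Mean transfer loss L_T of a labeled (source) batch."""
        return transformer_loss(self(bundle), y)
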