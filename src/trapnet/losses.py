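"""Loss terms of the joint adaptation objective.

The training objective combines four terms:

    L = L_CE + alpha * lambda(p) * L_Adv + beta * L_CA + gamma * L_T

* ``L_CE`` — supervised cross-entropy on labeled source images.
* ``L_Adv`` — a reverse-focal adversarial loss on the domain discriminator:
  each sample is weighted by ``exp(D)`` (source) or ``exp(1-D)`` (target),
  up-weighting easily discriminated — i.e. poorly aligned — samples.
* ``L_CA`` — correlation alignment of the label-classifier output batches:
  the squared Frobenius distance of their d x d covariance (correlation)
  matrices, scaled by 1/(4 d^2).  Its backward pass is the analytic
  chain-rule formula rather than tape replay.
* ``L_T`` — cross-entropy on the class scores Z emitted by the transformer
  token head, computed on labeled (source) samples only.

All reductions are arithmetic means over the batch.  Functions accept either
plain numpy arrays (returning floats/arrays) or autograd ``Tensor``s
(returning a ``Tensor`` wired into the graph).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autograd import Tensor, gather_rows, logsumexp

__all__ = [
    "LossBreakdown",
    "coral_gradient",
    "coral_loss",
    "correlation_matrix",
    "cross_entropy",
    "reverse_focal_adv_loss",
    "reverse_focal_adv_loss_logits",
    "source_ce_loss",
    "total_loss",
    "transformer_loss",
]


def _as_array(x) -> np.ndarray:
    return x.data if isinstance(x, Tensor) else np.asarray(x, dtype=float)


def _check_classifier_batch(B: np.ndarray, name: str) -> None:
    if B.ndim != 2:
        raise ValueError(f"{name} must be a 2-D (batch x features) matrix")
    if B.shape[0] < 2:
        raise ValueError(f"{name}: batch too small for covariance (need N >= 2)")
    if not np.all(np.isfinite(B)):
        raise ValueError(f"{name} contains non-finite entries")


def correlation_matrix(B) -> np.ndarray:
    """Sample covariance of the columns of a batch matrix B (N x d).

    Computed as (1/(N-1)) * (B'B - (1/N) (1'B)'(1'B)), which equals the
    column-centered covariance with the N-1 (Bessel) normalization.
    """
    B = _as_array(B)
    _check_classifier_batch(B, "B")
    n = B.shape[0]
    s = B.sum(axis=0)
    C = (B.T @ B - np.outer(s, s) / n) / (n - 1)
    return (C + C.T) / 2.0  # enforce exact symmetry


def _coral_value(bs: np.ndarray, bt: np.ndarray) -> tuple[float, np.ndarray]:
    d = bs.shape[1]
    diff = correlation_matrix(bs) - correlation_matrix(bt)
    return float((diff**2).sum() / (4.0 * d * d)), diff


def coral_gradient(B_S, B_T) -> tuple[np.ndarray, np.ndarray]:
    """Analytic partials of `coral_loss` w.r.t. both classifier batches.

    d L_CA / d B_S = 1/(d^2 (N_S - 1)) * (B_S - 1 mean(B_S)) (C_S - C_T)
    d L_CA / d B_T = -1/(d^2 (N_T - 1)) * (B_T - 1 mean(B_T)) (C_S - C_T)

    The target gradient carries the opposite sign because C_T enters the
    covariance difference negatively.
    """
    bs, bt = _as_array(B_S), _as_array(B_T)
    _check_classifier_batch(bs, "B_S")
    _check_classifier_batch(bt, "B_T")
    if bs.shape[1] != bt.shape[1]:
        raise ValueError("B_S and B_T must share the feature dimension d")
    d = bs.shape[1]
    diff = correlation_matrix(bs) - correlation_matrix(bt)
    g_s = (bs - bs.mean(axis=0)) @ diff / (d * d * (bs.shape[0] - 1))
    g_t = -(bt - bt.mean(axis=0)) @ diff / (d * d * (bt.shape[0] - 1))
    return g_s, g_t


def coral_loss(B_S, B_T):
    """Correlation-alignment loss (1/(4 d^2)) * ||C_S - C_T||_F^2.

    Symmetric in its arguments, zero iff the two batch covariances agree.
    Tensor inputs produce a scalar Tensor whose backward pass applies
    `coral_gradient` analytically.
    """
    bs, bt = _as_array(B_S), _as_array(B_T)
    _check_classifier_batch(bs, "B_S")
    _check_classifier_batch(bt, "B_T")
    if bs.shape[1] != bt.shape[1]:
        raise ValueError("B_S and B_T must share the feature dimension d")
    value, _ = _coral_value(bs, bt)
    if not (isinstance(B_S, Tensor) or isinstance(B_T, Tensor)):
        return value

    ts = B_S if isinstance(B_S, Tensor) else Tensor(bs)
    tt = B_T if isinstance(B_T, Tensor) else Tensor(bt)

    def backward(g):
        g = float(np.asarray(g))
        g_s, g_t = coral_gradient(bs, bt)
        if ts.requires_grad:
            ts._accumulate(g * g_s)
        if tt.requires_grad:
            tt._accumulate(g * g_t)

    return ts._node(np.asarray(value, dtype=bs.dtype), (ts, tt), backward)


def reverse_focal_adv_loss(d_src, d_tgt, detach_weights: bool = True):
    """Reverse-focal domain-adversarial loss.

    -(1/n_s) sum exp(D_i) log D_i  -  (1/n_t) sum exp(1-D_j) log(1-D_j)

    ``d_src``/``d_tgt`` are discriminator outputs (source-probabilities),
    strictly inside (0, 1); callers are responsible for clamping.  The focal
    weights exp(D) and exp(1-D) are treated as constants for gradient
    purposes unless ``detach_weights=False``.
    """
    src_arr, tgt_arr = _as_array(d_src), _as_array(d_tgt)
    for name, arr in (("d_src", src_arr), ("d_tgt", tgt_arr)):
        if arr.size < 1:
            raise ValueError(f"{name} must contain at least one score")
        if np.any(arr <= 0.0) or np.any(arr >= 1.0):
            raise ValueError(f"{name} scores must lie strictly inside (0, 1)")

    ds = d_src if isinstance(d_src, Tensor) else Tensor(src_arr)
    dt = d_tgt if isinstance(d_tgt, Tensor) else Tensor(tgt_arr)
    w_src = np.exp(src_arr) if detach_weights else ds.exp()
    w_tgt = np.exp(1.0 - tgt_arr) if detach_weights else (1.0 - dt).exp()
    loss = -(w_src * ds.log()).mean() - (w_tgt * (1.0 - dt).log()).mean()
    if isinstance(d_src, Tensor) or isinstance(d_tgt, Tensor):
        return loss
    return float(loss.data)


def reverse_focal_adv_loss_logits(z_src, z_tgt, detach_weights: bool = True):
    """`reverse_focal_adv_loss` evaluated from discriminator logits.

    Uses -log D = softplus(-z) and -log(1-D) = softplus(z), so the gradient
    never vanishes when the discriminator saturates — the clamped
    probability-space form zeroes the gradient outside the clamp range,
    which can trap the adversarial game in a saturated state.  Values agree
    with the probability-space form wherever the scores are representable.
    """
    zs = z_src if isinstance(z_src, Tensor) else Tensor(np.asarray(z_src, dtype=float))
    zt = z_tgt if isinstance(z_tgt, Tensor) else Tensor(np.asarray(z_tgt, dtype=float))
    if zs.size < 1 or zt.size < 1:
        raise ValueError("each domain needs at least one score")
    d_s = 1.0 / (1.0 + np.exp(-zs.data))
    d_t = 1.0 / (1.0 + np.exp(-zt.data))
    w_src = np.exp(d_s) if detach_weights else zs.sigmoid().exp()
    w_tgt = np.exp(1.0 - d_t) if detach_weights else (1.0 - zt.sigmoid()).exp()
    loss = (w_src * (-zs).softplus()).mean() + (w_tgt * zt.softplus()).mean()
    if isinstance(z_src, Tensor) or isinstance(z_tgt, Tensor):
        return loss
    return float(loss.data)


def cross_entropy(logits, y):
    """Mean negative log-softmax of the true-class score.

    ``y`` holds zero-based integer class labels; an out-of-range label
    raises IndexError.
    """
    y = np.asarray(y)
    arr = _as_array(logits)
    if arr.ndim != 2:
        raise ValueError("logits must be 2-D (batch x classes)")
    if y.shape[0] != arr.shape[0]:
        raise ValueError("labels and logits disagree on batch size")
    if y.size and (y.min() < 0 or y.max() >= arr.shape[1]):
        raise IndexError("class label out of range")
    t = logits if isinstance(logits, Tensor) else Tensor(arr)
    loss = (logsumexp(t, axis=1) - gather_rows(t, y)).mean()
    return loss if isinstance(logits, Tensor) else float(loss.data)


def transformer_loss(Z, y):
    """Cross-entropy on the transformer head's class scores (source only)."""
    return cross_entropy(Z, y)


def source_ce_loss(logits, y):
    """Supervised cross-entropy of the label classifier on source samples."""
    return cross_entropy(logits, y)


@dataclass
class LossBreakdown:
    """The four loss terms with their weights and the adversarial ramp.

    ``ramp`` is lambda(p) from the schedules module; the effective
    adversarial weight is ``alpha * ramp``.
    """

    l_ce: float
    l_adv: float
    l_ca: float
    l_t: float
    alpha: float = 1.0
    beta: float = 0.25
    gamma: float = 0.25
    ramp: float = 1.0

    @property
    def weights(self) -> tuple[float, float, float]:
        return (self.alpha, self.beta, self.gamma)

    @property
    def total(self):
        return total_loss(self)


def total_loss(parts: LossBreakdown):
    """Weighted total objective; works on floats and on Tensors alike."""
    if min(parts.alpha, parts.beta, parts.gamma) < 0:
        raise ValueError("loss weights must be non-negative")
    return (
        parts.l_ce
        + (parts.alpha * parts.ramp) * parts.l_adv
        + parts.beta * parts.l_ca
        + parts.gamma * parts.l_t
    )
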