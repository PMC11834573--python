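"""Functional neural-network building blocks on the autograd backend.

Models are pure functions of a nested-dict parameter tree of NumPy arrays;
gradients come from reverse-mode automatic differentiation (the ``autograd``
package).  This keeps every forward pass deterministic and every training
run exactly reproducible from its seed, at the cost of CPU-scale speed —
the intended regime for this package's desk-scale experiments.
"""

from __future__ import annotations

import autograd.numpy as anp
import numpy as np
from autograd.misc import flatten

__all__ = [
    "init_linear", "linear", "init_embedding", "embedding",
    "init_layer_norm", "layer_norm", "gelu", "softmax", "softplus", "sigmoid",
    "smooth_l1", "cross_entropy_logits", "bce_logits",
    "AdamState", "adam_step", "linear_warmup_decay", "clip_global_norm",
    "tree_scale", "ParamInit",
]


class ParamInit:
    """Seeded initializer producing Glorot-scaled weights."""

    def __init__(self, seed: int):
        self.rng = np.random.default_rng(seed)

    def dense(self, fan_in: int, fan_out: int) -> np.ndarray:
        scale = np.sqrt(2.0 / (fan_in + fan_out))
        return self.rng.normal(0.0, scale, (fan_in, fan_out))

    def embed(self, n: int, d: int) -> np.ndarray:
        return self.rng.normal(0.0, 0.02, (n, d))


def init_linear(init: ParamInit, d_in: int, d_out: int, zero: bool = False) -> dict:
    w = np.zeros((d_in, d_out)) if zero else init.dense(d_in, d_out)
    return {"w": w, "b": np.zeros(d_out)}


def linear(p: dict, x):
    return x @ p["w"] + p["b"]


def init_embedding(init: ParamInit, n_tokens: int, d: int) -> dict:
    return {"table": init.embed(n_tokens, d)}


def embedding(p: dict, idx):
    return p["table"][idx]


def init_layer_norm(d: int) -> dict:
    return {"gamma": np.ones(d), "beta": np.zeros(d)}


def layer_norm(p: dict, x, eps: float = 1e-5):
    mu = anp.mean(x, axis=-1, keepdims=True)
    xc = x - mu
    var = anp.mean(xc * xc, axis=-1, keepdims=True)
    return p["gamma"] * xc / anp.sqrt(var + eps) + p["beta"]


def gelu(x):
    # tanh approximation; x*x*x instead of x**3 keeps the autodiff tape cheap
    return 0.5 * x * (1.0 + anp.tanh(0.7978845608028654 * (x + 0.044715 * (x * x * x))))


def softmax(x, axis=-1):
    x = x - anp.max(x, axis=axis, keepdims=True)
    e = anp.exp(x)
    return e / anp.sum(e, axis=axis, keepdims=True)


def softplus(x):
    return anp.logaddexp(0.0, x)


def sigmoid(x):
    return 0.5 * (anp.tanh(0.5 * x) + 1.0)


def smooth_l1(pred, target, beta: float = 1.0):
    """Huber-style loss: quadratic below ``beta``, linear above (elementwise)."""
    d = anp.abs(pred - target)
    return anp.where(d < beta, 0.5 * d * d / beta, d - 0.5 * beta)


def cross_entropy_logits(logits, targets, weights=None):
    """Mean cross-entropy of integer ``targets`` under ``logits``.

    ``weights`` (same shape as ``targets``) selects/weights positions; the
    mean is over total weight.
    """
    logits_max = anp.max(logits, axis=-1)
    logz = anp.log(anp.sum(anp.exp(logits - logits_max[..., None]), axis=-1)) + logits_max
    onehot = np.eye(logits.shape[-1])[np.asarray(targets)]
    ll = anp.sum(logits * onehot, axis=-1)
    nll = logz - ll
    if weights is None:
        return anp.mean(nll)
    w = np.asarray(weights, dtype=float)
    return anp.sum(nll * w) / max(w.sum(), 1e-12)


def bce_logits(logits, labels, weights=None):
    """Mean binary cross-entropy of {0,1} labels under logit scores."""
    labels = np.asarray(labels, dtype=float)
    # log(1+e^x) formulated stably via logaddexp
    nll = softplus(logits) - labels * logits
    if weights is None:
        return anp.mean(nll)
    w = np.asarray(weights, dtype=float)
    return anp.sum(nll * w) / max(w.sum(), 1e-12)


class AdamState:
    """Adam moments over a flattened parameter tree."""

    def __init__(self, params: dict):
        flat, _ = flatten(params)
        self.m = np.zeros_like(flat)
        self.v = np.zeros_like(flat)
        self.t = 0


def adam_step(
    params: dict,
    grads: dict,
    state: AdamState,
    lr: float,
    betas: tuple[float, float] = (0.9, 0.99),
    eps: float = 1e-8,
    weight_decay: float = 0.0,
) -> dict:
    """One Adam update with decoupled weight decay; returns new params."""
    flat_p, unflatten = flatten(params)
    flat_g, _ = flatten(grads)
    b1, b2 = betas
    state.t += 1
    state.m = b1 * state.m + (1 - b1) * flat_g
    state.v = b2 * state.v + (1 - b2) * flat_g**2
    mhat = state.m / (1 - b1**state.t)
    vhat = state.v / (1 - b2**state.t)
    flat_p = flat_p - lr * (mhat / (np.sqrt(vhat) + eps) + weight_decay * flat_p)
    return unflatten(flat_p)


def linear_warmup_decay(step: int, peak_lr: float, warmup_steps: int, total_steps: int) -> float:
    """Piecewise-linear schedule: 0 → peak over warmup, then linear decay to 0."""
    if total_steps <= 0:
        return peak_lr
    if warmup_steps > 0 and step < warmup_steps:
        return peak_lr * (step + 1) / warmup_steps
    if total_steps <= warmup_steps:
        return peak_lr
    frac = (step - warmup_steps) / max(total_steps - warmup_steps, 1)
    return peak_lr * max(0.0, 1.0 - frac)


def clip_global_norm(grads: dict, max_norm: float) -> dict:
    """Rescale a gradient tree so its global L2 norm is at most ``max_norm``."""
    flat, unflatten = flatten(grads)
    norm = np.linalg.norm(flat)
    if norm > max_norm > 0:
        flat = flat * (max_norm / norm)
    return unflatten(flat)


def tree_scale(params: dict, factor: float) -> dict:
    flat, unflatten = flatten(params)
    return unflatten(flat * factor)
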