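"""Capsule-network primitives: squash, dynamic routing, margin loss.

Each primitive exists twice: a plain NumPy reference (public API, exact at
the degenerate points, used for analysis and as the comparison point in
tests) and a graph version built on :mod:`.autodiff` Tensors that the
trainable capsule classifiers differentiate through.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor

__all__ = ["squash", "dynamic_routing", "margin_loss",
           "squash_t", "routing_t", "margin_loss_t"]


def squash(v: np.ndarray, axis: int = -1) -> np.ndarray:
    """Capsule nonlinearity ``(|v|^2 / (1 + |v|^2)) * v / |v|``.

    Preserves direction while mapping the norm into [0, 1): norm 0 -> 0
    (exactly), 1 -> 0.5, 3 -> 0.9.
    """
    v = np.asarray(v, dtype=float)
    n2 = np.sum(v * v, axis=axis, keepdims=True)
    norm = np.sqrt(n2)
    scale = np.where(norm > 0, n2 / (1.0 + n2) / np.where(norm > 0, norm, 1.0), 0.0)
    return v * scale


def dynamic_routing(u_hat: np.ndarray, iters: int = 3) -> np.ndarray:
    """Route prediction vectors to parent capsules by iterative agreement.

    ``u_hat`` has shape ``(..., n_in, n_parent, dim)``: the prediction each
    input capsule makes for each parent.  Routing logits start at zero;
    each iteration computes couplings as a softmax over parents, forms each
    parent as the squash of its coupling-weighted prediction sum, then
    increases the logit of every (input, parent) pair by the scalar product
    of prediction and parent.  Returns the final parents,
    shape ``(..., n_parent, dim)``.
    """
    if iters < 1:
        raise ValueError("iters must be >= 1")
    u_hat = np.asarray(u_hat, dtype=float)
    b = np.zeros(u_hat.shape[:-1])
    for i in range(iters):
        e = np.exp(b - b.max(axis=-1, keepdims=True))
        c = e / e.sum(axis=-1, keepdims=True)
        s = np.sum(c[..., None] * u_hat, axis=-3)
        v = squash(s, axis=-1)
        if i < iters - 1:
            b = b + np.sum(u_hat * v[..., None, :, :], axis=-1)
    return v


def margin_loss(class_norms: np.ndarray, true_label: int,
                m_plus: float = 0.9, m_minus: float = 0.1, lam: float = 0.5) -> float:
    """Separation-margin objective on class-capsule norms.

    ``sum_k T_k max(0, m+ - |v_k|)^2 + lam (1 - T_k) max(0, |v_k| - m-)^2``
    with ``T_k`` the one-hot indicator of the true class.
    """
    norms = np.asarray(class_norms, dtype=float)
    T = np.zeros_like(norms)
    T[true_label] = 1.0
    pos = np.maximum(0.0, m_plus - norms) ** 2
    neg = np.maximum(0.0, norms - m_minus) ** 2
    return float(np.sum(T * pos + lam * (1.0 - T) * neg))


# ---------------------------------------------------------------------------
# Differentiable graph versions
# ---------------------------------------------------------------------------

def squash_t(x: Tensor, axis: int = -1, eps: float = 1e-12) -> Tensor:
    n2 = x.square().sum(axis=axis, keepdims=True)
    scale = n2 / (1.0 + n2) / (n2 + eps).sqrt()
    return x * scale


def routing_t(u_hat: Tensor, iters: int = 3) -> Tensor:
    """Differentiable routing; u_hat: (B, N, K, D) -> parents (B, K, D)."""
    B, N, K, D = u_hat.shape
    b = Tensor(np.zeros((B, N, K)))
    for i in range(iters):
        c = b.softmax(axis=-1)
        s = Tensor.einsum("bnk,bnkd->bkd", c, u_hat)
        v = squash_t(s, axis=-1)
        if i < iters - 1:
            b = b + Tensor.einsum("bnkd,bkd->bnk", u_hat, v)
    return v


def margin_loss_t(class_caps: Tensor, labels: np.ndarray,
                  m_plus: float = 0.9, m_minus: float = 0.1, lam: float = 0.5) -> Tensor:
    """Mean margin loss over a batch; class_caps: (B, K, D), labels: (B,)."""
    B, K, _ = class_caps.shape
    norms = (class_caps.square().sum(axis=-1) + 1e-12).sqrt()  # (B, K)
    T = np.zeros((B, K))
    T[np.arange(B), labels] = 1.0
    pos = (Tensor(np.full((B, K), m_plus)) - norms).relu().square()
    neg = (norms - Tensor(np.full((B, K), m_minus))).relu().square()
    per_sample = (Tensor(T) * pos + lam * Tensor(1.0 - T) * neg).sum(axis=1)
    return per_sample.mean()
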