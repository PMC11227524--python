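"""Minimal reverse-mode automatic differentiation on NumPy arrays.

Supports exactly the operator set the classifiers in this package need:
broadcast arithmetic, matmul, reductions, relu/sqrt/square, softmax,
valid-mode strided 1D/2D convolution, max pooling, and a fused
softmax-cross-entropy head.  Gradients are accumulated through a
topologically sorted tape; correctness is verified against central finite
differences in the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "Adam"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, s in enumerate(shape):
        if s == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple = ()
        self._backward = None

    # -- construction helpers -------------------------------------------
    @staticmethod
    def _wrap(other):
        return other if isinstance(other, Tensor) else Tensor(other)

    @classmethod
    def _from_op(cls, data, parents, backward):
        out = cls(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    @property
    def shape(self):
        return self.data.shape

    # -- arithmetic ------------------------------------------------------
    def __add__(self, other):
        other = self._wrap(other)

        def backward(g):
            return (_unbroadcast(g, self.shape), _unbroadcast(g, other.shape))

        return Tensor._from_op(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        return Tensor._from_op(-self.data, (self,), lambda g: (-g,))

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        other = self._wrap(other)

        def backward(g):
            return (
                _unbroadcast(g * other.data, self.shape),
                _unbroadcast(g * self.data, other.shape),
            )

        return Tensor._from_op(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._wrap(other)

        def backward(g):
            return (
                _unbroadcast(g / other.data, self.shape),
                _unbroadcast(-g * self.data / other.data**2, other.shape),
            )

        return Tensor._from_op(self.data / other.data, (self, other), backward)

    def __matmul__(self, other):
        other = self._wrap(other)

        def backward(g):
            a, b = self.data, other.data
            ga = g @ np.swapaxes(b, -1, -2)
            gb = np.swapaxes(a, -1, -2) @ g
            return (_unbroadcast(ga, a.shape), _unbroadcast(gb, b.shape))

        return Tensor._from_op(self.data @ other.data, (self, other), backward)

    @staticmethod
    def einsum(sub: str, a, b):
        """Two-operand einsum.

        Valid whenever every contracted index is shared by both operands
        (the usual tensor-contraction case), so each operand's gradient is
        again an einsum of the output gradient with the other operand.
        """
        a, b = Tensor._wrap(a), Tensor._wrap(b)
        ins, out = sub.split("->")
        sa, sb = ins.split(",")
        data = np.einsum(sub, a.data, b.data, optimize=True)

        def backward(g):
            ga = np.einsum(f"{out},{sb}->{sa}", g, b.data, optimize=True)
            gb = np.einsum(f"{out},{sa}->{sb}", g, a.data, optimize=True)
            return (ga, gb)

        return Tensor._from_op(data, (a, b), backward)

    @staticmethod
    def caps_predict(u, W):
        """Per-capsule linear predictions: (B,N,D),(N,K,D,E) -> (B,N,K,E).

        Equivalent to ``einsum('bnd,nkde->bnke')`` but arranged as N
        batched (B,D)@(D,K*E) matmuls, which is far faster for many small
        capsules.
        """
        u, W = Tensor._wrap(u), Tensor._wrap(W)
        B, N, D = u.data.shape
        _, K, _, E = W.data.shape
        u_t = np.ascontiguousarray(u.data.transpose(1, 0, 2))       # (N,B,D)
        W_m = np.ascontiguousarray(W.data.transpose(0, 2, 1, 3)).reshape(N, D, K * E)
        out = (u_t @ W_m).reshape(N, B, K, E).transpose(1, 0, 2, 3)

        def backward(g):
            g_t = np.ascontiguousarray(g.transpose(1, 0, 2, 3)).reshape(N, B, K * E)
            gu = (g_t @ W_m.transpose(0, 2, 1)).transpose(1, 0, 2)
            gW = (u_t.transpose(0, 2, 1) @ g_t).reshape(N, D, K, E).transpose(0, 2, 1, 3)
            return (gu, gW)

        return Tensor._from_op(out, (u, W), backward)

    def square(self):
        return Tensor._from_op(self.data**2, (self,), lambda g: (2.0 * g * self.data,))

    def sqrt(self):
        out_data = np.sqrt(self.data)

        def backward(g):
            return (g * 0.5 / np.maximum(out_data, 1e-300),)

        return Tensor._from_op(out_data, (self,), backward)

    def relu(self):
        mask = self.data > 0
        return Tensor._from_op(self.data * mask, (self,), lambda g: (g * mask,))

    # -- shape ops -------------------------------------------------------
    def reshape(self, *shape):
        orig = self.shape
        return Tensor._from_op(
            self.data.reshape(*shape), (self,), lambda g: (g.reshape(orig),)
        )

    def transpose(self, axes):
        inv = np.argsort(axes)
        return Tensor._from_op(
            self.data.transpose(axes), (self,), lambda g: (g.transpose(inv),)
        )

    def sum(self, axis=None, keepdims=False):
        def backward(g):
            if axis is None:
                return (np.broadcast_to(g, self.shape).copy(),)
            gg = g if keepdims else np.expand_dims(g, axis)
            return (np.broadcast_to(gg, self.shape).copy(),)

        return Tensor._from_op(self.data.sum(axis=axis, keepdims=keepdims), (self,), backward)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- nonlinear primitives -------------------------------------------
    def softmax(self, axis=-1):
        z = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(z)
        p = e / e.sum(axis=axis, keepdims=True)

        def backward(g):
            return (p * (g - (g * p).sum(axis=axis, keepdims=True)),)

        return Tensor._from_op(p, (self,), backward)

    def conv1d(self, w: "Tensor", stride: int = 1):
        """Valid-mode 1D convolution. self: (B, C, L); w: (F, C, k)."""
        w = self._wrap(w)
        x = self.data
        k = w.data.shape[-1]
        cols = np.lib.stride_tricks.sliding_window_view(x, k, axis=2)[:, :, ::stride, :]
        out = np.einsum("bclk,fck->bfl", cols, w.data, optimize=True)

        def backward(g):
            gw = np.einsum("bfl,bclk->fck", g, cols, optimize=True)
            gx = np.zeros_like(x)
            L_out = g.shape[2]
            for ki in range(k):
                contrib = np.einsum("bfl,fc->bcl", g, w.data[:, :, ki], optimize=True)
                gx[:, :, ki : ki + stride * L_out : stride] += contrib
            return (gx, gw)

        return Tensor._from_op(out, (self, w), backward)

    def conv2d(self, w: "Tensor", stride=(1, 1)):
        """Valid-mode 2D convolution. self: (B, C, H, W); w: (F, C, kh, kw)."""
        w = self._wrap(w)
        x = self.data
        kh, kw = w.data.shape[-2:]
        sh, sw = stride
        cols = np.lib.stride_tricks.sliding_window_view(x, (kh, kw), axis=(2, 3))
        cols = cols[:, :, ::sh, ::sw, :, :]  # (B, C, Ho, Wo, kh, kw)
        out = np.einsum("bchwij,fcij->bfhw", cols, w.data, optimize=True)

        def backward(g):
            gw = np.einsum("bfhw,bchwij->fcij", g, cols, optimize=True)
            gx = np.zeros_like(x)
            Ho, Wo = g.shape[2:]
            for i in range(kh):
                for j in range(kw):
                    contrib = np.einsum("bfhw,fc->bchw", g, w.data[:, :, i, j], optimize=True)
                    gx[:, :, i : i + sh * Ho : sh, j : j + sw * Wo : sw] += contrib
            return (gx, gw)

        return Tensor._from_op(out, (self, w), backward)

    def maxpool1d(self, size: int = 2):
        """Non-overlapping max pooling along the last axis (tail cropped)."""
        x = self.data
        L = (x.shape[-1] // size) * size
        xc = x[..., :L].reshape(*x.shape[:-1], L // size, size)
        out = xc.max(axis=-1)
        arg = xc.argmax(axis=-1)

        def backward(g):
            gx = np.zeros_like(x)
            gc = np.zeros_like(xc)
            np.put_along_axis(gc, arg[..., None], g[..., None], axis=-1)
            gx[..., :L] = gc.reshape(*x.shape[:-1], L)
            return (gx,)

        return Tensor._from_op(out, (self,), backward)

    def maxpool2d(self, size=(2, 2)):
        ph, pw = size
        x = self.data
        H = (x.shape[-2] // ph) * ph
        W = (x.shape[-1] // pw) * pw
        xc = x[..., :H, :W].reshape(*x.shape[:-2], H // ph, ph, W // pw, pw)
        xc = np.moveaxis(xc, -3, -2)  # (..., H', W', ph, pw)
        flat = xc.reshape(*xc.shape[:-2], ph * pw)
        out = flat.max(axis=-1)
        arg = flat.argmax(axis=-1)

        def backward(g):
            gflat = np.zeros_like(flat)
            np.put_along_axis(gflat, arg[..., None], g[..., None], axis=-1)
            gc = gflat.reshape(*xc.shape)
            gc = np.moveaxis(gc, -2, -3)
            gx = np.zeros_like(x)
            gx[..., :H, :W] = gc.reshape(*x.shape[:-2], H, W)
            return (gx,)

        return Tensor._from_op(out, (self,), backward)

    def cross_entropy(self, labels: np.ndarray):
        """Mean softmax cross-entropy; self: (B, K) logits, labels: (B,) ints."""
        z = self.data - self.data.max(axis=1, keepdims=True)
        e = np.exp(z)
        p = e / e.sum(axis=1, keepdims=True)
        B = p.shape[0]
        nll = -np.log(np.maximum(p[np.arange(B), labels], 1e-300)).mean()

        def backward(g):
            gp = p.copy()
            gp[np.arange(B), labels] -= 1.0
            return (g * gp / B,)

        return Tensor._from_op(nll, (self,), backward)

    # -- backprop --------------------------------------------------------
    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar output")
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        for t in topo:
            t.grad = None
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t._backward is None or t.grad is None:
                continue
            grads = t._backward(t.grad)
            for p, g in zip(t._parents, grads):
                if p.requires_grad:
                    p.grad = p.grad + g if p.grad is not None else g


class Adam:
    """Adam optimizer over a list of parameter Tensors."""

    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = list(params)
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def step(self):
        self.t += 1
        for i, p in enumerate(self.params):
            g = p.grad
            if g is None:
                continue
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad = None
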