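"""Minimal reverse-mode automatic differentiation over NumPy arrays.

This is the numerical core shared by the CNN and self-attention affinity
regressors.  It is deliberately small: only the operations those
architectures need are provided, each with an explicit backward closure.
Keeping the backward pass in-package is what makes the DeconvNet
attribution rule possible — DeconvNet replaces the ReLU backward rule
(gate by the forward activation sign) with a rectification of the
incoming backward signal, which is selected here via the ``relu_rule``
argument of :meth:`Tensor.backward`.

Gradient correctness is checked against central finite differences in the
test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "tensor", "parameter"]

# ReLU backward rule in effect during a backward() call.
# "gradient": standard backprop; "deconvnet": rectify the incoming signal.
_RELU_RULE = "gradient"


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, dim in enumerate(shape):
        if dim == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A NumPy array with a gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False, _prev=(), _backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in _prev)
        self._prev = tuple(_prev)
        self._backward = _backward

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):  # pragma: no cover
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # ---- graph machinery -------------------------------------------------

    def backward(self, grad: np.ndarray | None = None, relu_rule: str = "gradient"):
        """Backpropagate from this tensor.

        Parameters
        ----------
        grad:
            Seed gradient; defaults to ones (suitable for scalar outputs).
        relu_rule:
            ``"gradient"`` for standard backprop, ``"deconvnet"`` to apply
            the DeconvNet rule at every ReLU.
        """
        if relu_rule not in ("gradient", "deconvnet"):
            raise ValueError(f"unknown relu_rule: {relu_rule!r}")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._prev:
                stack.append((p, False))
        for node in topo:
            node.grad = np.zeros_like(node.data)
        self.grad = (
            np.ones_like(self.data) if grad is None else np.asarray(grad, dtype=np.float64)
        )
        global _RELU_RULE
        _RELU_RULE = relu_rule
        try:
            for node in reversed(topo):
                if node._backward is not None:
                    node._backward(node.grad)
        finally:
            _RELU_RULE = "gradient"

    # ---- elementwise arithmetic -----------------------------------------

    def _coerce(self, other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def __add__(self, other):
        other = self._coerce(other)
        out = Tensor(self.data + other.data, _prev=(self, other))

        def _bw(g):
            if self.requires_grad:
                self.grad += _unbroadcast(g, self.data.shape)
            if other.requires_grad:
                other.grad += _unbroadcast(g, other.data.shape)

        out._backward = _bw
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, _prev=(self,))

        def _bw(g):
            if self.requires_grad:
                self.grad += _unbroadcast(-g, self.data.shape)

        out._backward = _bw
        return out

    def __sub__(self, other):
        return self + (-self._coerce(other))

    def __rsub__(self, other):
        return self._coerce(other) + (-self)

    def __mul__(self, other):
        other = self._coerce(other)
        out = Tensor(self.data * other.data, _prev=(self, other))

        def _bw(g):
            if self.requires_grad:
                self.grad += _unbroadcast(g * other.data, self.data.shape)
            if other.requires_grad:
                other.grad += _unbroadcast(g * self.data, other.data.shape)

        out._backward = _bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, scalar: float):
        return self * (1.0 / float(scalar))

    def square(self):
        return self * self

    def abs(self):
        sign = np.sign(self.data)
        out = Tensor(np.abs(self.data), _prev=(self,))

        def _bw(g):
            if self.requires_grad:
                self.grad += g * sign

        out._backward = _bw
        return out

    # ---- linear algebra ---------------------------------------------------

    def matmul(self, other: "Tensor"):
        other = self._coerce(other)
        out = Tensor(np.matmul(self.data, other.data), _prev=(self, other))

        def _bw(g):
            if self.requires_grad:
                ga = np.matmul(g, np.swapaxes(other.data, -1, -2))
                self.grad += _unbroadcast(ga, self.data.shape)
            if other.requires_grad:
                gb = np.matmul(np.swapaxes(self.data, -1, -2), g)
                other.grad += _unbroadcast(gb, other.data.shape)

        out._backward = _bw
        return out

    __matmul__ = matmul

    # ---- shape ops ---------------------------------------------------------

    def reshape(self, *shape):
        old = self.data.shape
        out = Tensor(self.data.reshape(*shape), _prev=(self,))

        def _bw(g):
            if self.requires_grad:
                self.grad += g.reshape(old)

        out._backward = _bw
        return out

    def transpose(self, axes):
        inv = np.argsort(axes)
        out = Tensor(self.data.transpose(axes), _prev=(self,))

        def _bw(g):
            if self.requires_grad:
                self.grad += g.transpose(inv)

        out._backward = _bw
        return out

    def flip(self, axes):
        out = Tensor(np.flip(self.data, axis=axes), _prev=(self,))

        def _bw(g):
            if self.requires_grad:
                self.grad += np.flip(g, axis=axes)

        out._backward = _bw
        return out

    # ---- reductions ---------------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), _prev=(self,))
        shape = self.data.shape

        def _bw(g):
            if self.requires_grad:
                if axis is None:
                    self.grad += np.broadcast_to(g, shape)
                else:
                    gg = g if keepdims else np.expand_dims(g, axis)
                    self.grad += np.broadcast_to(gg, shape)

        out._backward = _bw
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) / n

    # ---- nonlinearities -----------------------------------------------------

    def relu(self):
        mask = self.data > 0
        out = Tensor(np.where(mask, self.data, 0.0), _prev=(self,))

        def _bw(g):
            if self.requires_grad:
                if _RELU_RULE == "deconvnet":
                    # DeconvNet: rectify the incoming backward signal, ignore
                    # the forward activation mask.
                    self.grad += np.where(g > 0, g, 0.0)
                else:
                    self.grad += g * mask

        out._backward = _bw
        return out

    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-self.data))
        out = Tensor(s, _prev=(self,))

        def _bw(g):
            if self.requires_grad:
                self.grad += g * s * (1.0 - s)

        out._backward = _bw
        return out

    def softmax(self):
        """Softmax over the last axis."""
        z = self.data - self.data.max(axis=-1, keepdims=True)
        e = np.exp(z)
        p = e / e.sum(axis=-1, keepdims=True)
        out = Tensor(p, _prev=(self,))

        def _bw(g):
            if self.requires_grad:
                dot = (g * p).sum(axis=-1, keepdims=True)
                self.grad += p * (g - dot)

        out._backward = _bw
        return out

    def layer_norm(self, gamma: "Tensor", beta: "Tensor", eps: float = 1e-5):
        """Layer normalization over the last axis with learned scale/shift."""
        mu = self.data.mean(axis=-1, keepdims=True)
        xc = self.data - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        inv = 1.0 / np.sqrt(var + eps)
        xhat = xc * inv
        out = Tensor(xhat * gamma.data + beta.data, _prev=(self, gamma, beta))
        d = self.data.shape[-1]

        def _bw(g):
            if gamma.requires_grad:
                gamma.grad += _unbroadcast(g * xhat, gamma.data.shape)
            if beta.requires_grad:
                beta.grad += _unbroadcast(g, beta.data.shape)
            if self.requires_grad:
                gx = g * gamma.data
                t1 = gx
                t2 = gx.mean(axis=-1, keepdims=True)
                t3 = xhat * (gx * xhat).mean(axis=-1, keepdims=True)
                self.grad += inv * (t1 - t2 - t3)

        out._backward = _bw
        return out

    # ---- sequence-specific ops ----------------------------------------------

    def conv1d(self, w: "Tensor"):
        """Cross-correlate a (B, C, L) input with (F, C, m) filters -> (B, F, K).

        K = L - m + 1; no padding, stride 1.  This is the motif-scanner
        convolution of the CNN models.
        """
        w = self._coerce(w)
        x = self.data
        f, c, m = w.data.shape
        if x.shape[1] != c:
            raise ValueError("channel mismatch in conv1d")
        if x.shape[2] < m:
            raise ValueError("input narrower than filter")
        windows = np.lib.stride_tricks.sliding_window_view(x, m, axis=2)  # (B,C,K,m)
        out_data = np.einsum("bckm,fcm->bfk", windows, w.data, optimize=True)
        out = Tensor(out_data, _prev=(self, w))

        def _bw(g):  # g: (B, F, K)
            if w.requires_grad:
                w.grad += np.einsum("bfk,bckm->fcm", g, windows, optimize=True)
            if self.requires_grad:
                gx = np.zeros_like(x)
                for j in range(m):
                    gx[:, :, j : j + g.shape[2]] += np.einsum(
                        "bfk,fc->bck", g, w.data[:, :, j], optimize=True
                    )
                self.grad += gx

        out._backward = _bw
        return out

    def multi_head_attention(self, wq: "Tensor", wk: "Tensor", wv: "Tensor",
                             n_heads: int):
        """Fused multi-head scaled-dot-product self-attention.

        ``self`` is (B, L, D); ``wq``/``wk``/``wv`` are (D, D) projections.
        Per head h of dimension d_k = D / n_heads the output is
        ``softmax(Q K^T / sqrt(d_k)) V`` with heads concatenated back to
        (B, L, D).  Fusing the whole block into one node keeps the
        training loop fast; the backward pass is hand-derived and covered
        by finite-difference tests.
        """
        b, l, d = self.data.shape
        if d % n_heads != 0:
            raise ValueError("model dimension not divisible by n_heads")
        dk = d // n_heads
        inv = 1.0 / np.sqrt(dk)

        def split(x):  # (B,L,D) -> (B,H,L,dk)
            return x.reshape(b, l, n_heads, dk).transpose(0, 2, 1, 3)

        def merge(x):  # (B,H,L,dk) -> (B,L,D)
            return x.transpose(0, 2, 1, 3).reshape(b, l, d)

        q = split(self.data @ wq.data)
        k = split(self.data @ wk.data)
        v = split(self.data @ wv.data)
        s = np.matmul(q, k.transpose(0, 1, 3, 2)) * inv
        s -= s.max(axis=-1, keepdims=True)
        p = np.exp(s)
        p /= p.sum(axis=-1, keepdims=True)
        out = Tensor(merge(np.matmul(p, v)), _prev=(self, wq, wk, wv))

        def _bw(g):
            g4 = split(g)
            gv = np.matmul(p.transpose(0, 1, 3, 2), g4)
            gp = np.matmul(g4, v.transpose(0, 1, 3, 2))
            gs = p * (gp - (gp * p).sum(axis=-1, keepdims=True)) * inv
            gq = np.matmul(gs, k)
            gk = np.matmul(gs.transpose(0, 1, 3, 2), q)
            gq, gk, gv = merge(gq), merge(gk), merge(gv)
            if wq.requires_grad:
                wq.grad += np.einsum("bld,ble->de", self.data, gq, optimize=True)
            if wk.requires_grad:
                wk.grad += np.einsum("bld,ble->de", self.data, gk, optimize=True)
            if wv.requires_grad:
                wv.grad += np.einsum("bld,ble->de", self.data, gv, optimize=True)
            if self.requires_grad:
                self.grad += (
                    gq @ wq.data.T + gk @ wk.data.T + gv @ wv.data.T
                )

        out._backward = _bw
        return out

    def max_pool1d(self, p: int):
        """Non-overlapping max pooling with window ``p`` over the last axis."""
        b, f, k = self.data.shape
        if k % p != 0:
            raise ValueError(f"pool window {p} does not divide length {k}")
        xr = self.data.reshape(b, f, k // p, p)
        idx = xr.argmax(axis=-1)
        out = Tensor(xr.max(axis=-1), _prev=(self,))

        def _bw(g):
            if self.requires_grad:
                gx = np.zeros_like(xr)
                bi, fi, ki = np.indices(idx.shape)
                gx[bi, fi, ki, idx] = g
                self.grad += gx.reshape(b, f, k)

        out._backward = _bw
        return out


def tensor(data) -> Tensor:
    """Wrap an array as a constant (non-trainable) tensor."""
    return Tensor(data)


def parameter(data) -> Tensor:
    """Wrap an array as a trainable tensor."""
    return Tensor(np.array(data, dtype=np.float64), requires_grad=True)
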