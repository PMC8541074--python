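"""Reverse-mode automatic differentiation over numpy arrays.

A :class:`Tensor` wraps an ndarray and remembers how it was produced; calling
``backward()`` on a scalar walks the graph in reverse topological order and
accumulates gradients into every tensor with ``requires_grad``.  Only the
operations the classifier needs are implemented: broadcast add/mul, matmul,
the usual pointwise nonlinearities, 2-D convolution (im2col), batch
normalization, sequence-step selection, 1-D average pooling, and a fused
softmax cross-entropy.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Tensor", "add", "mul", "matmul", "relu", "sigmoid", "tanh",
    "conv2d", "batchnorm2d", "select_step", "avg_pool1d",
    "cross_entropy", "softmax",
]


class Tensor:
    """An ndarray node in the autodiff graph."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    @property
    def shape(self):
        return self.data.shape

    def accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.array(g, dtype=self.data.dtype)
        else:
            self.grad += g

    def zero_grad(self) -> None:
        self.grad = None

    def backward(self) -> None:
        """Backpropagate from this scalar through the recorded graph."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS: graphs include an unrolled GRU
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"


def _node(data: np.ndarray, parents: tuple[Tensor, ...], backward) -> Tensor:
    out = Tensor(data)
    if any(p.requires_grad for p in parents):
        out.requires_grad = True
        out._parents = parents
        out._backward = backward
    return out


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


def add(a: Tensor, b: Tensor) -> Tensor:
    def backward(g):
        if a.requires_grad:
            a.accumulate(_unbroadcast(g, a.shape))
        if b.requires_grad:
            b.accumulate(_unbroadcast(g, b.shape))
    return _node(a.data + b.data, (a, b), backward)


def mul(a: Tensor, b: Tensor) -> Tensor:
    def backward(g):
        if a.requires_grad:
            a.accumulate(_unbroadcast(g * b.data, a.shape))
        if b.requires_grad:
            b.accumulate(_unbroadcast(g * a.data, b.shape))
    return _node(a.data * b.data, (a, b), backward)


def matmul(a: Tensor, b: Tensor) -> Tensor:
    def backward(g):
        if a.requires_grad:
            a.accumulate(g @ b.data.T)
        if b.requires_grad:
            b.accumulate(a.data.T @ g)
    return _node(a.data @ b.data, (a, b), backward)


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0
    def backward(g):
        if x.requires_grad:
            x.accumulate(g * mask)
    return _node(x.data * mask, (x,), backward)


def sigmoid(x: Tensor) -> Tensor:
    y = 1.0 / (1.0 + np.exp(-x.data))
    def backward(g):
        if x.requires_grad:
            x.accumulate(g * y * (1.0 - y))
    return _node(y, (x,), backward)


def tanh(x: Tensor) -> Tensor:
    y = np.tanh(x.data)
    def backward(g):
        if x.requires_grad:
            x.accumulate(g * (1.0 - y * y))
    return _node(y, (x,), backward)


def reshape(x: Tensor, shape) -> Tensor:
    old = x.data.shape
    def backward(g):
        if x.requires_grad:
            x.accumulate(g.reshape(old))
    return _node(x.data.reshape(shape), (x,), backward)


def transpose2d(x: Tensor) -> Tensor:
    def backward(g):
        if x.requires_grad:
            x.accumulate(g.T)
    return _node(x.data.T, (x,), backward)


def select_step(x: Tensor, t: int) -> Tensor:
    """Select time step ``t`` from a (batch, time, features) tensor."""
    def backward(g):
        if x.requires_grad:
            full = np.zeros_like(x.data)
            full[:, t, :] = g
            x.accumulate(full)
    return _node(x.data[:, t, :], (x,), backward)


def avg_pool1d(x: Tensor, width: int) -> Tensor:
    """Non-overlapping mean pooling along the last axis of a 2-D tensor."""
    n, f = x.data.shape
    if f % width:
        raise ValueError(f"feature size {f} not divisible by pool width {width}")
    y = x.data.reshape(n, f // width, width).mean(axis=-1)
    def backward(g):
        if x.requires_grad:
            x.accumulate(np.repeat(g / width, width, axis=-1).reshape(n, f))
    return _node(y, (x,), backward)


def conv2d(x: Tensor, w: Tensor, b: Tensor, stride: int = 1, padding: int = 1) -> Tensor:
    """2-D convolution (cross-correlation) via im2col.

    ``x``: (N, C, H, W); ``w``: (Cout, C, kh, kw); ``b``: (Cout,).
    """
    N, C, H, W = x.data.shape
    Cout, Cin, kh, kw = w.data.shape
    s, p = stride, padding
    xp = np.pad(x.data, ((0, 0), (0, 0), (p, p), (p, p)))
    Ho = (H + 2 * p - kh) // s + 1
    Wo = (W + 2 * p - kw) // s + 1
    win = sliding_window_view(xp, (kh, kw), axis=(2, 3))[:, :, ::s, ::s]
    cols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(
        N * Ho * Wo, C * kh * kw
    )
    out = cols @ w.data.reshape(Cout, -1).T + b.data
    out = out.reshape(N, Ho, Wo, Cout).transpose(0, 3, 1, 2)

    def backward(g):
        gm = np.ascontiguousarray(g.transpose(0, 2, 3, 1)).reshape(N * Ho * Wo, Cout)
        if w.requires_grad:
            w.accumulate((gm.T @ cols).reshape(w.data.shape))
        if b.requires_grad:
            b.accumulate(gm.sum(axis=0))
        if x.requires_grad:
            dcols = (gm @ w.data.reshape(Cout, -1)).reshape(N, Ho, Wo, C, kh, kw)
            dxp = np.zeros_like(xp)
            for i in range(kh):
                for j in range(kw):
                    dxp[:, :, i:i + s * Ho:s, j:j + s * Wo:s] += dcols[
                        :, :, :, :, i, j
                    ].transpose(0, 3, 1, 2)
            x.accumulate(dxp[:, :, p:p + H, p:p + W])

    return _node(out, (x, w, b), backward)


def batchnorm2d(
    x: Tensor,
    gamma: Tensor,
    beta: Tensor,
    running_mean: np.ndarray,
    running_var: np.ndarray,
    training: bool,
    momentum: float = 0.1,
    eps: float = 1e-5,
) -> Tensor:
    """Per-channel batch normalization for (N, C, H, W) activations.

    In training mode the batch statistics are used and the running
    estimates updated in place; in eval mode the running estimates are
    used and the op is a per-channel affine map.
    """
    if training:
        mu = x.data.mean(axis=(0, 2, 3))
        var = x.data.var(axis=(0, 2, 3))
        running_mean *= 1 - momentum
        running_mean += momentum * mu
        running_var *= 1 - momentum
        running_var += momentum * var
    else:
        mu, var = running_mean, running_var
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu[None, :, None, None]) * inv[None, :, None, None]
    out = gamma.data[None, :, None, None] * xhat + beta.data[None, :, None, None]

    def backward(g):
        if gamma.requires_grad:
            gamma.accumulate((g * xhat).sum(axis=(0, 2, 3)))
        if beta.requires_grad:
            beta.accumulate(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            gs = g * gamma.data[None, :, None, None]
            if training:
                m = x.data.shape[0] * x.data.shape[2] * x.data.shape[3]
                sum_gs = gs.sum(axis=(0, 2, 3))
                sum_gs_xhat = (gs * xhat).sum(axis=(0, 2, 3))
                dx = (
                    gs
                    - (sum_gs / m)[None, :, None, None]
                    - xhat * (sum_gs_xhat / m)[None, :, None, None]
                ) * inv[None, :, None, None]
            else:
                dx = gs * inv[None, :, None, None]
            x.accumulate(dx)

    return _node(out, (x, gamma, beta), backward)


def softmax(logits: np.ndarray, axis: int = -1) -> np.ndarray:
    """Plain numpy softmax (used at inference time)."""
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def cross_entropy(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Mean softmax cross-entropy against integer class targets."""
    n = logits.data.shape[0]
    p = softmax(logits.data)
    eps = np.finfo(p.dtype).tiny
    loss = -np.mean(np.log(p[np.arange(n), targets] + eps))

    def backward(g):
        if logits.requires_grad:
            d = p.copy()
            d[np.arange(n), targets] -= 1.0
            logits.accumulate(g * d / n)

    return _node(np.asarray(loss), (logits,), backward)
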