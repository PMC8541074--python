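"""Parameterized layers on top of the autograd core."""

from __future__ import annotations

import numpy as np

from .autograd import (
    Tensor, add, batchnorm2d, conv2d, matmul, mul, reshape, select_step,
    sigmoid, tanh, transpose2d,
)

__all__ = ["Module", "Conv2d", "BatchNorm2d", "Linear", "GRU"]


class Module:
    """Base class: parameter discovery and train/eval mode propagation."""

    training: bool = True

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for v in self.__dict__.values():
            if isinstance(v, Tensor) and v.requires_grad:
                params.append(v)
            elif isinstance(v, Module):
                params.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
                    elif isinstance(item, Tensor) and item.requires_grad:
                        params.append(item)
        return params

    def _submodules(self):
        for v in self.__dict__.values():
            if isinstance(v, Module):
                yield v
            elif isinstance(v, (list, tuple)):
                yield from (m for m in v if isinstance(m, Module))

    def train(self) -> None:
        self.training = True
        for m in self._submodules():
            m.train()

    def eval(self) -> None:
        self.training = False
        for m in self._submodules():
            m.eval()

    def state_arrays(self) -> list[np.ndarray]:
        """All learnable parameter arrays plus normalization statistics."""
        arrays = [p.data for p in self.parameters()]
        for m in self._iter_all():
            if isinstance(m, BatchNorm2d):
                arrays += [m.running_mean, m.running_var]
        return arrays

    def _iter_all(self):
        yield self
        for m in self._submodules():
            yield from m._iter_all()


def _he_conv(rng: np.random.Generator, cout: int, cin: int, k: int) -> np.ndarray:
    std = np.sqrt(2.0 / (cin * k * k))
    return rng.normal(0.0, std, size=(cout, cin, k, k))


def _orthogonal(rng: np.random.Generator, rows: int, cols: int) -> np.ndarray:
    a = rng.standard_normal((max(rows, cols), min(rows, cols)))
    q, r = np.linalg.qr(a)
    q *= np.sign(np.diag(r))
    return q[:rows, :cols] if q.shape != (rows, cols) else q


class Conv2d(Module):
    def __init__(self, cin: int, cout: int, k: int = 3, stride: int = 1,
                 padding: int = 1, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        self.stride, self.padding = stride, padding
        self.weight = Tensor(_he_conv(rng, cout, cin, k), requires_grad=True)
        self.bias = Tensor(np.zeros(cout), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, self.stride, self.padding)


class BatchNorm2d(Module):
    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Tensor(np.ones(channels), requires_grad=True)
        self.beta = Tensor(np.zeros(channels), requires_grad=True)
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)
        self.momentum, self.eps = momentum, eps

    def __call__(self, x: Tensor) -> Tensor:
        return batchnorm2d(
            x, self.gamma, self.beta, self.running_mean, self.running_var,
            self.training, self.momentum, self.eps,
        )


class Linear(Module):
    def __init__(self, fin: int, fout: int, rng: np.random.Generator | None = None,
                 bias_init: float = 0.0):
        rng = rng or np.random.default_rng()
        std = np.sqrt(2.0 / fin)
        self.weight = Tensor(rng.normal(0.0, std, size=(fout, fin)), requires_grad=True)
        self.bias = Tensor(np.full(fout, bias_init, dtype=float), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return add(matmul(x, transpose2d(self.weight)), self.bias)


class _GRULayer(Module):
    """One GRU layer: update/reset gates and candidate state.

    Gate equations follow the standard formulation
    z = σ(W_z x + U_z h + b_z), r = σ(W_r x + U_r h + b_r),
    n = tanh(W_n x + b_n + r ⊙ (U_n h + u_n)), h' = (1−z) ⊙ h + z' …
    with h' = (1 − z) ⊙ n + z ⊙ h.
    """

    def __init__(self, fin: int, hidden: int, rng: np.random.Generator):
        std = np.sqrt(1.0 / fin)
        def win():
            return Tensor(rng.normal(0.0, std, size=(fin, hidden)), requires_grad=True)
        def wrec():
            return Tensor(_orthogonal(rng, hidden, hidden), requires_grad=True)
        def b():
            return Tensor(np.zeros(hidden), requires_grad=True)
        self.Wz, self.Uz, self.bz = win(), wrec(), b()
        self.Wr, self.Ur, self.br = win(), wrec(), b()
        self.Wn, self.Un, self.bn, self.un = win(), wrec(), b(), b()
        self.hidden = hidden

    def step(self, x_t: Tensor, h: Tensor) -> Tensor:
        z = sigmoid(add(add(matmul(x_t, self.Wz), matmul(h, self.Uz)), self.bz))
        r = sigmoid(add(add(matmul(x_t, self.Wr), matmul(h, self.Ur)), self.br))
        n = tanh(add(add(matmul(x_t, self.Wn), self.bn),
                     mul(r, add(matmul(h, self.Un), self.un))))
        one_minus_z = add(Tensor(np.ones_like(z.data)), mul(Tensor(np.full_like(z.data, -1.0)), z))
        return add(mul(one_minus_z, n), mul(z, h))


class GRU(Module):
    """Stacked GRU over a (batch, time, features) sequence.

    Returns the top layer's hidden state at the last time step.
    """

    def __init__(self, fin: int, hidden: int, num_layers: int = 2,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        self.layers = [
            _GRULayer(fin if i == 0 else hidden, hidden, rng)
            for i in range(num_layers)
        ]
        self.hidden = hidden

    def __call__(self, x: Tensor) -> Tensor:
        n, T, _ = x.data.shape
        states = [
            Tensor(np.zeros((n, layer.hidden), dtype=x.data.dtype))
            for layer in self.layers
        ]
        for t in range(T):
            inp = select_step(x, t)
            for i, layer in enumerate(self.layers):
                states[i] = layer.step(inp, states[i])
                inp = states[i]
        return states[-1]
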