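"""Minimal reverse-mode automatic differentiation on numpy arrays.

This backend exists so the package's neural networks (the two-layer LSTM
baseline and the nine-block few-shot 1D CNN) can be trained with plain
numpy.  It is a conventional define-by-run tape: every operation returns a
:class:`Tensor` holding the forward value and a closure that accumulates
gradients into its parents.  Only the operations the package's models need
are implemented (dense/convolution/pooling/batch-norm primitives,
elementwise nonlinearities, reductions), all in float64.

The engine is deliberately small and has no notion of devices, graphs
surviving ``backward``, or higher-order derivatives.
"""

from __future__ import annotations

import math
from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = [
    "Tensor",
    "Parameter",
    "Module",
    "Linear",
    "Conv1d",
    "BatchNorm1d",
    "Adam",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum leading extra axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A numpy array with a gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward: Callable[[], None] | None = None
        self._parents: tuple[Tensor, ...] = ()

    # -- graph construction helpers -------------------------------------
    @staticmethod
    def _make(data: np.ndarray, parents: tuple["Tensor", ...],
              backward: Callable[[np.ndarray], None]) -> "Tensor":
        out = Tensor(data)
        out.requires_grad = any(p.requires_grad for p in parents)
        if out.requires_grad:
            out._parents = parents

            def _run():
                backward(out.grad)

            out._backward = _run
        return out

    def _accum(self, g: np.ndarray) -> None:
        if not self.requires_grad:
            return
        g = _unbroadcast(np.asarray(g, dtype=np.float64), self.data.shape)
        if self.grad is None:
            self.grad = g.copy()
        else:
            self.grad += g

    # -- basic arithmetic ------------------------------------------------
    @staticmethod
    def _coerce(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    def __add__(self, other) -> "Tensor":
        other = Tensor._coerce(other)

        def bw(g):
            self._accum(g)
            other._accum(g)

        return Tensor._make(self.data + other.data, (self, other), bw)

    __radd__ = __add__

    def __neg__(self) -> "Tensor":
        def bw(g):
            self._accum(-g)

        return Tensor._make(-self.data, (self,), bw)

    def __sub__(self, other) -> "Tensor":
        return self + (-Tensor._coerce(other))

    def __rsub__(self, other) -> "Tensor":
        return Tensor._coerce(other) + (-self)

    def __mul__(self, other) -> "Tensor":
        other = Tensor._coerce(other)

        def bw(g):
            self._accum(g * other.data)
            other._accum(g * self.data)

        return Tensor._make(self.data * other.data, (self, other), bw)

    __rmul__ = __mul__

    def __truediv__(self, other) -> "Tensor":
        other = Tensor._coerce(other)

        def bw(g):
            self._accum(g / other.data)
            other._accum(-g * self.data / other.data ** 2)

        return Tensor._make(self.data / other.data, (self, other), bw)

    def __pow__(self, p: float) -> "Tensor":
        def bw(g):
            self._accum(g * p * self.data ** (p - 1))

        return Tensor._make(self.data ** p, (self,), bw)

    def __matmul__(self, other) -> "Tensor":
        other = Tensor._coerce(other)

        def bw(g):
            self._accum(g @ np.swapaxes(other.data, -1, -2))
            other._accum(np.swapaxes(self.data, -1, -2) @ g)

        return Tensor._make(self.data @ other.data, (self, other), bw)

    # -- elementwise nonlinearities --------------------------------------
    def tanh(self) -> "Tensor":
        y = np.tanh(self.data)

        def bw(g):
            self._accum(g * (1.0 - y ** 2))

        return Tensor._make(y, (self,), bw)

    def sigmoid(self) -> "Tensor":
        y = 1.0 / (1.0 + np.exp(-np.clip(self.data, -60, 60)))

        def bw(g):
            self._accum(g * y * (1.0 - y))

        return Tensor._make(y, (self,), bw)

    def exp(self) -> "Tensor":
        y = np.exp(np.clip(self.data, -700, 700))

        def bw(g):
            self._accum(g * y)

        return Tensor._make(y, (self,), bw)

    def log(self) -> "Tensor":
        def bw(g):
            self._accum(g / self.data)

        return Tensor._make(np.log(self.data), (self,), bw)

    def sqrt(self) -> "Tensor":
        y = np.sqrt(self.data)

        def bw(g):
            self._accum(g * 0.5 / np.maximum(y, 1e-300))

        return Tensor._make(y, (self,), bw)

    def relu_floor(self, floor: float = 0.0) -> "Tensor":
        """max(x, floor) elementwise — the hinge used by the contrastive loss."""
        mask = self.data > floor

        def bw(g):
            self._accum(g * mask)

        return Tensor._make(np.where(mask, self.data, floor), (self,), bw)

    # -- reductions / shaping --------------------------------------------
    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        y = self.data.sum(axis=axis, keepdims=keepdims)

        def bw(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.data.shape))

        return Tensor._make(y, (self,), bw)

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        n = self.data.size if axis is None else (
            np.prod([self.data.shape[a] for a in np.atleast_1d(axis)]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def reshape(self, *shape) -> "Tensor":
        orig = self.data.shape

        def bw(g):
            self._accum(g.reshape(orig))

        return Tensor._make(self.data.reshape(*shape), (self,), bw)

    def swapaxes(self, a: int, b: int) -> "Tensor":
        def bw(g):
            self._accum(np.swapaxes(g, a, b))

        return Tensor._make(np.swapaxes(self.data, a, b), (self,), bw)

    def __getitem__(self, idx) -> "Tensor":
        def bw(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            self._accum(full)

        return Tensor._make(self.data[idx], (self,), bw)

    @staticmethod
    def concatenate(tensors: Sequence["Tensor"], axis: int = 0) -> "Tensor":
        sizes = [t.data.shape[axis] for t in tensors]
        offsets = np.cumsum([0] + sizes)

        def bw(g):
            for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(a, b)
                t._accum(g[tuple(sl)])

        return Tensor._make(
            np.concatenate([t.data for t in tensors], axis=axis),
            tuple(tensors), bw)

    # -- structured ops used by the models -------------------------------
    def conv1d(self, weight: "Tensor", bias: "Tensor | None" = None,
               padding: int = 0) -> "Tensor":
        """1-D convolution, stride 1.  self: (N, Cin, L), weight: (Cout, Cin, K).

        Computed as a sum of K shifted (N·L, Cin) @ (Cin, Cout) products in a
        channels-last layout, which keeps every matmul dense for BLAS.
        """
        x = self.data
        w = weight.data
        cout, cin, k = w.shape
        if padding:
            xp = np.pad(x, ((0, 0), (0, 0), (padding, padding)))
        else:
            xp = x
        lout = xp.shape[-1] - k + 1
        xt = np.ascontiguousarray(xp.transpose(0, 2, 1))  # (N, Lp, Cin)
        y = np.zeros((xt.shape[0], lout, cout))
        for j in range(k):
            y += xt[:, j:j + lout, :] @ w[:, :, j].T
        if bias is not None:
            y += bias.data
        y = y.transpose(0, 2, 1)  # (N, Cout, Lout)

        def bw(g):
            gt = np.ascontiguousarray(g.transpose(0, 2, 1))  # (N, Lout, Cout)
            gt2 = gt.reshape(-1, cout)
            gw = np.empty_like(w)
            for j in range(k):
                gw[:, :, j] = gt2.T @ xt[:, j:j + lout, :].reshape(-1, cin)
            weight._accum(gw)
            if bias is not None:
                bias._accum(gt2.sum(axis=0))
            if self.requires_grad:
                gxt = np.zeros_like(xt)
                for j in range(k):
                    gxt[:, j:j + lout, :] += gt @ w[:, :, j]
                gxp = gxt.transpose(0, 2, 1)
                if padding:
                    gxp = gxp[:, :, padding:-padding or None]
                self._accum(gxp)

        return Tensor._make(y, (self, weight) + (() if bias is None else (bias,)), bw)

    def maxpool1d(self, k: int = 2) -> "Tensor":
        """Non-overlapping max pooling along the last axis (stride = k).

        A trailing remainder shorter than ``k`` is dropped, as is conventional.
        """
        x = self.data
        n, c, l = x.shape
        lo = l // k
        xt = x[:, :, :lo * k].reshape(n, c, lo, k)
        arg = xt.argmax(axis=-1)
        y = np.take_along_axis(xt, arg[..., None], axis=-1)[..., 0]

        def bw(g):
            gx = np.zeros((n, c, lo, k))
            np.put_along_axis(gx, arg[..., None], g[..., None], axis=-1)
            gx = gx.reshape(n, c, lo * k)
            if lo * k < l:
                gx = np.pad(gx, ((0, 0), (0, 0), (0, l - lo * k)))
            self._accum(gx)

        return Tensor._make(y, (self,), bw)

    def adaptive_avg_pool1d(self, out_len: int) -> "Tensor":
        """Average pooling to a fixed output length, for any input length.

        Output bin ``i`` averages input samples ``[floor(iL/out), ceil((i+1)L/out))``,
        so the result has length ``out_len`` whether the input is longer or
        shorter than the target.
        """
        x = self.data
        n, c, l = x.shape
        starts = (np.arange(out_len) * l) // out_len
        ends = -(-((np.arange(out_len) + 1) * l) // out_len)  # ceil
        idx = np.concatenate([np.arange(a, b) for a, b in zip(starts, ends)])
        counts = (ends - starts).astype(np.float64)
        offsets = np.concatenate([[0], np.cumsum(counts)]).astype(np.intp)
        gathered = x[:, :, idx]
        y = np.add.reduceat(gathered, offsets[:-1], axis=-1) / counts

        def bw(g):
            gexp = np.repeat(g / counts, (ends - starts), axis=-1)
            gx = np.zeros_like(x)
            np.add.at(gx, (slice(None), slice(None), idx), gexp)
            self._accum(gx)

        return Tensor._make(y, (self,), bw)

    def batchnorm(self, gamma: "Tensor", beta: "Tensor",
                  mean: np.ndarray, var: np.ndarray,
                  eps: float = 1e-5) -> "Tensor":
        """Fused batch normalization over (N, C, L) with given statistics.

        ``mean``/``var`` are treated as functions of the input when they are
        the batch statistics; the backward pass uses the standard fused
        batch-norm gradient.
        """
        x = self.data
        inv_std = 1.0 / np.sqrt(var + eps)
        xhat = (x - mean) * inv_std
        y = gamma.data * xhat + beta.data

        def bw(g):
            axes = (0, 2)
            gamma._accum((g * xhat).sum(axis=axes, keepdims=True))
            beta._accum(g.sum(axis=axes, keepdims=True))
            if self.requires_grad:
                dxhat = g * gamma.data
                m = x.shape[0] * x.shape[2]
                dx = inv_std * (
                    dxhat - dxhat.mean(axis=axes, keepdims=True)
                    - xhat * (dxhat * xhat).mean(axis=axes, keepdims=True))
                # when mean/var are running (eval) statistics the correction
                # terms are absent; the caller signals that with m == 0
                self._accum(dx if m > 1 else dxhat * inv_std)

        return Tensor._make(y, (self, gamma, beta), bw)

    def batchnorm_eval(self, gamma: "Tensor", beta: "Tensor",
                       mean: np.ndarray, var: np.ndarray,
                       eps: float = 1e-5) -> "Tensor":
        """Batch normalization with fixed (running) statistics."""
        inv_std = 1.0 / np.sqrt(var + eps)
        xhat = (self.data - mean) * inv_std
        y = gamma.data * xhat + beta.data

        def bw(g):
            gamma._accum((g * xhat).sum(axis=(0, 2), keepdims=True))
            beta._accum(g.sum(axis=(0, 2), keepdims=True))
            if self.requires_grad:
                self._accum(g * gamma.data * inv_std)

        return Tensor._make(y, (self, gamma, beta), bw)

    # -- backward driver --------------------------------------------------
    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward()


class Parameter(Tensor):
    """A trainable tensor."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    """Base class tracking parameters and train/eval mode."""

    def __init__(self):
        self.training = True

    def parameters(self) -> list[Parameter]:
        out: list[Parameter] = []
        for v in self.__dict__.values():
            if isinstance(v, Parameter):
                out.append(v)
            elif isinstance(v, Module):
                out.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        out.extend(item.parameters())
                    elif isinstance(item, Parameter):
                        out.append(item)
        return out

    def train(self, mode: bool = True) -> "Module":
        self.training = mode
        for v in self.__dict__.values():
            if isinstance(v, Module):
                v.train(mode)
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        item.train(mode)
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def state_arrays(self) -> list[np.ndarray]:
        """Copies of all parameter arrays plus buffers (for checkpointing)."""
        arrs = [p.data.copy() for p in self.parameters()]
        arrs += [b.copy() for b in self._buffers()]
        return arrs

    def load_state_arrays(self, arrs: list[np.ndarray]) -> None:
        params = self.parameters()
        for p, a in zip(params, arrs[: len(params)]):
            p.data = a.copy()
        for buf, a in zip(self._buffers(), arrs[len(params):]):
            buf[...] = a

    def _buffers(self) -> list[np.ndarray]:
        out: list[np.ndarray] = []
        for v in self.__dict__.values():
            if isinstance(v, Module):
                out.extend(v._buffers())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        out.extend(item._buffers())
        if isinstance(self, BatchNorm1d):
            out.extend([self.running_mean, self.running_var])
        return out


def _kaiming(rng: np.random.Generator, fan_in: int, shape) -> np.ndarray:
    bound = math.sqrt(1.0 / max(fan_in, 1))
    return rng.uniform(-bound, bound, size=shape)


class Linear(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        super().__init__()
        self.weight = Parameter(_kaiming(rng, n_in, (n_in, n_out)))
        self.bias = Parameter(_kaiming(rng, n_in, (n_out,)))

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class Conv1d(Module):
    def __init__(self, c_in: int, c_out: int, kernel: int,
                 rng: np.random.Generator, padding: str | int = "same"):
        super().__init__()
        self.weight = Parameter(_kaiming(rng, c_in * kernel, (c_out, c_in, kernel)))
        self.bias = Parameter(_kaiming(rng, c_in * kernel, (c_out,)))
        self.padding = (kernel - 1) // 2 if padding == "same" else int(padding)

    def __call__(self, x: Tensor) -> Tensor:
        return x.conv1d(self.weight, self.bias, padding=self.padding)


class BatchNorm1d(Module):
    """Batch normalization over (N, C, L) with per-channel statistics."""

    def __init__(self, n_channels: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.gamma = Parameter(np.ones((1, n_channels, 1)))
        self.beta = Parameter(np.zeros((1, n_channels, 1)))
        self.eps = eps
        self.momentum = momentum
        self.running_mean = np.zeros((1, n_channels, 1))
        self.running_var = np.ones((1, n_channels, 1))

    def __call__(self, x: Tensor) -> Tensor:
        if self.training:
            mu = x.data.mean(axis=(0, 2), keepdims=True)
            var = x.data.var(axis=(0, 2), keepdims=True)
            self.running_mean *= (1 - self.momentum)
            self.running_mean += self.momentum * mu
            self.running_var *= (1 - self.momentum)
            self.running_var += self.momentum * var
            return x.batchnorm(self.gamma, self.beta, mu, var, self.eps)
        return x.batchnorm_eval(self.gamma, self.beta, self.running_mean,
                                self.running_var, self.eps)


class Adam:
    """Adam optimizer (Kingma & Ba) with the standard bias correction."""

    def __init__(self, params: Iterable[Parameter], lr: float = 1e-4,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
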