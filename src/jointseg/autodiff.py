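"""A compact reverse-mode automatic differentiation core on numpy arrays.

Everything the segmentation network needs — broadcast arithmetic, reductions,
N-dimensional convolution via an im2col/matmul lowering, pooling, nearest
upsampling — is expressed as ``Tensor`` operations that record a backward
closure.  ``Tensor.backward()`` runs the tape in reverse topological order.

The engine is deliberately small and CPU-oriented: single precision by
default, no graph optimisation, no broadcasting corner cases beyond numpy's
own rules.  It is sized for the desk-scale 2-D/3-D phantom experiments this
package targets, where single-core numpy matmuls dominate the runtime.
"""

from __future__ import annotations

import contextlib
from typing import Callable

import numpy as np

__all__ = ["Tensor", "no_grad", "concat", "Adam"]

_GRAD_ENABLED = [True]


@contextlib.contextmanager
def no_grad():
    """Disable graph recording (inference mode)."""
    _GRAD_ENABLED.append(False)
    try:
        yield
    finally:
        _GRAD_ENABLED.pop()


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, (g, s) in enumerate(zip(grad.shape, shape)):
        if s == 1 and g != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float32 if not isinstance(
            data, np.ndarray) else data.dtype)
        if self.data.dtype.kind != "f":
            self.data = self.data.astype(np.float32)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents: tuple[Tensor, ...] = ()
        self._backward: Callable[[], None] | None = None

    # -- graph plumbing ---------------------------------------------------

    @staticmethod
    def _make(data, parents, backward) -> "Tensor":
        out = Tensor.__new__(Tensor)
        out.data = data
        out.grad = None
        parents = tuple(p for p in parents if p.requires_grad)
        if _GRAD_ENABLED[-1] and parents:
            out.requires_grad = True
            out._parents = parents
            out._backward = backward
        else:
            out.requires_grad = False
            out._parents = ()
            out._backward = None
        return out

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.array(g, dtype=self.data.dtype, copy=True).reshape(self.data.shape)
        else:
            self.grad += g.reshape(self.data.shape)

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar output")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
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
                node._backward()

    def zero_grad(self) -> None:
        self.grad = None

    def detach(self) -> np.ndarray:
        return self.data

    # -- basic properties -------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    # -- arithmetic -------------------------------------------------------

    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float32))

    def __add__(self, other):
        other = Tensor._lift(other)
        out_data = self.data + other.data

        def bw():
            if self.requires_grad:
                self._accum(_unbroadcast(out.grad, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(out.grad, other.data.shape))

        out = Tensor._make(out_data, (self, other), bw)
        return out

    __radd__ = __add__

    def __neg__(self):
        def bw():
            self._accum(-out.grad)

        out = Tensor._make(-self.data, (self,), bw)
        return out

    def __sub__(self, other):
        return self + (-Tensor._lift(other))

    def __rsub__(self, other):
        return Tensor._lift(other) + (-self)

    def __mul__(self, other):
        other = Tensor._lift(other)
        out_data = self.data * other.data

        def bw():
            if self.requires_grad:
                self._accum(_unbroadcast(out.grad * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(out.grad * self.data, other.data.shape))

        out = Tensor._make(out_data, (self, other), bw)
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = Tensor._lift(other)
        out_data = self.data / other.data

        def bw():
            if self.requires_grad:
                self._accum(_unbroadcast(out.grad / other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(-out.grad * out_data / other.data,
                                          other.data.shape))

        out = Tensor._make(out_data, (self, other), bw)
        return out

    def __rtruediv__(self, other):
        return Tensor._lift(other) / self

    def __pow__(self, exponent: float):
        out_data = self.data ** exponent

        def bw():
            self._accum(out.grad * exponent * self.data ** (exponent - 1))

        out = Tensor._make(out_data, (self,), bw)
        return out

    def __abs__(self):
        out_data = np.abs(self.data)

        def bw():
            self._accum(out.grad * np.sign(self.data))

        out = Tensor._make(out_data, (self,), bw)
        return out

    def __getitem__(self, idx):
        out_data = self.data[idx]

        def bw():
            g = np.zeros_like(self.data)
            np.add.at(g, idx, out.grad)
            self._accum(g)

        out = Tensor._make(np.ascontiguousarray(out_data), (self,), bw)
        return out

    # -- reductions & reshaping -------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def bw():
            g = out.grad
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.data.shape))

        out = Tensor._make(np.asarray(out_data), (self,), bw)
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in np.atleast_1d(axis)])
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.data.shape
        out_data = self.data.reshape(shape)

        def bw():
            self._accum(out.grad.reshape(old))

        out = Tensor._make(out_data, (self,), bw)
        return out

    def transpose(self, axes):
        inv = np.argsort(axes)

        def bw():
            self._accum(out.grad.transpose(inv))

        out = Tensor._make(np.ascontiguousarray(self.data.transpose(axes)),
                           (self,), bw)
        return out

    # -- nonlinearities ----------------------------------------------------

    def exp(self):
        out_data = np.exp(self.data)

        def bw():
            self._accum(out.grad * out_data)

        out = Tensor._make(out_data, (self,), bw)
        return out

    def log(self):
        def bw():
            self._accum(out.grad / self.data)

        out = Tensor._make(np.log(self.data), (self,), bw)
        return out

    def leaky_relu(self, slope: float = 0.01):
        mask = self.data > 0
        out_data = np.where(mask, self.data, slope * self.data)

        def bw():
            self._accum(out.grad * np.where(mask, 1.0, slope).astype(self.data.dtype))

        out = Tensor._make(out_data, (self,), bw)
        return out

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-self.data))

        def bw():
            self._accum(out.grad * out_data * (1.0 - out_data))

        out = Tensor._make(out_data, (self,), bw)
        return out

    def clip(self, lo: float, hi: float):
        """Clamp values; gradient passes only where strictly inside [lo, hi]."""
        mask = (self.data > lo) & (self.data < hi)

        def bw():
            self._accum(out.grad * mask)

        out = Tensor._make(np.clip(self.data, lo, hi), (self,), bw)
        return out

    def softmax(self, axis: int = 1):
        """Numerically stable softmax along ``axis``."""
        z = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(z)
        p = e / e.sum(axis=axis, keepdims=True)

        def bw():
            g = out.grad
            dot = (g * p).sum(axis=axis, keepdims=True)
            self._accum(p * (g - dot))

        out = Tensor._make(p, (self,), bw)
        return out

    # -- linear algebra ----------------------------------------------------

    def matmul(self, other: "Tensor"):
        other = Tensor._lift(other)
        out_data = self.data @ other.data

        def bw():
            if self.requires_grad:
                self._accum(out.grad @ other.data.swapaxes(-1, -2))
            if other.requires_grad:
                other._accum(self.data.swapaxes(-1, -2) @ out.grad)

        out = Tensor._make(out_data, (self, other), bw)
        return out

    __matmul__ = matmul

    # -- spatial ops (N-d, channel-first layout (B, C, *spatial)) ----------

    def conv(self, weight: "Tensor", bias: "Tensor | None" = None):
        """Same-padded stride-1 N-d convolution (cross-correlation).

        ``self``: (B, Cin, *S); ``weight``: (Cout, Cin, *K) with odd kernel
        sizes; ``bias``: (Cout,) or None.
        """
        x, w = self.data, weight.data
        B, cin = x.shape[:2]
        S = x.shape[2:]
        K = w.shape[2:]
        d = len(K)
        cout = w.shape[0]
        prod_s = int(np.prod(S))
        pads = [((k - 1) // 2, k // 2) for k in K]
        padded_shape = (B, cin) + tuple(s + sum(p) for s, p in zip(S, pads))
        core = (slice(None), slice(None)) + tuple(
            slice(p[0], p[0] + s) for s, p in zip(S, pads))
        xp = np.zeros(padded_shape, dtype=x.dtype)
        xp[core] = x
        # accumulate over kernel offsets: out[b,o,:] += w[:,:,k] @ x_shift_k
        offsets = list(np.ndindex(*K))
        shifted = []  # cached (B, Cin, prodS) slices, reused in backward
        out2 = np.zeros((B, cout, prod_s), dtype=x.dtype)
        for kidx in offsets:
            sl = (slice(None), slice(None)) + tuple(
                slice(i, i + S[a]) for a, i in enumerate(kidx))
            m = xp[sl].reshape(B, cin, prod_s)
            shifted.append(m)
            out2 += w[(slice(None), slice(None)) + kidx] @ m
        out_data = out2.reshape(B, cout, *S)
        if bias is not None:
            out_data += bias.data.reshape((1, cout) + (1,) * d)

        def bw():
            g2 = out.grad.reshape(B, cout, prod_s)  # view
            if weight.requires_grad:
                dw = np.zeros_like(w)
                for kidx, m in zip(offsets, shifted):
                    dw[(slice(None), slice(None)) + kidx] = np.tensordot(
                        g2, m, axes=([0, 2], [0, 2]))
                weight._accum(dw)
            if bias is not None and bias.requires_grad:
                bias._accum(g2.sum(axis=(0, 2)))
            if self.requires_grad:
                dxp = np.zeros_like(xp)
                for kidx in offsets:
                    w_k = w[(slice(None), slice(None)) + kidx]
                    piece = (w_k.T @ g2).reshape(B, cin, *S)
                    sl = (slice(None), slice(None)) + tuple(
                        slice(i, i + S[a]) for a, i in enumerate(kidx))
                    dxp[sl] += piece
                self._accum(dxp[core])

        parents = (self, weight) if bias is None else (self, weight, bias)
        out = Tensor._make(out_data, parents, bw)
        return out

    def instance_norm(self, gamma: "Tensor", beta: "Tensor",
                      eps: float = 1e-5):
        """Fused per-sample, per-channel normalisation over spatial axes.

        ``self``: (B, C, *S); ``gamma``/``beta``: (C,) scale and shift.
        """
        x = self.data
        spatial = tuple(range(2, x.ndim))
        mu = x.mean(axis=spatial, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=spatial, keepdims=True)
        inv = 1.0 / np.sqrt(var + eps)
        xn = xc * inv
        bshape = (1, -1) + (1,) * len(spatial)
        out_data = xn * gamma.data.reshape(bshape) + beta.data.reshape(bshape)

        def bw():
            g = out.grad
            if gamma.requires_grad:
                gamma._accum((g * xn).sum(axis=(0,) + spatial))
            if beta.requires_grad:
                beta._accum(g.sum(axis=(0,) + spatial))
            if self.requires_grad:
                gg = g * gamma.data.reshape(bshape)
                m1 = gg.mean(axis=spatial, keepdims=True)
                m2 = (gg * xn).mean(axis=spatial, keepdims=True)
                self._accum(inv * (gg - m1 - xn * m2))

        out = Tensor._make(out_data, (self, gamma, beta), bw)
        return out

    def avg_pool(self, factor: int = 2):
        """Average pooling by ``factor`` along every spatial axis."""
        x = self.data
        B, C = x.shape[:2]
        S = x.shape[2:]
        if any(s % factor for s in S):
            raise ValueError(f"spatial shape {S} not divisible by {factor}")
        newshape = [B, C]
        for s in S:
            newshape += [s // factor, factor]
        xr = x.reshape(newshape)
        axes = tuple(range(3, 3 + 2 * len(S), 2))
        out_data = xr.mean(axis=axes)
        scale = 1.0 / factor ** len(S)

        def bw():
            g = out.grad * scale
            for ax in range(2, 2 + len(S)):
                g = np.repeat(g, factor, axis=ax)
            self._accum(g)

        out = Tensor._make(np.ascontiguousarray(out_data), (self,), bw)
        return out

    def upsample_nearest(self, factor: int = 2):
        """Nearest-neighbour upsampling by ``factor`` along spatial axes."""
        x = self.data
        S = x.shape[2:]
        out_data = x
        for ax in range(2, 2 + len(S)):
            out_data = np.repeat(out_data, factor, axis=ax)

        def bw():
            g = out.grad
            B, C = x.shape[:2]
            newshape = [B, C]
            for s in S:
                newshape += [s, factor]
            axes = tuple(range(3, 3 + 2 * len(S), 2))
            self._accum(g.reshape(newshape).sum(axis=axes))

        out = Tensor._make(out_data, (self,), bw)
        return out


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    """Concatenate tensors along ``axis``."""
    datas = [t.data for t in tensors]
    out_data = np.concatenate(datas, axis=axis)
    sizes = [d.shape[axis] for d in datas]
    offsets = np.cumsum([0] + sizes)

    def bw():
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * out_data.ndim
                sl[axis] = slice(lo, hi)
                t._accum(out.grad[tuple(sl)])

    out = Tensor._make(out_data, tuple(tensors), bw)
    return out


class Adam:
    """Adam optimiser over a list of parameter tensors."""

    def __init__(self, params: list[Tensor], lr: float = 5e-4,
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
        b1t = 1 - self.b1 ** self.t
        b2t = 1 - self.b2 ** self.t
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / b1t
            vhat = self.v[i] / b2t
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
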