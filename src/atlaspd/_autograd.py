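"""Minimal reverse-mode automatic differentiation on numpy arrays.

Define-by-run graph of :class:`Tensor` nodes with the handful of operations
the sequence models need: broadcasting arithmetic, batched matmul,
reshape/transpose, pointwise nonlinearities, reductions, softmax, and fused
layer-norm / dropout / LSTM / cross-entropy ops with hand-derived backward
passes (gradient-checked in the test suite).  Evaluation-mode code wraps
forward passes in :func:`no_grad` so no graph is retained.
"""

from __future__ import annotations

import contextlib

import numpy as np

__all__ = ["Tensor", "no_grad", "is_grad_enabled"]

_GRAD_ENABLED = True


@contextlib.contextmanager
def no_grad():
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def is_grad_enabled() -> bool:
    return _GRAD_ENABLED


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` over the axes that were broadcast from ``shape``."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "_parents", "_bw")

    def __init__(self, data, parents=(), bw=None):
        self.data = data if isinstance(data, np.ndarray) else np.asarray(data, dtype=float)
        self.grad: np.ndarray | None = None
        if _GRAD_ENABLED:
            self._parents = parents
            self._bw = bw
        else:
            self._parents = ()
            self._bw = None

    # -- graph ------------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.copy() if g.base is not None or g.flags.writeable is False else g
        else:
            self.grad = self.grad + g

    def backward(self, grad: np.ndarray | None = None) -> None:
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
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
        self.grad = np.ones_like(self.data) if grad is None else np.asarray(grad)
        for node in reversed(topo):
            if node._bw is not None and node.grad is not None:
                node._bw(node.grad)

    # -- arithmetic -------------------------------------------------------
    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=float))

    def __add__(self, other):
        if isinstance(other, (int, float)):  # dtype-preserving constant
            out = Tensor(self.data + other, (self,))
            out._bw = (lambda g: self._accumulate(g)) if _GRAD_ENABLED else None
            return out
        o = Tensor._lift(other)
        out = Tensor(self.data + o.data, (self, o))
        def bw(g):
            self._accumulate(_unbroadcast(g, self.data.shape))
            o._accumulate(_unbroadcast(g, o.data.shape))
        out._bw = bw if _GRAD_ENABLED else None
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, (self,))
        out._bw = (lambda g: self._accumulate(-g)) if _GRAD_ENABLED else None
        return out

    def __sub__(self, other):
        if isinstance(other, (int, float)):
            return self + (-other)
        return self + (-Tensor._lift(other))

    def __rsub__(self, other):
        return Tensor._lift(other) + (-self)

    def __mul__(self, other):
        if isinstance(other, (int, float)):  # dtype-preserving constant
            out = Tensor(self.data * other, (self,))
            out._bw = (lambda g: self._accumulate(g * other)) if _GRAD_ENABLED else None
            return out
        o = Tensor._lift(other)
        out = Tensor(self.data * o.data, (self, o))
        def bw(g):
            self._accumulate(_unbroadcast(g * o.data, self.data.shape))
            o._accumulate(_unbroadcast(g * self.data, o.data.shape))
        out._bw = bw if _GRAD_ENABLED else None
        return out

    __rmul__ = __mul__

    def __truediv__(self, scalar):
        if isinstance(scalar, Tensor):
            raise TypeError("division only by python scalars")
        return self * (1.0 / scalar)

    def matmul(self, other: "Tensor") -> "Tensor":
        o = Tensor._lift(other)
        out = Tensor(self.data @ o.data, (self, o))
        def bw(g):
            a, b = self.data, o.data
            if b.ndim >= 2:
                ga = g @ np.swapaxes(b, -1, -2)
            else:
                ga = np.expand_dims(g, -1) * b
            if a.ndim >= 2:
                gb = np.swapaxes(a, -1, -2) @ g
            else:
                gb = np.expand_dims(a, -1) * np.expand_dims(g, -2)
            self._accumulate(_unbroadcast(ga, a.shape))
            o._accumulate(_unbroadcast(gb, b.shape))
        out._bw = bw if _GRAD_ENABLED else None
        return out

    __matmul__ = matmul

    # -- shape ------------------------------------------------------------
    def reshape(self, *shape) -> "Tensor":
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        orig = self.data.shape
        out = Tensor(self.data.reshape(shape), (self,))
        out._bw = (lambda g: self._accumulate(g.reshape(orig))) if _GRAD_ENABLED else None
        return out

    def transpose(self, *axes) -> "Tensor":
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)
        out = Tensor(self.data.transpose(axes), (self,))
        out._bw = (lambda g: self._accumulate(g.transpose(inv))) if _GRAD_ENABLED else None
        return out

    def __getitem__(self, key) -> "Tensor":
        out = Tensor(self.data[key], (self,))
        def bw(g):
            full = np.zeros_like(self.data)
            np.add.at(full, key, g)
            self._accumulate(full)
        out._bw = bw if _GRAD_ENABLED else None
        return out

    # -- pointwise --------------------------------------------------------
    def tanh(self) -> "Tensor":
        y = np.tanh(self.data)
        out = Tensor(y, (self,))
        out._bw = (lambda g: self._accumulate(g * (1 - y * y))) if _GRAD_ENABLED else None
        return out

    def sigmoid(self) -> "Tensor":
        y = 1.0 / (1.0 + np.exp(-self.data))
        out = Tensor(y, (self,))
        out._bw = (lambda g: self._accumulate(g * y * (1 - y))) if _GRAD_ENABLED else None
        return out

    def relu(self) -> "Tensor":
        y = np.maximum(self.data, 0)
        out = Tensor(y, (self,))
        out._bw = (lambda g: self._accumulate(g * (self.data > 0))) if _GRAD_ENABLED else None
        return out

    # -- reductions -------------------------------------------------------
    def sum(self, axis=None, keepdims=False) -> "Tensor":
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), (self,))
        def bw(g):
            if axis is None:
                self._accumulate(np.broadcast_to(g, self.data.shape).astype(self.data.dtype))
                return
            gg = g if keepdims else np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(gg, self.data.shape).astype(self.data.dtype))
        out._bw = bw if _GRAD_ENABLED else None
        return out

    def mean(self, axis=None, keepdims=False) -> "Tensor":
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- fused ops --------------------------------------------------------
    def softmax(self, axis: int = -1) -> "Tensor":
        z = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(z)
        p = e / e.sum(axis=axis, keepdims=True)
        out = Tensor(p, (self,))
        def bw(g):
            dot = (g * p).sum(axis=axis, keepdims=True)
            self._accumulate(p * (g - dot))
        out._bw = bw if _GRAD_ENABLED else None
        return out

    def layer_norm(self, gamma: "Tensor", beta: "Tensor", eps: float = 1e-5) -> "Tensor":
        x = self.data
        mu = x.mean(axis=-1, keepdims=True)
        var = x.var(axis=-1, keepdims=True)
        inv = 1.0 / np.sqrt(var + eps)
        xhat = (x - mu) * inv
        out = Tensor(xhat * gamma.data + beta.data, (self, gamma, beta))
        def bw(g):
            d = x.shape[-1]
            gxhat = g * gamma.data
            gx = inv * (gxhat - gxhat.mean(axis=-1, keepdims=True)
                        - xhat * (gxhat * xhat).mean(axis=-1, keepdims=True))
            self._accumulate(gx.astype(x.dtype))
            red = tuple(range(g.ndim - 1))
            gamma._accumulate((g * xhat).sum(axis=red))
            beta._accumulate(g.sum(axis=red))
            del d
        out._bw = bw if _GRAD_ENABLED else None
        return out

    def dropout(self, p: float, rng: np.random.Generator, training: bool) -> "Tensor":
        if not training or p <= 0:
            return self
        mask = (rng.random(self.data.shape) >= p) / (1.0 - p)
        mask = mask.astype(self.data.dtype)
        return self * Tensor(mask)

    def cross_entropy(self, target_idx: np.ndarray) -> tuple["Tensor", np.ndarray]:
        """Softmax cross-entropy over the last axis; returns (loss, probs)."""
        z = self.data - self.data.max(axis=-1, keepdims=True)
        e = np.exp(z)
        p = e / e.sum(axis=-1, keepdims=True)
        n = self.data.shape[0]
        nll = -np.log(np.clip(p[np.arange(n), target_idx], 1e-12, None))
        out = Tensor(np.array(nll.mean()), (self,))
        def bw(g):
            grad = p.copy()
            grad[np.arange(n), target_idx] -= 1.0
            self._accumulate((float(g) / n) * grad)
        out._bw = bw if _GRAD_ENABLED else None
        return out, p


def lstm(x: Tensor, wx: Tensor, wh: Tensor, b: Tensor) -> Tensor:
    """Single-layer LSTM over a (B, T, D) input; returns hidden states (B, T, H).

    Fused op with a hand-written backward-through-time pass.  Gate order in
    the packed weight matrices is (input, forget, cell, output).
    """
    xd = x.data
    B, T, D = xd.shape
    H = wh.data.shape[0]
    dtype = xd.dtype

    a_all = xd.reshape(B * T, D) @ wx.data  # precompute input projections
    a_all = a_all.reshape(B, T, 4 * H) + b.data

    h = np.zeros((B, H), dtype=dtype)
    c = np.zeros((B, H), dtype=dtype)
    hs = np.empty((B, T, H), dtype=dtype)
    gates = np.empty((B, T, 4 * H), dtype=dtype)   # i, f, g, o post-activation
    cs = np.empty((B, T, H), dtype=dtype)
    tanh_cs = np.empty((B, T, H), dtype=dtype)
    for t in range(T):
        a = a_all[:, t] + h @ wh.data
        i = 1.0 / (1.0 + np.exp(-a[:, :H]))
        f = 1.0 / (1.0 + np.exp(-a[:, H:2 * H]))
        g = np.tanh(a[:, 2 * H:3 * H])
        o = 1.0 / (1.0 + np.exp(-a[:, 3 * H:]))
        c = f * c + i * g
        tc = np.tanh(c)
        h = o * tc
        gates[:, t, :H], gates[:, t, H:2 * H] = i, f
        gates[:, t, 2 * H:3 * H], gates[:, t, 3 * H:] = g, o
        cs[:, t] = c
        tanh_cs[:, t] = tc
        hs[:, t] = h

    out = Tensor(hs, (x, wx, wh, b))

    def bw(ghs):
        dA = np.empty((B, T, 4 * H), dtype=dtype)
        dh_next = np.zeros((B, H), dtype=dtype)
        dc_next = np.zeros((B, H), dtype=dtype)
        for t in range(T - 1, -1, -1):
            i = gates[:, t, :H]
            f = gates[:, t, H:2 * H]
            g = gates[:, t, 2 * H:3 * H]
            o = gates[:, t, 3 * H:]
            tc = tanh_cs[:, t]
            c_prev = cs[:, t - 1] if t > 0 else np.zeros((B, H), dtype=dtype)
            h_prev = hs[:, t - 1] if t > 0 else np.zeros((B, H), dtype=dtype)
            dh = ghs[:, t] + dh_next
            do = dh * tc
            dc = dh * o * (1 - tc * tc) + dc_next
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            da = dA[:, t]
            da[:, :H] = di * i * (1 - i)
            da[:, H:2 * H] = df * f * (1 - f)
            da[:, 2 * H:3 * H] = dg * (1 - g * g)
            da[:, 3 * H:] = do * o * (1 - o)
            dh_next = da @ wh.data.T
            dc_next = dc * f
            wh._accumulate(h_prev.T @ da)
        flat = dA.reshape(B * T, 4 * H)
        x._accumulate((flat @ wx.data.T).reshape(B, T, D))
        wx._accumulate(xd.reshape(B * T, D).T @ flat)
        b._accumulate(flat.sum(axis=0))

    out._bw = bw if is_grad_enabled() else None
    return out
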