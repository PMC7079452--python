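"""Minimal reverse-mode autodiff over numpy arrays.

Small, vectorized and dependency-free: enough machinery to train the
seq2seq canonicalizer and the convolutional QSAR head on a single CPU.
Every op builds a closure that accumulates gradients into its parents;
``Tensor.backward`` runs them in reverse topological order.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concatenate", "stack"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (reverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum over leading axes added by broadcasting
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    # sum over axes that were size-1 in the original
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


def _as_tensor(x) -> "Tensor":
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float64), requires_grad=False)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = requires_grad
        self._parents: tuple = ()
        self._backward = None

    # -- bookkeeping ---------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    def _make(self, data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def _accum(self, grad: np.ndarray):
        if self.grad is None:
            self.grad = grad.copy() if isinstance(grad, np.ndarray) else np.asarray(grad)
        else:
            self.grad = self.grad + grad

    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar tensor")
            grad = np.ones_like(self.data)
        self.grad = np.asarray(grad, dtype=np.float64)
        topo, seen = [], set()

        def visit(t):
            stack = [(t, False)]
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
                    if p.requires_grad and id(p) not in seen:
                        stack.append((p, False))

        visit(self)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)

    # -- arithmetic ----------------------------------------------------
    def __add__(self, other):
        other = _as_tensor(other)
        out_data = self.data + other.data

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.data.shape))

        return self._make(out_data, (self, other), bw)

    __radd__ = __add__

    def __neg__(self):
        def bw(g):
            self._accum(-g)

        return self._make(-self.data, (self,), bw)

    def __sub__(self, other):
        return self + (-_as_tensor(other))

    def __rsub__(self, other):
        return _as_tensor(other) + (-self)

    def __mul__(self, other):
        other = _as_tensor(other)
        out_data = self.data * other.data

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.data.shape))

        return self._make(out_data, (self, other), bw)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = _as_tensor(other)
        out_data = self.data / other.data

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g / other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(-g * self.data / other.data ** 2, other.data.shape))

        return self._make(out_data, (self, other), bw)

    def __matmul__(self, other):
        other = _as_tensor(other)
        out_data = np.matmul(self.data, other.data)

        def bw(g):
            if self.requires_grad:
                ga = np.matmul(g, np.swapaxes(other.data, -1, -2))
                self._accum(_unbroadcast(ga, self.data.shape))
            if other.requires_grad:
                gb = np.matmul(np.swapaxes(self.data, -1, -2), g)
                other._accum(_unbroadcast(gb, other.data.shape))

        return self._make(out_data, (self, other), bw)

    def __pow__(self, p: float):
        out_data = self.data ** p

        def bw(g):
            self._accum(g * p * self.data ** (p - 1))

        return self._make(out_data, (self,), bw)

    # -- elementwise nonlinearities -------------------------------------
    def exp(self):
        out_data = np.exp(self.data)

        def bw(g):
            self._accum(g * out_data)

        return self._make(out_data, (self,), bw)

    def log(self):
        def bw(g):
            self._accum(g / self.data)

        return self._make(np.log(self.data), (self,), bw)

    def sqrt(self):
        out_data = np.sqrt(self.data)

        def bw(g):
            self._accum(g * 0.5 / out_data)

        return self._make(out_data, (self,), bw)

    def relu(self):
        mask = self.data > 0

        def bw(g):
            self._accum(g * mask)

        return self._make(self.data * mask, (self,), bw)

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-np.clip(self.data, -60, 60)))

        def bw(g):
            self._accum(g * out_data * (1.0 - out_data))

        return self._make(out_data, (self,), bw)

    def tanh(self):
        out_data = np.tanh(self.data)

        def bw(g):
            self._accum(g * (1.0 - out_data ** 2))

        return self._make(out_data, (self,), bw)

    # -- reductions ----------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def bw(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.data.shape).copy())

        return self._make(out_data, (self,), bw)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def max(self, axis: int, keepdims: bool = False):
        """Max along one axis; gradient flows to the first argmax only."""
        idx = np.argmax(self.data, axis=axis)
        out_data = np.take_along_axis(self.data, np.expand_dims(idx, axis), axis=axis)
        if not keepdims:
            out_data = np.squeeze(out_data, axis=axis)

        def bw(g):
            g = np.asarray(g)
            if not keepdims:
                g = np.expand_dims(g, axis)
            gi = np.zeros_like(self.data)
            np.put_along_axis(gi, np.expand_dims(idx, axis), g, axis=axis)
            self._accum(gi)

        return self._make(out_data, (self,), bw)

    def log_softmax(self, axis: int = -1):
        m = self.data.max(axis=axis, keepdims=True)
        z = self.data - m
        lse = np.log(np.exp(z).sum(axis=axis, keepdims=True))
        out_data = z - lse
        sm = np.exp(out_data)

        def bw(g):
            self._accum(g - sm * g.sum(axis=axis, keepdims=True))

        return self._make(out_data, (self,), bw)

    def softmax(self, axis: int = -1):
        return self.log_softmax(axis=axis).exp()

    # -- shape ops -----------------------------------------------------
    def reshape(self, *shape):
        orig = self.data.shape

        def bw(g):
            self._accum(g.reshape(orig))

        return self._make(self.data.reshape(*shape), (self,), bw)

    def transpose(self, *axes):
        inv = np.argsort(axes)

        def bw(g):
            self._accum(g.transpose(*inv))

        return self._make(self.data.transpose(*axes), (self,), bw)

    def __getitem__(self, key):
        out_data = self.data[key]

        def bw(g):
            gi = np.zeros_like(self.data)
            np.add.at(gi, key, g)
            self._accum(gi)

        return self._make(out_data, (self,), bw)

    def take_rows(self, indices: np.ndarray):
        """Row gather (embedding lookup): returns data[indices] along axis 0."""
        indices = np.asarray(indices)
        out_data = self.data[indices]

        def bw(g):
            gi = np.zeros_like(self.data)
            np.add.at(gi, indices.reshape(-1), g.reshape(-1, self.data.shape[-1]))
            self._accum(gi)

        return self._make(out_data, (self,), bw)

    def take_along_last(self, indices: np.ndarray):
        """Pick one entry per position along the last axis (CE target pick)."""
        idx = np.expand_dims(np.asarray(indices), -1)
        out_data = np.take_along_axis(self.data, idx, axis=-1)

        def bw(g):
            gi = np.zeros_like(self.data)
            np.put_along_axis(gi, idx, g, axis=-1)
            self._accum(gi)

        return self._make(out_data, (self,), bw)

    def unfold1d(self, k: int):
        """(B, L, D) -> (B, L-k+1, k*D) sliding windows; backward scatters."""
        B, L, D = self.data.shape
        W = L - k + 1
        windows = np.lib.stride_tricks.sliding_window_view(self.data, (k,), axis=1)
        # sliding_window_view gives (B, W, D, k); reorder to (B, W, k, D)
        out_data = np.ascontiguousarray(windows.transpose(0, 1, 3, 2)).reshape(B, W, k * D)

        def bw(g):
            g4 = g.reshape(B, W, k, D)
            gi = np.zeros_like(self.data)
            for j in range(k):
                gi[:, j:j + W, :] += g4[:, :, j, :]
            self._accum(gi)

        return self._make(out_data, (self,), bw)


def concatenate(tensors, axis: int = -1) -> Tensor:
    datas = [t.data for t in tensors]
    out = Tensor(np.concatenate(datas, axis=axis))
    if any(t.requires_grad for t in tensors):
        sizes = [d.shape[axis] for d in datas]
        offsets = np.cumsum([0] + sizes)

        def bw(g):
            for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
                if t.requires_grad:
                    sl = [slice(None)] * g.ndim
                    sl[axis] = slice(lo, hi)
                    t._accum(g[tuple(sl)])

        out.requires_grad = True
        out._parents = tuple(tensors)
        out._backward = bw
    return out


def stack(tensors, axis: int = 0) -> Tensor:
    datas = [np.expand_dims(t.data, axis) for t in tensors]
    out = Tensor(np.concatenate(datas, axis=axis))
    if any(t.requires_grad for t in tensors):
        def bw(g):
            for i, t in enumerate(tensors):
                if t.requires_grad:
                    sl = [slice(None)] * g.ndim
                    sl[axis] = i
                    t._accum(g[tuple(sl)])

        out.requires_grad = True
        out._parents = tuple(tensors)
        out._backward = bw
    return out
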