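"""Minimal reverse-mode automatic differentiation over numpy arrays.

Supports exactly the operator set the sequence-design models need: broadcast
arithmetic, (batched) matmul, pointwise nonlinearities, concatenation and
slicing, reductions, softmax / fused softmax-cross-entropy, embedding lookup
and stride-2 "same"-padded 2-D convolution. Gradients accumulate into
``Tensor.grad``; call :meth:`Tensor.backward` on a scalar.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "softmax", "cross_entropy_logits", "embedding",
           "conv2d"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (reverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for i, s in enumerate(shape):
        if s == 1 and grad.shape[i] != 1:
            grad = grad.sum(axis=i, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, parents=(),
                 backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad or any(
            p.requires_grad for p in parents)
        self._parents = parents
        self._backward = backward

    # -- helpers ----------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def _accumulate(self, g: np.ndarray) -> None:
        if not self.requires_grad:
            return
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    # -- arithmetic -------------------------------------------------------
    def __add__(self, other):
        other = self._wrap(other)
        out = Tensor(self.data + other.data, parents=(self, other))

        def bw(g):
            self._accumulate(_unbroadcast(g, self.shape))
            other._accumulate(_unbroadcast(g, other.shape))
        out._backward = bw
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, parents=(self,))
        out._backward = lambda g: self._accumulate(-g)
        return out

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        other = self._wrap(other)
        out = Tensor(self.data * other.data, parents=(self, other))

        def bw(g):
            self._accumulate(_unbroadcast(g * other.data, self.shape))
            other._accumulate(_unbroadcast(g * self.data, other.shape))
        out._backward = bw
        return out

    __rmul__ = __mul__

    def matmul(self, other: "Tensor") -> "Tensor":
        other = self._wrap(other)
        out = Tensor(self.data @ other.data, parents=(self, other))

        def bw(g):
            self._accumulate(_unbroadcast(
                g @ np.swapaxes(other.data, -1, -2), self.shape))
            other._accumulate(_unbroadcast(
                np.swapaxes(self.data, -1, -2) @ g, other.shape))
        out._backward = bw
        return out

    __matmul__ = matmul

    # -- nonlinearities ---------------------------------------------------
    def tanh(self):
        y = np.tanh(self.data)
        out = Tensor(y, parents=(self,))
        out._backward = lambda g: self._accumulate(g * (1.0 - y * y))
        return out

    def sigmoid(self):
        y = 1.0 / (1.0 + np.exp(-np.clip(self.data, -60, 60)))
        out = Tensor(y, parents=(self,))
        out._backward = lambda g: self._accumulate(g * y * (1.0 - y))
        return out

    def relu(self):
        mask = self.data > 0
        out = Tensor(self.data * mask, parents=(self,))
        out._backward = lambda g: self._accumulate(g * mask)
        return out

    # -- shape ops --------------------------------------------------------
    def reshape(self, shape):
        orig = self.shape
        out = Tensor(self.data.reshape(shape), parents=(self,))
        out._backward = lambda g: self._accumulate(g.reshape(orig))
        return out

    def __getitem__(self, key):
        out = Tensor(self.data[key], parents=(self,))

        def bw(g):
            full = np.zeros_like(self.data)
            full[key] += g
            self._accumulate(full)
        out._backward = bw
        return out

    # -- reductions -------------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims),
                     parents=(self,))

        def bw(g):
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(g, self.shape).copy())
        out._backward = bw
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- autodiff driver --------------------------------------------------
    def backward(self) -> None:
        assert self.data.size == 1, "backward() expects a scalar loss"
        topo: list[Tensor] = []
        seen: set[int] = set()

        def visit(t: Tensor):
            stack = [(t, iter(t._parents))]
            seen.add(id(t))
            while stack:
                node, it = stack[-1]
                advanced = False
                for p in it:
                    if id(p) not in seen and p.requires_grad:
                        seen.add(id(p))
                        stack.append((p, iter(p._parents)))
                        advanced = True
                        break
                if not advanced:
                    topo.append(node)
                    stack.pop()

        visit(self)
        self.grad = np.ones_like(self.data)
        # Reverse topological order: a node's grad is complete before its
        # backward closure distributes it to the parents.
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    datas = [t.data for t in tensors]
    out = Tensor(np.concatenate(datas, axis=axis), parents=tuple(tensors))
    sizes = [d.shape[axis] for d in datas]

    def bw(g):
        start = 0
        for t, s in zip(tensors, sizes):
            idx = [slice(None)] * g.ndim
            idx[axis if axis >= 0 else g.ndim + axis] = slice(start, start + s)
            t._accumulate(g[tuple(idx)])
            start += s
    out._backward = bw
    return out


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    z = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    y = e / e.sum(axis=axis, keepdims=True)
    out = Tensor(y, parents=(x,))

    def bw(g):
        x._accumulate(y * (g - (g * y).sum(axis=axis, keepdims=True)))
    out._backward = bw
    return out


def cross_entropy_logits(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Per-element categorical cross-entropy.

    ``logits``: (..., C); ``targets``: integer array of shape (...).
    Returns a Tensor of shape (...) with -log p[target].
    """
    z = logits.data - logits.data.max(axis=-1, keepdims=True)
    lse = np.log(np.exp(z).sum(axis=-1, keepdims=True))
    logp = z - lse
    t = np.asarray(targets)
    picked = np.take_along_axis(logp, t[..., None], axis=-1)[..., 0]
    out = Tensor(-picked, parents=(logits,))

    def bw(g):
        p = np.exp(logp)
        onehot = np.zeros_like(p)
        np.put_along_axis(onehot, t[..., None], 1.0, axis=-1)
        logits._accumulate((p - onehot) * g[..., None])
    out._backward = bw
    return out


def embedding(weight: Tensor, idx: np.ndarray) -> Tensor:
    idx = np.asarray(idx, dtype=np.int64)
    out = Tensor(weight.data[idx], parents=(weight,))

    def bw(g):
        if weight.requires_grad:
            if weight.grad is None:
                weight.grad = np.zeros_like(weight.data)
            np.add.at(weight.grad, idx, g)
    out._backward = bw
    return out


def conv2d(x: Tensor, w: Tensor, b: Tensor, stride: tuple[int, int] = (1, 1),
           ) -> Tensor:
    """'Same'-padded 2-D convolution, NHWC layout.

    ``x``: (B, H, W, Cin); ``w``: (kh, kw, Cin, Cout); ``b``: (Cout,).
    Output spatial size is ceil(H/sh) x ceil(W/sw).
    """
    sh, sw = stride
    kh, kw, cin, cout = w.shape
    ph, pw = kh // 2, kw // 2
    xp = np.pad(x.data, ((0, 0), (ph, ph), (pw, pw), (0, 0)))
    win = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(1, 2))
    # win: (B, H', W', Cin, kh, kw); subsample by stride
    win = win[:, ::sh, ::sw]
    out_data = np.einsum("bhwcij,ijco->bhwo", win, w.data,
                         optimize=True) + b.data
    out = Tensor(out_data, parents=(x, w, b))
    bsz, ho, wo, _ = out_data.shape

    def bw(g):
        if w.requires_grad:
            gw = np.einsum("bhwo,bhwcij->ijco", g, win, optimize=True)
            w._accumulate(gw)
        if b.requires_grad:
            b._accumulate(g.sum(axis=(0, 1, 2)))
        if x.requires_grad:
            gxp = np.zeros_like(xp)
            for i in range(kh):
                for j in range(kw):
                    patch = np.einsum("bhwo,co->bhwc", g, w.data[i, j],
                                      optimize=True)
                    gxp[:, i:i + ho * sh:sh, j:j + wo * sw:sw, :] += patch
            x._accumulate(gxp[:, ph:ph + x.shape[1], pw:pw + x.shape[2], :])
    out._backward = bw
    return out
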