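"""Minimal reverse-mode automatic differentiation over numpy arrays.

Supports exactly the operations needed by the tabular networks and the
small 3D CNN: broadcasting arithmetic, matmul, elementwise nonlinearities,
reductions, 3D (depthwise) convolution and a numerically stable binary
cross-entropy on logits. Gradients flow to any leaf tensor created with
``requires_grad=True``, including input volumes (used for saliency maps).
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "conv3d", "depthwise_conv3d", "bce_with_logits"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndiff = grad.ndim - len(shape)
    if ndiff > 0:
        grad = grad.sum(axis=tuple(range(ndiff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """An ndarray node in a dynamically built computation graph."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents = tuple(parents)
        self._backward = backward

    # -- graph plumbing ----------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without gradient requires a scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
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
        self.grad = np.asarray(grad, dtype=np.float64)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accumulate(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = grad.copy()
        else:
            self.grad = self.grad + grad

    # -- arithmetic --------------------------------------------------------

    @staticmethod
    def _coerce(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def __add__(self, other):
        other = self._coerce(other)
        out = Tensor(self.data + other.data,
                     self.requires_grad or other.requires_grad,
                     parents=(self, other))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.data.shape))

        out._backward = bwd
        return out

    __radd__ = __add__

    def __mul__(self, other):
        other = self._coerce(other)
        out = Tensor(self.data * other.data,
                     self.requires_grad or other.requires_grad,
                     parents=(self, other))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.data.shape))

        out._backward = bwd
        return out

    __rmul__ = __mul__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        return self + (-self._coerce(other))

    def __rsub__(self, other):
        return self._coerce(other) + (-self)

    def __truediv__(self, other):
        return self * self._coerce(other) ** -1.0

    def __rtruediv__(self, other):
        return self._coerce(other) * self ** -1.0

    def __pow__(self, exponent: float):
        out = Tensor(self.data ** exponent, self.requires_grad, parents=(self,))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g * exponent * self.data ** (exponent - 1.0))

        out._backward = bwd
        return out

    def __matmul__(self, other):
        other = self._coerce(other)
        out = Tensor(self.data @ other.data,
                     self.requires_grad or other.requires_grad,
                     parents=(self, other))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g @ other.data.swapaxes(-1, -2))
            if other.requires_grad:
                other._accumulate(self.data.swapaxes(-1, -2) @ g)

        out._backward = bwd
        return out

    # -- elementwise nonlinearities ---------------------------------------

    def exp(self):
        val = np.exp(self.data)
        out = Tensor(val, self.requires_grad, parents=(self,))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g * val)

        out._backward = bwd
        return out

    def log(self):
        out = Tensor(np.log(self.data), self.requires_grad, parents=(self,))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g / self.data)

        out._backward = bwd
        return out

    def sigmoid(self):
        val = 0.5 * (1.0 + np.tanh(0.5 * self.data))  # stable logistic
        out = Tensor(val, self.requires_grad, parents=(self,))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g * val * (1.0 - val))

        out._backward = bwd
        return out

    def relu(self):
        mask = self.data > 0
        out = Tensor(self.data * mask, self.requires_grad, parents=(self,))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g * mask)

        out._backward = bwd
        return out

    def swish(self):
        return self * self.sigmoid()

    # -- reductions / shaping ---------------------------------------------

    def sum(self, axis=None, keepdims=False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims),
                     self.requires_grad, parents=(self,))

        def bwd(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accumulate(np.broadcast_to(g, self.data.shape).copy())
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(g, self.data.shape).copy())

        out._backward = bwd
        return out

    def mean(self, axis=None, keepdims=False):
        if axis is None:
            n = self.data.size
        else:
            axes = (axis,) if isinstance(axis, int) else tuple(axis)
            n = int(np.prod([self.data.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), self.requires_grad, parents=(self,))

        def bwd(g):
            if self.requires_grad:
                self._accumulate(g.reshape(self.data.shape))

        out._backward = bwd
        return out


# -- convolution primitives ------------------------------------------------


def _pad_spatial(x: np.ndarray, pad: int) -> np.ndarray:
    if pad == 0:
        return x
    width = [(0, 0), (0, 0)] + [(pad, pad)] * 3
    return np.pad(x, width)


def _out_size(size: int, k: int, stride: int, pad: int) -> int:
    return (size + 2 * pad - k) // stride + 1


def _gather_cols(xp: np.ndarray, k: int, stride: int, oshape) -> np.ndarray:
    """Stack the k^3 shifted views of the padded input: (k^3, N, C, *oshape)."""
    od, oh, ow = oshape
    cols = np.empty((k ** 3,) + xp.shape[:2] + (od, oh, ow), dtype=xp.dtype)
    i = 0
    for a in range(k):
        for b in range(k):
            for c in range(k):
                cols[i] = xp[:, :,
                             a:a + stride * od:stride,
                             b:b + stride * oh:stride,
                             c:c + stride * ow:stride]
                i += 1
    return cols


def _scatter_cols(grad_cols: np.ndarray, xp_shape, k: int, stride: int, oshape) -> np.ndarray:
    od, oh, ow = oshape
    gxp = np.zeros(xp_shape, dtype=grad_cols.dtype)
    i = 0
    for a in range(k):
        for b in range(k):
            for c in range(k):
                gxp[:, :,
                    a:a + stride * od:stride,
                    b:b + stride * oh:stride,
                    c:c + stride * ow:stride] += grad_cols[i]
                i += 1
    return gxp


def conv3d(x: Tensor, w: Tensor, b: Tensor | None = None,
           stride: int = 1, padding: int = 0) -> Tensor:
    """3D convolution. x: (N,C,D,H,W), w: (F,C,k,k,k), b: (F,)."""
    n, cin, d, h, wd = x.data.shape
    f, cin_w, k, _, _ = w.data.shape
    if cin != cin_w:
        raise ValueError(f"channel mismatch: input has {cin}, kernel expects {cin_w}")
    oshape = (_out_size(d, k, stride, padding),
              _out_size(h, k, stride, padding),
              _out_size(wd, k, stride, padding))
    xp = _pad_spatial(x.data, padding)
    cols = _gather_cols(xp, k, stride, oshape)  # (k3, N, C, od, oh, ow)
    wk = w.data.reshape(f, cin, k ** 3)
    out_data = np.einsum("kncdhw,fck->nfdhw", cols, wk, optimize=True)
    if b is not None:
        out_data = out_data + b.data.reshape(1, f, 1, 1, 1)
    parents = (x, w) if b is None else (x, w, b)
    out = Tensor(out_data, any(p.requires_grad for p in parents), parents=parents)

    def bwd(g):
        if w.requires_grad:
            gw = np.einsum("nfdhw,kncdhw->fck", g, cols, optimize=True)
            w._accumulate(gw.reshape(w.data.shape))
        if b is not None and b.requires_grad:
            b._accumulate(g.sum(axis=(0, 2, 3, 4)))
        if x.requires_grad:
            gcols = np.einsum("nfdhw,fck->kncdhw", g, wk, optimize=True)
            gxp = _scatter_cols(gcols, xp.shape, k, stride, oshape)
            if padding:
                gxp = gxp[:, :, padding:-padding, padding:-padding, padding:-padding]
            x._accumulate(gxp)

    out._backward = bwd
    return out


def depthwise_conv3d(x: Tensor, w: Tensor, b: Tensor | None = None,
                     stride: int = 1, padding: int = 0) -> Tensor:
    """Depthwise 3D convolution. x: (N,C,D,H,W), w: (C,k,k,k), b: (C,)."""
    n, cin, d, h, wd = x.data.shape
    c_w, k = w.data.shape[0], w.data.shape[1]
    if cin != c_w:
        raise ValueError(f"channel mismatch: input has {cin}, kernel expects {c_w}")
    oshape = (_out_size(d, k, stride, padding),
              _out_size(h, k, stride, padding),
              _out_size(wd, k, stride, padding))
    xp = _pad_spatial(x.data, padding)
    cols = _gather_cols(xp, k, stride, oshape)
    wk = w.data.reshape(cin, k ** 3)
    out_data = np.einsum("kncdhw,ck->ncdhw", cols, wk, optimize=True)
    if b is not None:
        out_data = out_data + b.data.reshape(1, cin, 1, 1, 1)
    parents = (x, w) if b is None else (x, w, b)
    out = Tensor(out_data, any(p.requires_grad for p in parents), parents=parents)

    def bwd(g):
        if w.requires_grad:
            gw = np.einsum("ncdhw,kncdhw->ck", g, cols, optimize=True)
            w._accumulate(gw.reshape(w.data.shape))
        if b is not None and b.requires_grad:
            b._accumulate(g.sum(axis=(0, 2, 3, 4)))
        if x.requires_grad:
            gcols = np.einsum("ncdhw,ck->kncdhw", g, wk, optimize=True)
            gxp = _scatter_cols(gcols, xp.shape, k, stride, oshape)
            if padding:
                gxp = gxp[:, :, padding:-padding, padding:-padding, padding:-padding]
            x._accumulate(gxp)

    out._backward = bwd
    return out


def bce_with_logits(logits: Tensor, targets: np.ndarray,
                    weights: np.ndarray | None = None) -> Tensor:
    """Mean binary cross-entropy on raw logits (numerically stable)."""
    z = logits.data
    y = np.asarray(targets, dtype=np.float64).reshape(z.shape)
    losses = np.logaddexp(0.0, z) - y * z
    if weights is None:
        loss_val = losses.mean()
    else:
        wts = np.asarray(weights, dtype=np.float64).reshape(z.shape)
        loss_val = (losses * wts).sum() / wts.sum()
    out = Tensor(loss_val, logits.requires_grad, parents=(logits,))

    def bwd(g):
        if logits.requires_grad:
            p = 0.5 * (1.0 + np.tanh(0.5 * z))
            grad = (p - y)
            if weights is None:
                grad = grad / z.size
            else:
                wts = np.asarray(weights, dtype=np.float64).reshape(z.shape)
                grad = grad * wts / wts.sum()
            logits._accumulate(g * grad)

    out._backward = bwd
    return out
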