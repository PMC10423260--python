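"""A small reverse-mode automatic-differentiation engine on numpy arrays.

This is the numerical core under the deep AHI regressor: a define-by-run
tape of `Tensor` nodes supporting the operations the architecture needs —
elementwise arithmetic and activations, matrix multiplication, 1-D
convolution with stride and dilation, max pooling, reductions, slicing,
concatenation — each with an analytic backward rule.  `Tensor.backward()`
runs a topological sweep accumulating gradients into `grad`.

The engine is deliberately minimal: single device, no graph retention
across backward calls, float32 by default (float64 inputs stay float64,
which the numerical-gradient tests rely on).
"""

from __future__ import annotations

import numpy as np


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, (g, s) in enumerate(zip(grad.shape, shape)) if s == 1 and g != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A node in the autodiff tape wrapping a numpy array."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False, _prev=()):
        self.data = np.asarray(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._backward = None
        self._prev = _prev

    # -- plumbing ----------------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    @property
    def size(self):
        return self.data.size

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data, dtype=self.data.dtype)
        self.grad += g

    def backward(self) -> None:
        """Backpropagate from this (scalar) tensor through the tape."""
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS; graphs can be thousands of nodes deep
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._prev:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data, dtype=self.data.dtype)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- arithmetic --------------------------------------------------------

    def __add__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(np.asarray(other, self.data.dtype))
        out = Tensor(self.data + other.data, _prev=(self, other))

        def _bw(g):
            self._accumulate(_unbroadcast(g, self.data.shape))
            other._accumulate(_unbroadcast(g, other.data.shape))
        out._backward = _bw
        return out

    def __mul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(np.asarray(other, self.data.dtype))
        out = Tensor(self.data * other.data, _prev=(self, other))

        def _bw(g):
            self._accumulate(_unbroadcast(g * other.data, self.data.shape))
            other._accumulate(_unbroadcast(g * self.data, other.data.shape))
        out._backward = _bw
        return out

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        return self + (-other if isinstance(other, Tensor) else -np.asarray(other))

    def __rsub__(self, other):
        return (-self) + other

    __radd__ = __add__
    __rmul__ = __mul__

    def __truediv__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(np.asarray(other, self.data.dtype))
        return self * other.pow(-1.0)

    def pow(self, p: float) -> "Tensor":
        out = Tensor(self.data ** p, _prev=(self,))

        def _bw(g):
            self._accumulate(g * p * self.data ** (p - 1))
        out._backward = _bw
        return out

    def sqrt(self) -> "Tensor":
        return self.pow(0.5)

    def matmul(self, other: "Tensor") -> "Tensor":
        out = Tensor(self.data @ other.data, _prev=(self, other))

        def _bw(g):
            a, b = self.data, other.data
            ga = g @ np.swapaxes(b, -1, -2)
            gb = np.swapaxes(a, -1, -2) @ g
            self._accumulate(_unbroadcast(ga, a.shape))
            other._accumulate(_unbroadcast(gb, b.shape))
        out._backward = _bw
        return out

    __matmul__ = matmul

    # -- activations -------------------------------------------------------

    def exp(self) -> "Tensor":
        out = Tensor(np.exp(self.data), _prev=(self,))

        def _bw(g):
            self._accumulate(g * out.data)
        out._backward = _bw
        return out

    def log(self) -> "Tensor":
        out = Tensor(np.log(self.data), _prev=(self,))

        def _bw(g):
            self._accumulate(g / self.data)
        out._backward = _bw
        return out

    def tanh(self) -> "Tensor":
        out = Tensor(np.tanh(self.data), _prev=(self,))

        def _bw(g):
            self._accumulate(g * (1.0 - out.data ** 2))
        out._backward = _bw
        return out

    def sigmoid(self) -> "Tensor":
        out = Tensor(1.0 / (1.0 + np.exp(-self.data)), _prev=(self,))

        def _bw(g):
            self._accumulate(g * out.data * (1.0 - out.data))
        out._backward = _bw
        return out

    def leaky_relu(self, alpha: float = 0.1) -> "Tensor":
        out = Tensor(np.where(self.data > 0, self.data, alpha * self.data),
                     _prev=(self,))

        def _bw(g):
            self._accumulate(g * np.where(self.data > 0, 1.0, alpha))
        out._backward = _bw
        return out

    # -- reductions and reshaping -----------------------------------------

    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), _prev=(self,))

        def _bw(g):
            if axis is None:
                self._accumulate(np.broadcast_to(g, self.data.shape).copy())
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(g, self.data.shape).copy())
        out._backward = _bw
        return out

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        if axis is None:
            denom = self.data.size
        else:
            axes = (axis,) if isinstance(axis, int) else axis
            denom = int(np.prod([self.data.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / denom)

    def reshape(self, *shape) -> "Tensor":
        out = Tensor(self.data.reshape(*shape), _prev=(self,))

        def _bw(g):
            self._accumulate(g.reshape(self.data.shape))
        out._backward = _bw
        return out

    def transpose(self, *axes) -> "Tensor":
        out = Tensor(self.data.transpose(*axes), _prev=(self,))
        inv = np.argsort(axes)

        def _bw(g):
            self._accumulate(g.transpose(*inv))
        out._backward = _bw
        return out

    def __getitem__(self, idx) -> "Tensor":
        out = Tensor(self.data[idx], _prev=(self,))

        def _bw(g):
            gx = np.zeros_like(self.data)
            gx[idx] += g  # basic slicing only: no duplicate positions
            self._accumulate(gx)
        out._backward = _bw
        return out

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"


# ---------------------------------------------------------------------------
# free functions
# ---------------------------------------------------------------------------

def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis),
                 _prev=tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def _bw(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            t._accumulate(piece)
    out._backward = _bw
    return out


def conv1d(x: Tensor, w: Tensor, b: Tensor | None = None, stride: int = 1,
           dilation: int = 1, padding: int = 0) -> Tensor:
    """1-D convolution (cross-correlation): x (N, Cin, L), w (Cout, Cin, K)."""
    N, Cin, L = x.data.shape
    Cout, Cin2, K = w.data.shape
    assert Cin == Cin2, "channel mismatch"
    span = (K - 1) * dilation + 1
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding))) if padding else x.data
    Lp = xp.shape[2]
    if Lp < span:
        raise ValueError("input shorter than the dilated kernel span")
    L_out = (Lp - span) // stride + 1
    win = np.lib.stride_tricks.sliding_window_view(xp, span, axis=2)[..., ::dilation]
    win = win[:, :, ::stride][:, :, :L_out]  # (N, Cin, L_out, K)
    y = np.einsum("nclk,ock->nol", win, w.data, optimize=True)
    if b is not None:
        y = y + b.data[None, :, None]
    prev = (x, w) + ((b,) if b is not None else ())
    out = Tensor(y, _prev=prev)

    def _bw(g):
        gw = np.einsum("nol,nclk->ock", g, win, optimize=True)
        w._accumulate(gw.astype(w.data.dtype, copy=False))
        if b is not None:
            b._accumulate(g.sum(axis=(0, 2)).astype(b.data.dtype, copy=False))
        gxp = np.zeros_like(xp)
        for k in range(K):
            # tap k touches positions k*dilation + stride*j, distinct per j
            gxp[:, :, k * dilation: k * dilation + stride * L_out: stride] += \
                np.einsum("nol,oc->ncl", g, w.data[:, :, k], optimize=True)
        gx = gxp[:, :, padding: Lp - padding] if padding else gxp
        x._accumulate(gx.astype(x.data.dtype, copy=False))
    out._backward = _bw
    return out


def maxpool1d(x: Tensor, kernel: int) -> Tensor:
    """Non-overlapping max pooling with stride == kernel; tail trimmed."""
    N, C, L = x.data.shape
    Lo = L // kernel
    if Lo < 1:
        raise ValueError("sequence shorter than the pooling kernel")
    blocks = x.data[:, :, : Lo * kernel].reshape(N, C, Lo, kernel)
    arg = blocks.argmax(axis=3)
    out = Tensor(np.take_along_axis(blocks, arg[..., None], axis=3)[..., 0],
                 _prev=(x,))

    def _bw(g):
        gb = np.zeros((N, C, Lo, kernel), dtype=x.data.dtype)
        np.put_along_axis(gb, arg[..., None], g[..., None], axis=3)
        gx = np.zeros_like(x.data)
        gx[:, :, : Lo * kernel] = gb.reshape(N, C, Lo * kernel)
        x._accumulate(gx)
    out._backward = _bw
    return out


def mse(pred: Tensor, target: np.ndarray) -> Tensor:
    """Mean squared error against a constant target."""
    diff = pred - Tensor(np.asarray(target, pred.data.dtype))
    return (diff * diff).mean()
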