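"""Reverse-mode automatic differentiation on numpy arrays.

A deliberately small define-by-run engine: every operation returns a new
:class:`Tensor` holding the forward value and a closure that propagates
gradients to its parents.  Only the operations needed by the segmentation
models live here (elementwise arithmetic, matmul, reductions, shape ops,
2-D convolution / transposed convolution / max-pooling via im2col, and a
bilinear resize).  Gradients flow only through tensors whose subgraph
contains a parameter with ``requires_grad=True``, so frozen submodels cost
no backward work.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "as_tensor",
    "concat",
    "stack",
    "conv2d",
    "conv_transpose2d",
    "max_pool2d",
    "bilinear_resize",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    # -- construction helpers -------------------------------------------------

    @staticmethod
    def _from_op(data, parents, backward):
        out = Tensor(data)
        out._parents = tuple(p for p in parents if p.requires_grad)
        out.requires_grad = bool(out._parents)
        if out.requires_grad:
            out._backward = backward
        return out

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def dtype(self):
        return self.data.dtype

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def _accum(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.array(grad, dtype=self.data.dtype, copy=True)
        else:
            self.grad += grad

    def backward(self, grad=None) -> None:
        if not self.requires_grad:
            raise RuntimeError("backward() on a tensor that requires no grad")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [self]
        while stack:  # iterative DFS; training graphs can be deep (BPTT)
            node = stack[-1]
            if id(node) in seen:
                stack.pop()
                continue
            unvisited = [p for p in node._parents if id(p) not in seen]
            if unvisited:
                stack.extend(unvisited)
            else:
                seen.add(id(node))
                topo.append(node)
                stack.pop()
        if grad is None:
            grad = np.ones_like(self.data)
        self._accum(np.asarray(grad, dtype=self.data.dtype))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
                node._backward = None  # free closures as we go

    # -- arithmetic -----------------------------------------------------------

    def __add__(self, other):
        other = as_tensor(other, self.dtype)

        def bwd(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.shape))

        return Tensor._from_op(self.data + other.data, (self, other), bwd)

    __radd__ = __add__

    def __neg__(self):
        def bwd(g):
            self._accum(-g)

        return Tensor._from_op(-self.data, (self,), bwd)

    def __sub__(self, other):
        return self + (-as_tensor(other, self.dtype))

    def __rsub__(self, other):
        return as_tensor(other, self.dtype) + (-self)

    def __mul__(self, other):
        other = as_tensor(other, self.dtype)

        def bwd(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.shape))

        return Tensor._from_op(self.data * other.data, (self, other), bwd)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other, self.dtype)

        def bwd(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g / other.data, self.shape))
            if other.requires_grad:
                other._accum(
                    _unbroadcast(-g * self.data / (other.data * other.data), other.shape)
                )

        return Tensor._from_op(self.data / other.data, (self, other), bwd)

    def __rtruediv__(self, other):
        return as_tensor(other, self.dtype) / self

    def __pow__(self, exponent: float):
        def bwd(g):
            self._accum(g * exponent * self.data ** (exponent - 1))

        return Tensor._from_op(self.data**exponent, (self,), bwd)

    def __matmul__(self, other):
        other = as_tensor(other, self.dtype)
        out = np.matmul(self.data, other.data)

        def bwd(g):
            if self.requires_grad:
                ga = np.matmul(g, np.swapaxes(other.data, -1, -2))
                self._accum(_unbroadcast(ga, self.shape))
            if other.requires_grad:
                gb = np.matmul(np.swapaxes(self.data, -1, -2), g)
                other._accum(_unbroadcast(gb, other.shape))

        return Tensor._from_op(out, (self, other), bwd)

    def __getitem__(self, idx):
        def bwd(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            self._accum(full)

        return Tensor._from_op(self.data[idx], (self,), bwd)

    # -- reductions / shape ---------------------------------------------------

    def sum(self, axis=None, keepdims=False):
        def bwd(g):
            if axis is None:
                self._accum(np.broadcast_to(g, self.shape))
                return
            gg = g
            if not keepdims:
                gg = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(gg, self.shape))

        return Tensor._from_op(self.data.sum(axis=axis, keepdims=keepdims), (self,), bwd)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else np.prod(
            [self.shape[a] for a in np.atleast_1d(axis)]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])

        def bwd(g):
            self._accum(g.reshape(self.shape))

        return Tensor._from_op(self.data.reshape(shape), (self,), bwd)

    def transpose(self, axes):
        inv = np.argsort(axes)

        def bwd(g):
            self._accum(g.transpose(inv))

        return Tensor._from_op(self.data.transpose(axes), (self,), bwd)

    # -- pointwise nonlinearities --------------------------------------------

    def exp(self):
        out = np.exp(self.data)

        def bwd(g):
            self._accum(g * out)

        return Tensor._from_op(out, (self,), bwd)

    def log(self):
        def bwd(g):
            self._accum(g / self.data)

        return Tensor._from_op(np.log(self.data), (self,), bwd)

    def sqrt(self):
        out = np.sqrt(self.data)

        def bwd(g):
            self._accum(g * 0.5 / out)

        return Tensor._from_op(out, (self,), bwd)

    def sigmoid(self):
        out = 1.0 / (1.0 + np.exp(-self.data))

        def bwd(g):
            self._accum(g * out * (1.0 - out))

        return Tensor._from_op(out, (self,), bwd)

    def tanh(self):
        out = np.tanh(self.data)

        def bwd(g):
            self._accum(g * (1.0 - out * out))

        return Tensor._from_op(out, (self,), bwd)

    def leaky_relu(self, alpha: float = 0.10):
        mask = self.data >= 0
        scale = np.where(mask, 1.0, alpha).astype(self.data.dtype)

        def bwd(g):
            self._accum(g * scale)

        return Tensor._from_op(self.data * scale, (self,), bwd)

    def softmax(self, axis: int = -1):
        shifted = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(shifted)
        out = e / e.sum(axis=axis, keepdims=True)

        def bwd(g):
            dot = (g * out).sum(axis=axis, keepdims=True)
            self._accum(out * (g - dot))

        return Tensor._from_op(out, (self,), bwd)


def as_tensor(value, dtype=None) -> Tensor:
    if isinstance(value, Tensor):
        return value
    arr = np.asarray(value)
    if dtype is not None and arr.dtype != dtype and np.issubdtype(arr.dtype, np.floating):
        arr = arr.astype(dtype)
    elif dtype is not None and not np.issubdtype(arr.dtype, np.floating):
        arr = arr.astype(dtype)
    return Tensor(arr)


def concat(tensors, axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bwd(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accum(g[tuple(sl)])

    return Tensor._from_op(
        np.concatenate([t.data for t in tensors], axis=axis), tensors, bwd
    )


def stack(tensors, axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]

    def bwd(g):
        parts = np.moveaxis(g, axis, 0)
        for t, piece in zip(tensors, parts):
            if t.requires_grad:
                t._accum(piece)

    return Tensor._from_op(np.stack([t.data for t in tensors], axis=axis), tensors, bwd)


# -- im2col machinery ---------------------------------------------------------


def _conv_out_size(size, k, s, d, p):
    return (size + 2 * p - d * (k - 1) - 1) // s + 1


def _im2col(x: np.ndarray, kh, kw, sh, sw, dh, dw, ph, pw):
    """Return (cols, (Ho, Wo)) with cols of shape (N, C*kh*kw, Ho*Wo)."""
    n, c, h, w = x.shape
    ho = _conv_out_size(h, kh, sh, dh, ph)
    wo = _conv_out_size(w, kw, sw, dw, pw)
    xp = np.pad(x, ((0, 0), (0, 0), (ph, ph), (pw, pw))) if (ph or pw) else x
    cols = np.empty((n, c, kh, kw, ho, wo), dtype=x.dtype)
    for i in range(kh):
        ri = slice(i * dh, i * dh + sh * (ho - 1) + 1, sh)
        for j in range(kw):
            rj = slice(j * dw, j * dw + sw * (wo - 1) + 1, sw)
            cols[:, :, i, j] = xp[:, :, ri, rj]
    return cols.reshape(n, c * kh * kw, ho * wo), (ho, wo)


def _col2im(cols: np.ndarray, xshape, kh, kw, sh, sw, dh, dw, ph, pw):
    """Adjoint of :func:`_im2col`; scatter-adds columns back into an image."""
    n, c, h, w = xshape
    ho = _conv_out_size(h, kh, sh, dh, ph)
    wo = _conv_out_size(w, kw, sw, dw, pw)
    cols = cols.reshape(n, c, kh, kw, ho, wo)
    xp = np.zeros((n, c, h + 2 * ph, w + 2 * pw), dtype=cols.dtype)
    for i in range(kh):
        ri = slice(i * dh, i * dh + sh * (ho - 1) + 1, sh)
        for j in range(kw):
            rj = slice(j * dw, j * dw + sw * (wo - 1) + 1, sw)
            xp[:, :, ri, rj] += cols[:, :, i, j]
    if ph or pw:
        return xp[:, :, ph : ph + h, pw : pw + w]
    return xp


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None, *, stride=1, padding=0,
           dilation=1) -> Tensor:
    """2-D convolution (cross-correlation), NCHW layout, weight (F, C, kh, kw)."""
    sh, sw = (stride, stride) if np.isscalar(stride) else stride
    ph, pw = (padding, padding) if np.isscalar(padding) else padding
    dh, dw = (dilation, dilation) if np.isscalar(dilation) else dilation
    f, c, kh, kw = w.shape
    n = x.shape[0]
    cols, (ho, wo) = _im2col(x.data, kh, kw, sh, sw, dh, dw, ph, pw)
    w2 = w.data.reshape(f, c * kh * kw)
    out = np.matmul(w2, cols).reshape(n, f, ho, wo)
    if b is not None:
        out += b.data.reshape(1, f, 1, 1)
    parents = (x, w) if b is None else (x, w, b)

    def bwd(g):
        g2 = g.reshape(n, f, ho * wo)
        if w.requires_grad:
            gw = np.matmul(g2, cols.transpose(0, 2, 1)).sum(axis=0)
            w._accum(gw.reshape(w.shape))
        if b is not None and b.requires_grad:
            b._accum(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            dcols = np.matmul(w2.T, g2)
            x._accum(_col2im(dcols, x.shape, kh, kw, sh, sw, dh, dw, ph, pw))

    return Tensor._from_op(out, parents, bwd)


def conv_transpose2d(x: Tensor, w: Tensor, b: Tensor | None = None, *, stride=1,
                     padding=0, output_padding=0) -> Tensor:
    """Transposed 2-D convolution, weight (Cin, Cout, kh, kw).

    Output size per axis: ``(in - 1) * stride - 2 * padding + kernel + output_padding``
    with ``0 <= output_padding < stride``.
    """
    sh, sw = (stride, stride) if np.isscalar(stride) else stride
    ph, pw = (padding, padding) if np.isscalar(padding) else padding
    oph, opw = (output_padding, output_padding) if np.isscalar(output_padding) else output_padding
    cin, cout, kh, kw = w.shape
    n, _, hi, wi = x.shape
    ho = (hi - 1) * sh - 2 * ph + kh + oph
    wo = (wi - 1) * sw - 2 * pw + kw + opw
    x2 = x.data.reshape(n, cin, hi * wi)
    w2 = w.data.reshape(cin, cout * kh * kw)
    cols = np.matmul(w2.T, x2)
    out = _col2im(cols, (n, cout, ho, wo), kh, kw, sh, sw, 1, 1, ph, pw)
    if b is not None:
        out += b.data.reshape(1, cout, 1, 1)
    parents = (x, w) if b is None else (x, w, b)

    def bwd(g):
        dcols, _ = _im2col(g, kh, kw, sh, sw, 1, 1, ph, pw)
        if x.requires_grad:
            x._accum(np.matmul(w2, dcols).reshape(x.shape))
        if w.requires_grad:
            gw = np.matmul(x2, dcols.transpose(0, 2, 1)).sum(axis=0)
            w._accum(gw.reshape(w.shape))
        if b is not None and b.requires_grad:
            b._accum(g.sum(axis=(0, 2, 3)))

    return Tensor._from_op(out, parents, bwd)


def max_pool2d(x: Tensor, kernel: int = 3, stride: int = 2, padding: int = 1) -> Tensor:
    n, c, h, w = x.shape
    cols, (ho, wo) = _im2col(
        np.where(np.isneginf(x.data), x.data, x.data),  # copy-safe view
        kernel, kernel, stride, stride, 1, 1, padding, padding,
    )
    # padded entries are zeros; make them -inf so they never win the max
    if padding:
        pad_mask_src = np.pad(
            np.zeros((n, c, h, w), dtype=bool), ((0, 0), (0, 0), (padding,) * 2, (padding,) * 2),
            constant_values=True,
        )
        mask_cols = np.empty((n, c, kernel, kernel, ho, wo), dtype=bool)
        for i in range(kernel):
            ri = slice(i, i + stride * (ho - 1) + 1, stride)
            for j in range(kernel):
                rj = slice(j, j + stride * (wo - 1) + 1, stride)
                mask_cols[:, :, i, j] = pad_mask_src[:, :, ri, rj]
        cols = cols.reshape(n, c, kernel * kernel, ho * wo)
        cols = np.where(mask_cols.reshape(n, c, kernel * kernel, ho * wo), -np.inf, cols)
    else:
        cols = cols.reshape(n, c, kernel * kernel, ho * wo)
    idx = cols.argmax(axis=2)
    out = np.take_along_axis(cols, idx[:, :, None, :], axis=2)[:, :, 0, :]

    def bwd(g):
        dcols = np.zeros((n, c, kernel * kernel, ho * wo), dtype=g.dtype)
        np.put_along_axis(dcols, idx[:, :, None, :], g.reshape(n, c, 1, ho * wo), axis=2)
        x._accum(
            _col2im(dcols.reshape(n, c * kernel * kernel, ho * wo), x.shape,
                    kernel, kernel, stride, stride, 1, 1, padding, padding)
        )

    return Tensor._from_op(out.reshape(n, c, ho, wo), (x,), bwd)


def bilinear_resize(x: Tensor, out_hw: tuple[int, int]) -> Tensor:
    """Differentiable bilinear resize of an NCHW tensor (half-pixel centers)."""
    n, c, h, w = x.shape
    ho, wo = out_hw
    if (ho, wo) == (h, w):
        return x

    def axis_coords(size_in, size_out):
        src = (np.arange(size_out) + 0.5) * (size_in / size_out) - 0.5
        i0 = np.clip(np.floor(src).astype(int), 0, size_in - 1)
        i1 = np.clip(i0 + 1, 0, size_in - 1)
        frac = np.clip(src - np.floor(src), 0.0, 1.0)
        frac = np.where(src < 0, 0.0, frac)
        return i0, i1, frac

    r0, r1, fr = axis_coords(h, ho)
    c0, c1, fc = axis_coords(w, wo)
    fr = fr.astype(x.dtype)[None, None, :, None]
    fc = fc.astype(x.dtype)[None, None, None, :]
    d = x.data
    top = d[:, :, r0][:, :, :, c0] * (1 - fc) + d[:, :, r0][:, :, :, c1] * fc
    bot = d[:, :, r1][:, :, :, c0] * (1 - fc) + d[:, :, r1][:, :, :, c1] * fc
    out = top * (1 - fr) + bot * fr

    def bwd(g):
        dx = np.zeros_like(d)
        gtop = g * (1 - fr)
        gbot = g * fr
        for rows, gpart in ((r0, gtop), (r1, gbot)):
            left = gpart * (1 - fc)
            right = gpart * fc
            tmp = np.zeros((n, c, ho, w), dtype=g.dtype)
            np.add.at(tmp, (slice(None), slice(None), slice(None), c0), left)
            np.add.at(tmp, (slice(None), slice(None), slice(None), c1), right)
            np.add.at(dx, (slice(None), slice(None), rows), tmp)
        x._accum(dx)

    return Tensor._from_op(out, (x,), bwd)
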