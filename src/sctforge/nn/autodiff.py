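"""Minimal reverse-mode automatic differentiation over numpy arrays.

A :class:`Tensor` wraps a float32 ndarray and records the operations applied
to it; :meth:`Tensor.backward` runs reverse-mode accumulation over the
recorded tape. Only the operations the image-translation network needs are
provided: broadcasting arithmetic, matmul, reductions, ELU, 2-D convolution
(im2col), 2x2 transposed convolution and 2x2 max-pooling.

All computation is float32 and fully deterministic: identical inputs and
parameters produce bit-identical outputs on a given platform.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "conv2d", "conv_transpose2d", "maxpool2x2"]


def _as_array(x) -> np.ndarray:
    a = np.asarray(x, dtype=np.float32)
    return a


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (reverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    nd = grad.ndim - len(shape)
    if nd > 0:
        grad = grad.sum(axis=tuple(range(nd)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = _as_array(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents: tuple = ()

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    # -- autograd core --------------------------------------------------------
    def _make(self, data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = parents
            out._backward = backward
        return out

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar output")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS; graphs can exceed recursion limits
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
                node._backward(node.grad)
            node._backward = None
            node._parents = ()

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.astype(np.float32, copy=True)
        else:
            self.grad += g

    # -- arithmetic -----------------------------------------------------------
    def __add__(self, other):
        other = self._wrap(other)

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.data.shape))

        return self._make(self.data + other.data, (self, other), bw)

    __radd__ = __add__

    def __neg__(self):
        def bw(g):
            self._accum(-g)

        return self._make(-self.data, (self,), bw)

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        other = self._wrap(other)

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.data.shape))

        return self._make(self.data * other.data, (self, other), bw)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._wrap(other)

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g / other.data, self.data.shape))
            if other.requires_grad:
                other._accum(
                    _unbroadcast(-g * self.data / (other.data**2), other.data.shape)
                )

        return self._make(self.data / other.data, (self, other), bw)

    def __rtruediv__(self, other):
        return self._wrap(other) / self

    def __pow__(self, p: float):
        if not np.isscalar(p):
            raise TypeError("only scalar exponents are supported")

        def bw(g):
            self._accum(g * p * self.data ** (p - 1))

        return self._make(self.data**p, (self,), bw)

    def abs(self):
        s = np.sign(self.data)  # subgradient 0 at 0

        def bw(g):
            self._accum(g * s)

        return self._make(np.abs(self.data), (self,), bw)

    def sqrt(self):
        out_data = np.sqrt(self.data)

        def bw(g):
            self._accum(g * 0.5 / out_data)

        return self._make(out_data, (self,), bw)

    def elu(self, alpha: float = 1.0):
        neg = alpha * (np.exp(np.minimum(self.data, 0.0)) - 1.0)
        out_data = np.where(self.data > 0, self.data, neg)
        deriv = np.where(self.data > 0, 1.0, neg + alpha).astype(np.float32)

        def bw(g):
            self._accum(g * deriv)

        return self._make(out_data, (self,), bw)

    # -- shape ops ------------------------------------------------------------
    def reshape(self, *shape):
        old = self.data.shape

        def bw(g):
            self._accum(g.reshape(old))

        return self._make(self.data.reshape(*shape), (self,), bw)

    def __getitem__(self, idx):
        def bw(g):
            full = np.zeros_like(self.data)
            full[idx] = g
            self._accum(full)

        return self._make(self.data[idx], (self,), bw)

    def pad2d(self, pad, mode: str = "constant"):
        """Pad the two trailing (spatial) axes of an NCHW tensor.

        pad = (top, bottom, left, right). Reflect-mode gradients are folded
        back onto the mirrored source pixels.
        """
        t, b, l, r = pad
        width = [(0, 0)] * (self.data.ndim - 2) + [(t, b), (l, r)]
        out_data = np.pad(self.data, width, mode=mode)
        H, W = self.data.shape[-2:]

        def bw(g):
            if mode == "constant":
                self._accum(g[..., t : t + H, l : l + W])
            else:  # reflect: scatter-add mirrored contributions
                idx_h = np.pad(np.arange(H), (t, b), mode=mode)
                idx_w = np.pad(np.arange(W), (l, r), mode=mode)
                acc = np.zeros_like(self.data)
                np.add.at(acc, (Ellipsis, idx_h[:, None], idx_w[None, :]), g)
                self._accum(acc)

        return self._make(out_data, (self,), bw)

    # -- reductions -----------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def bw(g):
            if axis is None:
                self._accum(np.broadcast_to(g, self.data.shape).astype(np.float32))
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.data.shape).astype(np.float32))

        return self._make(out_data, (self,), bw)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in np.atleast_1d(axis)]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def __matmul__(self, other):
        other = self._wrap(other)

        def bw(g):
            if self.requires_grad:
                self._accum(g @ other.data.T)
            if other.requires_grad:
                other._accum(self.data.T @ g)

        return self._make(self.data @ other.data, (self, other), bw)


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    tensors = [Tensor._wrap(t) for t in tensors]
    data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bw(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            if t.requires_grad:
                t._accum(piece)

    out = Tensor(data)
    if any(t.requires_grad for t in tensors):
        out.requires_grad = True
        out._parents = tuple(tensors)
        out._backward = bw
    return out


# -- convolution primitives (NCHW) --------------------------------------------


def _im2col(xp: np.ndarray, kh: int, kw: int) -> np.ndarray:
    """(N,C,Hp,Wp) -> (N, Ho, Wo, C*kh*kw) windows for stride 1."""
    win = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(2, 3))
    # win: (N, C, Ho, Wo, kh, kw)
    n, c, ho, wo = win.shape[:4]
    return win.transpose(0, 2, 3, 1, 4, 5).reshape(n, ho, wo, c * kh * kw)


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None, padding: int = 0) -> Tensor:
    """Stride-1 2-D convolution (cross-correlation) of NCHW input.

    w has shape (C_out, C_in, kh, kw); b, if given, shape (C_out,).
    """
    kh, kw = w.data.shape[2:]
    if padding:
        xp = np.pad(x.data, ((0, 0), (0, 0), (padding,) * 2, (padding,) * 2))
    else:
        xp = x.data
    col = _im2col(xp, kh, kw)  # (N,Ho,Wo,C*kh*kw)
    n, ho, wo, k = col.shape
    wmat = w.data.reshape(w.data.shape[0], -1)  # (O, K)
    out = col.reshape(-1, k) @ wmat.T  # (N*Ho*Wo, O)
    out = out.reshape(n, ho, wo, -1).transpose(0, 3, 1, 2)
    if b is not None:
        out = out + b.data[None, :, None, None]

    def bw(g):
        gm = g.transpose(0, 2, 3, 1).reshape(-1, w.data.shape[0])  # (NHW, O)
        if w.requires_grad:
            gw = gm.T @ col.reshape(-1, k)
            w._accum(gw.reshape(w.data.shape))
        if b is not None and b.requires_grad:
            b._accum(gm.sum(axis=0))
        if x.requires_grad:
            gcol = gm @ wmat  # (NHW, K)
            gcol = gcol.reshape(n, ho, wo, x.data.shape[1], kh, kw)
            gxp = np.zeros_like(xp)
            for i in range(kh):
                for j in range(kw):
                    gxp[:, :, i : i + ho, j : j + wo] += gcol[:, :, :, :, i, j].transpose(
                        0, 3, 1, 2
                    )
            if padding:
                gxp = gxp[:, :, padding:-padding, padding:-padding]
            x._accum(gxp)

    parents = (x, w) if b is None else (x, w, b)
    return x._make(out.astype(np.float32), parents, bw)


def conv_transpose2d(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """2x2-kernel, stride-2 transposed convolution: exact x2 upsampling.

    w has shape (C_in, C_out, 2, 2). Non-overlapping kernels make the
    operation a per-offset linear map, which keeps it cheap and exactly
    invertible in shape.
    """
    n, cin, h, wdt = x.data.shape
    cout = w.data.shape[1]
    out = np.empty((n, cout, 2 * h, 2 * wdt), dtype=np.float32)
    xm = x.data.transpose(0, 2, 3, 1).reshape(-1, cin)  # (NHW, Cin)
    for i in range(2):
        for j in range(2):
            o = xm @ w.data[:, :, i, j]  # (NHW, Cout)
            out[:, :, i::2, j::2] = o.reshape(n, h, wdt, cout).transpose(0, 3, 1, 2)
    if b is not None:
        out += b.data[None, :, None, None]

    def bw(g):
        if b is not None and b.requires_grad:
            b._accum(g.sum(axis=(0, 2, 3)))
        gx = np.zeros_like(x.data) if x.requires_grad else None
        for i in range(2):
            for j in range(2):
                gm = g[:, :, i::2, j::2].transpose(0, 2, 3, 1).reshape(-1, cout)
                if w.requires_grad:
                    if w.grad is None:
                        w.grad = np.zeros_like(w.data)
                    w.grad[:, :, i, j] += xm.T @ gm  # (Cin, Cout)
                if gx is not None:
                    gxm = gm @ w.data[:, :, i, j].T  # (NHW, Cin)
                    gx += gxm.reshape(n, h, wdt, cin).transpose(0, 3, 1, 2)
        if gx is not None:
            x._accum(gx)

    parents = (x, w) if b is None else (x, w, b)
    return x._make(out, parents, bw)


def maxpool2x2(x: Tensor) -> Tensor:
    n, c, h, w = x.data.shape
    if h % 2 or w % 2:
        raise ValueError("maxpool2x2 requires even spatial dimensions")
    win = x.data.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
    win = win.reshape(n, c, h // 2, w // 2, 4)
    idx = win.argmax(axis=-1)
    out = np.take_along_axis(win, idx[..., None], axis=-1)[..., 0]

    def bw(g):
        gwin = np.zeros((n, c, h // 2, w // 2, 4), dtype=np.float32)
        np.put_along_axis(gwin, idx[..., None], g[..., None], axis=-1)
        gwin = gwin.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        x._accum(gwin.reshape(n, c, h, w))

    return x._make(out, (x,), bw)
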