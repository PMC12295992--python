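"""A compact reverse-mode automatic-differentiation engine on numpy arrays.

This is the numerical substrate for the multitask network: dense tensors
(float32), a dynamically built computation graph, and backward passes via
topological sort. Heavy operations (3D convolution, depthwise convolution,
nearest-neighbor resize, trilinear grid sampling) are dedicated primitives
implemented with strided views and BLAS matmuls so that CPU training of the
tiny preset is practical; everything else (activations, reductions,
normalizations) composes from the generic primitives below.

Conventions
-----------
* volumes are ``(B, C, D, H, W)``;
* point features are ``(P, C)``; point coordinates ``(P, 3)`` normalized to
  [0, 1] over the volume extent;
* convolutions use "same-ceil" padding: every stride-``s`` conv maps spatial
  size ``n`` to ``ceil(n / s)``.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["Tensor", "concat", "conv3d", "depthwise_conv3d", "resize_nearest",
           "grid_sample"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Reduce ``grad`` back to ``shape`` after numpy broadcasting."""
    if grad.shape == shape:
        return grad
    nd = grad.ndim - len(shape)
    if nd > 0:
        grad = grad.sum(axis=tuple(range(nd)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        # float inputs keep their precision (float64 for oracle-grade
        # checks); everything else becomes the engine's float32 workhorse
        arr = np.asarray(data)
        if arr.dtype not in (np.float32, np.float64):
            arr = arr.astype(np.float32)
        self.data = arr
        self.grad = None
        self.requires_grad = requires_grad
        self._backward = None
        self._parents = ()

    # -- graph plumbing ----------------------------------------------------

    @staticmethod
    def _make(data, parents, backward):
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def _accum(self, g):
        if self.grad is None:
            self.grad = np.asarray(g, dtype=self.data.dtype).copy()
        else:
            self.grad += g

    def backward(self, grad=None):
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self.grad = (
            np.ones_like(self.data) if grad is None
            else np.asarray(grad, dtype=self.data.dtype)
        )
        for t in reversed(topo):
            if t._backward is not None:
                t._backward(t.grad)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    # -- basics ------------------------------------------------------------

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

    @staticmethod
    def _wrap(x) -> "Tensor":
        if isinstance(x, Tensor):
            return x
        if isinstance(x, (int, float)):
            # float32 scalars: array-array promotion would otherwise drag
            # the whole float32 graph up to float64
            return Tensor(np.float32(x))
        return Tensor(x)

    # -- arithmetic --------------------------------------------------------

    def __add__(self, other):
        other = Tensor._wrap(other)

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.shape))

        return Tensor._make(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            if self.requires_grad:
                self._accum(-g)

        return Tensor._make(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-Tensor._wrap(other))

    def __rsub__(self, other):
        return Tensor._wrap(other) + (-self)

    def __mul__(self, other):
        other = Tensor._wrap(other)

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.shape))

        return Tensor._make(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = Tensor._wrap(other)

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g / other.data, self.shape))
            if other.requires_grad:
                other._accum(
                    _unbroadcast(-g * self.data / other.data**2, other.shape)
                )

        return Tensor._make(self.data / other.data, (self, other), backward)

    def __rtruediv__(self, other):
        return Tensor._wrap(other) / self

    def square(self):
        def backward(g):
            if self.requires_grad:
                self._accum(2.0 * g * self.data)

        return Tensor._make(self.data**2, (self,), backward)

    def sqrt(self):
        out_data = np.sqrt(self.data)

        def backward(g):
            if self.requires_grad:
                self._accum(g * 0.5 / np.maximum(out_data, 1e-12))

        return Tensor._make(out_data, (self,), backward)

    def log(self):
        def backward(g):
            if self.requires_grad:
                self._accum(g / self.data)

        return Tensor._make(np.log(self.data), (self,), backward)

    # -- activations -------------------------------------------------------

    def relu(self):
        mask = self.data > 0

        def backward(g):
            if self.requires_grad:
                self._accum(g * mask)

        return Tensor._make(self.data * mask, (self,), backward)

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-self.data))

        def backward(g):
            if self.requires_grad:
                self._accum(g * out_data * (1.0 - out_data))

        return Tensor._make(out_data, (self,), backward)

    def tanh(self):
        out_data = np.tanh(self.data)

        def backward(g):
            if self.requires_grad:
                self._accum(g * (1.0 - out_data**2))

        return Tensor._make(out_data, (self,), backward)

    def silu(self):
        s = 1.0 / (1.0 + np.exp(-self.data))

        def backward(g):
            if self.requires_grad:
                self._accum(g * (s + self.data * s * (1.0 - s)))

        return Tensor._make(self.data * s, (self,), backward)

    def clip(self, lo: float, hi: float):
        """Clamp values; gradient is passed through inside [lo, hi] only."""
        inside = (self.data >= lo) & (self.data <= hi)

        def backward(g):
            if self.requires_grad:
                self._accum(g * inside)

        return Tensor._make(np.clip(self.data, lo, hi), (self,), backward)

    # -- reductions --------------------------------------------------------

    def sum(self, axis=None, keepdims=False):
        def backward(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accum(np.broadcast_to(g, self.shape))
                return
            axes = (axis,) if isinstance(axis, int) else tuple(axis)
            if not keepdims:
                g = np.expand_dims(g, tuple(a % self.ndim for a in axes))
            self._accum(np.broadcast_to(g, self.shape))

        return Tensor._make(
            self.data.sum(axis=axis, keepdims=keepdims), (self,), backward
        )

    def mean(self, axis=None, keepdims=False):
        if axis is None:
            n = self.data.size
        else:
            axes = (axis,) if isinstance(axis, int) else tuple(axis)
            n = int(np.prod([self.shape[a % self.ndim] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def min(self, axis: int):
        """Minimum along one axis; gradient flows to the argmin entries."""
        idx = np.argmin(self.data, axis=axis)
        out_data = np.take_along_axis(
            self.data, np.expand_dims(idx, axis), axis=axis
        ).squeeze(axis)

        def backward(g):
            if not self.requires_grad:
                return
            gx = np.zeros_like(self.data)
            np.put_along_axis(
                gx, np.expand_dims(idx, axis), np.expand_dims(g, axis), axis=axis
            )
            self._accum(gx)

        return Tensor._make(out_data, (self,), backward)

    # -- shape -------------------------------------------------------------

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.shape

        def backward(g):
            if self.requires_grad:
                self._accum(g.reshape(old))

        return Tensor._make(self.data.reshape(shape), (self,), backward)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)

        def backward(g):
            if self.requires_grad:
                self._accum(g.transpose(inv))

        return Tensor._make(self.data.transpose(axes), (self,), backward)

    def __getitem__(self, key):
        def backward(g):
            if self.requires_grad:
                gx = np.zeros_like(self.data)
                gx[key] = g
                self._accum(gx)

        return Tensor._make(self.data[key], (self,), backward)

    def __matmul__(self, other):
        other = Tensor._wrap(other)

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g @ np.swapaxes(other.data, -1, -2),
                                         self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(np.swapaxes(self.data, -1, -2) @ g,
                                          other.shape))

        return Tensor._make(self.data @ other.data, (self, other), backward)


def concat(tensors, axis: int = 0) -> Tensor:
    tensors = [Tensor._wrap(t) for t in tensors]
    sizes = [t.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            if t.requires_grad:
                t._accum(piece)

    return Tensor._make(
        np.concatenate([t.data for t in tensors], axis=axis), tensors, backward
    )


# ---------------------------------------------------------------------------
# convolution primitives
# ---------------------------------------------------------------------------


def _same_ceil_pads(shape, k: int, s: int):
    pads, outs = [], []
    for n in shape:
        out = -(-n // s)
        total = max((out - 1) * s + k - n, 0)
        pads.append((total // 2, total - total // 2))
        outs.append(out)
    return pads, outs


def conv3d(x: Tensor, w: Tensor, b: Tensor | None = None, stride: int = 1) -> Tensor:
    """3D convolution, ``x (B,Cin,D,H,W)``, ``w (Cout,Cin,k,k,k)``.

    Padding is "same-ceil": output spatial size is ``ceil(n / stride)``.
    Implemented as im2col + matmul; the backward input pass scatters the
    column gradient back with one strided slice-add per kernel offset.
    """
    B, Cin, D, H, W = x.shape
    Cout, Cin_w, k, _, _ = w.shape
    assert Cin == Cin_w, (Cin, Cin_w)
    s = stride
    pads, (Do, Ho, Wo) = _same_ceil_pads((D, H, W), k, s)
    xp = np.pad(x.data, [(0, 0), (0, 0), *pads])

    win = sliding_window_view(xp, (k, k, k), axis=(2, 3, 4))[:, :, ::s, ::s, ::s]
    # (B, Do, Ho, Wo, Cin, k, k, k) -> (B*L, Cin*k^3)
    col = np.ascontiguousarray(win.transpose(0, 2, 3, 4, 1, 5, 6, 7))
    col2 = col.reshape(B * Do * Ho * Wo, Cin * k**3)
    wmat = w.data.reshape(Cout, Cin * k**3)
    out = col2 @ wmat.T
    if b is not None:
        out += b.data
    out = out.reshape(B, Do, Ho, Wo, Cout).transpose(0, 4, 1, 2, 3)

    parents = (x, w) if b is None else (x, w, b)

    def backward(g):
        gmat = g.transpose(0, 2, 3, 4, 1).reshape(B * Do * Ho * Wo, Cout)
        if b is not None and b.requires_grad:
            b._accum(gmat.sum(axis=0))
        if w.requires_grad:
            w._accum((gmat.T @ col2).reshape(w.shape))
        if x.requires_grad:
            gcol = (gmat @ wmat).reshape(B, Do, Ho, Wo, Cin, k, k, k)
            gcol = gcol.transpose(0, 4, 1, 2, 3, 5, 6, 7)  # (B,Cin,Do,Ho,Wo,k,k,k)
            gxp = np.zeros_like(xp)
            for i in range(k):
                for j in range(k):
                    for l in range(k):
                        gxp[
                            :,
                            :,
                            i : i + s * Do : s,
                            j : j + s * Ho : s,
                            l : l + s * Wo : s,
                        ] += gcol[:, :, :, :, :, i, j, l]
            (p0, _), (p1, _), (p2, _) = pads
            x._accum(gxp[:, :, p0 : p0 + D, p1 : p1 + H, p2 : p2 + W])

    return Tensor._make(out, parents, backward)


def depthwise_conv3d(x: Tensor, w: Tensor, b: Tensor | None = None,
                     stride: int = 1) -> Tensor:
    """Depthwise 3D convolution, ``w (C, k, k, k)``, one filter per channel."""
    B, C, D, H, W = x.shape
    Cw, k, _, _ = w.shape
    assert C == Cw, (C, Cw)
    s = stride
    pads, (Do, Ho, Wo) = _same_ceil_pads((D, H, W), k, s)
    xp = np.pad(x.data, [(0, 0), (0, 0), *pads])
    win = sliding_window_view(xp, (k, k, k), axis=(2, 3, 4))[:, :, ::s, ::s, ::s]
    out = np.einsum("bcdhwijk,cijk->bcdhw", win, w.data, optimize=True)
    if b is not None:
        out += b.data[None, :, None, None, None]

    parents = (x, w) if b is None else (x, w, b)

    def backward(g):
        if b is not None and b.requires_grad:
            b._accum(g.sum(axis=(0, 2, 3, 4)))
        if w.requires_grad:
            w._accum(np.einsum("bcdhw,bcdhwijk->cijk", g, win, optimize=True))
        if x.requires_grad:
            gxp = np.zeros_like(xp)
            for i in range(k):
                for j in range(k):
                    for l in range(k):
                        gxp[
                            :,
                            :,
                            i : i + s * Do : s,
                            j : j + s * Ho : s,
                            l : l + s * Wo : s,
                        ] += g * w.data[None, :, i, j, l, None, None, None]
            (p0, _), (p1, _), (p2, _) = pads
            x._accum(gxp[:, :, p0 : p0 + D, p1 : p1 + H, p2 : p2 + W])

    return Tensor._make(out, parents, backward)


def resize_nearest(x: Tensor, out_spatial) -> Tensor:
    """Nearest-neighbor resize of ``(B,C,D,H,W)`` to ``out_spatial`` (upsampling).

    The adjoint pools gradient blocks with ``add.reduceat``; this requires
    the monotone index map of upsampling (out >= in per axis).
    """
    B, C = x.shape[:2]
    in_sp = x.shape[2:]
    out_sp = tuple(int(n) for n in out_spatial)
    assert all(o >= i for o, i in zip(out_sp, in_sp)), "resize_nearest upsamples only"
    idx = [
        np.minimum((np.floor((np.arange(o) + 0.5) * i / o)).astype(int), i - 1)
        for o, i in zip(out_sp, in_sp)
    ]
    out = x.data[:, :, idx[0]][:, :, :, idx[1]][:, :, :, :, idx[2]]

    def backward(g):
        if not x.requires_grad:
            return
        for ax, (o, i, ix) in enumerate(zip(out_sp, in_sp, idx)):
            starts = np.searchsorted(ix, np.arange(i), side="left")
            g = np.add.reduceat(g, starts, axis=2 + ax)
        x._accum(g)

    return Tensor._make(out, (x,), backward)


def grid_sample(feat: Tensor, coords: Tensor) -> Tensor:
    """Trilinear sampling of ``feat (C,D,H,W)`` at normalized ``coords (P,3)``.

    A coordinate ``c in [0,1]`` spans the volume extent along its axis; the
    center of cell ``i`` sits at ``(i + 0.5)/n``. Coordinates outside [0,1]
    are clamped to the border (border padding). Differentiable with respect
    to both the features and the coordinates (the coordinate gradient is
    zero in the clamped region, as for any clamp).
    """
    C = feat.shape[0]
    sp = np.asarray(feat.shape[1:], dtype=np.float32)  # (3,)
    P = coords.shape[0]

    cont = coords.data * sp - 0.5  # continuous cell coords
    inside = (cont >= 0.0) & (cont <= sp - 1.0)
    c = np.clip(cont, 0.0, sp - 1.0)
    i0 = np.minimum(np.floor(c).astype(int), np.maximum(sp - 2, 0).astype(int))
    i0 = np.maximum(i0, 0)
    i1 = np.minimum(i0 + 1, (sp - 1).astype(int))  # degenerate (size-1) axes
    frac = c - i0  # in [0,1]

    fdata = feat.data.reshape(C, -1)
    D, H, W = (int(v) for v in sp)
    corners = []  # (weight (P,), lin index (P,), dw/dfrac per axis)
    for dx in (0, 1):
        for dy in (0, 1):
            for dz in (0, 1):
                wx = frac[:, 0] if dx else 1.0 - frac[:, 0]
                wy = frac[:, 1] if dy else 1.0 - frac[:, 1]
                wz = frac[:, 2] if dz else 1.0 - frac[:, 2]
                weight = wx * wy * wz
                ix = i1[:, 0] if dx else i0[:, 0]
                iy = i1[:, 1] if dy else i0[:, 1]
                iz = i1[:, 2] if dz else i0[:, 2]
                lin = ix * H * W + iy * W + iz
                sx = (1.0 if dx else -1.0) * wy * wz
                sy = (1.0 if dy else -1.0) * wx * wz
                sz = (1.0 if dz else -1.0) * wx * wy
                corners.append((weight, lin, np.column_stack([sx, sy, sz])))

    vals = [fdata[:, lin].T for _, lin, _ in corners]  # each (P, C)
    out = np.zeros((P, C), dtype=np.float32)
    for (weight, _, _), v in zip(corners, vals):
        out += weight[:, None] * v

    def backward(g):  # g: (P, C)
        if feat.requires_grad:
            gf = np.zeros((np.prod(feat.shape[1:]).astype(int), C), dtype=np.float32)
            for weight, lin, _ in corners:
                np.add.at(gf, lin, weight[:, None] * g)
            feat._accum(gf.T.reshape(feat.shape))
        if coords.requires_grad:
            gc = np.zeros((P, 3), dtype=np.float32)
            for (_, _, dwd), v in zip(corners, vals):
                gv = (g * v).sum(axis=1)  # (P,)
                gc += dwd * gv[:, None]
            gc *= inside  # clamp region: no coordinate gradient
            gc *= sp[None, :]  # chain rule through cont = coords * sp - 0.5
            coords._accum(gc)

    return Tensor._make(out, (feat, coords), backward)
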