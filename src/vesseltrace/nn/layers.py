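"""Neural-network layers built on the autodiff engine.

Includes the building blocks of the hybrid architecture: MBConv encoder
blocks (inverted bottleneck with squeeze-excitation), the conv/norm/ReLU
decoder blocks, chain graph convolutions with symmetric normalization, and
residual graph-convolution (RGConv) refinement blocks for polylines.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, conv3d, depthwise_conv3d


def _param(arr) -> Tensor:
    """Trainable float32 parameter."""
    return Tensor(np.asarray(arr, dtype=np.float32), requires_grad=True)


__all__ = [
    "Module",
    "Linear",
    "Conv3d",
    "DepthwiseConv3d",
    "InstanceNorm3d",
    "BatchNorm3d",
    "LayerNorm",
    "SqueezeExcite",
    "MBConv",
    "ConvNormAct",
    "chain_adjacency",
    "GraphConv",
    "RGConvBlock",
]


class Module:
    """Minimal module container: tracks parameters through attributes."""

    training: bool = True

    def parameters(self):
        params, seen = [], set()

        def walk(obj):
            if isinstance(obj, Tensor):
                if obj.requires_grad and id(obj) not in seen:
                    seen.add(id(obj))
                    params.append(obj)
            elif isinstance(obj, Module):
                for v in vars(obj).values():
                    walk(v)
            elif isinstance(obj, (list, tuple)):
                for v in obj:
                    walk(v)

        walk(self)
        return params

    def modules(self):
        mods = [self]

        def walk(obj):
            if isinstance(obj, Module):
                mods.append(obj)
                for v in vars(obj).values():
                    walk(v)
            elif isinstance(obj, (list, tuple)):
                for v in obj:
                    walk(v)

        for v in vars(self).values():
            walk(v)
        return mods

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def train(self, mode: bool = True):
        for m in self.modules():
            m.training = mode
        return self

    def eval(self):
        return self.train(False)

    def state_dict(self) -> dict:
        return {f"p{i}": p.data for i, p in enumerate(self.parameters())}

    def load_state_dict(self, state: dict):
        params = self.parameters()
        if len(state) != len(params):
            raise ValueError(
                f"checkpoint has {len(state)} arrays, model has {len(params)}"
            )
        for i, p in enumerate(params):
            arr = np.asarray(state[f"p{i}"], dtype=np.float32)
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for parameter {i}")
            p.data = arr.copy()

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Linear(Module):
    def __init__(self, cin: int, cout: int, rng: np.random.Generator,
                 zero_init: bool = False):
        scale = 0.0 if zero_init else np.sqrt(2.0 / cin)
        self.w = _param(rng.normal(0, 1, (cin, cout)) * scale)
        self.b = _param(np.zeros(cout))

    def forward(self, x: Tensor) -> Tensor:
        return x @ self.w + self.b


class Conv3d(Module):
    def __init__(self, cin: int, cout: int, k: int, rng: np.random.Generator,
                 stride: int = 1, zero_init: bool = False):
        scale = 0.0 if zero_init else np.sqrt(2.0 / (cin * k**3))
        self.w = _param(rng.normal(0, 1, (cout, cin, k, k, k)) * scale)
        self.b = _param(np.zeros(cout))
        self.stride = stride

    def forward(self, x: Tensor) -> Tensor:
        return conv3d(x, self.w, self.b, stride=self.stride)


class DepthwiseConv3d(Module):
    def __init__(self, c: int, k: int, rng: np.random.Generator, stride: int = 1):
        scale = np.sqrt(2.0 / k**3)
        self.w = _param(rng.normal(0, 1, (c, k, k, k)) * scale)
        self.b = _param(np.zeros(c))
        self.stride = stride

    def forward(self, x: Tensor) -> Tensor:
        return depthwise_conv3d(x, self.w, self.b, stride=self.stride)


class InstanceNorm3d(Module):
    """Per-sample, per-channel normalization over the spatial axes."""

    def __init__(self, c: int, eps: float = 1e-5):
        self.gamma = _param(np.ones((1, c, 1, 1, 1)))
        self.beta = _param(np.zeros((1, c, 1, 1, 1)))
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=(2, 3, 4), keepdims=True)
        xc = x - mu
        var = xc.square().mean(axis=(2, 3, 4), keepdims=True)
        return xc / (var + self.eps).sqrt() * self.gamma + self.beta


class BatchNorm3d(Module):
    """Batch normalization over (batch, spatial); tracks running statistics."""

    def __init__(self, c: int, eps: float = 1e-5, momentum: float = 0.1):
        self.gamma = _param(np.ones((1, c, 1, 1, 1)))
        self.beta = _param(np.zeros((1, c, 1, 1, 1)))
        self.eps = eps
        self.momentum = momentum
        self.running_mean = np.zeros((1, c, 1, 1, 1), dtype=np.float32)
        self.running_var = np.ones((1, c, 1, 1, 1), dtype=np.float32)

    def forward(self, x: Tensor) -> Tensor:
        if self.training:
            mu = x.mean(axis=(0, 2, 3, 4), keepdims=True)
            xc = x - mu
            var = xc.square().mean(axis=(0, 2, 3, 4), keepdims=True)
            m = self.momentum
            self.running_mean = (1 - m) * self.running_mean + m * mu.data
            self.running_var = (1 - m) * self.running_var + m * var.data
            return xc / (var + self.eps).sqrt() * self.gamma + self.beta
        xc = x - Tensor(self.running_mean)
        return (
            xc / Tensor(np.sqrt(self.running_var + self.eps)) * self.gamma + self.beta
        )


def make_norm(kind: str, c: int) -> Module:
    if kind == "instance":
        return InstanceNorm3d(c)
    if kind == "batch":
        return BatchNorm3d(c)
    raise ValueError(f"unknown norm kind {kind!r}")


class LayerNorm(Module):
    """Normalization over the last (feature) axis of (P, C) point features."""

    def __init__(self, c: int, eps: float = 1e-5):
        self.gamma = _param(np.ones(c))
        self.beta = _param(np.zeros(c))
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = xc.square().mean(axis=-1, keepdims=True)
        return xc / (var + self.eps).sqrt() * self.gamma + self.beta


class SqueezeExcite(Module):
    """Global-context channel gating (squeeze-and-excitation)."""

    def __init__(self, c: int, rng: np.random.Generator, reduction: int = 4):
        hidden = max(c // reduction, 2)
        self.fc1 = Linear(c, hidden, rng)
        self.fc2 = Linear(hidden, c, rng)

    def forward(self, x: Tensor) -> Tensor:
        B, C = x.shape[:2]
        pooled = x.mean(axis=(2, 3, 4))  # (B, C)
        gate = self.fc2(self.fc1(pooled).silu()).sigmoid()  # (B, C)
        return x * gate.reshape(B, C, 1, 1, 1)


class MBConv(Module):
    """Mobile inverted bottleneck: expand -> depthwise -> SE -> project.

    Residual connection when stride is 1 and channel counts match.
    """

    def __init__(self, cin: int, cout: int, rng: np.random.Generator,
                 stride: int = 1, expand: int = 2, norm: str = "instance"):
        ce = cin * expand
        self.expand = Conv3d(cin, ce, 1, rng)
        self.norm1 = make_norm(norm, ce)
        self.dw = DepthwiseConv3d(ce, 3, rng, stride=stride)
        self.norm2 = make_norm(norm, ce)
        self.se = SqueezeExcite(ce, rng)
        self.project = Conv3d(ce, cout, 1, rng)
        self.norm3 = make_norm(norm, cout)
        self.residual = stride == 1 and cin == cout

    def forward(self, x: Tensor) -> Tensor:
        y = self.norm1(self.expand(x)).silu()
        y = self.norm2(self.dw(y)).silu()
        y = self.se(y)
        y = self.norm3(self.project(y))
        return x + y if self.residual else y


class ConvNormAct(Module):
    """conv3 -> norm -> activation, the voxel-decoder unit block."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator,
                 stride: int = 1, norm: str = "instance", act: str = "relu"):
        self.conv = Conv3d(cin, cout, 3, rng, stride=stride)
        self.norm = make_norm(norm, cout)
        self.act = act

    def forward(self, x: Tensor) -> Tensor:
        y = self.norm(self.conv(x))
        return y.relu() if self.act == "relu" else y.silu()


# ---------------------------------------------------------------------------
# graph layers on the polyline chain
# ---------------------------------------------------------------------------


def chain_adjacency(n: int) -> np.ndarray:
    """Symmetric-normalized chain operator D^{-1/2} (A + I) D^{-1/2}.

    A is the path graph on n ordered points (i ~ i±1); self-loops included.
    """
    a = np.zeros((n, n), dtype=np.float32)
    idx = np.arange(n - 1)
    a[idx, idx + 1] = 1.0
    a[idx + 1, idx] = 1.0
    a += np.eye(n, dtype=np.float32)
    d = a.sum(axis=1)
    dinv = 1.0 / np.sqrt(d)
    return a * dinv[:, None] * dinv[None, :]


class GraphConv(Module):
    """x -> Ahat @ (x W) + b on (P, C) point features."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator,
                 zero_init: bool = False):
        self.lin = Linear(cin, cout, rng, zero_init=zero_init)

    def forward(self, x: Tensor, ahat: np.ndarray) -> Tensor:
        return Tensor(ahat) @ self.lin(x)


class RGConvBlock(Module):
    """Residual graph-conv block: x + [GraphConv -> SiLU -> LayerNorm] x 2."""

    def __init__(self, c: int, rng: np.random.Generator):
        self.gc1 = GraphConv(c, c, rng)
        self.ln1 = LayerNorm(c)
        self.gc2 = GraphConv(c, c, rng)
        self.ln2 = LayerNorm(c)

    def forward(self, x: Tensor, ahat: np.ndarray) -> Tensor:
        y = self.ln1(self.gc1(x, ahat).silu())
        y = self.ln2(self.gc2(y, ahat).silu())
        return x + y
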