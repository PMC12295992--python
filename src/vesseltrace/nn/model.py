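"""The hybrid multitask network: one forward pass yields a vessel
probability mask and a connected centerline polyline with real-valued
coordinates.

Architecture
------------
* **Encoder** — a stem convolution (stride 2) followed by MBConv stages;
  five feature maps at downsampling factors 2, 4, 8, 16, 32 (ceil
  division at every step).
* **Voxel decoder** — U-Net style: nearest-neighbor upsample to the skip's
  exact shape, concatenate the encoder skip, then conv/norm/ReLU blocks;
  a final upsample to full resolution and a 1x1x1 head give per-voxel
  lumen probabilities.
* **Centerline decoder** — five stages, coarse to fine. A stage samples
  point features from its pyramid level at the current candidate
  coordinates (trilinear ``grid_sample``), predicts a bounded neighborhood
  of ``k`` auxiliary sampling locations per point, fuses point + neighbor
  features (+ the coordinates themselves) with a pointwise linear map,
  refines with residual graph-conv blocks on the fixed polyline chain, and
  emits coordinate offsets through a zero-initialized graph-conv head. The
  chain connectivity is fixed once at construction: the output is always a
  single connected polyline, so no post-processing exists anywhere.

All coordinates inside the decoder are normalized to [0,1]^3 over the
volume extent; conversion to world mm happens only at the API boundary
(:meth:`VesselCenterlineNet.predict`).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from ..core import Centerline, ImageVolume, ProbabilityMask
from ..preprocess import WindowSpec, apply_window, normalized_to_world
from .autodiff import Tensor, concat, grid_sample, resize_nearest
from .layers import (
    ConvNormAct,
    Conv3d,
    GraphConv,
    Linear,
    MBConv,
    Module,
    RGConvBlock,
    chain_adjacency,
)

__all__ = ["NetworkConfig", "VesselCenterlineNet", "init_polyline",
           "tiny_config", "paper_config"]

N_STAGES = 5


@dataclass
class NetworkConfig:
    """Hyperparameters of the hybrid network.

    ``stage_channels`` are the encoder widths of the five stages;
    ``num_points`` the (fixed) length of the predicted polyline;
    ``neighbors_k`` how many auxiliary sampling locations each point
    predicts; offsets to them are tanh-bounded by one cell of the stage's
    feature grid.
    """

    stage_channels: tuple = (8, 16, 24, 32, 48)
    num_points: int = 96
    neighbors_k: int = 4
    rgconv_blocks_per_stage: int = 2
    cl_channels: int | None = 48  # constant centerline-decoder width;
    # None mirrors the per-stage encoder widths instead
    encoder_blocks_per_stage: int = 1
    expand_ratio: int = 2
    norm: str = "instance"
    include_coords: bool = True
    seed: int = 0

    def __post_init__(self):
        if len(self.stage_channels) != N_STAGES:
            raise ValueError("stage_channels must have 5 entries")
        if min(self.stage_channels) < 1:
            raise ValueError("channels must be strictly positive")
        if self.num_points < 2:
            raise ValueError("num_points must be >= 2")
        if self.neighbors_k < 1:
            raise ValueError("neighbors_k must be >= 1")


def tiny_config(**kw) -> NetworkConfig:
    """CPU-scale preset used throughout the test suite (48^3 volumes)."""
    kw.setdefault("num_points", 32)
    return NetworkConfig(**kw)


def paper_config(**kw) -> NetworkConfig:
    """Study-scale preset: EfficientNetV2-b0-like widths, 96 points."""
    kw.setdefault("stage_channels", (16, 32, 48, 96, 192))
    kw.setdefault("num_points", 96)
    return NetworkConfig(**kw)


def init_polyline(seed: int, num_points: int) -> np.ndarray:
    """Random straight-segment initialization in normalized coordinates.

    Two endpoints uniform in [0.2, 0.8]^3, ``num_points`` equally spaced
    between them. Reproducible by seed.
    """
    if num_points < 2:
        raise ValueError("num_points must be >= 2")
    rng = np.random.default_rng(seed)
    a, b = rng.uniform(0.2, 0.8, size=(2, 3))
    t = np.linspace(0.0, 1.0, num_points)[:, None]
    return (a[None, :] * (1 - t) + b[None, :] * t).astype(np.float32)


class _CenterlineStage(Module):
    def __init__(self, c_map: int, c_out: int, cfg: NetworkConfig,
                 rng: np.random.Generator):
        k = cfg.neighbors_k
        self.k = k
        self.nbr_head = Linear(c_map, k * 3, rng)
        fuse_in = c_map * (1 + k) + (4 if cfg.include_coords else 0)
        self.fuse = Linear(fuse_in, c_out, rng)
        self.blocks = [RGConvBlock(c_out, rng)
                       for _ in range(cfg.rgconv_blocks_per_stage)]
        self.coord_head = GraphConv(c_out, 3, rng, zero_init=True)
        self.include_coords = cfg.include_coords

    def forward(self, fmap: Tensor, coords: Tensor, ahat: np.ndarray) -> Tensor:
        P = coords.shape[0]
        pts_f = grid_sample(fmap, coords)  # (P, C)
        # bounded neighborhood: offsets at most one stage-cell per axis
        bound = 1.0 / np.asarray(fmap.shape[1:], dtype=np.float32)
        off = self.nbr_head(pts_f).tanh().reshape(P, self.k, 3) * bound[None, None, :]
        nbrs_c = (coords.reshape(P, 1, 3) + off).reshape(P * self.k, 3)
        nbrs_f = grid_sample(fmap, nbrs_c).reshape(P, -1)
        pieces = [pts_f, nbrs_f]
        if self.include_coords:
            # positional conditioning: the candidate coordinates plus the
            # point's normalized chain parameter. Sampled conv features are
            # translation-equivariant and identical for co-located points;
            # without an explicit position/identity input the shared head
            # moves clustered points identically and the polyline collapses
            # instead of spreading along the vessel.
            chain_t = Tensor(np.linspace(0.0, 1.0, P, dtype=np.float32)[:, None])
            pieces += [coords, chain_t]
        x = self.fuse(concat(pieces, axis=1))
        for blk in self.blocks:
            x = blk(x, ahat)
        delta = self.coord_head(x, ahat)
        return (coords + delta).clip(0.0, 1.0)


class VesselCenterlineNet(Module):
    """Encoder + voxel decoder + centerline decoder; one pass, two outputs."""

    def __init__(self, config: NetworkConfig | None = None):
        cfg = config or NetworkConfig()
        self.config = cfg
        rng = np.random.default_rng(cfg.seed)
        ch = cfg.stage_channels
        nm, ex = cfg.norm, cfg.expand_ratio

        # encoder: stem (stride 2) + MBConv stages (first block of a stage
        # carries the stride/width change, the rest are residual)
        self.stem = ConvNormAct(1, ch[0], rng, stride=2, norm=nm, act="silu")
        nb = cfg.encoder_blocks_per_stage
        self.enc = []
        for s in range(N_STAGES):
            cin = ch[0] if s == 0 else ch[s - 1]
            stride = 1 if s == 0 else 2
            blocks = [MBConv(cin, ch[s], rng, stride=stride, expand=ex, norm=nm)]
            blocks += [
                MBConv(ch[s], ch[s], rng, stride=1, expand=ex, norm=nm)
                for _ in range(nb - 1)
            ]
            self.enc.append(blocks)

        # voxel decoder: 4 up-blocks along the pyramid + full-res head
        self.dec = []
        for lvl in range(N_STAGES - 2, -1, -1):  # 3,2,1,0
            cin = ch[lvl + 1] + ch[lvl]
            self.dec.append(
                [ConvNormAct(cin, ch[lvl], rng, norm=nm),
                 ConvNormAct(ch[lvl], ch[lvl], rng, norm=nm)]
            )
        self.head_conv = ConvNormAct(ch[0], ch[0], rng, norm=nm)
        self.head = Conv3d(ch[0], 1, 1, rng)

        # centerline decoder: coarse -> fine over [enc5, d16, d8, d4, d2]
        map_ch = [ch[4], ch[3], ch[2], ch[1], ch[0]]
        if cfg.cl_channels is None:
            out_ch = [ch[4], ch[3], ch[2], ch[1], ch[0]]
        else:
            # the graph layers are cheap compared with the 3D convolutions;
            # a constant width avoids starving the fine stages (8 channels
            # is too thin to encode the refinement geometry precisely)
            out_ch = [cfg.cl_channels] * N_STAGES
        self.cl_stages = [
            _CenterlineStage(map_ch[s], out_ch[s], cfg, rng)
            for s in range(N_STAGES)
        ]
        self._ahat = chain_adjacency(cfg.num_points)
        # the starting polyline is drawn once, when the model is initialized,
        # and kept fixed for training and inference (a seeded buffer — the
        # decoder refines the same canonical chain for every input volume)
        self.init_coords = init_polyline(cfg.seed, cfg.num_points)

    # -- pieces ------------------------------------------------------------

    def encoder_forward(self, x: Tensor) -> list:
        """Five encoder maps at downsampling 2^1 .. 2^5."""
        if min(x.shape[2:]) < 2**N_STAGES:
            raise ValueError(
                f"input spatial dims {x.shape[2:]} smaller than {2**N_STAGES}"
            )
        feats = []
        y = self.stem(x)
        for stage_blocks in self.enc:
            for blk in stage_blocks:
                y = blk(y)
            feats.append(y)
        return feats

    def voxel_decoder_forward(self, feats: list, out_spatial) -> tuple:
        """Returns (probability volume (B,1,*out_spatial), sampling pyramid)."""
        pyramid = [feats[-1]]  # coarsest encoder map heads the pyramid
        y = feats[-1]
        for i, lvl in enumerate(range(N_STAGES - 2, -1, -1)):
            y = resize_nearest(y, feats[lvl].shape[2:])
            y = concat([y, feats[lvl]], axis=1)
            for blk in self.dec[i]:
                y = blk(y)
            pyramid.append(y)
        y = resize_nearest(y, out_spatial)
        prob = self.head(self.head_conv(y)).sigmoid()
        return prob, pyramid

    def centerline_decoder_forward(self, pyramid: list, init_coords) -> list:
        """Five refinement stages; returns the per-stage polylines (Tensors).

        ``pyramid`` entries must be single-sample maps (C, D, H, W); stage s
        samples pyramid level s (coarse to fine).
        """
        coords = init_coords if isinstance(init_coords, Tensor) else Tensor(init_coords)
        if coords.shape != (self.config.num_points, 3):
            raise ValueError(
                f"init polyline must be ({self.config.num_points}, 3), got {coords.shape}"
            )
        out = []
        for stage, fmap in zip(self.cl_stages, pyramid):
            coords = stage(fmap, coords, self._ahat)
            out.append(coords)
        return out

    # -- full pass ---------------------------------------------------------

    def forward(self, vol: Tensor | np.ndarray, init_coords=None):
        """One pass over a batch (B,1,D,H,W) of windowed volumes.

        Returns ``(mask_prob, stage_polylines)`` where ``stage_polylines``
        is a list over the batch of lists over the five stages. By default
        every sample starts from the model's fixed initial polyline;
        ``init_coords`` (one (P,3) array per sample) overrides it.
        """
        x = vol if isinstance(vol, Tensor) else Tensor(vol)
        if x.ndim == 3:
            x = x.reshape(1, 1, *x.shape)
        B = x.shape[0]
        feats = self.encoder_forward(x)
        prob, pyramid = self.voxel_decoder_forward(feats, x.shape[2:])
        if init_coords is None:
            init_coords = [self.init_coords] * B
        polylines = []
        for b in range(B):
            sample_pyr = [m[b] for m in pyramid]
            polylines.append(
                self.centerline_decoder_forward(sample_pyr, init_coords[b])
            )
        return prob, polylines

    def predict(self, vol: ImageVolume, window: WindowSpec = WindowSpec(),
                seed: int = 0) -> tuple:
        """Inference API: HU volume in, (ProbabilityMask, Centerline mm) out.

        The returned polyline is the final-stage output converted to world
        millimetres — emitted as-is, with no post-processing. ``seed`` is
        accepted for interface stability but inference is deterministic:
        the initial polyline is the model's fixed buffer.
        """
        self.eval()
        normed = apply_window(vol, window)
        prob, polylines = self.forward(normed.values[None, None])
        mask = ProbabilityMask(prob.data[0], vol.spacing_mm, vol.origin_mm)
        pts_mm = normalized_to_world(polylines[0][-1].data, vol)
        self.train()
        return mask, Centerline(pts_mm)


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------


def save_checkpoint(path, model: VesselCenterlineNet,
                    window: WindowSpec = WindowSpec(), extra: dict | None = None):
    import json

    meta = dict(config=asdict(model.config),
                window=dict(level_hu=window.level_hu, width_hu=window.width_hu),
                extra=extra or {})
    arrays = model.state_dict()
    np.savez_compressed(path, __meta__=json.dumps(meta), **arrays)


def load_checkpoint(path) -> tuple:
    import json

    with np.load(path, allow_pickle=False) as z:
        meta = json.loads(str(z["__meta__"]))
        cfg = NetworkConfig(**{**meta["config"],
                               "stage_channels": tuple(meta["config"]["stage_channels"])})
        model = VesselCenterlineNet(cfg)
        model.load_state_dict({k: z[k] for k in z.files if k != "__meta__"})
    window = WindowSpec(**meta["window"])
    return model, window, meta.get("extra", {})
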