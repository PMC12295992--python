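"""The composite training loss.

Five ingredients supervise the two heads jointly:

* **voxel loss** — focal + Dice on the predicted probability volume:
  ``L_vox = -sum_i sum_k Mt (1 - Mp) log Mp  -  (2/|K|) sum_k  sum_i Mt Mp / sum_i (Mt + Mp)``
  (natural log, probabilities clamped at 1e-7; perfect prediction tends
  to -1, the Dice term's minimum);
* **Chamfer distance** — symmetric sum of nearest-point distances between
  the predicted and ground-truth point sets (unsquared Euclidean norm by
  default, ``squared=True`` available);
* **edge-length regularizer** — sum of squared consecutive-edge lengths;
  for fixed endpoints it is minimized by the uniform point placement;
* **point-in-lumen regularizer** — the voxel loss evaluated on the mask
  probabilities trilinearly sampled at the predicted points, against an
  all-ones target; a stop-gradient keeps it from training the voxel head,
  while the coordinates still receive gradient through the interpolation
  weights;
* **EMA normalization** — the voxel and lumen terms enter the total through
  their exponential moving average ``L_bar = alpha L_bar + (1-alpha) L``
  (alpha = 0.9); only the current-step loss carries gradient, scaled by
  ``1 - alpha``.

Total: ``L = L_vox_bar + L_cd + L_elr + L_plr_bar``. The Chamfer term is
applied to every centerline-decoder stage output (deep supervision) unless
disabled. Losses live in normalized [0,1] coordinates; evaluation metrics
are in mm.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .nn.autodiff import Tensor, concat, grid_sample

__all__ = [
    "EMAState",
    "LossBreakdown",
    "voxel_loss",
    "chamfer_loss",
    "edge_length_reg",
    "point_lumen_reg",
    "ema_update",
    "total_loss",
]

PROB_EPS = 1e-7


def _wrap(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


@dataclass
class EMAState:
    """Running exponentially averaged loss for one head.

    With ``warm_start`` the running value is seeded with the first observed
    loss instead of 0, so the tracked term is on the raw loss's scale from
    step one (this changes only the logged/applied value, never the
    gradient, which is always ``(1-alpha)`` times the current loss's).
    """

    alpha: float = 0.9
    running: float = 0.0
    step: int = 0
    warm_start: bool = False

    def __post_init__(self):
        if not 0.0 <= self.alpha < 1.0:
            raise ValueError("alpha must be in [0, 1)")


@dataclass
class LossBreakdown:
    """Loss components as applied in the total (vox/plr are the EMA terms).

    ``raw_vox`` / ``raw_plr`` carry the current-step values before
    exponential averaging, for logging.
    """

    l_vox: float
    l_cd: float
    l_elr: float
    l_plr: float
    l_total: float
    raw_vox: float = 0.0
    raw_plr: float = 0.0
    total: Tensor | None = field(default=None, repr=False)


def voxel_loss(mp, mt, class_axis: int | None = None) -> Tensor:
    """Focal + Dice voxel loss, summed over classes.

    ``mp`` are predicted probabilities in (0,1) (clamped at 1e-7), ``mt``
    the binary ground truth on the same grid. With ``class_axis=None`` the
    whole array is one class (K=1); otherwise the Dice term averages over
    the classes indexed by that axis (2/|K| times the per-class ratio sum)
    while the focal term is a plain elementwise sum either way.

    For single-channel vessel masks the training loop calls this with the
    explicit background complement stacked as a second class: with K=1 the
    focal term vanishes on background voxels and nothing suppresses false
    positives, so the class set must include the background for the
    segmentation to be trainable.
    """
    mp = _wrap(mp)
    mt_data = mt.data if isinstance(mt, Tensor) else np.asarray(mt, dtype=np.float32)
    if mp.shape != mt_data.shape:
        raise ValueError(f"grid mismatch: {mp.shape} vs {mt_data.shape}")
    mt_t = Tensor(mt_data)
    mpc = mp.clip(PROB_EPS, 1.0 - PROB_EPS)
    focal = -(mt_t * (1.0 - mpc) * mpc.log()).sum()
    if class_axis is None:
        dice = 2.0 * (mt_t * mpc).sum() / (mt_t + mpc).sum()
        return focal - dice
    k = mp.shape[class_axis]
    axes = tuple(a for a in range(mp.ndim) if a != class_axis)
    ratios = (mt_t * mpc).sum(axis=axes) / (mt_t + mpc).sum(axis=axes)
    return focal - (2.0 / k) * ratios.sum()


def chamfer_loss(cp, ct, squared: bool = False) -> Tensor:
    """Symmetric Chamfer distance between two point sets (N,3) and (M,3)."""
    cp = _wrap(cp)
    ct = _wrap(ct)
    if cp.shape[0] == 0 or ct.shape[0] == 0:
        raise ValueError("chamfer_loss needs nonempty point sets")
    diff = cp.reshape(cp.shape[0], 1, 3) - ct.reshape(1, ct.shape[0], 3)
    sq = diff.square().sum(axis=2)
    # exact sqrt: the autodiff sqrt backward floors its denominator, which
    # bounds the (sub)gradient at coinciding points by the unit vector
    d = sq if squared else sq.sqrt()
    return d.min(axis=1).sum() + d.min(axis=0).sum()


def edge_length_reg(cp, mode: str = "sum_squared") -> Tensor:
    """Uniform-edge regularizer on a polyline (N,3).

    ``sum_squared`` (default): sum over consecutive edges of the squared
    edge length. ``variance_of_edges``: variance of edge lengths — an
    alternative reading that directly penalizes non-uniformity.
    """
    cp = _wrap(cp)
    n = cp.shape[0]
    if n < 2:
        raise ValueError("need at least 2 points")
    edges = cp[1:] - cp[: n - 1]
    sq = edges.square().sum(axis=1)
    if mode == "sum_squared":
        return sq.sum()
    if mode == "variance_of_edges":
        lengths = (sq + 1e-12).sqrt()
        return (lengths - lengths.mean()).square().mean()
    raise ValueError(f"unknown mode {mode!r}")


def point_lumen_reg(cp, mp_vol, skip_ends: int = 0) -> Tensor:
    """Penalty for predicted points outside the predicted lumen.

    Samples the mask probability volume ``mp_vol`` ((1,D,H,W) Tensor, or
    (D,H,W)) at the normalized point coordinates ``cp`` with trilinear
    interpolation and evaluates the voxel loss against an all-ones target
    over the sampled set. The sampled probabilities are detached
    (stop-gradient: nothing flows back into the voxel head), but the point
    coordinates do receive gradient through the interpolation weights.

    ``skip_ends`` optionally excludes that many points at each end of the
    chain (an endpoint on the vessel's end face samples ~0.5 by
    construction even when perfectly placed).
    """
    cp = _wrap(cp)
    mp_vol = _wrap(mp_vol)
    if mp_vol.ndim == 3:
        mp_vol = mp_vol.reshape(1, *mp_vol.shape)
    if skip_ends > 0 and cp.shape[0] > 2 * skip_ends:
        cp = cp[skip_ends : cp.shape[0] - skip_ends]
    probs = grid_sample(mp_vol.detach(), cp)  # (P, 1); stop-grad on the mask
    n = probs.shape[0]
    p = probs.clip(PROB_EPS, 1.0 - PROB_EPS)
    focal = -((1.0 - p) * p.log()).sum()
    dice = 2.0 * p.sum() / (float(n) + p.sum())
    return focal - dice


def matched_polyline_loss(cp, ct) -> Tensor:
    """Order-aware polyline regression loss for intermediate supervision.

    The target polyline is resampled to the predicted point count by
    arclength-uniform index selection, and the mean point-to-point
    Euclidean distance is taken under the better of the two chain
    directions (the tube has no intrinsic orientation). Unlike the Chamfer
    distance this assigns every predicted point a unique target, which
    conditions the early decoder stages much better; the final stage is
    still trained with the order-free Chamfer distance.
    """
    cp = _wrap(cp)
    ct_data = ct.data if isinstance(ct, Tensor) else np.asarray(ct, dtype=np.float32)
    if cp.shape[0] < 2 or ct_data.shape[0] < 2:
        raise ValueError("matched_polyline_loss needs polylines of >= 2 points")
    p = cp.shape[0]
    idx = np.linspace(0, ct_data.shape[0] - 1, p).round().astype(int)
    tgt_fwd = ct_data[idx]
    tgt_rev = tgt_fwd[::-1].copy()
    d_fwd = (cp - Tensor(tgt_fwd)).square().sum(axis=1).sqrt().sum()
    d_rev = (cp - Tensor(tgt_rev)).square().sum(axis=1).sqrt().sum()
    return d_fwd if d_fwd.item() <= d_rev.item() else d_rev


def ema_update(state: EMAState, value):
    """Advance the EMA and return the training term.

    For a plain float this returns the new running value. For a Tensor it
    returns ``alpha * running_prev + (1 - alpha) * value`` in which only the
    current-step loss carries gradient — the literal reading of the update
    rule used as the applied loss term.
    """
    a = state.alpha
    val = value.item() if isinstance(value, Tensor) else float(value)
    if not np.isfinite(val):
        raise FloatingPointError(f"non-finite loss value {val}")
    if state.warm_start and state.step == 0:
        state.running = val
    prev = state.running
    state.running = a * prev + (1.0 - a) * val
    state.step += 1
    if isinstance(value, Tensor):
        return a * prev + (1.0 - a) * value
    return state.running


def total_loss(
    mp,
    mt,
    stage_polylines,
    ct_list,
    ema_vox: EMAState,
    ema_plr: EMAState,
    deep_supervision: bool = True,
    stage_supervision: str = "matched",
    centerline_weight: float = 1.0,
    squared_chamfer: bool = False,
    elr_mode: str = "sum_squared",
    normalize_by_ema: bool = False,
) -> LossBreakdown:
    """Compose the full training loss for one batch.

    ``mp``: (B,1,D,H,W) predicted probabilities; ``mt``: matching binary
    target; ``stage_polylines``: per-sample lists of per-stage (P,3)
    normalized polylines; ``ct_list``: per-sample (M,3) normalized ground
    truth points. Per-sample terms are averaged over the batch so the loss
    scale is batch-size independent.

    The final stage always carries the Chamfer term; with deep supervision
    the intermediate stages carry either additional Chamfer terms
    (``stage_supervision="chamfer"``) or the order-aware matched polyline
    loss (``"matched"``, default — see :func:`matched_polyline_loss`).
    """
    mp = _wrap(mp)
    B = mp.shape[0]
    mt_arr = np.asarray(mt, dtype=np.float32)
    # vessel channel + explicit background complement as a second class
    mp2 = concat([mp, 1.0 - mp], axis=1)
    mt2 = np.concatenate([mt_arr, 1.0 - mt_arr], axis=1)
    l_vox = voxel_loss(mp2, mt2, class_axis=1) * (1.0 / B)

    l_cd, l_elr, l_plr = Tensor(0.0), Tensor(0.0), Tensor(0.0)
    for b in range(B):
        stages = stage_polylines[b]
        l_cd = l_cd + chamfer_loss(stages[-1], ct_list[b], squared=squared_chamfer)
        if deep_supervision:
            if stage_supervision == "matched":
                for s in stages[:-1]:
                    l_cd = l_cd + matched_polyline_loss(s, ct_list[b])
            elif stage_supervision == "chamfer":
                for s in stages[:-1]:
                    l_cd = l_cd + chamfer_loss(s, ct_list[b], squared=squared_chamfer)
            else:
                raise ValueError(f"unknown stage_supervision {stage_supervision!r}")
        l_elr = l_elr + edge_length_reg(stages[-1], mode=elr_mode)
        l_plr = l_plr + point_lumen_reg(stages[-1], mp[b])
    l_cd = l_cd * (centerline_weight / B)
    l_elr = l_elr * (1.0 / B)
    l_plr = l_plr * (1.0 / B)

    if normalize_by_ema:
        # alternative mode: raw loss divided by its detached running average
        ema_update(ema_vox, l_vox.item())
        ema_update(ema_plr, l_plr.item())
        vox_term = l_vox * (1.0 / max(abs(ema_vox.running), 1e-8))
        plr_term = l_plr * (1.0 / max(abs(ema_plr.running), 1e-8))
    else:
        vox_term = ema_update(ema_vox, l_vox)
        plr_term = ema_update(ema_plr, l_plr)

    total = vox_term + l_cd + l_elr + plr_term
    return LossBreakdown(
        l_vox=vox_term.item(),
        l_cd=l_cd.item(),
        l_elr=l_elr.item(),
        l_plr=plr_term.item(),
        l_total=total.item(),
        raw_vox=l_vox.item(),
        raw_plr=l_plr.item(),
        total=total,
    )
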