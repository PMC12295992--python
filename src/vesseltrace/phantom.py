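"""Synthetic CTA-like phantoms of unbranched tubular vessels.

Each phantom is a triplet (HU volume, binary lumen mask, analytic
centerline) on a regular grid — by default 2 mm isotropic with sparse
ground-truth annotation points every ~6 mm of arclength, emulating the
structure of aortic CTA data with radiologist-placed centerline points.

Curve families
--------------
``straight``
    a line segment with arbitrary orientation;
``arc``
    a circular arc (radius 40–80 mm by default);
``aorta_like``
    a half-circular arch joined C1-smoothly to two straight descending
    limbs — the classic candy-cane silhouette of the thoracic aorta.

The tube is the set of voxels whose centers lie within ``radius_mm`` of the
curve; HU values are two-level (lumen vs. background) with an optional
Gaussian partial-volume blur at the wall.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree

from .core import Centerline, ImageVolume, ProbabilityMask
from . import io as vio

__all__ = [
    "PhantomSpec",
    "generate_curve",
    "rasterize_tube",
    "render_volume",
    "make_dataset",
    "default_spec_distribution",
]

CURVE_KINDS = ("straight", "arc", "aorta_like")


@dataclass
class PhantomSpec:
    """Parameters of one synthetic tubular phantom."""

    curve_kind: str = "aorta_like"
    radius_mm: float = 10.0
    grid_shape: tuple = (48, 48, 48)
    spacing_mm: tuple = (2.0, 2.0, 2.0)
    lumen_hu: float = 300.0
    background_hu: float = 0.0
    edge_softness_mm: float = 1.0
    gt_point_spacing_mm: float = 6.0
    seed: int = 0
    # optional explicit curve parameters (otherwise randomized from `seed`):
    # straight: length_mm, direction; arc: arc_radius_mm, arc_angle_rad;
    # aorta_like: arch_radius_mm, limb_lengths_mm
    curve_params: dict = field(default_factory=dict)

    def validate(self) -> None:
        if self.curve_kind not in CURVE_KINDS:
            raise ValueError(f"unknown curve_kind {self.curve_kind!r}")
        if self.radius_mm <= 0 or self.gt_point_spacing_mm <= 0:
            raise ValueError("radius_mm and gt_point_spacing_mm must be positive")
        if self.edge_softness_mm < 0:
            raise ValueError("edge_softness_mm must be nonnegative")
        spacing = np.asarray(self.spacing_mm, dtype=float)
        if np.any(spacing <= 0) or len(self.grid_shape) != 3:
            raise ValueError("need 3 positive spacings and a 3D grid shape")
        if self.radius_mm < 2.0 * spacing.max():
            raise ValueError(
                f"radius_mm={self.radius_mm} not resolvable: must be >= 2 x "
                f"max spacing ({2 * spacing.max()} mm)"
            )

    @property
    def extent_mm(self) -> np.ndarray:
        return np.asarray(self.grid_shape) * np.asarray(self.spacing_mm, dtype=float)

    @property
    def margin_mm(self) -> float:
        """Clearance the tube surface must keep from the volume boundary."""
        return self.radius_mm + 2.0 * float(np.max(self.spacing_mm))


# ---------------------------------------------------------------------------
# analytic curves
# ---------------------------------------------------------------------------


def _resample_by_arclength(dense: np.ndarray, step: float) -> np.ndarray:
    """Sample a dense polyline at uniform arclength intervals <= step."""
    seglen = np.linalg.norm(np.diff(dense, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seglen)])
    total = arc[-1]
    n_gaps = max(int(np.ceil(total / step)), 1)
    targets = np.linspace(0.0, total, n_gaps + 1)
    return np.column_stack([np.interp(targets, arc, dense[:, a]) for a in range(3)])


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def _random_rotation(rng: np.random.Generator, max_tilt_rad: float = 0.3) -> np.ndarray:
    """Free spin about z composed with a small tilt about x and y."""
    a = rng.uniform(0, 2 * np.pi)
    bx, by = rng.uniform(-max_tilt_rad, max_tilt_rad, size=2)
    cz, sz = np.cos(a), np.sin(a)
    cx, sx = np.cos(bx), np.sin(bx)
    cy, sy = np.cos(by), np.sin(by)
    rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1.0]])
    rx = np.array([[1.0, 0, 0], [0, cx, -sx], [0, sx, cx]])
    ry = np.array([[cy, 0, sy], [0, 1.0, 0], [-sy, 0, cy]])
    return rz @ ry @ rx


def _canonical_dense_curve(spec: PhantomSpec, rng: np.random.Generator,
                           shrink: float = 1.0) -> np.ndarray:
    """Dense curve in a canonical frame, centered at the origin."""
    p = spec.curve_params
    usable = (spec.extent_mm - 2.0 * spec.margin_mm) * shrink
    if np.any(usable <= 0):
        raise ValueError("grid too small for the requested tube radius")

    if spec.curve_kind == "straight":
        direction = _unit(
            np.asarray(p.get("direction", rng.normal(size=3)), dtype=float)
        )
        if "length_mm" in p:
            length = float(p["length_mm"])
        else:
            half = np.min((usable / 2.0) / np.maximum(np.abs(direction), 1e-12))
            length = 2.0 * half * rng.uniform(0.75, 0.95)
        t = np.linspace(-length / 2.0, length / 2.0, 2000)
        return t[:, None] * direction[None, :]

    if spec.curve_kind == "arc":
        R = float(p.get("arc_radius_mm", rng.uniform(40.0, 80.0)))
        if "arc_angle_rad" in p:
            theta = float(p["arc_angle_rad"])
        else:
            theta_max = np.pi
            for _ in range(60):
                t = np.linspace(0, theta_max, 400)
                pts = np.column_stack(
                    [R * np.sin(t), R * (1 - np.cos(t)), np.zeros_like(t)]
                )
                span = pts.max(axis=0) - pts.min(axis=0)
                if np.all(span <= usable):
                    break
                theta_max *= 0.92
            theta = theta_max * rng.uniform(0.7, 1.0)
        t = np.linspace(0, theta, 2000)
        pts = np.column_stack([R * np.sin(t), R * (1 - np.cos(t)), np.zeros_like(t)])
        return pts - (pts.max(axis=0) + pts.min(axis=0)) / 2.0

    # aorta_like: limb up, half arch over, limb down
    usable_xy = float(min(usable[0], usable[1]))
    usable_z = float(usable[2])
    Ra_hi = min(30.0, usable_xy / 2.0 * 0.95, usable_z * 0.6)
    Ra_lo = min(16.0, 0.8 * Ra_hi)
    Ra = float(p.get("arch_radius_mm", rng.uniform(Ra_lo, Ra_hi)))
    lmax = max(usable_z - Ra, 1e-3)
    if "limb_lengths_mm" in p:
        l1, l2 = (float(v) for v in p["limb_lengths_mm"])
    else:
        l1, l2 = rng.uniform(0.7, 1.0, size=2) * lmax
    t1 = np.linspace(0.0, 1.0, 600)
    limb1 = np.column_stack(
        [np.full_like(t1, -Ra), np.zeros_like(t1), -l1 + t1 * l1]
    )
    ta = np.linspace(0.0, np.pi, 1000)
    arch = np.column_stack([-Ra * np.cos(ta), np.zeros_like(ta), Ra * np.sin(ta)])
    t2 = np.linspace(0.0, 1.0, 600)
    limb2 = np.column_stack([np.full_like(t2, Ra), np.zeros_like(t2), -t2 * l2])
    pts = np.vstack([limb1, arch[1:], limb2[1:]])
    return pts - (pts.max(axis=0) + pts.min(axis=0)) / 2.0


def generate_curve(spec: PhantomSpec) -> Centerline:
    """Generate the analytic centerline, sampled every ``gt_point_spacing_mm``.

    The curve is randomized from ``spec.seed`` (orientation and free size
    parameters) unless pinned through ``spec.curve_params``, then placed at
    the grid center. Points are ordered and arclength-uniform; world mm.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    center = spec.extent_mm / 2.0
    m = spec.margin_mm
    # a random tilt can push a snugly sized curve past the margin; shrink the
    # free size parameters slightly and redraw (explicitly pinned parameters
    # do not shrink, so impossible requests still fail loudly below)
    for attempt in range(10):
        dense = _canonical_dense_curve(spec, rng, shrink=0.96**attempt)
        if spec.curve_kind != "straight" and spec.curve_params.get("rotate", True):
            dense = dense @ _random_rotation(rng).T
        dense = dense - (dense.max(axis=0) + dense.min(axis=0)) / 2.0 + center
        lo, hi = dense.min(axis=0), dense.max(axis=0)
        if np.all(lo >= m - 1e-9) and np.all(hi <= spec.extent_mm - m + 1e-9):
            break
    else:
        raise ValueError(
            f"curve does not fit in the grid with margin {m:.1f} mm "
            f"(extent {spec.extent_mm}, curve bbox {lo.round(1)}..{hi.round(1)})"
        )
    return Centerline(_resample_by_arclength(dense, spec.gt_point_spacing_mm))


# ---------------------------------------------------------------------------
# rasterization and rendering
# ---------------------------------------------------------------------------


def _voxel_centers(spec: PhantomSpec) -> np.ndarray:
    spacing = np.asarray(spec.spacing_mm, dtype=float)
    axes = [
        (np.arange(n) + 0.5) * s for n, s in zip(spec.grid_shape, spacing)
    ]
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    return np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])


def rasterize_tube(curve: Centerline, spec: PhantomSpec) -> ProbabilityMask:
    """Binary lumen mask: voxel centers within ``radius_mm`` of the curve.

    The polyline is densely resampled (step <= min(spacing)/4) before the
    distance query, so the chord approximation error stays far below a
    voxel. Tube ends are flat: voxels beyond the end planes (whose closest
    curve point is an endpoint, on its outward side) are excluded, so a
    straight tube is a finite cylinder of volume pi r^2 L.
    """
    step = float(np.min(spec.spacing_mm)) / 4.0
    dense = _resample_by_arclength(curve.points, step)
    tree = cKDTree(dense)

    centers = _voxel_centers(spec)
    # restrict the query to the tube's bounding box, for speed
    lo = dense.min(axis=0) - spec.radius_mm - 2 * step
    hi = dense.max(axis=0) + spec.radius_mm + 2 * step
    cand = np.all((centers >= lo) & (centers <= hi), axis=1)
    dist, idx = tree.query(centers[cand], k=1)

    inc = dist <= spec.radius_mm
    tan0 = _unit(dense[1] - dense[0])
    tan1 = _unit(dense[-1] - dense[-2])
    at0 = idx == 0
    at1 = idx == len(dense) - 1
    inc[at0] &= (centers[cand][at0] - dense[0]) @ tan0 >= 0
    inc[at1] &= (centers[cand][at1] - dense[-1]) @ tan1 <= 0

    flat = np.zeros(centers.shape[0], dtype=np.uint8)
    flat[np.flatnonzero(cand)[inc]] = 1
    values = flat.reshape(spec.grid_shape)
    if values.sum() == 0:
        raise ValueError(
            "rasterization produced an empty mask — tube radius below voxel resolution?"
        )
    return ProbabilityMask(values[None], spec.spacing_mm, np.zeros(3))


def render_volume(mask: ProbabilityMask, spec: PhantomSpec) -> ImageVolume:
    """Two-level HU rendering of the lumen mask with partial-volume blur."""
    fg = mask.values[0].astype(np.float32)
    hu = spec.background_hu + (spec.lumen_hu - spec.background_hu) * fg
    if spec.edge_softness_mm > 0:
        sigma_vox = spec.edge_softness_mm / np.asarray(spec.spacing_mm, dtype=float)
        hu = ndimage.gaussian_filter(hu, sigma=sigma_vox)
    return ImageVolume(hu.astype(np.float32), spec.spacing_mm, np.zeros(3))


def make_phantom(spec: PhantomSpec):
    """Run the full pipeline for one spec: (volume, mask, centerline)."""
    curve = generate_curve(spec)
    mask = rasterize_tube(curve, spec)
    vol = render_volume(mask, spec)
    return vol, mask, curve


# ---------------------------------------------------------------------------
# datasets
# ---------------------------------------------------------------------------


def default_spec_distribution(rng: np.random.Generator, **overrides) -> PhantomSpec:
    """Randomized per-case phantom parameters at the study's data scale.

    Mostly aorta-like cases with a minority of plain arcs and straight
    tubes; tube radius 8–15 mm, aortic scale on a 2 mm grid.
    """
    kind = rng.choice(CURVE_KINDS, p=[0.15, 0.15, 0.7])
    base = dict(
        curve_kind=str(kind),
        radius_mm=float(rng.uniform(8.0, 15.0)),
        edge_softness_mm=float(rng.uniform(0.5, 1.5)),
        lumen_hu=float(rng.uniform(250.0, 350.0)),
        background_hu=float(rng.uniform(-30.0, 30.0)),
        seed=int(rng.integers(0, 2**31 - 1)),
    )
    base.update(overrides)
    return PhantomSpec(**base)


def make_dataset(
    n: int,
    spec_distribution=default_spec_distribution,
    seed: int = 0,
    out_dir=None,
    **spec_overrides,
):
    """Generate ``n`` independent phantom cases.

    Cases are reproducible per (seed, index): case i is generated from
    ``SeedSequence([seed, i])`` regardless of ``n``. With ``out_dir`` set,
    volumes/masks go to NIfTI, centerlines to .vtp and .json, and a
    ``manifest.csv`` records per-case parameters.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    cases, rows = [], []
    for i in range(n):
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), i]))
        for attempt in range(20):
            spec = spec_distribution(rng, **spec_overrides)
            try:
                vol, mask, curve = make_phantom(spec)
                break
            except ValueError:
                continue
        else:
            raise RuntimeError(f"could not generate a fitting phantom for case {i}")
        cases.append((vol, mask, curve))
        rows.append(
            dict(
                case=i,
                curve_kind=spec.curve_kind,
                radius_mm=spec.radius_mm,
                n_gt_points=len(curve),
                curve_length_mm=curve.length,
                seed=spec.seed,
            )
        )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for i, (vol, mask, curve) in enumerate(cases):
            vio.write_volume(vol, out / f"case_{i:03d}_image.nii.gz")
            vio.write_mask(mask, out / f"case_{i:03d}_mask.nii.gz")
            vio.write_centerline(curve, out / f"case_{i:03d}_centerline.vtp")
            vio.write_centerline(curve, out / f"case_{i:03d}_centerline.json")
        pd.DataFrame(rows).to_csv(out / "manifest.csv", index=False)
    return cases
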