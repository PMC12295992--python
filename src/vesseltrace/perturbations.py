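"""Input perturbations: CT artifact models, robustness transforms, and
training augmentations.

Artifact models (applied to intensities only — ground truth never moves):

* additive Gaussian noise, zero mean, variance 15 HU^2 by default (the
  customary reading of a "variance of 15 HU": sigma ~ 3.87 HU);
* global calibration shift: one scalar per volume, uniform in [-10, 10] HU;
* linear motion blur: convolution with a normalized line kernel whose
  length corresponds to a displacement amplitude of 1-3 voxels along a
  (possibly random) direction.

Geometric robustness transforms (applied consistently to image, mask and
centerline, so ground-truth containment is preserved):

* rigid/similarity deformation (scaling + rotation about the volume
  center): image resampled with cubic B-spline interpolation, mask with
  Gaussian smoothing + linear resampling + 0.5 threshold, centerline with
  the exact analytic map;
* grid distortion: a smooth displacement field from a coarse control grid,
  spline-upsampled; the image warp inverts the forward field by fixed-point
  iteration, the centerline moves by the field evaluated at its points,
  and folding fields (non-positive Jacobian) are rejected.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from .core import Centerline, ImageVolume, ProbabilityMask

__all__ = [
    "ArtifactSpec",
    "DeformationSpec",
    "add_gaussian_noise",
    "calibration_shift",
    "motion_blur",
    "motion_kernel",
    "rigid_deform",
    "grid_distortion",
    "training_augment",
]


@dataclass
class ArtifactSpec:
    noise_variance_hu2: float = 15.0
    calib_shift_range_hu: tuple = (-10.0, 10.0)
    motion_amp_voxels: tuple = (1, 3)
    motion_direction: object = "random"  # unit 3-vector or "random"
    seed: int = 0

    def __post_init__(self):
        if self.noise_variance_hu2 < 0:
            raise ValueError("noise variance must be nonnegative")


@dataclass
class DeformationSpec:
    scale_range: tuple = (0.9, 1.1)
    rotation_range_deg: float = 10.0
    grid_control_points: int = 4
    grid_max_disp_mm: float = 4.0
    seed: int = 0


# ---------------------------------------------------------------------------
# intensity artifacts
# ---------------------------------------------------------------------------


def add_gaussian_noise(vol: ImageVolume, spec: ArtifactSpec) -> ImageVolume:
    if spec.noise_variance_hu2 == 0:
        return ImageVolume(vol.values.copy(), vol.spacing_mm, vol.origin_mm)
    rng = np.random.default_rng(spec.seed)
    noise = rng.normal(0.0, np.sqrt(spec.noise_variance_hu2), size=vol.shape)
    return ImageVolume(
        (vol.values + noise).astype(np.float32), vol.spacing_mm, vol.origin_mm
    )


def calibration_shift(vol: ImageVolume, spec: ArtifactSpec) -> ImageVolume:
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.calib_shift_range_hu
    c = rng.uniform(lo, hi)
    return ImageVolume(
        (vol.values + c).astype(np.float32), vol.spacing_mm, vol.origin_mm
    )


def motion_kernel(amplitude: float, direction) -> np.ndarray:
    """Normalized line kernel for a given displacement amplitude (voxels).

    The line spans ``amplitude`` voxels centered on the kernel origin
    (support ``amplitude + 1`` voxels along an axis-aligned direction);
    off-axis directions are rendered by trilinear splatting of dense line
    samples.
    """
    d = np.asarray(direction, dtype=float)
    d = d / np.linalg.norm(d)
    if amplitude <= 0:
        return np.ones((1, 1, 1))
    half = amplitude / 2.0
    r = int(np.ceil(half + 1e-9))
    size = 2 * r + 1
    kern = np.zeros((size, size, size))
    ts = np.linspace(-half, half, max(int(64 * amplitude), 2))
    pos = ts[:, None] * d[None, :] + r  # kernel-grid coordinates
    i0 = np.floor(pos).astype(int)
    f = pos - i0
    for dx in (0, 1):
        for dy in (0, 1):
            for dz in (0, 1):
                w = (
                    (f[:, 0] if dx else 1 - f[:, 0])
                    * (f[:, 1] if dy else 1 - f[:, 1])
                    * (f[:, 2] if dz else 1 - f[:, 2])
                )
                np.add.at(kern, (i0[:, 0] + dx, i0[:, 1] + dy, i0[:, 2] + dz), w)
    return kern / kern.sum()


def motion_blur(vol: ImageVolume, spec: ArtifactSpec) -> ImageVolume:
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.motion_amp_voxels
    amp = int(rng.integers(lo, hi + 1)) if hi > lo else int(lo)
    if amp <= 0:
        return ImageVolume(vol.values.copy(), vol.spacing_mm, vol.origin_mm)
    if isinstance(spec.motion_direction, str) and spec.motion_direction == "random":
        direction = rng.normal(size=3)
    else:
        direction = np.asarray(spec.motion_direction, dtype=float)
    kern = motion_kernel(amp, direction)
    out = ndimage.convolve(vol.values.astype(np.float64), kern, mode="reflect")
    return ImageVolume(out.astype(np.float32), vol.spacing_mm, vol.origin_mm)


# ---------------------------------------------------------------------------
# geometric transforms
# ---------------------------------------------------------------------------


def _check_inside(points: np.ndarray, vol: ImageVolume, margin_mm: float):
    lo = vol.origin_mm + margin_mm
    hi = vol.origin_mm + vol.extent_mm - margin_mm
    if np.any(points < lo) or np.any(points > hi):
        raise ValueError("transform pushes the tube out of the grid")


def _warp_intensity(values, vox_coords, order):
    return ndimage.map_coordinates(
        values.astype(np.float64), vox_coords, order=order, mode="nearest"
    )


def _warp_mask(mask_values, vox_coords):
    smoothed = ndimage.gaussian_filter(mask_values.astype(np.float64), sigma=1.0)
    warped = ndimage.map_coordinates(smoothed, vox_coords, order=1, mode="constant")
    return (warped >= 0.5).astype(np.uint8)


def rigid_deform(vol: ImageVolume, mask: ProbabilityMask, cl: Centerline,
                 spec: DeformationSpec):
    """Similarity transform (isotropic scale + rotation) about the volume
    center, applied consistently to image (cubic B-spline), mask
    (Gaussian-smoothed + thresholded) and centerline (exact analytic map)."""
    rng = np.random.default_rng(spec.seed)
    s = rng.uniform(*spec.scale_range)
    angles = np.deg2rad(
        rng.uniform(-spec.rotation_range_deg, spec.rotation_range_deg, size=3)
    )
    rots = []
    for ax, ang in enumerate(angles):
        c, si = np.cos(ang), np.sin(ang)
        r = np.eye(3)
        i, j = [(1, 2), (0, 2), (0, 1)][ax]
        r[i, i] = c
        r[j, j] = c
        r[i, j] = -si
        r[j, i] = si
        rots.append(r)
    m = s * (rots[0] @ rots[1] @ rots[2])

    if np.allclose(m, np.eye(3), atol=1e-12):
        return (
            ImageVolume(vol.values.copy(), vol.spacing_mm, vol.origin_mm),
            ProbabilityMask(mask.values.copy(), mask.spacing_mm, mask.origin_mm),
            Centerline(cl.points.copy()),
        )

    center = vol.origin_mm + vol.extent_mm / 2.0
    new_pts = (cl.points - center) @ m.T + center
    _check_inside(new_pts, vol, margin_mm=float(np.max(vol.spacing_mm)))

    # backward map in continuous voxel coordinates for resampling
    spacing = vol.spacing_mm
    minv = np.linalg.inv(m)
    shape = np.asarray(vol.shape)
    grid = np.stack(
        np.meshgrid(*[np.arange(n) for n in shape], indexing="ij"), axis=0
    ).astype(np.float64)
    world = (grid + 0.5) * spacing[:, None, None, None] + vol.origin_mm[:, None, None, None]
    rel = world - center[:, None, None, None]
    src_world = np.einsum("ij,jdhw->idhw", minv, rel) + center[:, None, None, None]
    src_vox = (src_world - vol.origin_mm[:, None, None, None]) / spacing[:, None, None, None] - 0.5

    new_vol = ImageVolume(
        _warp_intensity(vol.values, src_vox, order=3).astype(np.float32),
        spacing, vol.origin_mm,
    )
    new_mask = ProbabilityMask(
        _warp_mask(mask.values[0], src_vox)[None], spacing, mask.origin_mm
    )
    return new_vol, new_mask, Centerline(new_pts)


def _forward_field(vol: ImageVolume, spec: DeformationSpec, rng) -> np.ndarray:
    """Smooth world-mm displacement field (3, D, H, W) at voxel centers."""
    g = spec.grid_control_points
    ctrl = rng.uniform(-spec.grid_max_disp_mm, spec.grid_max_disp_mm, size=(3, g, g, g))
    ctrl[:, [0, -1], :, :] = 0.0  # pin the boundary so nothing leaves the grid
    ctrl[:, :, [0, -1], :] = 0.0
    ctrl[:, :, :, [0, -1]] = 0.0
    field = np.stack(
        [
            ndimage.zoom(ctrl[a], np.asarray(vol.shape) / g, order=3, mode="nearest")
            for a in range(3)
        ]
    )
    return field


def _jacobian_positive(field: np.ndarray, spacing: np.ndarray) -> bool:
    grads = [
        np.gradient(field[a], spacing[0], spacing[1], spacing[2]) for a in range(3)
    ]
    jac = np.zeros(field.shape[1:] + (3, 3))
    for i in range(3):
        for j in range(3):
            jac[..., i, j] = (i == j) + grads[i][j]
    return bool(np.linalg.det(jac).min() > 0)


def _field_at(field: np.ndarray, points_mm: np.ndarray, vol: ImageVolume) -> np.ndarray:
    vox = (points_mm - vol.origin_mm) / vol.spacing_mm - 0.5
    return np.stack(
        [
            ndimage.map_coordinates(field[a], vox.T, order=1, mode="nearest")
            for a in range(3)
        ],
        axis=1,
    )


def grid_distortion(vol: ImageVolume, mask: ProbabilityMask, cl: Centerline,
                    spec: DeformationSpec):
    """Smooth elastic deformation from a coarse control grid.

    Forward map: ``phi(p) = p + u(p)``; the centerline moves by the field
    at its points, the image is resampled through the fixed-point inverse
    of ``phi``. Fields with non-positive Jacobian determinant (folding)
    are rejected.
    """
    rng = np.random.default_rng(spec.seed)
    field = _forward_field(vol, spec, rng)
    if np.abs(field).max() < 1e-12:
        return (
            ImageVolume(vol.values.copy(), vol.spacing_mm, vol.origin_mm),
            ProbabilityMask(mask.values.copy(), mask.spacing_mm, mask.origin_mm),
            Centerline(cl.points.copy()),
        )
    if not _jacobian_positive(field, vol.spacing_mm):
        raise ValueError(
            "displacement field folds (non-positive Jacobian); reduce grid_max_disp_mm"
        )

    new_pts = cl.points + _field_at(field, cl.points, vol)
    _check_inside(new_pts, vol, margin_mm=float(np.max(vol.spacing_mm)))

    # invert phi on the voxel-center grid by fixed-point iteration
    shape = np.asarray(vol.shape)
    grid = np.stack(
        np.meshgrid(*[np.arange(n) for n in shape], indexing="ij"), axis=0
    ).astype(np.float64)
    world = (grid + 0.5) * vol.spacing_mm[:, None, None, None] + vol.origin_mm[:, None, None, None]
    flat = world.reshape(3, -1).T  # (N, 3)
    q = flat.copy()
    for _ in range(8):
        q = flat - _field_at(field, q, vol)
    src_vox = ((q - vol.origin_mm) / vol.spacing_mm - 0.5).T.reshape(world.shape)

    new_vol = ImageVolume(
        _warp_intensity(vol.values, src_vox, order=3).astype(np.float32),
        vol.spacing_mm, vol.origin_mm,
    )
    new_mask = ProbabilityMask(
        _warp_mask(mask.values[0], src_vox)[None], mask.spacing_mm, mask.origin_mm
    )
    return new_vol, new_mask, Centerline(new_pts)


# ---------------------------------------------------------------------------
# training augmentation
# ---------------------------------------------------------------------------


def _flip(vol, mask, cl, axis: int):
    vvals = np.flip(vol.values, axis=axis).copy()
    mvals = np.flip(mask.values[0], axis=axis).copy()
    pts = cl.points.copy()
    lo = vol.origin_mm[axis]
    pts[:, axis] = 2 * lo + vol.extent_mm[axis] - pts[:, axis]
    return (
        ImageVolume(vvals, vol.spacing_mm, vol.origin_mm),
        ProbabilityMask(mvals[None], mask.spacing_mm, mask.origin_mm),
        Centerline(pts),
    )


def training_augment(case, seed: int,
                     deform_spec: DeformationSpec | None = None,
                     artifact_spec: ArtifactSpec | None = None):
    """Random flip / rigid / elastic / noise / blur augmentation of a case.

    Image, mask and centerline are always transformed with the same map.
    Geometric transforms that would push the tube out of the grid are
    skipped for that draw.
    """
    vol, mask, cl = case
    rng = np.random.default_rng(seed)
    dspec = deform_spec or DeformationSpec()
    aspec = artifact_spec or ArtifactSpec()

    for axis in range(3):
        if rng.random() < 0.5:
            vol, mask, cl = _flip(vol, mask, cl, axis)
    try:
        if rng.random() < 0.5:
            vol, mask, cl = rigid_deform(
                vol, mask, cl, replace(dspec, seed=int(rng.integers(2**31 - 1)))
            )
        if rng.random() < 0.3:
            vol, mask, cl = grid_distortion(
                vol, mask, cl, replace(dspec, seed=int(rng.integers(2**31 - 1)))
            )
    except ValueError:
        pass  # transform would leave the grid; keep the undeformed case
    if rng.random() < 0.7:
        vol = add_gaussian_noise(
            vol, replace(aspec, seed=int(rng.integers(2**31 - 1)))
        )
    if rng.random() < 0.3:
        sigma_mm = rng.uniform(0.2, 1.0)
        blurred = ndimage.gaussian_filter(
            vol.values.astype(np.float64), sigma=sigma_mm / vol.spacing_mm
        )
        vol = ImageVolume(blurred.astype(np.float32), vol.spacing_mm, vol.origin_mm)
    return vol, mask, cl
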