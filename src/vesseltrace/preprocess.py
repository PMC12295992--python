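"""HU windowing and coordinate transforms.

Three coordinate frames appear in the pipeline:

* **world mm** — physical coordinates; all public centerlines and metrics.
* **continuous voxel** — voxel index space; the center of voxel ``i`` is at
  voxel coordinate ``i`` (so world = origin + (v + 0.5) * spacing).
* **normalized** — continuous voxel coordinate divided by the grid shape,
  shifted so the volume spans [0, 1]^3; this is the frame the centerline
  decoder operates in. ``normalized = (world - origin) / (shape * spacing)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import ImageVolume

__all__ = [
    "WindowSpec",
    "apply_window",
    "world_to_voxel",
    "voxel_to_world",
    "world_to_normalized",
    "normalized_to_world",
]


@dataclass(frozen=True)
class WindowSpec:
    """CT intensity window: center ``level_hu``, full width ``width_hu``.

    The defaults (level −200 HU, width 1400 HU) span [−900, 500] HU, covering
    lung parenchyma through contrast-enhanced lumen.
    """

    level_hu: float = -200.0
    width_hu: float = 1400.0

    def __post_init__(self):
        if self.width_hu <= 0:
            raise ValueError("window width must be positive")

    @property
    def lo(self) -> float:
        return self.level_hu - self.width_hu / 2.0

    @property
    def hi(self) -> float:
        return self.level_hu + self.width_hu / 2.0


def apply_window(vol: ImageVolume, window: WindowSpec = WindowSpec()) -> ImageVolume:
    """Clip HU values to the window and map them affinely onto [0, 1].

    ``out = clip((hu - (level - width/2)) / width, 0, 1)`` — monotone in HU.
    """
    out = np.clip((vol.values - window.lo) / window.width_hu, 0.0, 1.0)
    return ImageVolume(out.astype(np.float32), vol.spacing_mm, vol.origin_mm)


def _grid(vol_or_mask):
    shape = getattr(vol_or_mask, "grid_shape", None) or vol_or_mask.shape
    return (
        np.asarray(shape, dtype=float),
        vol_or_mask.spacing_mm,
        vol_or_mask.origin_mm,
    )


def world_to_voxel(points_mm, vol) -> tuple[np.ndarray, np.ndarray]:
    """World mm -> continuous voxel coordinates.

    Returns ``(coords, inside)`` where ``inside`` flags points whose
    continuous coordinate lies within [-0.5, shape - 0.5] per axis (i.e.
    inside the physical volume). Out-of-grid points are returned, not
    clipped.
    """
    shape, spacing, origin = _grid(vol)
    pts = np.atleast_2d(np.asarray(points_mm, dtype=float))
    coords = (pts - origin) / spacing - 0.5
    inside = np.all((coords >= -0.5) & (coords <= shape - 0.5), axis=1)
    return coords, inside


def voxel_to_world(coords, vol) -> np.ndarray:
    shape, spacing, origin = _grid(vol)
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    return (coords + 0.5) * spacing + origin


def world_to_normalized(points_mm, vol) -> np.ndarray:
    """World mm -> normalized [0,1]^3 network coordinates."""
    shape, spacing, origin = _grid(vol)
    pts = np.atleast_2d(np.asarray(points_mm, dtype=float))
    return (pts - origin) / (shape * spacing)


def normalized_to_world(coords01, vol) -> np.ndarray:
    shape, spacing, origin = _grid(vol)
    coords01 = np.atleast_2d(np.asarray(coords01, dtype=float))
    return coords01 * (shape * spacing) + origin
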