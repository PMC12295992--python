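"""Core containers shared across the package.

Coordinate convention (used everywhere, all formats):

* the grid is axis-aligned with 0-based voxel indices;
* the *center* of voxel ``i`` along an axis sits at world position
  ``origin + (i + 0.5) * spacing`` in millimetres;
* centerlines are ordered polylines of real-valued world-mm points, with the
  implicit chain connectivity ``point i -- point i+1``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ImageVolume", "ProbabilityMask", "Centerline", "FormatError"]


class FormatError(ValueError):
    """Raised when a file or array does not satisfy a format contract."""


def _as_triplet(x) -> np.ndarray:
    arr = np.asarray(x, dtype=float).reshape(-1)
    if arr.size != 3:
        raise ValueError(f"expected a 3-vector, got shape {arr.shape}")
    return arr


@dataclass
class ImageVolume:
    """A 3D scalar field in Hounsfield units on a regular grid.

    Parameters
    ----------
    values : (H, W, D) float array
        Voxel intensities in HU (or normalized units after windowing).
    spacing_mm : 3 positive floats
        Per-axis voxel spacing in millimetres.
    origin_mm : 3 floats
        World position of the grid corner; the center of voxel (0,0,0)
        is at ``origin_mm + 0.5 * spacing_mm``.
    """

    values: np.ndarray
    spacing_mm: np.ndarray = field(default_factory=lambda: np.full(3, 2.0))
    origin_mm: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise FormatError(f"ImageVolume must be 3D, got ndim={self.values.ndim}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("ImageVolume values must be finite")
        self.spacing_mm = _as_triplet(self.spacing_mm)
        if np.any(self.spacing_mm <= 0):
            raise ValueError("spacing_mm must be positive")
        self.origin_mm = _as_triplet(self.origin_mm)

    @property
    def shape(self) -> tuple:
        return self.values.shape

    @property
    def extent_mm(self) -> np.ndarray:
        """Physical size of the grid per axis (mm)."""
        return np.asarray(self.shape) * self.spacing_mm


@dataclass
class ProbabilityMask:
    """Per-voxel vessel probability (or binary ground truth) on an image grid.

    ``values`` has shape (K, H, W, D) with K classes; K = 1 throughout this
    package (vessel lumen vs. background).
    """

    values: np.ndarray
    spacing_mm: np.ndarray = field(default_factory=lambda: np.full(3, 2.0))
    origin_mm: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if self.values.ndim == 3:
            self.values = self.values[None]
        if self.values.ndim != 4:
            raise FormatError(
                f"ProbabilityMask must be (K,H,W,D), got ndim={self.values.ndim}"
            )
        if self.values.size and (self.values.min() < 0 or self.values.max() > 1):
            raise ValueError("mask values must lie in [0, 1]")
        self.spacing_mm = _as_triplet(self.spacing_mm)
        if np.any(self.spacing_mm <= 0):
            raise ValueError("spacing_mm must be positive")
        self.origin_mm = _as_triplet(self.origin_mm)

    @property
    def grid_shape(self) -> tuple:
        return self.values.shape[1:]

    @property
    def is_binary(self) -> bool:
        return bool(np.isin(self.values, (0, 1)).all())

    def binarize(self, threshold: float = 0.5) -> "ProbabilityMask":
        return ProbabilityMask(
            (self.values >= threshold).astype(np.uint8),
            self.spacing_mm,
            self.origin_mm,
        )


@dataclass
class Centerline:
    """An ordered polyline of N >= 2 points with real-valued 3D coordinates.

    Points are world millimetres unless a function documents otherwise
    (the network operates internally in normalized [0,1] coordinates).
    Connectivity is the implicit chain: point i is joined to point i+1 —
    no post-processing ever needs to reconstruct it.
    """

    points: np.ndarray

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise FormatError(f"Centerline points must be (N,3), got {self.points.shape}")
        if self.points.shape[0] < 2:
            raise FormatError("Centerline needs at least 2 points")
        if not np.all(np.isfinite(self.points)):
            raise ValueError("Centerline points must be finite")
        gaps = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
        if np.any(gaps == 0):
            raise ValueError("consecutive centerline points must be distinct")

    def __len__(self) -> int:
        return self.points.shape[0]

    @property
    def edge_lengths(self) -> np.ndarray:
        return np.linalg.norm(np.diff(self.points, axis=0), axis=1)

    @property
    def length(self) -> float:
        """Total arclength of the polyline."""
        return float(self.edge_lengths.sum())

    @property
    def arclengths(self) -> np.ndarray:
        """Cumulative arclength at each point, starting at 0."""
        return np.concatenate([[0.0], np.cumsum(self.edge_lengths)])
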