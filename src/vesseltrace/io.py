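"""Reading and writing of volumes, masks and centerlines.

Volumes and masks travel as NIfTI (.nii/.nii.gz); centerlines as VTK
PolyData XML (.vtp, one polyline cell, ASCII) or as JSON
(``{"points_mm": [[x, y, z], ...]}``). All formats share the package's
single coordinate convention (world mm, voxel center i at
origin + (i+0.5)*spacing).

Only axis-aligned NIfTI affines with positive diagonal are accepted:
anything else is the classic silent-axis-flip source of centerline bugs
and is rejected loudly.
"""

from __future__ import annotations

import json
import xml.etree.ElementTree as ET
from pathlib import Path

import nibabel as nib
import numpy as np

from .core import Centerline, FormatError, ImageVolume, ProbabilityMask

__all__ = [
    "read_volume",
    "write_volume",
    "read_mask",
    "write_mask",
    "read_centerline",
    "write_centerline",
]


def _affine_from(spacing_mm, origin_mm) -> np.ndarray:
    # nibabel maps integer index i -> world; our voxel-center convention puts
    # index i at origin + (i + 0.5) * spacing.
    aff = np.eye(4)
    aff[:3, :3] = np.diag(spacing_mm)
    aff[:3, 3] = np.asarray(origin_mm) + 0.5 * np.asarray(spacing_mm)
    return aff


def _grid_from_affine(aff: np.ndarray):
    lin = aff[:3, :3]
    off = np.diag(lin).copy()
    if np.any(off <= 0) or np.abs(lin - np.diag(off)).max() > 1e-6:
        raise FormatError(
            "only axis-aligned NIfTI affines with positive diagonal are supported; "
            f"got linear part {lin.tolist()}"
        )
    spacing = off
    origin = aff[:3, 3] - 0.5 * spacing
    return spacing, origin


def write_volume(vol: ImageVolume, path) -> None:
    img = nib.Nifti1Image(
        np.asarray(vol.values, dtype=np.float32),
        _affine_from(vol.spacing_mm, vol.origin_mm),
    )
    nib.save(img, str(path))


def read_volume(path) -> ImageVolume:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise FormatError(f"expected a 3D scalar NIfTI, got ndim={data.ndim}")
    spacing, origin = _grid_from_affine(img.affine)
    return ImageVolume(np.asarray(data, dtype=np.float32), spacing, origin)


def write_mask(mask: ProbabilityMask, path) -> None:
    """Binary masks are stored as uint8 {0,1}; probabilities as float32."""
    vals = mask.values[0]
    dtype = np.uint8 if mask.is_binary else np.float32
    img = nib.Nifti1Image(
        vals.astype(dtype), _affine_from(mask.spacing_mm, mask.origin_mm)
    )
    nib.save(img, str(path))


def read_mask(path) -> ProbabilityMask:
    vol = read_volume(path)
    return ProbabilityMask(vol.values[None], vol.spacing_mm, vol.origin_mm)


# ---------------------------------------------------------------------------
# Centerlines
# ---------------------------------------------------------------------------

_VTP_TEMPLATE = """<?xml version="1.0"?>
<VTKFile type="PolyData" version="0.1" byte_order="LittleEndian">
  <PolyData>
    <Piece NumberOfPoints="{n}" NumberOfVerts="0" NumberOfLines="1" NumberOfStrips="0" NumberOfPolys="0">
      <Points>
        <DataArray type="Float64" NumberOfComponents="3" format="ascii">
{points}
        </DataArray>
      </Points>
      <Lines>
        <DataArray type="Int64" Name="connectivity" format="ascii">
{connectivity}
        </DataArray>
        <DataArray type="Int64" Name="offsets" format="ascii">
{offsets}
        </DataArray>
      </Lines>
    </Piece>
  </PolyData>
</VTKFile>
"""


def _write_vtp(cl: Centerline, path) -> None:
    n = len(cl)
    pts = "\n".join(
        "          " + " ".join(repr(float(c)) for c in p) for p in cl.points
    )
    conn = "          " + " ".join(str(i) for i in range(n))
    text = _VTP_TEMPLATE.format(
        n=n, points=pts, connectivity=conn, offsets=f"          {n}"
    )
    Path(path).write_text(text)


def _read_vtp(path) -> Centerline:
    try:
        root = ET.parse(str(path)).getroot()
    except ET.ParseError as e:
        raise FormatError(f"not a parsable VTP file: {e}") from e
    piece = root.find("./PolyData/Piece")
    if piece is None:
        raise FormatError("VTP file contains no PolyData piece")
    pts_arr = piece.find("./Points/DataArray")
    if pts_arr is None or not (pts_arr.text or "").strip():
        raise FormatError("VTP file contains no points")
    flat = np.array(pts_arr.text.split(), dtype=float)
    if flat.size % 3:
        raise FormatError("VTP point array length is not a multiple of 3")
    points = flat.reshape(-1, 3)

    lines = piece.find("Lines")
    if lines is None:
        raise FormatError("VTP file has no Lines cells (unsupported topology)")
    arrays = {a.get("Name"): a for a in lines.findall("DataArray")}
    offsets = np.array((arrays["offsets"].text or "").split(), dtype=int)
    conn = np.array((arrays["connectivity"].text or "").split(), dtype=int)
    if offsets.size != 1:
        raise FormatError(
            f"expected a single polyline cell, found {offsets.size} (unsupported topology)"
        )
    order = conn[: offsets[0]]
    if order.size < 2:
        raise FormatError("polyline cell has fewer than 2 points")
    return Centerline(points[order])


def write_centerline(cl: Centerline, path) -> None:
    path = Path(path)
    if path.suffix == ".vtp":
        _write_vtp(cl, path)
    elif path.suffix == ".json":
        path.write_text(json.dumps({"points_mm": cl.points.tolist()}))
    else:
        raise FormatError(f"unsupported centerline format: {path.suffix}")


def read_centerline(path) -> Centerline:
    path = Path(path)
    if path.stat().st_size == 0:
        raise FormatError(f"empty centerline file: {path}")
    if path.suffix == ".vtp":
        return _read_vtp(path)
    if path.suffix == ".json":
        try:
            payload = json.loads(path.read_text())
        except json.JSONDecodeError as e:
            raise FormatError(f"not valid JSON: {e}") from e
        if not isinstance(payload, dict) or "points_mm" not in payload:
            raise FormatError('centerline JSON must contain a "points_mm" key')
        pts = np.asarray(payload["points_mm"], dtype=float)
        if pts.ndim != 2 or pts.shape[0] < 2 or pts.shape[1] != 3:
            raise FormatError(f"centerline JSON needs an (N>=2, 3) list, got {pts.shape}")
        return Centerline(pts)
    raise FormatError(f"unsupported centerline format: {path.suffix}")
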