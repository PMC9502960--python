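"""Reader/writer for the ImageJ ROI binary format (.roi and .zip bundles).

Implements the documented big-endian layout used by ImageJ's
RoiDecoder/RoiEncoder: a 64-byte header starting with the magic "Iout",
integer vertex coordinates relative to the bounding box, optional
sub-pixel float coordinates (SUB_PIXEL_RESOLUTION option bit), and the
ShapeRoi float path array for composite (multi-ring) ROIs.  Unknown
header options are ignored rather than rejected, since files in the wild
vary by ImageJ version.

Supported ROI types: polygon, freehand, traced, rectangle, oval, and
composite.  Line, point, angle and the polyline family are rejected with
an error naming the subtype — they have no area and cannot participate
in overlap analysis.
"""

from __future__ import annotations

import io
import struct
import zipfile
from pathlib import Path
from typing import BinaryIO

import numpy as np

from .errors import InvalidRoiError, RoiFormatError, UnsupportedRoiTypeError
from .roi_model import RegionOfInterest

__all__ = [
    "read_imagej_roi",
    "write_imagej_roi",
    "read_roi_zip",
    "write_roi_zip",
]

_MAGIC = b"Iout"
_VERSION = 228

# ROI type codes (header byte 6)
_T_POLYGON = 0
_T_RECT = 1
_T_OVAL = 2
_T_LINE = 3
_T_FREELINE = 4
_T_POLYLINE = 5
_T_NOROI = 6
_T_FREEHAND = 7
_T_TRACED = 8
_T_ANGLE = 9
_T_POINT = 10

_TYPE_NAMES = {
    _T_LINE: "line",
    _T_FREELINE: "freeline",
    _T_POLYLINE: "polyline",
    _T_NOROI: "noroi",
    _T_ANGLE: "angle",
    _T_POINT: "point",
}

_OPT_SUB_PIXEL = 128

# ShapeRoi path segment codes (java.awt.geom.PathIterator)
_SEG_MOVETO = 0.0
_SEG_LINETO = 1.0
_SEG_QUADTO = 2.0
_SEG_CUBICTO = 3.0
_SEG_CLOSE = 4.0

_N_OVAL_VERTICES = 72


def _read_all(stream: BinaryIO | bytes) -> bytes:
    if isinstance(stream, (bytes, bytearray)):
        return bytes(stream)
    return stream.read()


def read_imagej_roi(stream: BinaryIO | bytes) -> RegionOfInterest:
    """Decode one ImageJ .roi record into a RegionOfInterest.

    Label, grader and frame are left unset; the caller assigns them from
    the surrounding manifest.  Composite ROIs yield multiple rings.
    """
    data = _read_all(stream)
    if len(data) < 64:
        raise RoiFormatError(f"ROI record truncated at {len(data)} bytes")
    if data[:4] != _MAGIC:
        raise RoiFormatError(
            f"bad magic {data[:4]!r}; expected {_MAGIC!r} (not an ImageJ ROI)"
        )
    (
        _version,
        roi_type,
        _pad,
        top,
        left,
        bottom,
        right,
        n_coords,
    ) = struct.unpack(">hBbhhhhH", data[4:18])
    shape_roi_size = struct.unpack(">i", data[36:40])[0]
    options = struct.unpack(">h", data[50:52])[0]

    if roi_type == _T_RECT and shape_roi_size > 0:
        return _decode_shape_roi(data, shape_roi_size)
    if roi_type in _TYPE_NAMES:
        raise UnsupportedRoiTypeError(
            f"unsupported ImageJ ROI subtype '{_TYPE_NAMES[roi_type]}'"
        )
    if roi_type == _T_RECT:
        ring = np.array(
            [(left, top), (right, top), (right, bottom), (left, bottom)], dtype=float
        )
        return RegionOfInterest(rings=[ring])
    if roi_type == _T_OVAL:
        cx, cy = (left + right) / 2.0, (top + bottom) / 2.0
        rx, ry = (right - left) / 2.0, (bottom - top) / 2.0
        theta = np.linspace(0.0, 2.0 * np.pi, _N_OVAL_VERTICES, endpoint=False)
        ring = np.column_stack([cx + rx * np.cos(theta), cy + ry * np.sin(theta)])
        return RegionOfInterest(rings=[ring])
    if roi_type not in (_T_POLYGON, _T_FREEHAND, _T_TRACED):
        raise UnsupportedRoiTypeError(f"unsupported ImageJ ROI type code {roi_type}")

    if n_coords < 3:
        raise RoiFormatError(f"area ROI with {n_coords} vertices")
    base = 64
    need = base + 4 * n_coords
    if len(data) < need:
        raise RoiFormatError("coordinate block truncated")
    xs_i = np.frombuffer(data, dtype=">i2", count=n_coords, offset=base)
    ys_i = np.frombuffer(data, dtype=">i2", count=n_coords, offset=base + 2 * n_coords)
    sub_pixel = bool(options & _OPT_SUB_PIXEL) and len(data) >= need + 8 * n_coords
    if sub_pixel:
        xs = np.frombuffer(data, dtype=">f4", count=n_coords, offset=need).astype(float)
        ys = np.frombuffer(
            data, dtype=">f4", count=n_coords, offset=need + 4 * n_coords
        ).astype(float)
    else:
        xs = xs_i.astype(float) + left
        ys = ys_i.astype(float) + top
    return RegionOfInterest(rings=[np.column_stack([xs, ys])])


def _decode_shape_roi(data: bytes, n_floats: int) -> RegionOfInterest:
    if len(data) < 64 + 4 * n_floats:
        raise RoiFormatError("composite ROI shape array truncated")
    arr = np.frombuffer(data, dtype=">f4", count=n_floats, offset=64).astype(float)
    rings: list[np.ndarray] = []
    current: list[tuple[float, float]] = []
    i = 0
    while i < len(arr):
        seg = arr[i]
        if seg == _SEG_MOVETO:
            if len(current) >= 3:
                rings.append(np.array(current))
            current = [(arr[i + 1], arr[i + 2])]
            i += 3
        elif seg == _SEG_LINETO:
            current.append((arr[i + 1], arr[i + 2]))
            i += 3
        elif seg == _SEG_CLOSE:
            if len(current) >= 3:
                rings.append(np.array(current))
            current = []
            i += 1
        elif seg in (_SEG_QUADTO, _SEG_CUBICTO):
            raise UnsupportedRoiTypeError(
                "composite ROI contains curved (quad/cubic) path segments"
            )
        else:
            raise RoiFormatError(f"unknown path segment code {seg}")
    if len(current) >= 3:
        rings.append(np.array(current))
    if not rings:
        raise RoiFormatError("composite ROI contains no closed ring")
    return RegionOfInterest(rings=rings)


def _header(
    roi_type: int,
    bounds: tuple[int, int, int, int],
    n_coords: int,
    shape_roi_size: int = 0,
    options: int = 0,
) -> bytearray:
    top, left, bottom, right = bounds
    buf = bytearray(64)
    buf[0:4] = _MAGIC
    struct.pack_into(">h", buf, 4, _VERSION)
    buf[6] = roi_type
    struct.pack_into(">hhhhH", buf, 8, top, left, bottom, right, n_coords)
    struct.pack_into(">i", buf, 36, shape_roi_size)
    struct.pack_into(">h", buf, 50, options)
    return buf


def _int_bounds(rings: list[np.ndarray]) -> tuple[int, int, int, int]:
    allv = np.vstack(rings)
    left = int(np.floor(allv[:, 0].min()))
    top = int(np.floor(allv[:, 1].min()))
    right = int(np.ceil(allv[:, 0].max()))
    bottom = int(np.ceil(allv[:, 1].max()))
    return top, left, bottom, right


def write_imagej_roi(roi: RegionOfInterest) -> bytes:
    """Encode a RegionOfInterest as ImageJ .roi bytes.

    Single-ring ROIs become sub-pixel polygon records (coordinates stored
    both as bounding-box-relative integers, for old readers, and as
    absolute float32).  Multi-ring ROIs become composite ShapeRoi records.
    Reading the bytes back reproduces the rings to float32 precision.
    """
    if not isinstance(roi, RegionOfInterest) or not roi.rings:
        raise InvalidRoiError("cannot encode an ROI without rings")
    if len(roi.rings) == 1:
        ring = roi.rings[0]
        n = ring.shape[0]
        bounds = _int_bounds([ring])
        top, left, _, _ = bounds
        buf = _header(_T_POLYGON, bounds, n, options=_OPT_SUB_PIXEL)
        xi = np.round(ring[:, 0] - left).astype(">i2")
        yi = np.round(ring[:, 1] - top).astype(">i2")
        buf += xi.tobytes() + yi.tobytes()
        buf += ring[:, 0].astype(">f4").tobytes() + ring[:, 1].astype(">f4").tobytes()
        return bytes(buf)

    floats: list[float] = []
    for ring in roi.rings:
        floats.extend([_SEG_MOVETO, float(ring[0, 0]), float(ring[0, 1])])
        for x, y in ring[1:]:
            floats.extend([_SEG_LINETO, float(x), float(y)])
        floats.append(_SEG_CLOSE)
    buf = _header(_T_RECT, _int_bounds(roi.rings), 0, shape_roi_size=len(floats))
    buf += np.asarray(floats, dtype=">f4").tobytes()
    return bytes(buf)


def read_roi_zip(path_or_stream: str | Path | BinaryIO) -> list[RegionOfInterest]:
    """Read a .zip bundle of .roi entries, in archive order.

    Each ROI's grader/label is unset; entry names are attached for the
    caller via the returned ROIs' order matching ``zipfile`` namelist
    order (non-.roi entries are ignored).
    """
    rois = []
    with zipfile.ZipFile(path_or_stream) as zf:
        for name in zf.namelist():
            if not name.lower().endswith(".roi"):
                continue
            rois.append(read_imagej_roi(zf.read(name)))
    return rois


def write_roi_zip(
    rois: list[RegionOfInterest],
    path_or_stream: str | Path | BinaryIO,
    names: list[str] | None = None,
) -> None:
    """Write ROIs as a .zip bundle of .roi entries."""
    if names is None:
        names = [f"roi_{i:03d}.roi" for i in range(len(rois))]
    with zipfile.ZipFile(path_or_stream, "w", zipfile.ZIP_DEFLATED) as zf:
        for name, roi in zip(names, rois):
            if not name.lower().endswith(".roi"):
                name += ".roi"
            zf.writestr(name, write_imagej_roi(roi))
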