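"""Domain types for lesion annotations on en-face retinal frames.

Coordinate convention (fixed throughout the package): 0-based pixel
coordinates, x rightward, y downward, with pixel centers at integer
positions — pixel (row i, column j) spans the square
[j - 0.5, j + 0.5) x [i - 0.5, i + 0.5).  Polygon annotations use the
even-odd fill rule, matching ImageJ composite-ROI semantics, so interior
rings punch holes regardless of orientation.

The polygon form of an annotation is authoritative; binary masks are
derived rasterizations on a frame's pixel-center lattice.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import imageio.v3 as iio
import tifffile
from shapely.geometry import Polygon as _ShapelyPolygon
from shapely.geometry.base import BaseGeometry

from .errors import InvalidRoiError, ShapeMismatchError, ConfigurationError

__all__ = [
    "Modality",
    "LesionType",
    "Point2D",
    "ImageFrame",
    "RegionOfInterest",
    "BinaryMask",
    "AnnotationSet",
    "TreatmentGroup",
    "roi_to_mask",
    "rasterize_rings",
    "polygon_area_px",
    "roi_geometry",
    "read_mask_image",
    "write_mask_image",
]


class Modality(enum.Enum):
    """Imaging modality of an en-face frame."""

    OCTA_CHORIOCAPILLARIS = "octa_choriocapillaris"
    ICGA_EARLY = "icga_early"
    ICGA_MID = "icga_mid"


class LesionType(enum.Enum):
    """Lesion taxonomy used for annotation labels.

    On the choriocapillaris OCTA slab: TYPE_A is the coarse granulated
    hyper-reflective area, TYPE_B the roundish dark halo around it
    (shadowing from subretinal fluid), TYPE_C coarse granulated
    hypo-reflective spots inside TYPE_A.  On ICGA: HYPERFLUORESCENCE is
    the mid-phase choroidal hyperpermeability region, HYPOFLUORESCENCE
    the early-phase hypoperfusion spots.
    """

    TYPE_A = "type_a"
    TYPE_B = "type_b"
    TYPE_C = "type_c"
    HYPERFLUORESCENCE = "hyperfluorescence"
    HYPOFLUORESCENCE = "hypofluorescence"


class TreatmentGroup(enum.Enum):
    LASER = "laser"
    OBSERVATION = "observation"


@dataclass(frozen=True)
class Point2D:
    """A continuous pixel coordinate (x rightward, y downward)."""

    x: float
    y: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.x) and np.isfinite(self.y)):
            raise InvalidRoiError(f"non-finite point ({self.x}, {self.y})")

    def as_array(self) -> np.ndarray:
        return np.array([self.x, self.y], dtype=float)


@dataclass(frozen=True)
class ImageFrame:
    """Pixel grid plus physical field of view of one en-face frame.

    The field of view fixes the px -> mm conversion:
    one pixel covers (fov_width_mm / width) x (fov_height_mm / height) mm.
    """

    width: int
    height: int
    fov_width_mm: float
    fov_height_mm: float
    modality: Modality = Modality.OCTA_CHORIOCAPILLARIS

    def __post_init__(self) -> None:
        if self.width < 1 or self.height < 1:
            raise ConfigurationError(
                f"frame dimensions must be >= 1, got {self.width}x{self.height}"
            )
        if not (self.fov_width_mm > 0 and self.fov_height_mm > 0):
            raise ConfigurationError(
                "field of view must be positive, got "
                f"{self.fov_width_mm} x {self.fov_height_mm} mm"
            )

    @property
    def px_area_mm2(self) -> float:
        """Physical area of one pixel in mm^2."""
        return (self.fov_width_mm / self.width) * (self.fov_height_mm / self.height)

    def px2_to_mm2(self, area_px: float) -> float:
        return float(area_px) * self.px_area_mm2


def _as_ring(vertices: Iterable) -> np.ndarray:
    arr = np.asarray(
        [(v.x, v.y) if isinstance(v, Point2D) else tuple(v) for v in vertices],
        dtype=float,
    )
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise InvalidRoiError(f"ring must be an (n, 2) vertex list, got shape {arr.shape}")
    if arr.shape[0] < 3:
        raise InvalidRoiError(f"ring needs >= 3 vertices, got {arr.shape[0]}")
    if not np.all(np.isfinite(arr)):
        raise InvalidRoiError("ring contains non-finite vertices")
    return arr


@dataclass
class RegionOfInterest:
    """A labeled lesion annotation: one or more closed polygon rings.

    Rings are implicitly closed (last vertex connects back to the first)
    and combined under the even-odd rule, so a multifocal lesion is one
    ROI with several disjoint rings and a ring inside another is a hole.
    """

    rings: list[np.ndarray]
    label: LesionType | None = None
    grader: str | None = None
    frame: ImageFrame | None = None

    def __post_init__(self) -> None:
        if not self.rings:
            raise InvalidRoiError("ROI must have at least one ring")
        self.rings = [_as_ring(r) for r in self.rings]

    def with_rings(self, rings: Sequence[np.ndarray]) -> "RegionOfInterest":
        return RegionOfInterest(
            rings=[np.array(r, dtype=float) for r in rings],
            label=self.label,
            grader=self.grader,
            frame=self.frame,
        )

    def relabel(self, label: LesionType | None = None, grader: str | None = None,
                frame: ImageFrame | None = None) -> "RegionOfInterest":
        out = replace(self)
        out.rings = [r.copy() for r in self.rings]
        if label is not None:
            out.label = label
        if grader is not None:
            out.grader = grader
        if frame is not None:
            out.frame = frame
        return out


@dataclass
class BinaryMask:
    """Raster realization of an ROI on a frame's pixel lattice."""

    grid: np.ndarray
    frame: ImageFrame

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=bool)
        if self.grid.shape != (self.frame.height, self.frame.width):
            raise ShapeMismatchError(
                f"mask shape {self.grid.shape} does not match frame "
                f"{self.frame.height}x{self.frame.width}"
            )

    @property
    def area_px(self) -> int:
        return int(self.grid.sum())

    @property
    def area_mm2(self) -> float:
        return self.frame.px2_to_mm2(self.area_px)


@dataclass
class AnnotationSet:
    """All ROIs drawn by one grader on one eye's frame at one visit."""

    eye_id: str
    timepoint: int
    grader: str
    rois: list[RegionOfInterest] = field(default_factory=list)
    group: TreatmentGroup | None = None

    def __post_init__(self) -> None:
        if self.timepoint < 0:
            raise ConfigurationError(f"timepoint must be >= 0, got {self.timepoint}")
        seen: set[LesionType] = set()
        for roi in self.rois:
            if roi.label is None:
                continue
            if roi.label in seen:
                raise InvalidRoiError(
                    f"duplicate label {roi.label.name} in annotation set "
                    f"({self.eye_id}, t={self.timepoint}, grader={self.grader}); "
                    "multifocal lesions belong in one multi-ring ROI"
                )
            seen.add(roi.label)

    def roi_for(self, label: LesionType) -> RegionOfInterest | None:
        for roi in self.rois:
            if roi.label is label:
                return roi
        return None


# ---------------------------------------------------------------------------
# Geometry: even-odd fill via shapely, pixel-center scanline rasterization
# ---------------------------------------------------------------------------

def roi_geometry(roi: RegionOfInterest) -> BaseGeometry:
    """Continuous even-odd fill of an ROI as a shapely geometry.

    The even-odd region is the symmetric difference of the rings' simple
    fills, which handles holes and arbitrary nesting depth by parity.
    """
    geom: BaseGeometry | None = None
    for ring in roi.rings:
        poly = _ShapelyPolygon(ring)
        if not poly.is_valid:
            poly = poly.buffer(0)
        geom = poly if geom is None else geom.symmetric_difference(poly)
    assert geom is not None
    return geom


def polygon_area_px(roi: RegionOfInterest) -> float:
    """Continuous area of the ROI's even-odd fill, in px^2 (>= 0)."""
    return float(roi_geometry(roi).area)


def rasterize_rings(rings: Sequence[np.ndarray], width: int, height: int) -> np.ndarray:
    """Even-odd scanline rasterization on the pixel-center lattice.

    A cell (i, j) is set iff the point (x=j, y=i) lies inside the even-odd
    fill: a rightward ray from the pixel center crosses the ring edges an
    odd number of times.  Edges are treated half-open in y
    (min(y) <= i < max(y)) so shared vertices are counted once, and a
    crossing at x flips parity for all centers j > x.
    """
    flips = np.zeros((height, width + 1), dtype=np.int64)
    rows_all = np.arange(height, dtype=float)
    for ring in rings:
        x0 = ring[:, 0]
        y0 = ring[:, 1]
        x1 = np.roll(x0, -1)
        y1 = np.roll(y0, -1)
        keep = y0 != y1  # horizontal edges never cross a center row
        for ex0, ey0, ex1, ey1 in zip(x0[keep], y0[keep], x1[keep], y1[keep]):
            lo, hi = (ey0, ey1) if ey0 < ey1 else (ey1, ey0)
            r0 = max(0, int(np.ceil(lo)))
            if r0 < lo:  # ceil of an exact integer equals it; enforce lo <= row
                r0 += 1
            r1 = min(height - 1, int(np.ceil(hi)) - 1)
            if hi == np.floor(hi):  # half-open: row == max(y) excluded
                r1 = min(r1, int(hi) - 1)
            if r1 < r0:
                continue
            rows = rows_all[r0 : r1 + 1]
            xc = ex0 + (rows - ey0) * (ex1 - ex0) / (ey1 - ey0)
            # parity flips for centers strictly right of the crossing;
            # a center exactly on the crossing is taken as inside (flip at j)
            cols = np.floor(xc).astype(np.int64) + 1
            on_center = xc == np.floor(xc)
            cols[on_center] -= 1
            np.clip(cols, 0, width, out=cols)
            np.add.at(flips, (rows.astype(np.int64), cols), 1)
    parity = np.cumsum(flips[:, :width], axis=1) % 2
    return parity.astype(bool)


def roi_to_mask(roi: RegionOfInterest, frame: ImageFrame) -> BinaryMask:
    """Rasterize an ROI's even-odd fill on the frame's pixel-center lattice."""
    grid = rasterize_rings(roi.rings, frame.width, frame.height)
    return BinaryMask(grid=grid, frame=frame)


# ---------------------------------------------------------------------------
# Mask image I/O (8-bit grayscale PNG / TIFF; nonzero = true)
# ---------------------------------------------------------------------------

def read_mask_image(path: str | Path, frame: ImageFrame) -> BinaryMask:
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        arr = tifffile.imread(path)
    else:
        arr = iio.imread(path)
    arr = np.asarray(arr)
    if arr.ndim == 3:  # collapse any color/alpha channels
        arr = arr[..., : min(3, arr.shape[-1])].max(axis=-1)
    if arr.shape != (frame.height, frame.width):
        raise ShapeMismatchError(
            f"mask image {path.name} is {arr.shape}, frame expects "
            f"({frame.height}, {frame.width})"
        )
    return BinaryMask(grid=arr != 0, frame=frame)


def write_mask_image(mask: BinaryMask, path: str | Path) -> None:
    path = Path(path)
    arr = (mask.grid.astype(np.uint8)) * 255
    if path.suffix.lower() in {".tif", ".tiff"}:
        tifffile.imwrite(path, arr)
    else:
        iio.imwrite(path, arr)
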