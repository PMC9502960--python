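"""Landmark-based planar affine registration between modality frames.

The transform is the six-coefficient map

    [u]   [a00 a01 a02] [x]
    [v] = [a10 a11 a12] [y]
                        [1]

estimated from user-specified landmark pairs: exactly interpolating for
three non-collinear pairs, least-squares for more.  By convention the
ICGA frame is the moving image and the OCTA choriocapillaris frame is
fixed; all overlap computation then happens on the OCTA pixel grid.
ROIs are transformed as polygons (vertex mapping) rather than by warping
masks, avoiding a second rasterization error.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import (
    DegenerateLandmarksError,
    InsufficientLandmarksError,
    SingularTransformError,
)
from .roi_model import ImageFrame, Point2D, RegionOfInterest

__all__ = [
    "AffineTransform",
    "LandmarkPair",
    "RegistrationResult",
    "estimate_affine",
    "apply_to_point",
    "apply_to_points",
    "apply_to_roi",
    "warp_image",
    "read_landmarks_csv",
    "write_landmarks_csv",
]

#: moving landmarks closer to collinear than this singular-value ratio
#: (smallest / largest of the centered design) are rejected
COLLINEARITY_TOL = 1e-6


@dataclass(frozen=True)
class AffineTransform:
    a00: float
    a01: float
    a02: float
    a10: float
    a11: float
    a12: float

    def __post_init__(self) -> None:
        for name in ("a00", "a01", "a02", "a10", "a11", "a12"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"non-finite affine coefficient {name}")

    @classmethod
    def identity(cls) -> "AffineTransform":
        return cls(1.0, 0.0, 0.0, 0.0, 1.0, 0.0)

    @classmethod
    def from_matrix(cls, m: np.ndarray) -> "AffineTransform":
        m = np.asarray(m, dtype=float)
        return cls(m[0, 0], m[0, 1], m[0, 2], m[1, 0], m[1, 1], m[1, 2])

    def as_matrix(self) -> np.ndarray:
        """3x3 homogeneous matrix (last row [0, 0, 1])."""
        return np.array(
            [
                [self.a00, self.a01, self.a02],
                [self.a10, self.a11, self.a12],
                [0.0, 0.0, 1.0],
            ]
        )

    @property
    def det(self) -> float:
        """Determinant of the linear part; area scale factor is |det|."""
        return self.a00 * self.a11 - self.a01 * self.a10

    def compose(self, other: "AffineTransform") -> "AffineTransform":
        """Transform applying ``other`` first, then ``self``."""
        return AffineTransform.from_matrix(self.as_matrix() @ other.as_matrix())

    def invert(self) -> "AffineTransform":
        if abs(self.det) < 1e-300:
            raise SingularTransformError(
                f"linear part determinant {self.det} too small to invert"
            )
        return AffineTransform.from_matrix(np.linalg.inv(self.as_matrix()))

    def to_dict(self) -> dict[str, float]:
        return {k: float(getattr(self, k)) for k in ("a00", "a01", "a02", "a10", "a11", "a12")}

    @classmethod
    def from_dict(cls, d: dict[str, float]) -> "AffineTransform":
        return cls(**{k: float(d[k]) for k in ("a00", "a01", "a02", "a10", "a11", "a12")})

    def save_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def load_json(cls, path: str | Path) -> "AffineTransform":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass(frozen=True)
class LandmarkPair:
    """A matched point: ``moving`` on the ICGA frame, ``fixed`` on OCTA."""

    moving: Point2D
    fixed: Point2D


@dataclass(frozen=True)
class RegistrationResult:
    transform: AffineTransform
    rmse: float
    max_residual: float
    n_landmarks: int


def estimate_affine(pairs: list[LandmarkPair]) -> RegistrationResult:
    """Fit the affine minimizing sum ||T(moving_i) - fixed_i||^2.

    Three non-collinear pairs determine the transform exactly (residuals
    vanish to machine precision); more pairs give the least-squares fit.
    Raises if fewer than three pairs are given or the moving points are
    numerically collinear (conditioning ratio below COLLINEARITY_TOL).
    """
    if len(pairs) < 3:
        raise InsufficientLandmarksError(
            f"affine estimation needs >= 3 landmark pairs, got {len(pairs)}"
        )
    moving = np.array([[p.moving.x, p.moving.y] for p in pairs])
    fixed = np.array([[p.fixed.x, p.fixed.y] for p in pairs])

    centered = moving - moving.mean(axis=0)
    sv = np.linalg.svd(centered, compute_uv=False)
    if sv[0] == 0 or sv[-1] / sv[0] < COLLINEARITY_TOL:
        raise DegenerateLandmarksError(
            "moving landmarks are collinear or coincident "
            f"(singular-value ratio {0.0 if sv[0] == 0 else sv[-1] / sv[0]:.2e} "
            f"< {COLLINEARITY_TOL:g})"
        )

    design = np.column_stack([moving, np.ones(len(pairs))])
    coef, *_ = np.linalg.lstsq(design, fixed, rcond=None)
    t = AffineTransform(
        coef[0, 0], coef[1, 0], coef[2, 0], coef[0, 1], coef[1, 1], coef[2, 1]
    )
    mapped = apply_to_points(t, moving)
    res = np.linalg.norm(mapped - fixed, axis=1)
    return RegistrationResult(
        transform=t,
        rmse=float(np.sqrt(np.mean(res**2))),
        max_residual=float(res.max()),
        n_landmarks=len(pairs),
    )


def apply_to_points(t: AffineTransform, pts: np.ndarray) -> np.ndarray:
    """Map an (n, 2) array of (x, y) points through the affine."""
    pts = np.asarray(pts, dtype=float)
    lin = np.array([[t.a00, t.a01], [t.a10, t.a11]])
    return pts @ lin.T + np.array([t.a02, t.a12])


def apply_to_point(t: AffineTransform, p: Point2D) -> Point2D:
    u = t.a00 * p.x + t.a01 * p.y + t.a02
    v = t.a10 * p.x + t.a11 * p.y + t.a12
    return Point2D(u, v)


def apply_to_roi(
    t: AffineTransform,
    roi: RegionOfInterest,
    target_frame: ImageFrame | None = None,
) -> RegionOfInterest:
    """Map every ROI vertex through the affine, preserving ring structure.

    Label and grader carry over; ``frame`` is replaced by ``target_frame``
    when given.  Continuous area scales by |det| (before any clipping).
    """
    out = roi.relabel(frame=target_frame)
    out.rings = [apply_to_points(t, ring) for ring in roi.rings]
    return out


def warp_image(
    t: AffineTransform,
    image: np.ndarray,
    target_frame: ImageFrame,
    interpolation: str = "bilinear",
) -> np.ndarray:
    """Resample a moving-frame image onto the fixed target grid.

    Inverse warping: each target pixel center (u, v) is pulled back
    through t^-1 and the source image is sampled there (bilinear or
    nearest); samples outside the source fill with 0.
    """
    if interpolation not in ("nearest", "bilinear"):
        raise ValueError(f"unknown interpolation '{interpolation}'")
    inv = t.invert()
    uu, vv = np.meshgrid(
        np.arange(target_frame.width, dtype=float),
        np.arange(target_frame.height, dtype=float),
    )
    src = apply_to_points(inv, np.column_stack([uu.ravel(), vv.ravel()]))
    # map_coordinates indexes (row, col) = (y, x)
    coords = np.stack([src[:, 1], src[:, 0]])
    order = 0 if interpolation == "nearest" else 1
    out = ndimage.map_coordinates(
        np.asarray(image, dtype=float), coords, order=order, mode="constant", cval=0.0
    )
    return out.reshape(target_frame.height, target_frame.width)


def read_landmarks_csv(path: str | Path) -> list[LandmarkPair]:
    """Read landmark pairs from CSV with columns moving_x, moving_y, fixed_x, fixed_y."""
    df = pd.read_csv(path)
    required = {"moving_x", "moving_y", "fixed_x", "fixed_y"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"landmark CSV missing columns: {sorted(missing)}")
    return [
        LandmarkPair(
            moving=Point2D(row.moving_x, row.moving_y),
            fixed=Point2D(row.fixed_x, row.fixed_y),
        )
        for row in df.itertuples()
    ]


def write_landmarks_csv(pairs: list[LandmarkPair], path: str | Path) -> None:
    pd.DataFrame(
        {
            "moving_x": [p.moving.x for p in pairs],
            "moving_y": [p.moving.y for p in pairs],
            "fixed_x": [p.fixed.x for p in pairs],
            "fixed_y": [p.fixed.y for p in pairs],
        }
    ).to_csv(path, index=False)
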