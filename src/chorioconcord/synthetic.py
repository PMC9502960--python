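"""Ground-truthed synthetic paired-modality scenes.

Each scene emulates the geometry of a choriocapillaris lesion complex as
seen by the two modalities:

* OCTA frame (fixed): a star-convex type A hyper-reflective region with
  boundary r(theta) = r0 * (1 + sum_k a_k cos(k*theta + phi_k)); an
  optional type B halo as an annulus hugging the type A boundary; small
  type C hypo-reflective discs strictly inside type A.
* ICGA frame (moving): the mid-phase hyperfluorescence region is type A
  pushed through the inverse of the true inter-modality affine, with a
  controllable radial boundary discrepancy; early-phase hypofluorescence
  spots are shrunken copies of the type C discs (strictly smaller, as the
  OCTA lesion reads larger than its angiographic counterpart).

Landmarks on the two frames are related exactly by the true affine, and
simulated graders re-draw the true boundaries with smooth, angularly
correlated radial noise.  Two independent RNG streams (shape vs noise)
are derived from the master seed by fixed spawn keys, so appearance can
vary under fixed geometry and every output is bit-reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import ConfigurationError
from .imagej import write_roi_zip
from .registration import AffineTransform, LandmarkPair, apply_to_points
from .roi_model import (
    AnnotationSet,
    BinaryMask,
    ImageFrame,
    LesionType,
    Modality,
    Point2D,
    RegionOfInterest,
    TreatmentGroup,
    rasterize_rings,
    write_mask_image,
)

__all__ = [
    "SceneParams",
    "GroundTruthScene",
    "CohortParams",
    "CohortEye",
    "generate_scene",
    "render_images",
    "simulate_grader",
    "detect_landmarks",
    "generate_cohort",
    "write_scene_bundle",
    "random_affine",
    "DEFAULT_OCTA_FRAME",
    "DEFAULT_ICGA_FRAME",
]

DEFAULT_OCTA_FRAME = ImageFrame(1024, 1024, 12.0, 12.0, Modality.OCTA_CHORIOCAPILLARIS)
DEFAULT_ICGA_FRAME = ImageFrame(1024, 1024, 12.0, 12.0, Modality.ICGA_MID)

# fixed spawn keys for the per-scene RNG streams
_STREAM_SHAPE = 0
_STREAM_NOISE = 1
_STREAM_GRADER = 2


@dataclass(frozen=True)
class SceneParams:
    """Generator knobs; defaults are the package's study conditions.

    ``halo_present`` is the probability that the eye shows a type B halo
    (default 0.821, the prevalence observed clinically: 32/39 eyes).
    The random inter-modality affine stays within rotation +/-10 deg,
    isotropic scale 0.9-1.1 and translation +/-30 px unless
    ``true_affine`` pins it explicitly (mapping ICGA -> OCTA coords).
    """

    seed: int = 0
    frame: ImageFrame = DEFAULT_OCTA_FRAME
    icga_frame: ImageFrame = DEFAULT_ICGA_FRAME
    n_landmarks: int = 3
    true_affine: AffineTransform | None = None
    typeA_radius_mm: float = 1.5
    typeA_radius_jitter_mm: float = 0.3
    typeA_harmonics: int = 4
    typeA_harmonic_amp: float = 0.10
    halo_present: float = 0.821
    halo_width_mm: float = 0.35
    n_typeC_spots: int = 4
    spot_radius_mm: float = 0.16
    hypo_shrink: float = 0.6
    icga_boundary_sigma_px: float = 8.0
    grader_sigma_px: float = 4.0
    grader_corr_deg: float = 30.0
    noise_level: float = 0.15
    contrast: float = 60.0
    n_boundary_vertices: int = 256

    def __post_init__(self) -> None:
        halo = float(self.halo_present)
        if not 0.0 <= halo <= 1.0:
            raise ConfigurationError(f"halo_present must be in [0,1], got {halo}")
        for name in ("typeA_radius_mm", "halo_width_mm", "spot_radius_mm"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        if not 0 < self.hypo_shrink < 1:
            raise ConfigurationError(
                f"hypo_shrink must be in (0,1) so hypofluorescence spots are "
                f"strictly smaller than type C, got {self.hypo_shrink}"
            )
        if self.grader_sigma_px < 0 or self.icga_boundary_sigma_px < 0:
            raise ConfigurationError("boundary noise sigmas must be >= 0")
        min_radius = (self.typeA_radius_mm - self.typeA_radius_jitter_mm) * (
            1 - min(0.5, self.typeA_harmonics * self.typeA_harmonic_amp)
        )
        if self.n_typeC_spots > 0 and self.spot_radius_mm >= 0.5 * max(min_radius, 0.0):
            raise ConfigurationError(
                f"spot_radius_mm={self.spot_radius_mm} too large to fit strictly "
                f"inside a type A lesion of minimum radius ~{min_radius:.2f} mm"
            )

    @property
    def mm_per_px(self) -> float:
        return self.frame.fov_width_mm / self.frame.width


def random_affine(
    rng: np.random.Generator, center: tuple[float, float] = (512.0, 512.0)
) -> AffineTransform:
    """Random ICGA->OCTA affine within the generator's stated ranges.

    Rotation (+/-10 deg) and isotropic scale (0.9-1.1) act about the frame
    center, plus a +/-30 px translation, so frame content maps to frame
    content rather than pivoting about the corner origin.
    """
    theta = np.deg2rad(rng.uniform(-10.0, 10.0))
    s = rng.uniform(0.9, 1.1)
    tx, ty = rng.uniform(-30.0, 30.0, size=2)
    c, si = np.cos(theta), np.sin(theta)
    cx, cy = center
    # offset so that (cx, cy) maps to (cx + tx, cy + ty)
    a02 = cx + tx - (s * c * cx - s * si * cy)
    a12 = cy + ty - (s * si * cx + s * c * cy)
    return AffineTransform(s * c, -s * si, a02, s * si, s * c, a12)


def _perturb_rings_radial(
    rings: Sequence[np.ndarray],
    sigma_px: float,
    rng: np.random.Generator,
    corr_deg: float = 30.0,
) -> list[np.ndarray]:
    """Radially displace all rings of one ROI by a shared angular noise field."""
    if sigma_px == 0:
        return [r.copy() for r in rings]
    center = rings[0].mean(axis=0)
    out = []
    noise_grid_rng = rng
    # one field per ROI so nested rings (annuli) move together
    g = noise_grid_rng.standard_normal(360)
    if corr_deg > 0:
        half_width = corr_deg / 2.0
        k = np.exp(-0.5 * ((np.arange(360) - 180) / half_width) ** 2)
        g = np.real(np.fft.ifft(np.fft.fft(g) * np.fft.fft(np.fft.ifftshift(k))))
        g /= np.linalg.norm(k)
    grid = np.linspace(0.0, 2 * np.pi, 360, endpoint=False)
    for ring in rings:
        d = ring - center
        radii = np.hypot(d[:, 0], d[:, 1])
        ang = np.mod(np.arctan2(d[:, 1], d[:, 0]), 2 * np.pi)
        noise = np.interp(ang, grid, g, period=2 * np.pi)
        new_r = np.maximum(radii + sigma_px * noise, 0.05 * np.median(radii))
        out.append(
            np.column_stack([center[0] + new_r * np.cos(ang), center[1] + new_r * np.sin(ang)])
        )
    return out


def simulate_grader(
    true_roi: RegionOfInterest,
    sigma_px: float,
    seed: int | np.random.Generator,
    corr_deg: float = 30.0,
) -> RegionOfInterest:
    """A simulated observer re-drawing a true boundary.

    The boundary is displaced radially (about the ROI centroid) by a
    smooth angularly correlated Gaussian field of standard deviation
    ``sigma_px`` and correlation length ``corr_deg`` degrees; the radius
    is clipped away from zero so the polygon stays simple.  sigma 0
    reproduces the truth exactly.
    """
    if sigma_px < 0:
        raise ConfigurationError(f"grader sigma must be >= 0, got {sigma_px}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rings = _perturb_rings_radial(true_roi.rings, sigma_px, rng, corr_deg)
    out = true_roi.with_rings(rings)
    return out


def _circle(center: np.ndarray, radius: float, n: int = 64) -> np.ndarray:
    th = np.linspace(0.0, 2 * np.pi, n, endpoint=False)
    return np.column_stack([center[0] + radius * np.cos(th), center[1] + radius * np.sin(th)])


def _scale_rings(rings: list[np.ndarray], factor: float, center: np.ndarray) -> list[np.ndarray]:
    return [center + factor * (r - center) for r in rings]


@dataclass
class GroundTruthScene:
    """A paired-modality scene with exact ground truth.

    Polygons on the OCTA frame: ``type_a`` (one ring), ``type_b`` (annulus,
    two rings; None when the eye has no halo), ``type_c`` (one ring per
    spot).  Polygons on the ICGA frame: ``hyper`` and ``hypo``.
    ``true_affine`` maps ICGA (moving) to OCTA (fixed) coordinates and
    relates the landmark pairs exactly.  ``analytic_areas_mm2`` holds the
    closed-form areas of the generating shapes.
    """

    params: SceneParams
    true_affine: AffineTransform
    type_a: RegionOfInterest
    type_b: RegionOfInterest | None
    type_c: RegionOfInterest | None
    hyper: RegionOfInterest
    hypo: RegionOfInterest | None
    landmarks: list[LandmarkPair]
    analytic_areas_mm2: dict[str, float] = field(default_factory=dict)

    @property
    def seed(self) -> int:
        return self.params.seed

    def truth_mask(self, label: LesionType) -> BinaryMask:
        roi = {
            LesionType.TYPE_A: self.type_a,
            LesionType.TYPE_B: self.type_b,
            LesionType.TYPE_C: self.type_c,
            LesionType.HYPERFLUORESCENCE: self.hyper,
            LesionType.HYPOFLUORESCENCE: self.hypo,
        }[label]
        frame = (
            self.params.frame
            if label in (LesionType.TYPE_A, LesionType.TYPE_B, LesionType.TYPE_C)
            else self.params.icga_frame
        )
        if roi is None:
            return BinaryMask(np.zeros((frame.height, frame.width), bool), frame)
        return BinaryMask(rasterize_rings(roi.rings, frame.width, frame.height), frame)

    def truth_annotations(
        self, eye_id: str = "eye", timepoint: int = 0, grader: str = "truth",
        group: TreatmentGroup | None = None,
    ) -> tuple[AnnotationSet, AnnotationSet]:
        """(OCTA set, ICGA set) holding the exact true boundaries."""
        octa_rois = [self.type_a.relabel(LesionType.TYPE_A, grader, self.params.frame)]
        if self.type_b is not None:
            octa_rois.append(self.type_b.relabel(LesionType.TYPE_B, grader, self.params.frame))
        if self.type_c is not None:
            octa_rois.append(self.type_c.relabel(LesionType.TYPE_C, grader, self.params.frame))
        icga_rois = [
            self.hyper.relabel(LesionType.HYPERFLUORESCENCE, grader, self.params.icga_frame)
        ]
        if self.hypo is not None:
            icga_rois.append(
                self.hypo.relabel(LesionType.HYPOFLUORESCENCE, grader, self.params.icga_frame)
            )
        octa = AnnotationSet(eye_id, timepoint, grader, octa_rois, group)
        icga = AnnotationSet(eye_id, timepoint, grader, icga_rois, group)
        return octa, icga

    def grader_annotations(
        self,
        grader: str,
        grader_index: int = 0,
        sigma_px: float | None = None,
        eye_id: str = "eye",
        timepoint: int = 0,
        group: TreatmentGroup | None = None,
    ) -> tuple[AnnotationSet, AnnotationSet]:
        """(OCTA set, ICGA set) re-drawn by a simulated grader.

        The grader's noise stream is derived from the scene seed and
        ``grader_index`` by a fixed spawn key, so the same grader always
        re-draws the same scene the same way.
        """
        sigma = self.params.grader_sigma_px if sigma_px is None else sigma_px
        rng = np.random.default_rng([self.params.seed, _STREAM_GRADER, grader_index])
        octa_t, icga_t = self.truth_annotations(eye_id, timepoint, grader, group)
        corr = self.params.grader_corr_deg

        def redraw(roi: RegionOfInterest) -> RegionOfInterest:
            return simulate_grader(roi, sigma, rng, corr)

        octa = AnnotationSet(eye_id, timepoint, grader, [redraw(r) for r in octa_t.rois], group)
        icga = AnnotationSet(eye_id, timepoint, grader, [redraw(r) for r in icga_t.rois], group)
        return octa, icga

    def scaled(self, radius_factor: float) -> "GroundTruthScene":
        """Same scene with every lesion rescaled about its own center.

        Models follow-up shrinkage (or growth): areas scale by
        radius_factor**2; landmarks, affine and frames are unchanged.
        """
        if radius_factor <= 0:
            raise ConfigurationError("radius_factor must be positive")
        ca = self.type_a.rings[0].mean(axis=0)
        ch = self.hyper.rings[0].mean(axis=0)

        def scale_roi(roi: RegionOfInterest | None, center: np.ndarray):
            if roi is None:
                return None
            return roi.with_rings(_scale_rings(roi.rings, radius_factor, center))

        areas = {k: v * radius_factor**2 for k, v in self.analytic_areas_mm2.items()}
        return GroundTruthScene(
            params=self.params,
            true_affine=self.true_affine,
            type_a=scale_roi(self.type_a, ca),
            type_b=scale_roi(self.type_b, ca),
            type_c=scale_roi(self.type_c, ca),
            hyper=scale_roi(self.hyper, ch),
            hypo=scale_roi(self.hypo, ch),
            landmarks=self.landmarks,
            analytic_areas_mm2=areas,
        )


def _star_boundary(
    center: np.ndarray,
    r0: float,
    amps: np.ndarray,
    phases: np.ndarray,
    n_vertices: int,
    radial_offset: float = 0.0,
) -> np.ndarray:
    th = np.linspace(0.0, 2 * np.pi, n_vertices, endpoint=False)
    r = r0 * np.ones_like(th)
    for k, (a, ph) in enumerate(zip(amps, phases), start=1):
        r = r + r0 * a * np.cos(k * th + ph)
    r = r + radial_offset
    if np.any(r <= 0):
        raise ConfigurationError("harmonic amplitudes too large: boundary radius <= 0")
    return np.column_stack([center[0] + r * np.cos(th), center[1] + r * np.sin(th)])


def generate_scene(params: SceneParams) -> GroundTruthScene:
    """Build one deterministic ground-truth scene from its parameters."""
    shape_rng = np.random.default_rng([params.seed, _STREAM_SHAPE])
    frame = params.frame
    mmpp = params.mm_per_px

    # --- type A star-convex boundary on the OCTA frame
    cx = frame.width / 2 + shape_rng.uniform(-0.04, 0.04) * frame.width
    cy = frame.height / 2 + shape_rng.uniform(-0.04, 0.04) * frame.height
    center = np.array([cx, cy])
    r0_mm = params.typeA_radius_mm + shape_rng.uniform(-1, 1) * params.typeA_radius_jitter_mm
    r0_mm = max(r0_mm, 0.3 * params.typeA_radius_mm)
    r0 = r0_mm / mmpp
    k = params.typeA_harmonics
    amps = (
        params.typeA_harmonic_amp * shape_rng.uniform(-1, 1, size=k) / np.arange(1, k + 1)
        if k > 0
        else np.zeros(0)
    )
    phases = shape_rng.uniform(0, 2 * np.pi, size=k)
    ring_a = _star_boundary(center, r0, amps, phases, params.n_boundary_vertices)
    type_a = RegionOfInterest([ring_a])
    area_a_mm2 = np.pi * r0_mm**2 * (1 + 0.5 * float((amps**2).sum()))

    # --- type B halo: annulus hugging the type A boundary (even-odd rings)
    halo_p = float(params.halo_present)
    has_halo = bool(shape_rng.random() < halo_p)
    type_b = None
    halo_w_px = params.halo_width_mm / mmpp
    if has_halo:
        outer = _star_boundary(
            center, r0, amps, phases, params.n_boundary_vertices, radial_offset=halo_w_px
        )
        type_b = RegionOfInterest([outer, ring_a.copy()])

    # --- type C spots strictly inside type A
    type_c = None
    spot_r_px = params.spot_radius_mm / mmpp
    min_r = r0 * (1 - float(np.abs(amps).sum())) if k > 0 else r0
    spot_rings = []
    spot_area = 0.0
    for _ in range(params.n_typeC_spots):
        ang = shape_rng.uniform(0, 2 * np.pi)
        rad = shape_rng.uniform(0, max(min_r * 0.75 - 1.5 * spot_r_px, 0.0))
        c = center + rad * np.array([np.cos(ang), np.sin(ang)])
        spot_rings.append(_circle(c, spot_r_px))
        spot_area += np.pi * params.spot_radius_mm**2
    if spot_rings:
        type_c = RegionOfInterest(spot_rings)

    # --- inter-modality affine (ICGA -> OCTA) and ICGA-side truth
    t = (
        params.true_affine
        if params.true_affine is not None
        else random_affine(shape_rng, center=(frame.width / 2.0, frame.height / 2.0))
    )
    t_inv = t.invert()
    hyper_ring = apply_to_points(t_inv, ring_a)
    if params.icga_boundary_sigma_px > 0:
        hyper_ring = _perturb_rings_radial(
            [hyper_ring], params.icga_boundary_sigma_px, shape_rng, corr_deg=30.0
        )[0]
    hyper = RegionOfInterest([hyper_ring])

    hypo = None
    if spot_rings:
        hypo_rings = []
        for ring in spot_rings:
            mapped = apply_to_points(t_inv, ring)
            c = mapped.mean(axis=0)
            hypo_rings.append(c + params.hypo_shrink * (mapped - c))
        hypo = RegionOfInterest(hypo_rings)

    # --- landmarks: well-separated, non-collinear by construction; margin
    # large enough that the inverse affine keeps them inside the ICGA frame
    margin = 0.15 * min(frame.width, frame.height)
    min_dist = 0.2 * min(frame.width, frame.height)
    min_tri = 0.02 * frame.width * frame.height
    for _attempt in range(1000):
        fixed_pts = shape_rng.uniform(
            [margin, margin],
            [frame.width - margin, frame.height - margin],
            size=(params.n_landmarks, 2),
        )
        d = np.linalg.norm(fixed_pts[:, None] - fixed_pts[None, :], axis=-1)
        if params.n_landmarks > 1 and d[np.triu_indices(params.n_landmarks, 1)].min() < min_dist:
            continue
        p0, p1, p2 = fixed_pts[0], fixed_pts[1], fixed_pts[2]
        u, v = p1 - p0, p2 - p0
        tri = 0.5 * abs(u[0] * v[1] - u[1] * v[0])
        if tri < min_tri:
            continue
        break
    else:  # pragma: no cover - rejection sampling effectively always succeeds
        raise ConfigurationError("could not place well-separated landmarks")
    moving_pts = apply_to_points(t_inv, fixed_pts)
    landmarks = [
        LandmarkPair(moving=Point2D(*m), fixed=Point2D(*f))
        for m, f in zip(moving_pts, fixed_pts)
    ]

    areas = {
        "type_a": area_a_mm2,
        "type_c": spot_area,
        "hypo": spot_area * params.hypo_shrink**2 * abs(t_inv.det),
    }
    if has_halo:
        # annulus between r(theta) and r(theta)+w: integrates to pi*(2*r0*w + w^2)
        w_mm = params.halo_width_mm
        areas["type_b"] = np.pi * (2 * r0_mm * w_mm + w_mm**2)

    return GroundTruthScene(
        params=params,
        true_affine=t,
        type_a=type_a,
        type_b=type_b,
        type_c=type_c,
        hyper=hyper,
        hypo=hypo,
        landmarks=landmarks,
        analytic_areas_mm2=areas,
    )


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

_BACKGROUND = 60.0
_SUPPRESSED = 25.0
_MARKER_AMP = 600.0  # saturates to white; symmetric so centroids stay exact
_MARKER_ARM = 7.0
_MARKER_THICKNESS = 0.9


def _add_cross(img: np.ndarray, x: float, y: float) -> None:
    """Splat a sub-pixel cross marker (two perpendicular Gaussian bars)."""
    h, w = img.shape
    r = int(np.ceil(3 * _MARKER_ARM))
    j0, j1 = max(0, int(x) - r), min(w, int(x) + r + 1)
    i0, i1 = max(0, int(y) - r), min(h, int(y) + r + 1)
    if j0 >= j1 or i0 >= i1:
        return
    jj, ii = np.meshgrid(np.arange(j0, j1, dtype=float), np.arange(i0, i1, dtype=float))
    dx, dy = jj - x, ii - y
    long_sq = 2 * _MARKER_ARM**2
    thin_sq = 2 * _MARKER_THICKNESS**2
    bar_h = np.exp(-(dx**2) / long_sq - (dy**2) / thin_sq)
    bar_v = np.exp(-(dx**2) / thin_sq - (dy**2) / long_sq)
    img[i0:i1, j0:j1] += _MARKER_AMP * np.maximum(bar_h, bar_v)


def render_images(scene: GroundTruthScene) -> tuple[np.ndarray, np.ndarray]:
    """Render (OCTA, ICGA) uint8 grayscale rasters for a scene.

    OCTA: elevated mean inside type A, suppressed inside type B and C,
    granular multiplicative speckle.  ICGA: blurred bright
    hyperfluorescence, dark hypofluorescence spots, milder noise.
    Landmarks appear as bright sub-pixel crosses in both frames.
    The noise stream is independent of the shape stream, so two seeds
    can share geometry while differing in appearance.
    """
    p = scene.params
    noise_rng = np.random.default_rng([p.seed, _STREAM_NOISE])

    octa = np.full((p.frame.height, p.frame.width), _BACKGROUND)
    mask_a = scene.truth_mask(LesionType.TYPE_A).grid
    octa[mask_a] = _BACKGROUND + p.contrast
    if scene.type_b is not None:
        octa[scene.truth_mask(LesionType.TYPE_B).grid] = _SUPPRESSED
    if scene.type_c is not None:
        octa[scene.truth_mask(LesionType.TYPE_C).grid] = _SUPPRESSED
    octa = ndimage.gaussian_filter(octa, 1.0)
    if p.noise_level > 0:
        octa *= 1.0 + p.noise_level * noise_rng.standard_normal(octa.shape)

    icga = np.full((p.icga_frame.height, p.icga_frame.width), _BACKGROUND)
    icga[scene.truth_mask(LesionType.HYPERFLUORESCENCE).grid] = _BACKGROUND + p.contrast
    if scene.hypo is not None:
        icga[scene.truth_mask(LesionType.HYPOFLUORESCENCE).grid] = _SUPPRESSED
    icga = ndimage.gaussian_filter(icga, 2.0)
    if p.noise_level > 0:
        icga *= 1.0 + 0.5 * p.noise_level * noise_rng.standard_normal(icga.shape)

    for lm in scene.landmarks:
        _add_cross(octa, lm.fixed.x, lm.fixed.y)
        _add_cross(icga, lm.moving.x, lm.moving.y)

    return (
        np.clip(octa, 0, 255).astype(np.uint8),
        np.clip(icga, 0, 255).astype(np.uint8),
    )


def _marker_template(half: int = 12) -> np.ndarray:
    """Zero-mean matched-filter template of the rendered cross marker."""
    ax = np.arange(-half, half + 1, dtype=float)
    dx, dy = np.meshgrid(ax, ax)
    long_sq = 2 * _MARKER_ARM**2
    thin_sq = 2 * _MARKER_THICKNESS**2
    t = np.maximum(
        np.exp(-(dx**2) / long_sq - (dy**2) / thin_sq),
        np.exp(-(dx**2) / thin_sq - (dy**2) / long_sq),
    )
    return t - t.mean()


def detect_landmarks(
    image: np.ndarray, approx: np.ndarray, window: int = 18
) -> np.ndarray:
    """Refine approximate marker positions by matched-filter correlation.

    Each window is correlated with the zero-mean cross template; the
    correlation peak is refined to sub-pixel precision by a quadratic fit
    to its 3x3 neighborhood.  The zero-mean template suppresses the slowly
    varying lesion background under the marker.
    """
    from scipy import signal

    img = np.asarray(image, dtype=float)
    h, w = img.shape
    tpl = _marker_template()
    out = np.zeros_like(np.asarray(approx, dtype=float))
    for i, (x, y) in enumerate(np.asarray(approx, dtype=float)):
        j0, j1 = max(0, int(round(x)) - window), min(w, int(round(x)) + window + 1)
        i0, i1 = max(0, int(round(y)) - window), min(h, int(round(y)) + window + 1)
        crop = img[i0:i1, j0:j1]
        if crop.size == 0 or min(crop.shape) < 5:
            out[i] = (x, y)
            continue
        corr = signal.fftconvolve(crop, tpl[::-1, ::-1], mode="same")
        ci, cj = np.unravel_index(np.argmax(corr), corr.shape)
        # quadratic sub-pixel refinement (guard the window border)
        if 0 < ci < corr.shape[0] - 1:
            denom = 2 * corr[ci, cj] - corr[ci - 1, cj] - corr[ci + 1, cj]
            di = 0.5 * (corr[ci + 1, cj] - corr[ci - 1, cj]) / denom if denom != 0 else 0.0
        else:
            di = 0.0
        if 0 < cj < corr.shape[1] - 1:
            denom = 2 * corr[ci, cj] - corr[ci, cj - 1] - corr[ci, cj + 1]
            dj = 0.5 * (corr[ci, cj + 1] - corr[ci, cj - 1]) / denom if denom != 0 else 0.0
        else:
            dj = 0.0
        out[i] = (j0 + cj + np.clip(dj, -1, 1), i0 + ci + np.clip(di, -1, 1))
    return out


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CohortParams:
    """Study-level design for a synthetic longitudinal cohort.

    Shrinkage factors act on lesion *radius* between baseline and
    follow-up (area scales with their square).  The default 0.68 for
    both groups reproduces the observed ~0.46 area ratio after treatment
    or observation, with no built-in group difference.
    """

    n_eyes: int = 39
    shrinkage: dict = field(
        default_factory=lambda: {TreatmentGroup.LASER: 0.68, TreatmentGroup.OBSERVATION: 0.68}
    )
    graders: tuple[str, str] = ("grader1", "grader2")
    scene_template: SceneParams = field(default_factory=SceneParams)
    followup_timepoint: int = 1

    def __post_init__(self) -> None:
        if self.n_eyes < 2:
            raise ConfigurationError("a cohort needs >= 2 eyes")


@dataclass
class CohortEye:
    eye_id: str
    group: TreatmentGroup
    scenes: dict[int, GroundTruthScene]  # timepoint -> scene


def generate_cohort(
    n_eyes: int | None = None,
    cohort_params: CohortParams | None = None,
    seed: int = 0,
) -> tuple[list[CohortEye], pd.DataFrame]:
    """Generate a balanced two-group cohort with baseline + follow-up scenes.

    Each eye gets its own scene seed derived from the cohort seed; the
    follow-up scene is the baseline geometry with all lesions rescaled by
    the group's radius shrinkage factor.  Returns the eyes and a visit
    manifest (eye_id, timepoint, group, scene seed, shrinkage).
    """
    cp = cohort_params or CohortParams()
    if n_eyes is not None:
        cp = replace(cp, n_eyes=n_eyes)
    rng = np.random.default_rng([seed, 314159])
    groups = [TreatmentGroup.LASER, TreatmentGroup.OBSERVATION] * ((cp.n_eyes + 1) // 2)
    groups = groups[: cp.n_eyes]
    rng.shuffle(groups)  # type: ignore[arg-type]

    eyes: list[CohortEye] = []
    rows = []
    for i in range(cp.n_eyes):
        eye_id = f"eye{i:03d}"
        group = groups[i]
        scene_seed = int(rng.integers(0, 2**31 - 1))
        sp = replace(cp.scene_template, seed=scene_seed)
        baseline = generate_scene(sp)
        factor = float(cp.shrinkage[group])
        followup = baseline.scaled(factor)
        eyes.append(
            CohortEye(eye_id, group, {0: baseline, cp.followup_timepoint: followup})
        )
        for tp, shrink in ((0, 1.0), (cp.followup_timepoint, factor)):
            rows.append(
                {
                    "eye_id": eye_id,
                    "timepoint": tp,
                    "group": group.value,
                    "scene_seed": scene_seed,
                    "radius_factor": shrink,
                }
            )
    return eyes, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Scene bundle on disk
# ---------------------------------------------------------------------------

def write_scene_bundle(scene: GroundTruthScene, out_dir: str | Path) -> dict[str, str]:
    """Write one scene to disk: images, truth masks, ROIs, landmarks, truth JSON.

    Returns a mapping of artifact name -> file path (relative to out_dir).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    octa_img, icga_img = render_images(scene)

    import imageio.v3 as iio

    files: dict[str, str] = {}
    iio.imwrite(out / "octa.png", octa_img)
    iio.imwrite(out / "icga.png", icga_img)
    files["octa_image"] = "octa.png"
    files["icga_image"] = "icga.png"

    for label in LesionType:
        mask = scene.truth_mask(label)
        name = f"mask_{label.value}.png"
        write_mask_image(mask, out / name)
        files[f"mask_{label.value}"] = name

    octa_set, icga_set = scene.truth_annotations()
    rois = octa_set.rois + icga_set.rois
    names = [f"{r.label.value}.roi" for r in rois]
    write_roi_zip(rois, out / "truth_rois.zip", names)
    files["truth_rois"] = "truth_rois.zip"

    pd.DataFrame(
        {
            "moving_x": [lm.moving.x for lm in scene.landmarks],
            "moving_y": [lm.moving.y for lm in scene.landmarks],
            "fixed_x": [lm.fixed.x for lm in scene.landmarks],
            "fixed_y": [lm.fixed.y for lm in scene.landmarks],
        }
    ).to_csv(out / "landmarks.csv", index=False)
    files["landmarks"] = "landmarks.csv"

    p = scene.params
    truth = {
        "seed": p.seed,
        "true_affine": scene.true_affine.to_dict(),
        "analytic_areas_mm2": scene.analytic_areas_mm2,
        "frame": {
            "width": p.frame.width,
            "height": p.frame.height,
            "fov_width_mm": p.frame.fov_width_mm,
            "fov_height_mm": p.frame.fov_height_mm,
        },
        "icga_frame": {
            "width": p.icga_frame.width,
            "height": p.icga_frame.height,
            "fov_width_mm": p.icga_frame.fov_width_mm,
            "fov_height_mm": p.icga_frame.fov_height_mm,
        },
        "params": {
            "typeA_radius_mm": p.typeA_radius_mm,
            "halo_present": float(p.halo_present),
            "n_typeC_spots": p.n_typeC_spots,
            "icga_boundary_sigma_px": p.icga_boundary_sigma_px,
            "grader_sigma_px": p.grader_sigma_px,
            "noise_level": p.noise_level,
        },
    }
    (out / "truth.json").write_text(json.dumps(truth, indent=2))
    files["truth"] = "truth.json"
    return files
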