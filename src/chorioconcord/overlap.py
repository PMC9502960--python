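"""Jaccard-index overlap between co-registered lesion annotations.

JI = |A ∩ B| / |A ∪ B| for two regions A, B drawn on a common fixed
frame: cross-modality concordance (OCTA type A vs registered ICGA
hyperfluorescence) and interobserver agreement (same frame, two graders).

Two computation routes are provided and cross-checked: RASTER counts
pixel centers on the fixed frame's lattice (the primary route — manual
annotations are pixel-resolution objects), POLYGON clips the continuous
even-odd fills exactly and serves as the analytic oracle.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np

from .errors import (
    EmptyInputError,
    MissingAnnotationError,
    UndefinedOverlapError,
    ChorioconcordError,
)
from .registration import AffineTransform, apply_to_roi
from .roi_model import (
    AnnotationSet,
    ImageFrame,
    LesionType,
    RegionOfInterest,
    roi_geometry,
    roi_to_mask,
)

__all__ = [
    "OverlapMethod",
    "OverlapResult",
    "jaccard_index",
    "crossmodal_concordance",
    "interobserver_agreement",
    "cohort_ji_summary",
]


class OverlapMethod(enum.Enum):
    RASTER = "raster"
    POLYGON = "polygon"


@dataclass
class OverlapResult:
    """Intersection/union areas and Jaccard index for one ROI pair."""

    area_a_px: float
    area_b_px: float
    intersection_px: float
    union_px: float
    jaccard: float
    method: OverlapMethod
    frame: ImageFrame
    metadata: dict = field(default_factory=dict)

    @property
    def area_a_mm2(self) -> float:
        return self.frame.px2_to_mm2(self.area_a_px)

    @property
    def area_b_mm2(self) -> float:
        return self.frame.px2_to_mm2(self.area_b_px)

    @property
    def intersection_mm2(self) -> float:
        return self.frame.px2_to_mm2(self.intersection_px)

    @property
    def union_mm2(self) -> float:
        return self.frame.px2_to_mm2(self.union_px)


def jaccard_index(
    a: RegionOfInterest,
    b: RegionOfInterest,
    frame: ImageFrame,
    method: OverlapMethod = OverlapMethod.RASTER,
) -> OverlapResult:
    """Overlap of two annotations already expressed in the same frame.

    The caller registers first; no transform is applied here.  An empty
    union is an error, not JI = 0 — a missing lesion must surface loudly.
    """
    if method is OverlapMethod.RASTER:
        ga = roi_to_mask(a, frame).grid
        gb = roi_to_mask(b, frame).grid
        area_a = float(ga.sum())
        area_b = float(gb.sum())
        inter = float(np.logical_and(ga, gb).sum())
        union = float(np.logical_or(ga, gb).sum())
    else:
        geo_a = roi_geometry(a)
        geo_b = roi_geometry(b)
        area_a = float(geo_a.area)
        area_b = float(geo_b.area)
        # canonical operand order: polygon clipping is symmetric only up to
        # the last ulp, and JI must be exactly symmetric in (a, b)
        first, second = sorted((geo_a, geo_b), key=lambda g: g.wkb)
        inter = float(first.intersection(second).area)
        union = area_a + area_b - inter
    if union <= 0:
        raise UndefinedOverlapError(
            "both regions are empty on this frame; Jaccard index is undefined"
        )
    return OverlapResult(
        area_a_px=area_a,
        area_b_px=area_b,
        intersection_px=inter,
        union_px=union,
        jaccard=inter / union,
        method=method,
        frame=frame,
    )


def crossmodal_concordance(
    octa_set: AnnotationSet,
    icga_set: AnnotationSet,
    t: AffineTransform,
    frame: ImageFrame,
    method: OverlapMethod = OverlapMethod.RASTER,
) -> OverlapResult:
    """JI between OCTA type A and the registered ICGA hyperfluorescence.

    ``t`` maps ICGA (moving) coordinates onto the fixed OCTA frame; the
    hyperfluorescence ROI is transformed as a polygon and the overlap is
    measured on the OCTA grid.
    """
    roi_a = octa_set.roi_for(LesionType.TYPE_A)
    if roi_a is None:
        raise MissingAnnotationError(
            f"OCTA set ({octa_set.eye_id}, grader {octa_set.grader}) lacks a "
            f"{LesionType.TYPE_A.name} annotation"
        )
    roi_h = icga_set.roi_for(LesionType.HYPERFLUORESCENCE)
    if roi_h is None:
        raise MissingAnnotationError(
            f"ICGA set ({icga_set.eye_id}, grader {icga_set.grader}) lacks a "
            f"{LesionType.HYPERFLUORESCENCE.name} annotation"
        )
    res = jaccard_index(roi_a, apply_to_roi(t, roi_h, frame), frame, method)
    res.metadata.update(
        eye_id=octa_set.eye_id,
        timepoint=octa_set.timepoint,
        grader=octa_set.grader,
        comparison="octa_type_a_vs_icga_hyperfluorescence",
    )
    return res


def interobserver_agreement(
    set_g1: AnnotationSet,
    set_g2: AnnotationSet,
    frame: ImageFrame,
    label: LesionType,
    method: OverlapMethod = OverlapMethod.RASTER,
) -> OverlapResult:
    """JI between two graders' annotations of the same label on one frame.

    No registration is applied — both graders annotate the same image.
    """
    if set_g1.grader == set_g2.grader:
        raise ChorioconcordError(
            f"interobserver agreement needs two distinct graders, both are "
            f"'{set_g1.grader}'"
        )
    rois = []
    for s in (set_g1, set_g2):
        roi = s.roi_for(label)
        if roi is None:
            raise MissingAnnotationError(
                f"annotation set ({s.eye_id}, grader {s.grader}) lacks a "
                f"{label.name} annotation"
            )
        rois.append(roi)
    res = jaccard_index(rois[0], rois[1], frame, method)
    res.metadata.update(
        eye_id=set_g1.eye_id,
        timepoint=set_g1.timepoint,
        graders=(set_g1.grader, set_g2.grader),
        label=label.name,
        comparison="interobserver",
    )
    return res


def cohort_ji_summary(results: list[OverlapResult]) -> dict:
    """Mean ± sample SD of Jaccard indices over a cohort.

    SD uses the n-1 denominator; with a single value it is reported as
    0.0 together with an ``n_is_one`` flag.
    """
    if not results:
        raise EmptyInputError("cannot summarize an empty list of overlap results")
    ji = np.array([r.jaccard for r in results], dtype=float)
    n = len(ji)
    return {
        "mean": float(ji.mean()),
        "sd": float(ji.std(ddof=1)) if n > 1 else 0.0,
        "n": n,
        "n_is_one": n == 1,
    }
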