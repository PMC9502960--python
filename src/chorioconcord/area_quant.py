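"""Physical lesion-area measurement and cohort summary statistics.

Annotation areas are measured on the continuous polygon fill (px^2) and
converted to mm^2 through the frame's field of view.  Summaries follow
the standard clinical reporting forms — mean ± SD or median (IQR) with
type-7 (linearly interpolated) percentiles — and paired comparisons use
Student's t or the Wilcoxon signed-rank test; the caller chooses the
test explicitly (Wilcoxon is the default for areas, which are typically
right-skewed).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from ._stats import wilcoxon_signed_rank
from .errors import ConfigurationError, EmptyInputError
from .roi_model import AnnotationSet, ImageFrame, LesionType, TreatmentGroup, polygon_area_px

__all__ = [
    "StatisticKind",
    "PairedTest",
    "AreaMeasurement",
    "CohortSummary",
    "PairedTestResult",
    "measure_areas",
    "summarize",
    "compare_paired_areas",
    "measurements_to_frame",
]


class StatisticKind(enum.Enum):
    MEAN_SD = "mean_sd"
    MEDIAN_IQR = "median_iqr"


class PairedTest(enum.Enum):
    T_TEST = "t_test"
    WILCOXON = "wilcoxon"


@dataclass(frozen=True)
class AreaMeasurement:
    eye_id: str
    timepoint: int
    label: LesionType
    grader: str
    area_px: float
    area_mm2: float
    group: TreatmentGroup | None = None


@dataclass(frozen=True)
class CohortSummary:
    label: LesionType | None
    statistic_kind: StatisticKind
    center: float
    spread_low: float
    spread_high: float
    n: int
    n_is_one: bool = False


@dataclass(frozen=True)
class PairedTestResult:
    test: PairedTest
    statistic: float
    p_value: float
    n: int
    df: int | None = None
    n_zeros_dropped: int = 0
    exact: bool | None = None


def measure_areas(annotation_set: AnnotationSet, frame: ImageFrame) -> list[AreaMeasurement]:
    """One physical-area measurement per ROI in the set (polygon area)."""
    if frame.px_area_mm2 <= 0:
        raise ConfigurationError("frame has zero physical pixel area")
    out = []
    for roi in annotation_set.rois:
        area_px = polygon_area_px(roi)
        out.append(
            AreaMeasurement(
                eye_id=annotation_set.eye_id,
                timepoint=annotation_set.timepoint,
                label=roi.label,
                grader=annotation_set.grader,
                area_px=area_px,
                area_mm2=frame.px2_to_mm2(area_px),
                group=annotation_set.group,
            )
        )
    return out


def summarize(
    values,
    statistic_kind: StatisticKind = StatisticKind.MEDIAN_IQR,
    label: LesionType | None = None,
) -> CohortSummary:
    """Cohort summary of a list of measurements or raw numbers.

    MEAN_SD: arithmetic mean, spread = mean -/+ sample SD (ddof=1; SD
    reported 0 with an n=1 flag).  MEDIAN_IQR: median with 25th/75th
    percentiles under linear interpolation between order statistics.
    """
    arr = np.asarray(
        [v.area_mm2 if isinstance(v, AreaMeasurement) else float(v) for v in values],
        dtype=float,
    )
    if arr.size == 0:
        raise EmptyInputError("cannot summarize an empty measurement list")
    n = int(arr.size)
    if statistic_kind is StatisticKind.MEAN_SD:
        sd = float(arr.std(ddof=1)) if n > 1 else 0.0
        center = float(arr.mean())
        return CohortSummary(label, statistic_kind, center, center - sd, center + sd, n, n == 1)
    q25, q50, q75 = np.percentile(arr, [25, 50, 75])  # numpy default = type-7
    return CohortSummary(label, statistic_kind, float(q50), float(q25), float(q75), n, n == 1)


def compare_paired_areas(x, y, test: PairedTest = PairedTest.WILCOXON) -> PairedTestResult:
    """Paired two-sided comparison of two matched measurement lists.

    T_TEST is the paired Student's t with n-1 df; WILCOXON drops zero
    differences, uses midranks for ties, and is exact for small n
    (normal approximation with continuity correction beyond that).
    """
    x = np.asarray([v.area_mm2 if isinstance(v, AreaMeasurement) else float(v) for v in x])
    y = np.asarray([v.area_mm2 if isinstance(v, AreaMeasurement) else float(v) for v in y])
    if x.shape != y.shape:
        raise ValueError(f"paired inputs differ in length: {x.shape} vs {y.shape}")
    if test is PairedTest.T_TEST:
        if x.size < 2:
            raise EmptyInputError("paired t test needs >= 2 pairs")
        if np.allclose(x, y):
            # identical samples: zero numerator and denominator; define t=0, p=1
            return PairedTestResult(test, 0.0, 1.0, int(x.size), df=int(x.size) - 1)
        res = sps.ttest_rel(x, y)
        return PairedTestResult(
            test, float(res.statistic), float(res.pvalue), int(x.size), df=int(x.size) - 1
        )
    w = wilcoxon_signed_rank(x, y)
    return PairedTestResult(
        test,
        w.statistic,
        w.p_value,
        w.n,
        n_zeros_dropped=w.n_zeros_dropped,
        exact=w.exact,
    )


def measurements_to_frame(measurements: list[AreaMeasurement]) -> pd.DataFrame:
    """Tabular (CSV-ready) view of a list of area measurements."""
    return pd.DataFrame(
        {
            "eye_id": [m.eye_id for m in measurements],
            "timepoint": [m.timepoint for m in measurements],
            "group": [m.group.value if m.group else "" for m in measurements],
            "grader": [m.grader for m in measurements],
            "label": [m.label.name if m.label else "" for m in measurements],
            "area_px": [m.area_px for m in measurements],
            "area_mm2": [m.area_mm2 for m in measurements],
        }
    )
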