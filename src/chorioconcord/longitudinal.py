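"""Baseline-vs-follow-up lesion-area change and between-group comparison.

For each eye the baseline is visit 0 and the follow-up is the latest
visit; one change record is built per (eye, lesion label) present at
both, with explicit exclusion reporting for labels missing at either
end.  Pooled baseline-vs-follow-up comparisons use the Wilcoxon
signed-rank test; the laser-vs-observation contrast of the area changes
uses a two-way factorial ANOVA (group x lesion label, type-II sums of
squares for the unbalanced design) with a rank-based Mann-Whitney
companion per label.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .area_quant import AreaMeasurement, PairedTest, PairedTestResult, compare_paired_areas
from .errors import ChorioconcordError, EmptyInputError, MissingBaselineError
from .roi_model import LesionType, TreatmentGroup

__all__ = [
    "ChangeRecord",
    "ExclusionRecord",
    "build_changes",
    "paired_followup_test",
    "group_change_comparison",
    "changes_to_frame",
]


@dataclass(frozen=True)
class ChangeRecord:
    eye_id: str
    group: TreatmentGroup | None
    label: LesionType
    baseline_mm2: float
    followup_mm2: float
    followup_timepoint: int

    @property
    def delta_mm2(self) -> float:
        return self.followup_mm2 - self.baseline_mm2

    @property
    def relative_change(self) -> float:
        """delta / baseline; NaN (flagged undefined) when baseline is 0."""
        if self.baseline_mm2 == 0:
            return float("nan")
        return self.delta_mm2 / self.baseline_mm2

    @property
    def relative_change_defined(self) -> bool:
        return self.baseline_mm2 != 0


@dataclass(frozen=True)
class ExclusionRecord:
    eye_id: str
    label: LesionType
    reason: str


def build_changes(
    measurements: list[AreaMeasurement],
) -> tuple[list[ChangeRecord], list[ExclusionRecord]]:
    """Pair each eye's baseline (t=0) and latest-visit areas per label.

    Eyes with follow-up data but no baseline visit raise; labels present
    at only one end are excluded and named in the exclusion report, never
    silently dropped.
    """
    if not measurements:
        raise EmptyInputError("no measurements to build change records from")
    by_eye: dict[str, list[AreaMeasurement]] = {}
    for m in measurements:
        by_eye.setdefault(m.eye_id, []).append(m)

    changes: list[ChangeRecord] = []
    exclusions: list[ExclusionRecord] = []
    for eye_id in sorted(by_eye):
        ms = by_eye[eye_id]
        timepoints = sorted({m.timepoint for m in ms})
        if timepoints[0] != 0:
            raise MissingBaselineError(
                f"eye {eye_id} has no baseline (timepoint 0) measurement"
            )
        followup_t = timepoints[-1]
        if followup_t == 0:
            for label in sorted({m.label for m in ms}, key=lambda l: l.name):
                exclusions.append(ExclusionRecord(eye_id, label, "no follow-up visit"))
            continue
        base = {m.label: m for m in ms if m.timepoint == 0}
        follow = {m.label: m for m in ms if m.timepoint == followup_t}
        group = next((m.group for m in ms if m.group is not None), None)
        for label in sorted(set(base) | set(follow), key=lambda l: l.name):
            if label not in base:
                exclusions.append(ExclusionRecord(eye_id, label, "absent at baseline"))
            elif label not in follow:
                exclusions.append(ExclusionRecord(eye_id, label, "absent at follow-up"))
            else:
                changes.append(
                    ChangeRecord(
                        eye_id=eye_id,
                        group=group,
                        label=label,
                        baseline_mm2=base[label].area_mm2,
                        followup_mm2=follow[label].area_mm2,
                        followup_timepoint=followup_t,
                    )
                )
    return changes, exclusions


def paired_followup_test(
    records: list[ChangeRecord],
    label: LesionType,
    test: PairedTest = PairedTest.WILCOXON,
) -> PairedTestResult:
    """Baseline vs follow-up paired test for one lesion label, eyes pooled."""
    recs = [r for r in records if r.label is label]
    if not recs:
        raise EmptyInputError(f"no change records for label {label.name}")
    baseline = [r.baseline_mm2 for r in recs]
    followup = [r.followup_mm2 for r in recs]
    return compare_paired_areas(baseline, followup, test=test)


def group_change_comparison(records: list[ChangeRecord]) -> dict:
    """Laser-vs-observation comparison of area changes across lesion labels.

    Returns the two-way type-II ANOVA table on delta_mm2 (factors: group,
    label, interaction), the group main-effect F and p, and per-label
    Mann-Whitney U comparisons as the rank-based robustness companion.
    Labels with a group entirely missing are flagged and left out of the
    factorial model.
    """
    df = changes_to_frame(records)
    df = df[df["group"] != ""]
    if df.empty or df["group"].nunique() < 2:
        present = sorted(df["group"].unique()) if not df.empty else []
        missing = [g.value for g in TreatmentGroup if g.value not in present]
        raise ChorioconcordError(
            f"both treatment groups required; missing: {', '.join(missing) or 'all'}"
        )
    if df["label"].nunique() < 2:
        raise ChorioconcordError("two-way ANOVA needs >= 2 lesion labels")

    flagged: list[str] = []
    keep_labels = []
    for label, sub in df.groupby("label"):
        if sub["group"].nunique() < 2:
            flagged.append(label)
        else:
            keep_labels.append(label)
    model_df = df[df["label"].isin(keep_labels)].copy()
    if model_df["label"].nunique() >= 2:
        ols = smf.ols("delta_mm2 ~ C(group) * C(label)", data=model_df).fit()
        anova = sm.stats.anova_lm(ols, typ=2)
    else:
        ols = smf.ols("delta_mm2 ~ C(group)", data=model_df).fit()
        anova = sm.stats.anova_lm(ols, typ=2)

    group_row = anova.loc["C(group)"]
    per_label = {}
    for label in keep_labels:
        sub = df[df["label"] == label]
        groups = [g["delta_mm2"].to_numpy() for _, g in sub.groupby("group")]
        u, p_u = sps.mannwhitneyu(groups[0], groups[1], alternative="two-sided")
        f, p_f = sps.f_oneway(groups[0], groups[1])
        per_label[label] = {
            "n_per_group": {g: int(len(s)) for g, s in sub.groupby("group")},
            "mannwhitney_u": float(u),
            "mannwhitney_p": float(p_u),
            "f": float(f),
            "f_p": float(p_f),
        }
    return {
        "anova_table": anova,
        "group_effect_f": float(group_row["F"]),
        "group_effect_p": float(group_row["PR(>F)"]),
        "per_label": per_label,
        "flagged_labels": flagged,
        "n_records": int(len(model_df)),
    }


def changes_to_frame(records: list[ChangeRecord]) -> pd.DataFrame:
    """Tabular (CSV-ready) view of change records."""
    return pd.DataFrame(
        {
            "eye_id": [r.eye_id for r in records],
            "group": [r.group.value if r.group else "" for r in records],
            "label": [r.label.name for r in records],
            "baseline_mm2": [r.baseline_mm2 for r in records],
            "followup_mm2": [r.followup_mm2 for r in records],
            "delta_mm2": [r.delta_mm2 for r in records],
            "relative_change": [r.relative_change for r in records],
            "followup_timepoint": [r.followup_timepoint for r in records],
        }
    )
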