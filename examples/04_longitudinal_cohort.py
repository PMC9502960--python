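"""Baseline vs follow-up lesion-area change on a synthetic cohort.

Simulates a two-group cohort (laser vs observation) whose lesions shrink
between visits, measures per-lesion areas from grader annotations, and
runs the pooled paired test plus the two-way group x lesion comparison.
"""

import numpy as np

from chorioconcord import (
    LesionType,
    PairedTest,
    TreatmentGroup,
    build_changes,
    group_change_comparison,
    measure_areas,
    paired_followup_test,
)
from chorioconcord.synthetic import CohortParams, SceneParams, generate_cohort

cohort = CohortParams(
    n_eyes=20,
    shrinkage={TreatmentGroup.LASER: 0.6, TreatmentGroup.OBSERVATION: 0.8},
    scene_template=SceneParams(halo_present=1.0, grader_sigma_px=2.0),
)
eyes, manifest = generate_cohort(cohort_params=cohort, seed=11)

measurements = []
for eye in eyes:
    for tp, scene in eye.scenes.items():
        octa_set, _ = scene.grader_annotations(
            "grader1", eye_id=eye.eye_id, timepoint=tp, group=eye.group
        )
        measurements.extend(measure_areas(octa_set, scene.params.frame))

records, exclusions = build_changes(measurements)
print(f"{len(records)} change records, {len(exclusions)} exclusions")

for label in (LesionType.TYPE_A, LesionType.TYPE_B, LesionType.TYPE_C):
    recs = [r for r in records if r.label is label]
    rel = np.mean([r.relative_change for r in recs])
    test = paired_followup_test(records, label, PairedTest.WILCOXON)
    print(
        f"{label.name}: mean relative area change {rel:+.3f}, "
        f"Wilcoxon W={test.statistic:.0f}, p={test.p_value:.2e} (n={test.n})"
    )

cmp = group_change_comparison(records)
print(
    f"group effect (laser radius x0.6 vs observation x0.8): "
    f"F={cmp['group_effect_f']:.1f}, p={cmp['group_effect_p']:.2e}"
)
print(
    "-> every lesion type shrinks significantly, and the built-in group "
    "difference in shrinkage is picked up by the two-way ANOVA"
)
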