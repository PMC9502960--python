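"""Full cross-modality pipeline on one synthetic eye.

Generates a ground-truthed paired scene (OCTA choriocapillaris + mid-phase
ICGA), renders both frames with landmark crosses, recovers the
inter-modality affine from the detected landmarks, and measures the
Jaccard overlap of the OCTA type A lesion with the registered ICGA
hyperfluorescence region.
"""

import numpy as np

from chorioconcord import (
    LandmarkPair,
    OverlapMethod,
    Point2D,
    crossmodal_concordance,
    estimate_affine,
)
from chorioconcord.synthetic import (
    SceneParams,
    detect_landmarks,
    generate_scene,
    render_images,
)

params = SceneParams(seed=7, icga_boundary_sigma_px=4.0)
scene = generate_scene(params)
print(f"true type A area: {scene.analytic_areas_mm2['type_a']:.3f} mm^2 (closed form)")

octa_img, icga_img = render_images(scene)
approx_fixed = np.array([[lm.fixed.x, lm.fixed.y] for lm in scene.landmarks])
approx_moving = np.array([[lm.moving.x, lm.moving.y] for lm in scene.landmarks])
fixed = detect_landmarks(octa_img, approx_fixed)
moving = detect_landmarks(icga_img, approx_moving)
print(f"landmark detection error: {np.abs(fixed - approx_fixed).max():.3f} px (worst)")

reg = estimate_affine(
    [LandmarkPair(Point2D(*m), Point2D(*f)) for m, f in zip(moving, fixed)]
)
print(f"affine fit from {reg.n_landmarks} landmarks, rmse {reg.rmse:.2e} px")

octa_set, icga_set = scene.truth_annotations()
res = crossmodal_concordance(
    octa_set, icga_set, reg.transform, params.frame, OverlapMethod.RASTER
)
print(
    f"cross-modality JI = {res.jaccard:.4f} "
    f"(type A {res.area_a_mm2:.3f} mm^2 vs registered hyperfluorescence "
    f"{res.area_b_mm2:.3f} mm^2)"
)
print(
    "-> with a 4 px ICGA boundary discrepancy the two outlines still overlap "
    "strongly; JI < 1 reflects that discrepancy plus raster discretization"
)
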