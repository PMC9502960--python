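"""Ground-truth scene generator: determinism, containment, graders, rendering."""

import numpy as np
import pytest

from chorioconcord import (
    ImageFrame,
    LesionType,
    TreatmentGroup,
    polygon_area_px,
    simulate_grader,
)
from chorioconcord.errors import ConfigurationError
from chorioconcord.registration import apply_to_points
from chorioconcord.synthetic import (
    CohortParams,
    SceneParams,
    detect_landmarks,
    generate_cohort,
    generate_scene,
    render_images,
    write_scene_bundle,
)

SMALL = dict(
    frame=ImageFrame(256, 256, 12.0, 12.0),
    icga_frame=ImageFrame(256, 256, 12.0, 12.0),
)


class TestDeterminism:
    def test_same_seed_identical_scene(self):
        a = generate_scene(SceneParams(seed=5, **SMALL))
        b = generate_scene(SceneParams(seed=5, **SMALL))
        np.testing.assert_array_equal(a.type_a.rings[0], b.type_a.rings[0])
        np.testing.assert_array_equal(
            a.truth_mask(LesionType.TYPE_A).grid, b.truth_mask(LesionType.TYPE_A).grid
        )
        assert a.true_affine == b.true_affine

    def test_noise_stream_independent_of_shape(self):
        # same geometry params, different seeds for rendering only is not
        # supported directly; instead: same seed renders identically, and
        # geometry is byte-stable across renders
        sc = generate_scene(SceneParams(seed=9, **SMALL))
        img1, _ = render_images(sc)
        img2, _ = render_images(sc)
        np.testing.assert_array_equal(img1, img2)


class TestGeometryInvariants:
    @pytest.mark.parametrize("seed", range(4))
    def test_containment_and_disjointness(self, seed):
        sc = generate_scene(SceneParams(seed=seed, halo_present=1.0, **SMALL))
        a = sc.truth_mask(LesionType.TYPE_A).grid
        b = sc.truth_mask(LesionType.TYPE_B).grid
        c = sc.truth_mask(LesionType.TYPE_C).grid
        assert (c & ~a).sum() == 0  # type C strictly inside type A
        assert (b & a).sum() == 0  # halo disjoint from type A
        # halo borders type A: dilating the halo by one pixel touches A
        from scipy import ndimage

        assert (ndimage.binary_dilation(b) & a).sum() > 0

    @pytest.mark.parametrize("seed", range(4))
    def test_hypofluorescence_strictly_smaller_than_mapped_type_c(self, seed):
        sc = generate_scene(SceneParams(seed=seed, **SMALL))
        hypo_area = polygon_area_px(sc.hypo)
        mapped_c = apply_to_points(
            sc.true_affine.invert(), np.vstack(sc.type_c.rings)
        )  # noqa: F841 - mapped area via det
        c_in_icga = polygon_area_px(sc.type_c) * abs(sc.true_affine.invert().det)
        assert hypo_area < c_in_icga

    def test_landmarks_exactly_related_by_affine(self):
        sc = generate_scene(SceneParams(seed=3))
        moving = np.array([[lm.moving.x, lm.moving.y] for lm in sc.landmarks])
        fixed = np.array([[lm.fixed.x, lm.fixed.y] for lm in sc.landmarks])
        np.testing.assert_allclose(apply_to_points(sc.true_affine, moving), fixed, atol=1e-9)

    def test_halo_probability_degenerate(self):
        present = [
            generate_scene(SceneParams(seed=s, halo_present=p, **SMALL)).type_b is not None
            for p in (0.0, 1.0)
            for s in range(20)
        ]
        assert present[:20] == [False] * 20
        assert present[20:] == [True] * 20

    def test_zero_harmonics_circle_area_closed_form(self):
        sc = generate_scene(
            SceneParams(
                seed=1, typeA_harmonics=0, typeA_radius_jitter_mm=0.0, typeA_radius_mm=1.5
            )
        )
        area_mm2 = sc.params.frame.px2_to_mm2(polygon_area_px(sc.type_a))
        assert area_mm2 == pytest.approx(np.pi * 1.5**2, rel=0.01)
        assert sc.analytic_areas_mm2["type_a"] == pytest.approx(np.pi * 1.5**2, rel=1e-6)

    def test_analytic_area_matches_polygon_area(self):
        sc = generate_scene(SceneParams(seed=12))
        measured = sc.params.frame.px2_to_mm2(polygon_area_px(sc.type_a))
        assert measured == pytest.approx(sc.analytic_areas_mm2["type_a"], rel=0.005)

    def test_oversized_spots_rejected(self):
        with pytest.raises(ConfigurationError, match="spot_radius"):
            SceneParams(spot_radius_mm=1.4, typeA_radius_mm=1.5)


class TestSimulatedGrader:
    def test_sigma_zero_reproduces_truth(self):
        sc = generate_scene(SceneParams(seed=2, **SMALL))
        redrawn = simulate_grader(sc.type_a, 0.0, seed=99)
        np.testing.assert_array_equal(redrawn.rings[0], sc.type_a.rings[0])

    def test_negative_sigma_rejected(self):
        sc = generate_scene(SceneParams(seed=2, **SMALL))
        with pytest.raises(ConfigurationError):
            simulate_grader(sc.type_a, -1.0, seed=0)

    def test_mean_ji_band_and_monotone_in_sigma(self):
        # disc of radius 120 px: sigma 4 keeps JI in (0.8, 1.0) and above sigma 12
        from chorioconcord import OverlapMethod, RegionOfInterest, jaccard_index

        th = np.linspace(0, 2 * np.pi, 256, endpoint=False)
        truth = RegionOfInterest(
            [np.column_stack([150 + 120 * np.cos(th), 150 + 120 * np.sin(th)])]
        )
        frame = ImageFrame(300, 300, 3, 3)
        means = {}
        for sigma in (4.0, 12.0):
            jis = [
                jaccard_index(
                    truth, simulate_grader(truth, sigma, seed), frame, OverlapMethod.RASTER
                ).jaccard
                for seed in range(60)
            ]
            means[sigma] = np.mean(jis)
        assert 0.8 < means[4.0] < 1.0
        assert means[12.0] < means[4.0]


class TestRendering:
    def test_noiseless_contrast_matches_configured_value(self):
        sc = generate_scene(SceneParams(seed=4, noise_level=0.0, contrast=60.0))
        octa, icga = render_images(sc)
        from scipy import ndimage

        a = sc.truth_mask(LesionType.TYPE_A).grid
        interior = ndimage.binary_erosion(a, iterations=6)
        if sc.type_c is not None:
            interior &= ~ndimage.binary_dilation(
                sc.truth_mask(LesionType.TYPE_C).grid, iterations=6
            )
        exterior = ~ndimage.binary_dilation(a, iterations=10)
        if sc.type_b is not None:
            exterior &= ~ndimage.binary_dilation(
                sc.truth_mask(LesionType.TYPE_B).grid, iterations=6
            )
        # keep clear of the landmark crosses
        yy, xx = np.mgrid[0 : octa.shape[0], 0 : octa.shape[1]]
        for lm in sc.landmarks:
            near = (xx - lm.fixed.x) ** 2 + (yy - lm.fixed.y) ** 2 < 40**2
            interior &= ~near
            exterior &= ~near
        contrast = octa[interior].mean() - octa[exterior].mean()
        assert contrast == pytest.approx(60.0, rel=0.01)

    def test_landmark_crosses_recoverable_to_half_pixel(self):
        sc = generate_scene(SceneParams(seed=6))
        octa, icga = render_images(sc)
        fixed = np.array([[lm.fixed.x, lm.fixed.y] for lm in sc.landmarks])
        moving = np.array([[lm.moving.x, lm.moving.y] for lm in sc.landmarks])
        assert np.abs(detect_landmarks(octa, fixed) - fixed).max() <= 0.5
        assert np.abs(detect_landmarks(icga, moving) - moving).max() <= 0.5

    def test_images_are_uint8_frames(self):
        sc = generate_scene(SceneParams(seed=7, **SMALL))
        octa, icga = render_images(sc)
        assert octa.dtype == np.uint8 and octa.shape == (256, 256)
        assert icga.dtype == np.uint8


class TestScalingAndCohort:
    def test_scaled_scene_area_law(self):
        sc = generate_scene(SceneParams(seed=8, **SMALL))
        half = sc.scaled(0.5)
        assert polygon_area_px(half.type_a) == pytest.approx(
            0.25 * polygon_area_px(sc.type_a), rel=1e-9
        )
        assert half.analytic_areas_mm2["type_a"] == pytest.approx(
            0.25 * sc.analytic_areas_mm2["type_a"]
        )

    def test_unit_shrinkage_gives_zero_deltas(self):
        cp = CohortParams(
            n_eyes=4,
            shrinkage={TreatmentGroup.LASER: 1.0, TreatmentGroup.OBSERVATION: 1.0},
            scene_template=SceneParams(**SMALL),
        )
        eyes, _ = generate_cohort(cohort_params=cp, seed=0)
        for eye in eyes:
            assert polygon_area_px(eye.scenes[1].type_a) == pytest.approx(
                polygon_area_px(eye.scenes[0].type_a), rel=1e-12
            )

    def test_half_radius_quarters_true_area(self):
        cp = CohortParams(
            n_eyes=2,
            shrinkage={TreatmentGroup.LASER: 0.5, TreatmentGroup.OBSERVATION: 0.5},
            scene_template=SceneParams(**SMALL),
        )
        eyes, manifest = generate_cohort(cohort_params=cp, seed=1)
        for eye in eyes:
            assert polygon_area_px(eye.scenes[1].type_a) == pytest.approx(
                0.25 * polygon_area_px(eye.scenes[0].type_a), rel=1e-12
            )
        assert set(manifest.columns) >= {"eye_id", "timepoint", "group", "radius_factor"}

    def test_groups_balanced(self):
        eyes, _ = generate_cohort(
            cohort_params=CohortParams(n_eyes=10, scene_template=SceneParams(**SMALL)),
            seed=3,
        )
        counts = {g: sum(e.group is g for e in eyes) for g in TreatmentGroup}
        assert counts[TreatmentGroup.LASER] == counts[TreatmentGroup.OBSERVATION] == 5


class TestSceneBundle:
    def test_bundle_files_written_and_readable(self, tmp_path):
        from chorioconcord import read_roi_zip
        import json

        sc = generate_scene(SceneParams(seed=10, **SMALL))
        files = write_scene_bundle(sc, tmp_path)
        for f in files.values():
            assert (tmp_path / f).exists()
        rois = read_roi_zip(tmp_path / "truth_rois.zip")
        assert len(rois) >= 2
        truth = json.loads((tmp_path / "truth.json").read_text())
        assert set(truth["true_affine"]) == {"a00", "a01", "a02", "a10", "a11", "a12"}
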