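"""Jaccard overlap: analytic identities, oracle agreement, agreement workflows."""

import numpy as np
import pytest

from chorioconcord import (
    AffineTransform,
    AnnotationSet,
    ImageFrame,
    LesionType,
    OverlapMethod,
    RegionOfInterest,
    cohort_ji_summary,
    crossmodal_concordance,
    interobserver_agreement,
    jaccard_index,
    simulate_grader,
)
from chorioconcord.errors import (
    ChorioconcordError,
    EmptyInputError,
    MissingAnnotationError,
    UndefinedOverlapError,
)

from conftest import random_simple_polygon, square_roi


def disc_roi(cx, cy, r, n=128, **kw):
    th = np.linspace(0, 2 * np.pi, n, endpoint=False)
    return RegionOfInterest(
        [np.column_stack([cx + r * np.cos(th), cy + r * np.sin(th)])], **kw
    )


def two_disc_intersection(r1, r2, d):
    """Closed-form lens area of two discs with center distance d."""
    if d >= r1 + r2:
        return 0.0
    if d <= abs(r1 - r2):
        return np.pi * min(r1, r2) ** 2
    a1 = np.arccos((d**2 + r1**2 - r2**2) / (2 * d * r1))
    a2 = np.arccos((d**2 + r2**2 - r1**2) / (2 * d * r2))
    return (
        r1**2 * (a1 - np.sin(2 * a1) / 2) + r2**2 * (a2 - np.sin(2 * a2) / 2)
    )


class TestJaccardIdentities:
    @pytest.mark.parametrize("method", list(OverlapMethod))
    def test_identical_rois_give_one(self, unit_frame, method):
        roi = square_roi(10, 10, 30)
        assert jaccard_index(roi, roi, unit_frame, method).jaccard == pytest.approx(1.0)

    @pytest.mark.parametrize("method", list(OverlapMethod))
    def test_disjoint_squares_give_zero(self, unit_frame, method):
        a = square_roi(5.25, 5.25, 10)
        b = square_roi(25.25, 5.25, 10)
        assert jaccard_index(a, b, unit_frame, method).jaccard == 0.0

    def test_half_overlapping_unit_squares_exact_polygon(self, unit_frame):
        a = square_roi(0, 0, 1)
        b = square_roi(0.5, 0, 1)
        res = jaccard_index(a, b, unit_frame, OverlapMethod.POLYGON)
        assert res.intersection_px == pytest.approx(0.5)
        assert res.union_px == pytest.approx(1.5)
        assert res.jaccard == pytest.approx(1 / 3)

    def test_half_overlapping_squares_raster_1024(self):
        # scaled similarity keeps JI = 1/3; raster at 1024^2 within 0.01
        frame = ImageFrame(1024, 1024, 1.0, 1.0)
        a = square_roi(100.25, 100.25, 600)
        b = square_roi(400.25, 100.25, 600)
        res = jaccard_index(a, b, frame, OverlapMethod.RASTER)
        assert res.jaccard == pytest.approx(1 / 3, abs=0.01)

    @pytest.mark.parametrize("method", list(OverlapMethod))
    def test_symmetry(self, unit_frame, method):
        rng = np.random.default_rng(0)
        a = RegionOfInterest([random_simple_polygon(rng, center=(50, 50))])
        b = RegionOfInterest([random_simple_polygon(rng, center=(60, 55))])
        r1 = jaccard_index(a, b, unit_frame, method)
        r2 = jaccard_index(b, a, unit_frame, method)
        assert r1.jaccard == r2.jaccard

    def test_polygon_scale_invariance(self, unit_frame):
        rng = np.random.default_rng(4)
        a = RegionOfInterest([random_simple_polygon(rng, center=(50, 50))])
        b = RegionOfInterest([random_simple_polygon(rng, center=(55, 50))])
        base = jaccard_index(a, b, unit_frame, OverlapMethod.POLYGON).jaccard
        c, s = np.cos(0.4), np.sin(0.4)
        sim = np.array([[1.7 * c, -1.7 * s], [1.7 * s, 1.7 * c]])
        a2 = a.with_rings([r @ sim.T + 20 for r in a.rings])
        b2 = b.with_rings([r @ sim.T + 20 for r in b.rings])
        big = ImageFrame(400, 400, 1, 1)
        assert jaccard_index(a2, b2, big, OverlapMethod.POLYGON).jaccard == pytest.approx(
            base, abs=1e-9
        )

    def test_empty_union_is_loud(self, unit_frame):
        degenerate = RegionOfInterest([np.array([(0, 0), (1, 1), (2, 2)], float)])
        with pytest.raises(UndefinedOverlapError):
            jaccard_index(degenerate, degenerate, unit_frame, OverlapMethod.RASTER)

    def test_invariant_fields_consistent(self, unit_frame):
        a = square_roi(5.25, 5.25, 30)
        b = square_roi(15.25, 15.25, 30)
        for method in OverlapMethod:
            r = jaccard_index(a, b, unit_frame, method)
            assert r.intersection_px <= min(r.area_a_px, r.area_b_px)
            assert r.union_px == pytest.approx(
                r.area_a_px + r.area_b_px - r.intersection_px, rel=1e-9
            )
            assert 0 <= r.jaccard <= 1

    def test_mm2_properties_follow_frame_scale(self):
        frame = ImageFrame(100, 100, 2.0, 2.0)
        r = jaccard_index(square_roi(0, 0, 10), square_roi(0, 0, 10), frame,
                          OverlapMethod.POLYGON)
        assert r.area_a_mm2 == pytest.approx(100 * frame.px_area_mm2)


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(8))
    def test_polygon_vs_raster_within_perimeter_bound(self, seed):
        rng = np.random.default_rng(200 + seed)
        a = RegionOfInterest([random_simple_polygon(rng, center=(60, 60), radius=(15, 45))])
        b = RegionOfInterest([random_simple_polygon(rng, center=(70, 60), radius=(15, 45))])
        frame = ImageFrame(128, 128, 1, 1)
        jp = jaccard_index(a, b, frame, OverlapMethod.POLYGON)
        jr = jaccard_index(a, b, frame, OverlapMethod.RASTER)

        def perim(roi):
            return sum(
                np.sum(np.linalg.norm(np.roll(r, -1, axis=0) - r, axis=1)) for r in roi.rings
            )

        bound = 2 * (perim(a) + perim(b)) / min(jp.union_px, jr.union_px)
        assert abs(jp.jaccard - jr.jaccard) <= bound


class TestCrossmodal:
    def _sets(self, frame, t, hyper_equals_affine_image=True):
        th = np.linspace(0, 2 * np.pi, 256, endpoint=False)
        ring = np.column_stack([512 + 150 * np.cos(th), 512 + 150 * np.sin(th)])
        roi_a = RegionOfInterest([ring], label=LesionType.TYPE_A, grader="g1", frame=frame)
        inv = t.invert()
        lin = np.array([[inv.a00, inv.a01], [inv.a10, inv.a11]])
        hyper_ring = ring @ lin.T + np.array([inv.a02, inv.a12])
        roi_h = RegionOfInterest([hyper_ring], label=LesionType.HYPERFLUORESCENCE, grader="g1")
        octa = AnnotationSet("eye0", 0, "g1", [roi_a])
        icga = AnnotationSet("eye0", 0, "g1", [roi_h])
        return octa, icga

    def test_exact_affine_image_gives_near_unit_ji(self):
        frame = ImageFrame(1024, 1024, 12, 12)
        t = AffineTransform(1.05, -0.08, 17.0, 0.06, 0.97, -9.0)
        octa, icga = self._sets(frame, t)
        res = crossmodal_concordance(octa, icga, t, frame)
        assert res.jaccard >= 0.99
        assert res.metadata["eye_id"] == "eye0"

    def test_known_disc_overlap_fraction(self):
        # discs of known radii/offset: closed-form lens area vs measured
        frame = ImageFrame(1024, 1024, 12, 12)
        r1, r2, d = 150.0, 130.0, 60.0
        a = disc_roi(500, 500, r1, n=512).relabel(LesionType.TYPE_A, "g1")
        h = disc_roi(500 + d, 500, r2, n=512).relabel(LesionType.HYPERFLUORESCENCE, "g1")
        octa = AnnotationSet("e", 0, "g1", [a])
        icga = AnnotationSet("e", 0, "g1", [h])
        res = crossmodal_concordance(octa, icga, AffineTransform.identity(), frame)
        inter = two_disc_intersection(r1, r2, d)
        union = np.pi * r1**2 + np.pi * r2**2 - inter
        assert res.jaccard == pytest.approx(inter / union, abs=0.02)

    def test_missing_type_a_is_loud(self):
        frame = ImageFrame(64, 64, 1, 1)
        octa = AnnotationSet("e", 0, "g1", [])
        icga = AnnotationSet(
            "e", 0, "g1", [square_roi(1, 1, 5, label=LesionType.HYPERFLUORESCENCE)]
        )
        with pytest.raises(MissingAnnotationError, match="TYPE_A"):
            crossmodal_concordance(octa, icga, AffineTransform.identity(), frame)


class TestInterobserver:
    def test_zero_noise_graders_agree_perfectly(self, frame_1024):
        truth = disc_roi(512, 512, 120, label=LesionType.TYPE_A)
        g1 = AnnotationSet("e", 0, "g1", [simulate_grader(truth, 0, 1).relabel(grader="g1")])
        g2 = AnnotationSet("e", 0, "g2", [simulate_grader(truth, 0, 2).relabel(grader="g2")])
        res = interobserver_agreement(g1, g2, frame_1024, LesionType.TYPE_A)
        assert res.jaccard == pytest.approx(1.0)

    def test_agreement_degrades_with_noise(self):
        # median JI over seeds strictly lower at sigma 6 than sigma 2
        frame = ImageFrame(256, 256, 3, 3)
        truth = disc_roi(128, 128, 100, label=LesionType.TYPE_A)
        medians = {}
        for sigma in (2.0, 6.0):
            jis = []
            for seed in range(30):
                noisy = simulate_grader(truth, sigma, 1000 + seed).relabel(grader="g2")
                g1 = AnnotationSet("e", 0, "g1", [truth.relabel(grader="g1")])
                g2 = AnnotationSet("e", 0, "g2", [noisy])
                jis.append(
                    interobserver_agreement(g1, g2, frame, LesionType.TYPE_A).jaccard
                )
            medians[sigma] = np.median(jis)
        assert medians[6.0] < medians[2.0]

    def test_same_grader_rejected(self, unit_frame):
        s = AnnotationSet("e", 0, "g1", [square_roi(1, 1, 5, label=LesionType.TYPE_B)])
        with pytest.raises(ChorioconcordError, match="distinct"):
            interobserver_agreement(s, s, unit_frame, LesionType.TYPE_B)

    def test_missing_label_rejected(self, unit_frame):
        g1 = AnnotationSet("e", 0, "g1", [square_roi(1, 1, 5, label=LesionType.TYPE_B)])
        g2 = AnnotationSet("e", 0, "g2", [square_roi(1, 1, 5, label=LesionType.TYPE_A)])
        with pytest.raises(MissingAnnotationError, match="TYPE_B"):
            interobserver_agreement(g1, g2, unit_frame, LesionType.TYPE_B)


class TestCohortSummary:
    def test_single_value_flags_n1(self, unit_frame):
        roi = square_roi(1, 1, 5)
        res = jaccard_index(roi, roi, unit_frame, OverlapMethod.POLYGON)
        s = cohort_ji_summary([res])
        assert s == {"mean": 1.0, "sd": 0.0, "n": 1, "n_is_one": True}

    def test_mean_and_sample_sd(self, unit_frame):
        a = square_roi(0, 0, 10)
        results = []
        for shift, expected in ((0.0, 1.0), (5.0, 1 / 3)):
            b = square_roi(shift, 0, 10)
            results.append(jaccard_index(a, b, unit_frame, OverlapMethod.POLYGON))
        s = cohort_ji_summary(results)
        vals = np.array([1.0, 1 / 3])
        assert s["mean"] == pytest.approx(vals.mean())
        assert s["sd"] == pytest.approx(vals.std(ddof=1))

    def test_empty_rejected(self):
        with pytest.raises(EmptyInputError):
            cohort_ji_summary([])
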