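import math

import numpy as np
import pytest

from _oracle import brute_circle_score
from aortacad.circle import (
    PairTolerances,
    chord_through_centroid,
    circle_score,
    classify_shape,
    gradient_aligned_with_chord,
    opposed_gradients,
)
from aortacad.gradients import gradient_angle_image, sobel_field
from aortacad.phantom import Lesion, PhantomSpec, make_dissection_slice, make_healthy_slice
from aortacad.segmentation import label_components, threshold_lumen
from aortacad.types import AortaObject, BoundaryPair, GradientField, make_slice

TOL = PairTolerances(angle_tol_deg=10.0, line_tol_px=2.0)


def pair(p1, p2, g1, g2=0.0):
    return BoundaryPair(p1=p1, p2=p2, gtheta1=g1, gtheta2=g2)


class TestOpposedGradients:
    def test_exact_opposition(self):
        assert opposed_gradients(pair((0, 0), (1, 1), 10.0, 190.0), TOL)

    def test_within_tolerance(self):
        # circular difference 175 deg, within 10 deg of 180
        assert opposed_gradients(pair((0, 0), (1, 1), 10.0, 185.0), TOL)

    def test_orthogonal_rejected(self):
        assert not opposed_gradients(pair((0, 0), (1, 1), 10.0, 100.0), TOL)

    def test_wraparound(self):
        # 350 vs 170: difference 180 exactly, across the 0/360 seam
        assert opposed_gradients(pair((0, 0), (1, 1), 350.0, 170.0), TOL)

    def test_undefined_angle_is_false(self):
        assert not opposed_gradients(pair((0, 0), (1, 1), math.nan, 180.0), TOL)
        assert not opposed_gradients(pair((0, 0), (1, 1), 0.0, math.nan), TOL)


class TestGradientAlignedWithChord:
    def test_chord_along_x(self):
        assert gradient_aligned_with_chord(pair((0, 0), (0, 10), 0.0), TOL)

    def test_perpendicular_rejected(self):
        assert not gradient_aligned_with_chord(pair((0, 0), (10, 0), 0.0), TOL)

    def test_diagonal(self):
        assert gradient_aligned_with_chord(pair((0, 0), (7, 7), 45.0), TOL)

    def test_modulo_180_gradient_reversed(self):
        # chord is undirected: a 225-deg gradient aligns with a 45-deg chord
        assert gradient_aligned_with_chord(pair((0, 0), (7, 7), 225.0), TOL)

    def test_identical_pixels_rejected(self):
        from types import SimpleNamespace

        degenerate = SimpleNamespace(p1=(0, 0), p2=(0, 0), gtheta1=0.0, gtheta2=0.0)
        with pytest.raises(ValueError):
            gradient_aligned_with_chord(degenerate, TOL)
        with pytest.raises(ValueError):
            BoundaryPair(p1=(0, 0), p2=(0, 0), gtheta1=0.0, gtheta2=0.0)


class TestChordThroughCentroid:
    def test_collinear(self):
        assert chord_through_centroid(pair((0, 5), (10, 5), 0.0), (5.0, 5.0), TOL)

    def test_distance_five_rejected(self):
        assert not chord_through_centroid(pair((0, 0), (0, 10), 0.0), (5.0, 5.0), TOL)

    def test_inclusive_at_exact_tolerance(self):
        # line row=0; centroid exactly 2 px away
        assert chord_through_centroid(pair((0, 0), (0, 10), 0.0), (2.0, 5.0), TOL)


def _radial_disk(radius=20, shape=(64, 64), center=(32.0, 32.0)):
    """Rasterised disk object plus an ideal inward radial gradient field."""
    rr, cc = np.meshgrid(np.arange(shape[0]), np.arange(shape[1]), indexing="ij")
    disk = (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2
    obj = AortaObject.from_pixels(zip(*np.nonzero(disk)))
    gx = (center[1] - cc).astype(float)
    gy = (center[0] - rr).astype(float)
    field = GradientField(gx=gx, gy=gy, gtheta=gradient_angle_image(gx, gy))
    return obj, field


class TestCircleScore:
    def test_ideal_disk_scores_high_and_matches_oracle(self):
        obj, field = _radial_disk(radius=20)
        score = circle_score(obj, field, TOL)
        angles = [field.gtheta[r, c] for r, c in obj.boundary]
        expected, _ = brute_circle_score(
            list(obj.boundary), angles, obj.centroid, 10.0, 2.0
        )
        assert score == pytest.approx(expected)
        assert score >= 0.9

    def test_ellipse_scores_below_disk(self):
        obj, field = _radial_disk(radius=20)
        disk_score = circle_score(obj, field, TOL)
        spec = PhantomSpec(
            radius=20, shape=(160, 160), center=(80.0, 80.0),
            lesions=(Lesion("dissection", 0, 1, mode="ellipse", axis_ratio=3.0),),
        )
        ct, _, _ = make_dissection_slice(spec, 0)
        (eobj,) = label_components(threshold_lumen(ct, spec.hu_range), min_size=50)
        escore = circle_score(eobj, sobel_field(ct), TOL)
        assert escore < disk_score

    def test_flat_edge_scores_zero(self):
        # all gradient angles equal: the opposed condition is unsatisfiable
        obj, _ = _radial_disk(radius=10, shape=(32, 32), center=(16.0, 16.0))
        gx = np.ones((32, 32))
        gy = np.zeros((32, 32))
        field = GradientField(gx=gx, gy=gy, gtheta=gradient_angle_image(gx, gy))
        assert circle_score(obj, field, TOL) == 0.0

    def test_degenerate_boundary_rejected(self):
        obj = AortaObject.from_pixels([(0, 0), (0, 1), (1, 0), (1, 1)])
        gx = np.ones((4, 4))
        field = GradientField(gx=gx, gy=gx * 0, gtheta=gradient_angle_image(gx, gx * 0))
        with pytest.raises(ValueError, match="degenerate"):
            circle_score(obj, field, TOL)

    def test_matches_oracle_on_random_blobs(self):
        from conftest import random_blob

        rng = np.random.default_rng(7)
        checked = 0
        while checked < 5:
            drawn = random_blob(rng)
            if drawn is None:
                continue
            img, blob = drawn
            obj = AortaObject.from_pixels(zip(*np.nonzero(blob)))
            if not 8 <= len(obj.boundary) <= 200:
                continue
            field = sobel_field(make_slice(img, 0))
            angles = [field.gtheta[r, c] for r, c in obj.boundary]
            expected, _ = brute_circle_score(
                list(obj.boundary), angles, obj.centroid, 10.0, 2.0
            )
            assert circle_score(obj, field, TOL) == pytest.approx(expected)
            checked += 1

    def test_translation_invariance(self):
        spec = PhantomSpec(radius=15, center=(40.0, 40.0))
        ct, _ = make_healthy_slice(spec, 0)
        (obj,) = label_components(threshold_lumen(ct, spec.hu_range), min_size=50)
        s1 = circle_score(obj, sobel_field(ct), TOL)
        spec2 = PhantomSpec(radius=15, center=(73.0, 61.0))
        ct2, _ = make_healthy_slice(spec2, 0)
        (obj2,) = label_components(threshold_lumen(ct2, spec2.hu_range), min_size=50)
        s2 = circle_score(obj2, sobel_field(ct2), TOL)
        assert s1 == pytest.approx(s2)

    def test_rotation_invariance_quarter_turn(self):
        spec = PhantomSpec(
            radius=15,
            lesions=(Lesion("dissection", 0, 1, mode="ellipse", axis_ratio=2.0),),
            shape=(160, 160), center=(80.0, 80.0),
        )
        ct, _, _ = make_dissection_slice(spec, 0)
        (obj,) = label_components(threshold_lumen(ct, spec.hu_range), min_size=50)
        s1 = circle_score(obj, sobel_field(ct), TOL)
        rot = make_slice(np.rot90(ct.pixels).copy(), 0)
        (obj2,) = label_components(threshold_lumen(rot, spec.hu_range), min_size=50)
        s2 = circle_score(obj2, sobel_field(rot), TOL)
        assert s1 == pytest.approx(s2)

    def test_adding_partnered_pixels_never_decreases_numerator(self):
        # with the centroid held fixed, extra boundary pixels only add
        # candidate partners, so previously satisfied pixels stay satisfied
        obj, field = _radial_disk(radius=12, shape=(48, 48), center=(24.0, 24.0))
        full_boundary = list(obj.boundary)
        half = full_boundary[::2]
        angles_half = [field.gtheta[r, c] for r, c in half]
        angles_full = [field.gtheta[r, c] for r, c in full_boundary]
        _, n_half = brute_circle_score(half, angles_half, obj.centroid, 10.0, 2.0)
        _, n_full = brute_circle_score(full_boundary, angles_full, obj.centroid, 10.0, 2.0)
        assert n_full >= n_half


class TestClassifyShape:
    def test_high_score_is_circle_like(self):
        obj, field = _radial_disk(radius=20)
        assert classify_shape(obj, field, tol=TOL).label == "circle_like"

    def test_threshold_default_is_60_percent(self):
        obj, field = _radial_disk(radius=20)
        decision = classify_shape(obj, field, tol=TOL)
        assert decision.threshold == 0.60

    def test_low_score_is_candidate(self):
        obj, _ = _radial_disk(radius=10, shape=(32, 32), center=(16.0, 16.0))
        gx = np.ones((32, 32))
        field = GradientField(gx=gx, gy=gx * 0, gtheta=gradient_angle_image(gx, gx * 0))
        assert classify_shape(obj, field, tol=TOL).label == "dissection_candidate"

    def test_threshold_is_inclusive(self):
        from aortacad.types import CircleDecision

        assert CircleDecision(score=0.60, threshold=0.60).label == "circle_like"
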