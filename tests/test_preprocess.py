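"""Face alignment, edge filters, augmentation and the crop acceptance rule."""

import numpy as np
import pytest

from felgrim.descriptors import DegenerateGeometryError, build_default_registry, \
    evaluate_registry
from felgrim.preprocess import (AffineTransform, AugmentConfig, align_face,
                                apply_edge_filter, augment_sample,
                                compute_rotation_angle, crop_face,
                                geometric_transform, landmark_box,
                                whole_image_box)
from felgrim.schema import FaceAnnotation
from felgrim.synthetic import (GeneratorParams, PainState, deformed_template,
                               render_face)


def _template_ann():
    pts = deformed_template(PainState((0,) * 5), GeneratorParams(noise_sigma=0))
    return FaceAnnotation("tpl", pts, (224, 224))


def _rotate(ann, angle_deg, center=(112, 112)):
    tf = AffineTransform.rotation(angle_deg, center)
    return ann.replace(tf.apply(ann.points))


class TestRotationAngle:
    def test_horizontal_eye_line_is_zero(self):
        pts = _template_ann().points.copy()
        # eye-group centroids at (10,50) and (90,50)
        pts[12], pts[13] = (5, 50), (15, 50)
        pts[16], pts[17] = (85, 50), (95, 50)
        assert compute_rotation_angle(FaceAnnotation("x", pts)) == pytest.approx(0.0)

    @pytest.mark.parametrize("angle", [10.0, -25.0, 90.0, 179.0])
    def test_recovers_applied_rotation(self, angle):
        ann = _template_ann()
        assert compute_rotation_angle(_rotate(ann, angle)) == pytest.approx(
            angle, abs=1e-6)

    def test_coincident_centroids_raise(self):
        pts = _template_ann().points.copy()
        pts[16], pts[17] = pts[12], pts[13]
        with pytest.raises(DegenerateGeometryError):
            compute_rotation_angle(FaceAnnotation("x", pts))


class TestAlignFace:
    def test_output_eye_line_horizontal(self):
        ann = _rotate(_template_ann(), 17.0)
        img = render_face(ann)
        _, out_ann, _ = align_face(img, ann)
        assert abs(compute_rotation_angle(out_ann)) < 1e-6

    def test_full_image_crop_box_gives_pure_scaling(self):
        # crop landmarks on the image border, eyes horizontal, margin 0:
        # the transform must reduce to axis scaling onto the output canvas
        pts = _template_ann().points.copy()
        w = h = 224
        for i, (x, y) in zip((3, 10, 29, 30), [(0, 0), (w, 0), (0, h), (w, h)]):
            pts[i - 1] = (x, y)
        for i in (31, 32, 36, 37):
            pts[i - 1] = (w / 2, h / 2)
        ann = FaceAnnotation("x", pts, (w, h))
        img = np.zeros((h, w), np.uint8)
        _, _, tf = align_face(img, ann, out_size=(112, 112), margin_fraction=0.0)
        expect = np.array([[0.5, 0.0, 0.0], [0.0, 0.5, 0.0]])
        assert np.allclose(tf.matrix, expect, atol=1e-9)

    def test_alignment_invariant_to_input_rotation(self):
        ann = _template_ann()
        _, a0, _ = align_face(None, ann)
        _, a15, _ = align_face(None, _rotate(ann, 15.0))
        assert np.abs(a0.points - a15.points).max() < 0.5

    def test_idempotent_on_rendered_faces(self, small_dataset):
        rec = small_dataset.records[0]
        img = render_face(rec.annotation)
        out_img, out_ann, _ = align_face(img, rec.annotation)
        _, again, _ = align_face(out_img, out_ann)
        assert np.abs(again.points - out_ann.points).max() < 0.5

    def test_all_landmarks_inside_output(self, small_dataset):
        for rec in small_dataset.records[:10]:
            _, out_ann, _ = align_face(None, rec.annotation,
                                       out_size=(224, 224))
            assert out_ann.points.min() >= -1e-6
            assert out_ann.points.max() <= 224 + 1e-6

    def test_collapsed_crop_box_raises(self):
        pts = np.tile([[50.0, 50.0]], (37, 1))
        pts[12], pts[13] = (40, 50), (45, 50)
        pts[16], pts[17] = (55, 50), (60, 50)
        with pytest.raises(DegenerateGeometryError):
            align_face(np.zeros((100, 100), np.uint8),
                       FaceAnnotation("x", pts))


class TestEdgeFilters:
    def test_constant_image_zero_response(self):
        img = np.full((32, 32), 57, np.uint8)
        for kind in ("laplacian", "laplacian_bilateral", "prewitt", "sobel"):
            resp = apply_edge_filter(img, kind, rescale=False)
            assert np.allclose(resp, 0.0, atol=1e-9)
            assert resp.shape == img.shape

    def test_vertical_step_edge_directional_response(self):
        img = np.zeros((16, 16))
        img[:, 8:] = 200.0
        from felgrim.preprocess import _SOBEL_X
        import scipy.ndimage as ndi
        gx = ndi.convolve(img, _SOBEL_X, mode="reflect")
        gy = ndi.convolve(img, _SOBEL_X.T, mode="reflect")
        assert np.abs(gy).max() == 0.0         # no horizontal gradient
        assert np.abs(gx[:, 7:9]).min() > 0.0  # strong along the edge column

    def test_ramp_laplacian_interior_zero(self):
        # direct 4-neighbour convolution of a linear ramp vanishes inside
        img = np.outer(np.arange(5.0), np.ones(5)) + np.arange(5.0)
        resp = apply_edge_filter(img, "laplacian", rescale=False)
        assert np.allclose(resp[1:-1, 1:-1], 0.0, atol=1e-9)

    def test_translation_equivariance_interior(self, rng):
        img = rng.uniform(0, 255, size=(24, 24))
        shifted = np.roll(np.roll(img, 1, axis=0), 1, axis=1)
        for kind in ("laplacian", "sobel", "prewitt"):
            a = apply_edge_filter(img, kind, rescale=False)
            b = apply_edge_filter(shifted, kind, rescale=False)
            assert np.allclose(b[3:-3, 3:-3],
                               np.roll(np.roll(a, 1, 0), 1, 1)[3:-3, 3:-3])

    def test_unknown_kind(self):
        with pytest.raises(ValueError):
            apply_edge_filter(np.zeros((4, 4)), "canny")


class TestAugment:
    def test_identity_config_is_noop(self, small_dataset):
        rec = small_dataset.records[0]
        img = render_face(rec.annotation)
        rng = np.random.default_rng(0)
        out_img, out_ann = augment_sample(img, rec.annotation,
                                          AugmentConfig.identity(), rng)
        assert np.array_equal(out_img, img)
        assert np.array_equal(out_ann.points, rec.annotation.points)

    def test_pure_rotation_matches_closed_form(self):
        ann = _template_ann()
        tf = geometric_transform(10.0, 0.0, None, (224, 224))
        got = tf.apply(ann.points)
        t = np.deg2rad(10.0)
        rot = np.array([[np.cos(t), -np.sin(t)], [np.sin(t), np.cos(t)]])
        want = (ann.points - [112, 112]) @ rot.T + [112, 112]
        assert np.abs(got - want).max() < 1e-6

    def test_same_seed_reproduces(self, small_dataset):
        rec = small_dataset.records[1]
        img = render_face(rec.annotation)
        outs = []
        for _ in range(2):
            rng = np.random.default_rng(77)
            outs.append(augment_sample(img, rec.annotation, AugmentConfig(), rng))
        assert np.array_equal(outs[0][0], outs[1][0])
        assert np.array_equal(outs[0][1].points, outs[1][1].points)

    def test_rotation_draw_within_printed_ranges(self):
        ann = _template_ann()
        rng = np.random.default_rng(5)
        cfg = AugmentConfig(flip_prob=0.0, shear_range=(0.0, 0.0))
        for _ in range(25):
            _, out = augment_sample(None, ann, cfg, rng)
            ang = compute_rotation_angle(out) % 360
            assert (3 <= ang <= 19) or (341 <= ang <= 357)

    def test_raster_follows_landmarks(self):
        # a single bright dot lands where the transformed landmark predicts
        img = np.zeros((224, 224), np.uint8)
        ann = _template_ann()
        x, y = int(ann.point(22)[0]), int(ann.point(22)[1])
        img[y, x] = 255
        cfg = AugmentConfig(rotation_ranges=((10.0, 10.0), (10.0, 10.0)),
                            shear_range=(0.05, 0.05), flip_prob=0.0,
                            contrast=(1, 1), sharpness=(1, 1),
                            brightness=(1, 1), color_balance=(1, 1),
                            gaussian_blur=(0, 0))
        out_img, out_ann = augment_sample(img, ann, cfg,
                                          np.random.default_rng(0))
        py, px = np.unravel_index(np.argmax(out_img), out_img.shape)
        assert np.hypot(px - out_ann.point(22)[0],
                        py - out_ann.point(22)[1]) < 1.5

    def test_descriptors_invariant_under_similarity_augmentation(self, registry):
        """Rotation-only augmentation leaves all 35 descriptors unchanged."""
        ann = _template_ann()
        base = np.array(list(evaluate_registry(registry, ann).values()))
        tf = geometric_transform(15.0, 0.0, "left_right", (224, 224))
        moved = ann.replace(tf.apply(ann.points))
        vals = np.array(list(evaluate_registry(registry, moved).values()))
        assert np.abs(vals - base).max() < 1e-6

    def test_interval_validation(self):
        with pytest.raises(ValueError):
            AugmentConfig(shear_range=(0.2, -0.2))
        with pytest.raises(ValueError):
            AugmentConfig(crop_area_fraction=1.5)


class TestCropFace:
    def test_full_image_box_accepted(self, rng):
        img = rng.integers(0, 255, size=(50, 60), dtype=np.uint8)
        res = crop_face(img, whole_image_box(img))
        assert res.accepted
        assert res.image.shape == img.shape
        assert np.array_equal(res.image, img)

    def test_exact_threshold_rejected(self):
        img = np.zeros((100, 100), np.uint8)
        # 63.245^2 ~ 4000 px^2 would be 0.4 exactly; use integer 50x80
        res = crop_face(img, (0, 0, 50, 80))  # area ratio exactly 0.4
        assert not res.accepted
        assert res.area_ratio == pytest.approx(0.4)

    def test_just_above_threshold_accepted(self):
        img = np.zeros((100, 100), np.uint8)
        res = crop_face(img, (10, 10, 70, 70))  # 0.49 > 0.4
        assert res.accepted
        assert res.area_ratio == pytest.approx(0.49)
        assert res.image.shape == (100, 100)

    def test_out_of_image_box_clipped_before_test(self):
        img = np.zeros((100, 100), np.uint8)
        res = crop_face(img, (-50, -50, 120, 120))  # clips to 70x70
        assert res.accepted
        assert res.area_ratio == pytest.approx(0.49)

    def test_landmark_box_provider(self):
        ann = _template_ann()
        x, y, w, h = landmark_box(ann)
        assert x == ann.points[:, 0].min()
        assert x + w == ann.points[:, 0].max()
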