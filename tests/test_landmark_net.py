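"""NRMSE metric family and the reference landmark network."""

import numpy as np
import pytest

from felgrim.landmark_net import (LandmarkNet, NetConfig, build_reference_net,
                                  constant_baseline, model_report, nrmse,
                                  train_landmark_model)
from felgrim.schema import AUS, FaceAnnotation, N_LANDMARKS
from felgrim.synthetic import (GeneratorParams, PainState, deformed_template,
                               render_face)

from conftest import random_similarity


def _ann(pts, image_id="a"):
    return FaceAnnotation(image_id, np.asarray(pts, float))


def _faces(rng, n):
    out = []
    for k in range(n):
        pts = rng.uniform(20, 200, size=(N_LANDMARKS, 2))
        out.append(_ann(pts, f"im{k}"))
    return out


def loop_nrmse(preds, truths, include):
    """Independent double-loop implementation of the printed error formula."""
    total, count = 0.0, 0
    for p, t in zip(preds, truths):
        dn = np.sqrt(((t.point(33) - t.point(34)) ** 2).sum())
        for i in include:
            d = np.sqrt(((p.point(i) - t.point(i)) ** 2).sum())
            total += d / dn
            count += 1
    return total / count * 100.0


class TestNRMSE:
    def test_zero_for_perfect_predictions(self, rng):
        truths = _faces(rng, 3)
        assert nrmse(truths, truths) == 0.0

    def test_displacement_by_normalisation_distance_is_100(self, rng):
        truths = _faces(rng, 4)
        preds = []
        for t in truths:
            dn = np.sqrt(((t.point(33) - t.point(34)) ** 2).sum())
            preds.append(_ann(t.points + [dn, 0.0]))
        assert nrmse(preds, truths) == pytest.approx(100.0)

    def test_matches_double_loop_oracle(self, rng, schema):
        truths = _faces(rng, 2)
        preds = _faces(rng, 2)
        every = list(range(1, 38))
        assert nrmse(preds, truths) == pytest.approx(
            loop_nrmse(preds, truths, every), abs=1e-12)
        keep = sorted(set(every) - set(schema.nrmsew_excluded))
        assert len(keep) == 27  # NRMSEw always uses 27 landmarks
        assert nrmse(preds, truths, include=keep) == pytest.approx(
            loop_nrmse(preds, truths, keep), abs=1e-12)

    def test_scale_invariance_under_joint_similarity(self, rng):
        truths = _faces(rng, 3)
        preds = _faces(rng, 3)
        base = nrmse(preds, truths)
        mat, tvec = random_similarity(rng)
        tp = [_ann(a.points @ mat.T + tvec) for a in preds]
        tt = [_ann(a.points @ mat.T + tvec) for a in truths]
        assert nrmse(tp, tt) == pytest.approx(base, abs=1e-9)

    def test_union_is_count_weighted_mean_of_disjoint_subsets(self, rng):
        truths = _faces(rng, 3)
        preds = _faces(rng, 3)
        A = set(range(1, 16))
        B = set(range(16, 38))
        vA = nrmse(preds, truths, include=A)
        vB = nrmse(preds, truths, include=B)
        vAB = nrmse(preds, truths, include=A | B)
        assert vAB == pytest.approx((len(A) * vA + len(B) * vB) / 37, abs=1e-9)

    def test_degenerate_normalisation_names_image(self, rng):
        truths = _faces(rng, 1)
        truths[0].points[33] = truths[0].points[32]
        with pytest.raises(ValueError, match="im0"):
            nrmse(truths, truths)


class TestNetConstruction:
    def test_output_width_is_74(self):
        net, _ = build_reference_net(NetConfig())
        assert net.layers[-1].W.shape[0] == 74

    def test_flatten_head_has_more_parameters_than_pooling(self):
        _, n_gap = build_reference_net(NetConfig(head="global_average_pooling"))
        _, n_flat = build_reference_net(NetConfig(head="flatten"))
        assert n_flat > n_gap

    def test_parallel_block_kernel_shapes(self):
        from felgrim.landmark_net import _ParallelBlock
        for kind, shapes in (("symmetric", {(3, 3), (1, 1)}),
                             ("asymmetric", {(1, 3), (3, 1)}),
                             ("hybrid", {(3, 3), (1, 3), (3, 1)})):
            net, _ = build_reference_net(NetConfig(parallel_block=kind))
            block = [l for l in net.layers if isinstance(l, _ParallelBlock)][0]
            assert set(block.kernel_shapes) == shapes
        hybrid = set(_ParallelBlock.KERNELS["hybrid"])
        assert set(_ParallelBlock.KERNELS["symmetric"]) & hybrid
        assert set(_ParallelBlock.KERNELS["asymmetric"]) <= hybrid

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            NetConfig(head="max_pool")
        with pytest.raises(ValueError):
            NetConfig(dense_layers=(32, 16, 8))
        with pytest.raises(ValueError):
            NetConfig(parallel_block="diagonal")


def _tiny_training_set(n=24, size=32):
    params = GeneratorParams()
    rng = np.random.default_rng(0)
    imgs, anns = [], []
    from felgrim.synthetic import sample_face, sample_pain_state
    for k in range(n):
        state = sample_pain_state(bool(k % 2), params, rng)
        _, aligned = sample_face(state, params, rng, f"f{k}")
        scaled = FaceAnnotation(f"f{k}", aligned.points * (size / 224),
                                (size, size))
        imgs.append(render_face(aligned, size))
        anns.append(scaled)
    return np.stack(imgs), anns


class TestTraining:
    def test_zero_epochs_equals_untrained(self):
        imgs, anns = _tiny_training_set()
        model, history = train_landmark_model(imgs, anns,
                                              NetConfig(input_size=32),
                                              epochs=0, seed=1)
        fresh = LandmarkNet(NetConfig(input_size=32), seed=1)
        assert history == []
        for a, b in zip(model.parameters(), fresh.parameters()):
            assert np.array_equal(a, b)

    def test_same_seed_identical_validation_loss(self):
        imgs, anns = _tiny_training_set()
        losses = []
        for _ in range(2):
            net = LandmarkNet(NetConfig(input_size=32), seed=5)
            net.fit(imgs, anns, epochs=3)
            losses.append(net.history_)
        assert losses[0] == pytest.approx(losses[1], abs=1e-12)

    def test_training_reduces_validation_loss(self):
        imgs, anns = _tiny_training_set(n=48)
        net = LandmarkNet(NetConfig(input_size=32), seed=0)
        net.fit(imgs, anns, epochs=8)
        assert net.history_[-1] < net.history_[0] * 1.05
        assert min(net.history_) < net.history_[0]

    def test_empty_training_set_rejected(self):
        net = LandmarkNet(NetConfig(input_size=32))
        with pytest.raises(ValueError):
            net.fit(np.zeros((0, 32, 32)), [])


class TestModelReport:
    def test_perfect_oracle_predictor_all_zero(self, rng):
        truths = _faces(rng, 5)

        class Oracle:
            param_count = 0

            def predict(self, images):
                return truths

        rep = model_report(Oracle(), np.zeros((5, 8, 8)), truths)
        assert rep.nrmse_pct == 0.0
        assert rep.nrmsew_pct == 0.0
        assert all(v == 0.0 for v in rep.per_au_nrmse_pct.values())

    def test_per_au_values_recompose_to_overall(self, rng, schema):
        truths = _faces(rng, 6)
        preds = _faces(rng, 6)

        class Fixed:
            def predict(self, images):
                return preds

        rep = model_report(Fixed(), np.zeros((6, 8, 8)), truths, schema)
        weighted = sum(len(schema.au_indices(au)) * rep.per_au_nrmse_pct[au]
                       for au in AUS) / 37
        assert rep.nrmse_pct == pytest.approx(weighted, abs=1e-9)

    def test_nrmsew_below_nrmse_when_excluded_landmarks_carry_error(
            self, rng, schema):
        truths = _faces(rng, 4)
        preds = []
        for t in truths:
            pts = t.points.copy()
            for i in schema.nrmsew_excluded:
                pts[i - 1] += 40.0  # pile error onto the excluded set
            preds.append(_ann(pts))

        class Fixed:
            def predict(self, images):
                return preds

        rep = model_report(Fixed(), np.zeros((4, 8, 8)), truths, schema)
        assert rep.nrmsew_pct < rep.nrmse_pct

    def test_constant_baseline_predicts_mean_configuration(self, rng):
        truths = _faces(rng, 10)
        base = constant_baseline(truths)
        preds = base.predict(np.zeros((3, 8, 8)))
        mean_pts = np.mean([t.points for t in truths], axis=0)
        for p in preds:
            assert np.allclose(p.points, mean_pts)
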