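"""Architecture fidelity, gradients, features, fusion, freezing."""

import numpy as np
import pytest

from wmbrainage.network import NetworkSpec, build_network
from wmbrainage.train import (
    TrainConfig,
    TrainedSingleMapModel,
    extract_features,
    fit_fusion_head,
    predict_fusion,
    train_single_map,
)


def _tiny_spec(**kw):
    base = dict(
        input_shape=(8, 8, 8),
        conv_channels=(2, 3, 2, 2, 2, 2),
        feature_dim=3,
        dropout_rate=0.0,
        allow_small_axes=True,
        normalise_input=False,
        dtype="float64",
    )
    base.update(kw)
    return NetworkSpec(**base)


class TestArchitecture:
    def test_default_shape_trace_matches_design(self):
        t = NetworkSpec().shape_trace()
        assert t["post_block6_spatial"] == (2, 3, 2)
        assert t["block7_feature_dim"] == 100
        assert t["block8_fusion_input"] == 503
        assert t["conv_channels"][5] == 64
        assert t["dropout_rate"] == 0.5
        assert t["block7_flat_input"] == 64 * 2 * 3 * 2

    def test_cube_32_collapses_to_unit_extent(self):
        spec = NetworkSpec(input_shape=(32, 32, 32))
        assert spec.post_block6_shape == (1, 1, 1)

    def test_small_axis_rejected_without_flag(self):
        with pytest.raises(ValueError, match="annihilated"):
            build_network(NetworkSpec(input_shape=(24, 28, 24)))

    def test_small_axis_passthrough_with_flag(self):
        spec = NetworkSpec(input_shape=(24, 28, 24), allow_small_axes=True)
        assert spec.post_block6_shape == (1, 1, 1)

    def test_measured_trace_agrees_with_arithmetic(self):
        spec = _tiny_spec(input_shape=(33, 40, 36), dtype="float32")
        net = build_network(spec, seed=0)
        x = np.random.default_rng(0).normal(size=(33, 40, 36))
        measured = net.measure_trace(x)
        assert measured["block6_spatial"] == spec.post_block6_shape
        assert measured["block7_feature_len"] == spec.feature_dim
        assert measured["block7_flat_input"] == spec.flat_dim

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            NetworkSpec(conv_channels=(32, 64, 128))
        with pytest.raises(ValueError):
            NetworkSpec(feature_dim=0)
        with pytest.raises(ValueError):
            NetworkSpec(dropout_rate=1.0)


class TestGradientsAndDeterminism:
    def test_backward_matches_finite_differences(self):
        spec = _tiny_spec()
        net = build_network(spec, seed=1)
        rng = np.random.default_rng(0)
        x = rng.normal(size=(4, 8, 8, 8))
        cov = rng.normal(size=(4, 2))
        ages = rng.normal(60, 5, 4)

        def loss():
            pred, caches = net.forward(x, cov, train=True)
            r = pred - ages
            return 0.5 * np.sum(r**2), r, caches

        _, resid, caches = loss()
        grads = net.backward(resid, caches)
        eps = 1e-6
        for name in ("conv1_W", "conv4_W", "conv6_W", "bn3_gamma", "fc7_W", "head_W"):
            flat = net.params[name].reshape(-1)
            for i in rng.choice(flat.size, size=min(4, flat.size), replace=False):
                orig = flat[i]
                flat[i] = orig + eps
                lp, _, _ = loss()
                flat[i] = orig - eps
                lm, _, _ = loss()
                flat[i] = orig
                num = (lp - lm) / (2 * eps)
                ana = grads[name].reshape(-1)[i]
                assert abs(num - ana) / max(1e-8, abs(num) + abs(ana)) < 1e-5, name

    def test_dropout_only_in_training_mode(self):
        spec = _tiny_spec(
            dropout_rate=0.5, dtype="float32", input_shape=(16, 16, 16),
            conv_channels=(4, 4, 4, 4, 4, 16), feature_dim=8,
        )
        net = build_network(spec, seed=2)
        x = np.random.default_rng(1).normal(size=(3, 16, 16, 16)).astype(np.float32)
        cov = np.zeros((3, 2), np.float32)
        e1, _ = net.forward(x, cov, train=False)
        e2, _ = net.forward(x, cov, train=False)
        np.testing.assert_array_equal(e1, e2)  # eval deterministic
        rng_a = np.random.default_rng(10)
        rng_b = np.random.default_rng(11)
        t1, _ = net.forward(x, cov, train=True, rng=rng_a)
        t2, _ = net.forward(x, cov, train=True, rng=rng_b)
        assert not np.allclose(t1, t2)  # dropout active in training

    def test_feature_determinism_length_and_spatial_sensitivity(self):
        spec = _tiny_spec(dtype="float32")
        net = build_network(spec, seed=3)
        rng = np.random.default_rng(2)
        x = rng.normal(size=(8, 8, 8)).astype(np.float32)
        f1 = net.features(x)
        f2 = net.features(x)
        np.testing.assert_array_equal(f1, f2)
        assert f1.shape == (1, spec.feature_dim)
        perm = x.reshape(-1)[rng.permutation(x.size)].reshape(x.shape)
        assert not np.allclose(net.features(perm), f1)


@pytest.fixture(scope="module")
def tiny_training():
    rng = np.random.default_rng(0)
    n = 24
    ages = rng.uniform(45, 83, n)
    # volumes whose mean level tracks age plus structure
    base = rng.normal(size=(8, 8, 8)).astype(np.float32)
    vols = np.stack(
        [0.02 * a * np.ones((8, 8, 8), np.float32) + base + 0.05 * rng.normal(size=(8, 8, 8)).astype(np.float32) for a in ages]
    )
    sex = rng.integers(0, 2, n)
    scanner = rng.integers(0, 3, n)
    return vols, ages, sex, scanner


class TestTraining:
    def test_training_reduces_loss_and_beats_mean_baseline(self, tiny_training):
        vols, ages, sex, scanner = tiny_training
        spec = _tiny_spec(
            dtype="float32", normalise_input=False, conv_channels=(4, 4, 4, 4, 4, 4)
        )
        cfg = TrainConfig(epochs=4, batch_size=8, seed=0)
        m = train_single_map(vols, ages, sex, scanner, spec, cfg)
        assert len(m.loss_log) == 4
        assert m.loss_log[-1] < m.loss_log[0]
        pred = m.predict(vols, sex, scanner)
        mae = np.abs(pred - ages).mean()
        baseline = np.abs(ages - ages.mean()).mean()
        assert mae < baseline

    def test_same_seed_identical_parameters(self, tiny_training):
        vols, ages, sex, scanner = tiny_training
        spec = _tiny_spec(dtype="float32", conv_channels=(2, 2, 2, 2, 2, 2))
        cfg = TrainConfig(epochs=1, batch_size=8, seed=9)
        m1 = train_single_map(vols, ages, sex, scanner, spec, cfg)
        m2 = train_single_map(vols, ages, sex, scanner, spec, cfg)
        for k, v in m1.model.params.items():
            np.testing.assert_array_equal(v, m2.model.params[k])

    def test_single_participant_rejected(self, tiny_training):
        vols, ages, sex, scanner = tiny_training
        with pytest.raises(ValueError, match="two participants"):
            train_single_map(vols[:1], ages[:1], sex[:1], scanner[:1], _tiny_spec(), TrainConfig())

    def test_constant_age_degenerate_target(self, tiny_training):
        vols, _, sex, scanner = tiny_training
        ages = np.full(len(vols), 60.0)
        spec = _tiny_spec(dtype="float32", conv_channels=(2, 2, 2, 2, 2, 2))
        m = train_single_map(vols, ages, sex, scanner, spec, TrainConfig(epochs=2, seed=1))
        pred = m.predict(vols, sex, scanner)
        assert np.abs(pred - 60.0).mean() < 1.0

    def test_grid_mismatch_rejected(self, tiny_training):
        vols, ages, sex, scanner = tiny_training
        spec = _tiny_spec(dtype="float32", conv_channels=(2, 2, 2, 2, 2, 2))
        m = train_single_map(vols, ages, sex, scanner, spec, TrainConfig(epochs=1, seed=1))
        with pytest.raises(ValueError, match="grid"):
            extract_features(m, np.zeros((2, 9, 8, 8)))


class TestFusion:
    def test_exact_linear_solution_recovered(self):
        rng = np.random.default_rng(3)
        n, fd = 40, 4
        ages = rng.uniform(45, 83, n)
        feats = [rng.normal(size=(n, fd)) for _ in range(5)]
        feats[2][:, 1] = ages  # one coordinate equals age exactly
        cov = rng.normal(size=(n, 3))
        head = fit_fusion_head(feats, cov, ages)
        w = head.weights
        idx = 2 * fd + 1
        assert abs(w[idx] - 1.0) < 1e-8
        others = np.delete(w, idx)
        assert np.max(np.abs(others)) < 1e-8
        assert abs(head.intercept) < 1e-6

    def test_wrong_input_length_rejected(self):
        rng = np.random.default_rng(4)
        head = fit_fusion_head(
            [rng.normal(size=(30, 4))] * 5, rng.normal(size=(30, 3)), rng.uniform(50, 80, 30)
        )
        with pytest.raises(ValueError, match="fused input length"):
            predict_fusion(head, [rng.normal(size=(5, 3))] * 5, rng.normal(size=(5, 3)))

    def test_fusion_head_leaves_map_networks_untouched(self):
        rng = np.random.default_rng(5)
        spec = _tiny_spec(dtype="float32", conv_channels=(2, 2, 2, 2, 2, 2))
        net = build_network(spec, seed=6)
        trained = TrainedSingleMapModel("FA", spec, net)
        before = {k: v.copy() for k, v in net.get_state().items()}
        vols = rng.normal(size=(25, 8, 8, 8)).astype(np.float32)
        feats = extract_features(trained, vols)
        fit_fusion_head(
            [feats] * 5, rng.normal(size=(25, 3)), rng.uniform(45, 83, 25)
        )
        after = net.get_state()
        for k in before:
            np.testing.assert_array_equal(before[k], after[k])

    def test_predict_age_full_stack_and_missing_map_error(self):
        from wmbrainage.imgio import MAP_NAMES
        from wmbrainage.train import predict_age

        rng = np.random.default_rng(7)
        spec = _tiny_spec(dtype="float32", conv_channels=(2, 2, 2, 2, 2, 2))
        models = {
            m: TrainedSingleMapModel(m, spec, build_network(spec, seed=i))
            for i, m in enumerate(MAP_NAMES)
        }
        vols = {m: rng.normal(size=(3, 8, 8, 8)).astype(np.float32) for m in MAP_NAMES}
        ages = rng.uniform(45, 83, 20)
        head = fit_fusion_head(
            [rng.normal(size=(20, spec.feature_dim)) for _ in range(5)],
            rng.normal(size=(20, 3)),
            ages,
        )
        pred = predict_age(models, head, vols, np.zeros((3, 3)))
        assert pred.shape == (3,) and np.all(np.isfinite(pred))
        with pytest.raises(ValueError, match="MO"):
            predict_age(models, head, {m: vols[m] for m in MAP_NAMES[:4]}, np.zeros((3, 3)))

    def test_batch_vs_single_prediction_identical(self):
        rng = np.random.default_rng(6)
        spec = _tiny_spec(dtype="float32", conv_channels=(2, 2, 2, 2, 2, 2))
        net = build_network(spec, seed=7)
        trained = TrainedSingleMapModel("FA", spec, net)
        vols = rng.normal(size=(4, 8, 8, 8)).astype(np.float32)
        sex = np.array([0, 1, 0, 1])
        scanner = np.array([0, 1, 2, 0])
        batch = trained.predict(vols, sex, scanner)
        singles = np.concatenate(
            [trained.predict(vols[i], sex[i], scanner[i]) for i in range(4)]
        )
        np.testing.assert_allclose(batch, singles, rtol=0, atol=1e-5)
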