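"""Dual-branch regression network: shapes, transform, loss, symmetries."""

import numpy as np
import pytest

import sowmorph.engine as eg
from sowmorph.dbmonet import (DbmoNet, NetConfig, RegressionSample, loss,
                              predict, train_regressor)


@pytest.fixture(scope="module")
def tiny_config():
    return NetConfig(n_points=64, sa1_mlp=((8, 8), (8, 8)), sa2_mlp=((16, 16), (16, 16)),
                     location_global=32, edgeconv_k=6, edgeconv_channels=(8, 8, 8, 8),
                     feature_global=32, head=(16,), tnet_hidden=(8, 8), tnet_fc=8,
                     seed=0)


@pytest.fixture(scope="module")
def tiny_model(tiny_config):
    return DbmoNet(tiny_config)


@pytest.fixture(scope="module")
def cloud64(tiny_config):
    rng = np.random.default_rng(3)
    return rng.normal(0, 150, (64, 3)) + np.array([0, 0, 1700.0])


class TestArchitectureShapes:
    def test_default_config_printed_dimensions(self):
        cfg = NetConfig()
        assert cfg.sa2_channels == 256
        assert cfg.location_global == 1024
        assert cfg.feature_global == 1024
        assert cfg.fused_channels == 2048
        assert cfg.pam_tap_channels == 384

    def test_forward_shapes_any_valid_n(self, tiny_model, cloud64):
        pred, inter = tiny_model.forward(cloud64, return_intermediates=True)
        n = 64
        assert pred.data.shape == (1, 6)
        (c1, f1), (c2, f2) = inter["location_levels"]
        assert c1.shape == (n // 4, 3) and f1.shape[0] == n // 4
        assert c2.shape == (n // 16, 3)
        assert f2.shape == (n // 16, tiny_model.config.sa2_channels)
        assert inter["tap"].shape == (n, tiny_model.config.pam_tap_channels)
        assert inter["fused_width"] == tiny_model.config.fused_channels


class TestSpatialTransform:
    def test_theta_identity_at_init(self, tiny_model, cloud64):
        _, inter = tiny_model.forward(cloud64, return_intermediates=True)
        np.testing.assert_allclose(inter["theta"], np.eye(3))

    def test_applied_as_row_vector_times_matrix(self):
        x = eg.Tensor(np.array([[1.0, 2.0, 3.0]]))
        theta = np.diag([2.0, 2.0, 2.0])
        out = eg.matmul(x, eg.Tensor(theta))
        np.testing.assert_allclose(out.data, [[2.0, 4.0, 6.0]])
        swap = np.array([[0, 1, 0], [1, 0, 0], [0, 0, 1.0]])
        out = eg.matmul(x, eg.Tensor(swap))
        np.testing.assert_allclose(out.data, [[2.0, 1.0, 3.0]])


class TestFeatureBranch:
    def test_identical_points_zero_edge_differences(self, tiny_model):
        pts = np.tile([100.0, -50.0, 1500.0], (64, 1))
        _, inter = tiny_model.forward(pts, return_intermediates=True)
        for f in inter["edgeconv_features"]:
            # every point identical -> identical features per point
            assert np.allclose(f, f[0])

    def test_dynamic_graph_changes_between_layers(self, tiny_model, cloud64):
        from sowmorph.neighborhood import knn_feat

        _, inter = tiny_model.forward(cloud64, return_intermediates=True)
        k = tiny_model.config.edgeconv_k
        g1 = knn_feat(inter["edgeconv_features"][0], k).indices
        g2 = knn_feat(inter["edgeconv_features"][1], k).indices
        assert not np.array_equal(g1, g2)

    def test_k_not_smaller_than_n_raises(self, tiny_config):
        model = DbmoNet(tiny_config)
        pts = np.random.default_rng(0).normal(size=(6, 3))
        with pytest.raises(ValueError, match="must be < n"):
            model.feature_branch(eg.Tensor(pts))


class TestForward:
    def test_repeated_passes_bit_stable(self, tiny_model, cloud64):
        a = tiny_model.forward(cloud64).data
        b = tiny_model.forward(cloud64).data
        np.testing.assert_array_equal(a, b)

    def test_zero_weight_head_outputs_bias(self, tiny_config, cloud64):
        model = DbmoNet(tiny_config)
        last = model.head.layers[-1]
        last.W.data[:] = 0.0
        last.b.data[:] = [211.5, 36.4, 36.9, 86.6, 90.1, 84.6]
        for layer in model.head.layers[:-1]:
            layer.W.data[:] = 0.0
            layer.b.data[:] = 0.0
        pred = model.forward(cloud64)
        np.testing.assert_allclose(pred.data[0], [211.5, 36.4, 36.9, 86.6, 90.1, 84.6])

    def test_translation_invariance_via_centroid_centering(self, tiny_model, cloud64):
        shifted = cloud64 + np.array([500.0, -300.0, 250.0])
        a = tiny_model.forward(cloud64).data
        b = tiny_model.forward(shifted).data
        np.testing.assert_allclose(a, b, atol=1e-9)

    def test_permutation_invariance_of_prediction(self, tiny_model, cloud64):
        rng = np.random.default_rng(11)
        perm = rng.permutation(len(cloud64))
        a = tiny_model.forward(cloud64).data
        b = tiny_model.forward(cloud64[perm]).data
        np.testing.assert_allclose(a, b, atol=1e-9)


class TestLoss:
    def test_zero_when_prediction_equals_label(self):
        pred = eg.Tensor(np.ones((3, 6)) * 5)
        total, comps = loss(pred, np.ones((3, 6)) * 5)
        assert float(total.data) == 0.0
        assert all(v == 0.0 for v in comps.values())

    def test_single_sample_single_error(self):
        # BW off by 2, everything else exact: Loss = 2^2 = 4
        target = np.array([[211.5, 36.4, 36.9, 86.6, 90.1, 84.6]])
        pred_arr = target.copy()
        pred_arr[0, 0] += 2.0
        total, comps = loss(eg.Tensor(pred_arr), target)
        assert float(total.data) == pytest.approx(4.0)
        assert comps["BW"] == pytest.approx(4.0)

    def test_total_is_sum_of_six_components(self, rng):
        pred = eg.Tensor(rng.uniform(50, 250, (5, 6)))
        total, comps = loss(pred, rng.uniform(50, 250, (5, 6)))
        assert float(total.data) == pytest.approx(sum(comps.values()))

    def test_empty_batch_rejected(self):
        with pytest.raises(ValueError):
            loss(eg.Tensor(np.empty((0, 6))), np.empty((0, 6)))


class TestTraining:
    def _make_sets(self, tiny_config):
        rng = np.random.default_rng(4)
        def make(subject):
            pts = rng.normal(0, 150, (200, 3)) + [0, 0, 1700.0]
            target = np.array([211.5, 36.4, 36.9, 86.6, 90.1, 84.6]) \
                + rng.normal(0, 1, 6)
            return RegressionSample(pts, target, subject)
        train = [make(s) for s in range(4) for _ in range(2)]
        val = [make(s) for s in (8, 9)]
        return train, val

    def test_subject_leakage_is_hard_error(self, tiny_config):
        train, val = self._make_sets(tiny_config)
        val[0] = RegressionSample(val[0].points, val[0].target, subject_id=0)
        with pytest.raises(ValueError, match="leakage"):
            train_regressor(train, val, tiny_config, epochs=1)

    def test_zero_lr_constant_history(self, tiny_config):
        train, val = self._make_sets(tiny_config)
        cfg = NetConfig(**{**tiny_config.__dict__, "resample_each_epoch": False})
        _, hist = train_regressor(train, val, cfg, epochs=3, lr=0.0, seed=1)
        losses = [h["train_loss"] for h in hist]
        assert losses[0] == pytest.approx(losses[-1])

    def test_same_seed_identical_history(self, tiny_config):
        train, val = self._make_sets(tiny_config)
        _, h1 = train_regressor(train, val, tiny_config, epochs=2, seed=5)
        _, h2 = train_regressor(train, val, tiny_config, epochs=2, seed=5)
        assert h1 == h2

    def test_head_bias_initialised_to_label_mean_helps_start(self, tiny_config):
        train, val = self._make_sets(tiny_config)
        _, hist = train_regressor(train, val, tiny_config, epochs=1, seed=0)
        # starting near the label mean keeps the first epoch loss at the
        # label-variance scale rather than the raw-square scale (~211^2)
        assert hist[0]["train_loss"] < 500


def test_model_serialisation_roundtrip(tiny_config, cloud64, tmp_path):
    from sowmorph.dbmonet import load_model, save_model

    model = DbmoNet(tiny_config)
    path = tmp_path / "model.npz"
    save_model(model, path)
    back = load_model(path)
    np.testing.assert_array_equal(back.forward(cloud64).data,
                                  model.forward(cloud64).data)


def test_predict_handles_arbitrary_cloud_size(tiny_model, rng):
    out = predict(tiny_model, rng.normal(0, 100, (500, 3)), seed=1)
    assert out.shape == (6,)
    out_small = predict(tiny_model, rng.normal(0, 100, (40, 3)), seed=1)
    assert out_small.shape == (6,)
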