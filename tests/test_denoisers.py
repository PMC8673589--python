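"""Denoiser architectures, losses, and the training protocol."""

import numpy as np
import pytest

from denoiseiq import _nn
from denoiseiq import denoisers as dn
from denoiseiq import phantom_imaging as pi
from denoiseiq.evaluation_experiments import rmse


@pytest.fixture(scope="module")
def small_data():
    cfg = pi.study_32(n_train=120, n_validation=30)
    return pi.generate_dataset(cfg, seed=31, splits=("train", "validation"))


class TestArchitectures:
    def test_linear_minimal_depth_two_convs(self):
        model = dn.build_denoiser(dn.DenoiserArchitecture("linear", 2),
                                  np.random.default_rng(0))
        convs = [l for blk in model.blocks for l in blk]
        assert len(convs) == 2
        assert (convs[0].c_in, convs[0].c_out) == (1, 32)
        assert (convs[1].c_in, convs[1].c_out) == (32, 1)

    def test_depth_below_minimum_rejected(self):
        with pytest.raises(ValueError):
            dn.DenoiserArchitecture("linear", 1)
        with pytest.raises(ValueError):
            dn.DenoiserArchitecture("cnn", 2)
        with pytest.raises(ValueError):
            dn.DenoiserArchitecture("unknown", 5)

    @pytest.mark.parametrize("family,depth", [("linear", 4), ("cnn", 5),
                                              ("resnet", 5), ("resnet", 6)])
    def test_output_shape_preserved(self, family, depth):
        model = dn.build_denoiser(
            dn.DenoiserArchitecture(family, depth, features=8),
            np.random.default_rng(1))
        x = np.random.default_rng(2).normal(size=(2, 16, 16)).astype(np.float32)
        model.set_normalization(x)
        out = model.denoise(x)
        assert out.shape == x.shape
        assert np.isfinite(out).all()

    def test_cnn_layer_composition(self):
        model = dn.build_denoiser(dn.DenoiserArchitecture("cnn", 5),
                                  np.random.default_rng(0))
        kinds = [[type(l).__name__ for l in blk] for blk in model.blocks]
        assert kinds[0] == ["Conv2d", "ReLU"]
        assert kinds[1] == kinds[2] == ["Conv2d", "BatchNorm2d", "ReLU"]
        assert kinds[3] == ["Conv2d", "BatchNorm2d"]
        assert kinds[4] == ["Conv2d"]

    def test_resnet_tape_has_pairwise_and_long_skips(self):
        model = dn.build_denoiser(dn.DenoiserArchitecture("resnet", 7),
                                  np.random.default_rng(0))
        adds = [tag for op, tag in model.tape if op == "add"]
        # middle blocks 1..5 -> two pairwise skips + the long one
        assert adds == ["skip1", "skip3", "long"]
        saves = [tag for op, tag in model.tape if op == "save"]
        assert "long" in saves

    def test_resnet_skip_changes_forward(self):
        rng = np.random.default_rng(5)
        res = dn.build_denoiser(dn.DenoiserArchitecture("resnet", 5, features=4), rng)
        cnn = dn.build_denoiser(dn.DenoiserArchitecture("cnn", 5, features=4),
                                np.random.default_rng(5))
        # same weights by construction (same rng sequence)
        x = np.random.default_rng(6).normal(size=(1, 8, 8, 1)).astype(np.float32)
        a = res.forward_normalized(x)
        b = cnn.forward_normalized(x)
        assert not np.allclose(a, b)


class TestLosses:
    def test_mse_zero_on_equal(self):
        x = np.ones((3, 4, 4))
        assert dn.mse_loss(x, x) == 0.0

    def test_mse_batch_mean_of_image_sums(self):
        out = np.zeros((2, 2, 2))
        tgt = out.copy()
        tgt[1, 0, 1] = 2.0  # squared norm 4 in one of two images
        assert dn.mse_loss(out, tgt) == pytest.approx(2.0)

    def test_mse_nonnegative(self):
        r = np.random.default_rng(0)
        assert dn.mse_loss(r.normal(size=(2, 3, 3)), r.normal(size=(2, 3, 3))) >= 0

    def test_perceptual_identity_extractor_reduces_to_mse(self):
        r = np.random.default_rng(1)
        a, b = r.normal(size=(2, 4, 4, 1)), r.normal(size=(2, 4, 4, 1))
        assert dn.perceptual_loss(a, b, dn.IdentityFeatureExtractor()) == \
            pytest.approx(dn.mse_loss(a, b), rel=1e-6)

    def test_perceptual_zero_on_equal(self):
        x = np.random.default_rng(2).normal(size=(1, 8, 8, 1)).astype(np.float32)
        phi = dn.RandomConvFeatureExtractor(n_features=8)
        assert dn.perceptual_loss(x, x, phi) == 0.0

    def test_perceptual_gradient_flows_to_denoiser_not_extractor(self):
        """Finite-difference check through phi; phi's own grads stay zero."""
        phi = dn.RandomConvFeatureExtractor(n_features=4)
        rng = np.random.default_rng(3)
        out = rng.normal(size=(1, 6, 6, 1)).astype(np.float32)
        tgt = rng.normal(size=(1, 6, 6, 1)).astype(np.float32)

        def loss():
            fo = phi.forward(out, training=True)
            ft = phi.forward(tgt)
            return _nn.mse_image_loss(fo, ft)[0]

        fo = phi.forward(out, training=True)
        ft = phi.forward(tgt)
        _, dfeat = _nn.mse_image_loss(fo, ft)
        dout = phi.backward(dfeat.astype(np.float32))
        idx = (0, 2, 3, 0)
        eps = 1e-3
        old = out[idx]
        out[idx] = old + eps
        lp = loss()
        out[idx] = old - eps
        lm = loss()
        out[idx] = old
        assert dout[idx] == pytest.approx((lp - lm) / (2 * eps), rel=5e-3, abs=1e-5)
        assert all(np.all(p.grad == 0) for layer in phi.layers
                   for p in layer.params())


class TestTrainingAndInference:
    def test_identity_initialized_linear_net_is_identity(self):
        model = dn.build_denoiser(dn.DenoiserArchitecture("linear", 3, features=4),
                                  np.random.default_rng(0))
        for blk in model.blocks:
            conv = blk[0]
            conv.weight.value[...] = 0.0
            conv.bias.value[...] = 0.0
            # delta kernel routing channel 0 -> channel 0
            conv.weight.value[1, 1, 0, 0] = 1.0
        x = np.random.default_rng(1).normal(10, 3, size=(2, 8, 8)).astype(np.float32)
        model.set_normalization(x)
        np.testing.assert_allclose(model.denoise(x), x, rtol=1e-5, atol=1e-4)

    def test_one_epoch_smoke_records_history(self, small_data):
        model = dn.build_denoiser(dn.DenoiserArchitecture("cnn", 3, features=8),
                                  np.random.default_rng(4))
        cfg = dn.TrainingConfig(batch_present=10, batch_absent=10, epochs=1,
                                steps_per_epoch=2, seed=1)
        hist = dn.train_denoiser(model, small_data["train"],
                                 small_data["validation"], cfg)
        assert len(hist["val_loss"]) == 1 and model.trained

    def test_training_reduces_validation_rmse(self, small_data):
        model = dn.build_denoiser(dn.DenoiserArchitecture("cnn", 3, features=16),
                                  np.random.default_rng(7))
        cfg = dn.TrainingConfig(batch_present=20, batch_absent=20, epochs=30,
                                steps_per_epoch=10, seed=2, patience=30)
        dn.train_denoiser(model, small_data["train"], small_data["validation"],
                          cfg)
        val = small_data["validation"]
        noisy_rmse = rmse(val.images, val.targets)
        den_rmse = rmse(model.denoise(val.images), val.targets)
        assert den_rmse < noisy_rmse

    def test_training_reproducible_from_seed(self, small_data):
        outs = []
        for _ in range(2):
            model = dn.build_denoiser(
                dn.DenoiserArchitecture("linear", 3, features=8),
                np.random.default_rng(11))
            cfg = dn.TrainingConfig(batch_present=10, batch_absent=10, epochs=2,
                                    steps_per_epoch=3, seed=5)
            dn.train_denoiser(model, small_data["train"],
                              small_data["validation"], cfg)
            outs.append(model.denoise(small_data["validation"].images[:4]))
        np.testing.assert_array_equal(outs[0], outs[1])

    def test_inference_deterministic(self, small_data):
        model = dn.build_denoiser(dn.DenoiserArchitecture("resnet", 5, features=8),
                                  np.random.default_rng(3))
        model.set_normalization(small_data["train"].images)
        x = small_data["train"].images[:3]
        np.testing.assert_array_equal(model.denoise(x), model.denoise(x))

    def test_missing_targets_rejected(self, small_data):
        train = small_data["train"]
        no_targets = pi.ImageEnsemble(images=train.images, labels=train.labels)
        model = dn.build_denoiser(dn.DenoiserArchitecture("cnn", 3, features=4),
                                  np.random.default_rng(0))
        with pytest.raises(ValueError):
            dn.train_denoiser(model, no_targets, no_targets, dn.TrainingConfig())

    def test_linear_family_is_affine(self, small_data):
        """F(a g1 + (1-a) g2) = a F(g1) + (1-a) F(g2) for the linear family."""
        model = dn.build_denoiser(dn.DenoiserArchitecture("linear", 4, features=8),
                                  np.random.default_rng(13))
        model.set_normalization(small_data["train"].images)
        g1 = small_data["train"].images[:2]
        g2 = small_data["train"].images[2:4]
        alpha = 0.3
        lhs = model.denoise(alpha * g1 + (1 - alpha) * g2)
        rhs = alpha * model.denoise(g1) + (1 - alpha) * model.denoise(g2)
        np.testing.assert_allclose(lhs, rhs, atol=5e-3)

    def test_checkpoint_roundtrip(self, small_data, tmp_path):
        model = dn.build_denoiser(dn.DenoiserArchitecture("cnn", 4, features=8),
                                  np.random.default_rng(17))
        cfg = dn.TrainingConfig(batch_present=10, batch_absent=10, epochs=1,
                                steps_per_epoch=2, seed=9)
        dn.train_denoiser(model, small_data["train"], small_data["validation"],
                          cfg)
        path = tmp_path / "ckpt.npz"
        dn.save_checkpoint(model, path)
        back = dn.load_checkpoint(path)
        x = small_data["validation"].images[:3]
        np.testing.assert_allclose(back.denoise(x), model.denoise(x), atol=1e-6)


class TestLayerOperators:
    def test_matrix_path_equals_network_forward(self, small_data):
        model = dn.build_denoiser(dn.DenoiserArchitecture("linear", 3, features=6),
                                  np.random.default_rng(19))
        model.set_normalization(small_data["train"].images)
        ops = dn.extract_layer_operators(model)
        imgs = small_data["train"].images[:4]
        v = imgs.reshape(4, -1).astype(np.float64)
        for op in ops:
            v = op.apply(v)
        net = model.denoise(imgs).reshape(4, -1)
        rel = np.abs(v - net).max() / np.abs(net).max()
        assert rel < 1e-5

    def test_delta_kernel_layer_is_identity_matrix(self):
        from denoiseiq.covariance_propagation import conv_layer_operator

        w = np.zeros((3, 3, 1, 1))
        w[1, 1, 0, 0] = 1.0
        op = conv_layer_operator(w, np.zeros(1), (5, 5))
        assert (op.matrix.toarray() == np.eye(25)).all()

    def test_nonlinear_model_rejected(self):
        model = dn.build_denoiser(dn.DenoiserArchitecture("cnn", 3, features=4),
                                  np.random.default_rng(0))
        with pytest.raises(ValueError):
            dn.extract_layer_operators(model, image_shape=(8, 8))
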