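"""Tests of the autodiff engine and the WGAN-GP harmonizer mechanics."""

import numpy as np
import pandas as pd
import pytest

from ctharmony.nn import autodiff as ad
from ctharmony.nn.layers import Conv2d
from ctharmony.gan_harmonize import (
    ConvCritic,
    CriticSpec,
    DataError,
    GeneratorSpec,
    LossError,
    LossWeights,
    ScalingError,
    ShallowCNNGenerator,
    TrainConfig,
    generator_loss,
    gradient_penalty,
    harmonize_images,
    train_harmonizer,
)


class TestAutodiff:
    def test_gradients_match_finite_differences(self):
        rng = np.random.default_rng(0)
        x = ad.Tensor(rng.normal(size=(2, 3, 8, 8)))
        w = ad.parameter(rng.normal(size=(4, 3, 3, 3)) * 0.1)
        b = ad.parameter(rng.normal(size=4) * 0.1)

        def f():
            h = ad.relu(ad.conv2d(x, w, b, stride=1, padding=1))
            return ad.sum_(ad.mul(ad.tanh(h), ad.tanh(h)))

        loss = f()
        gw, gb = ad.grad(loss, [w, b])
        eps = 1e-6
        for p, g in ((w, gw), (b, gb)):
            idx = tuple(rng.integers(s) for s in p.data.shape)
            orig = p.data[idx]
            p.data[idx] = orig + eps
            fp = f().data
            p.data[idx] = orig - eps
            fm = f().data
            p.data[idx] = orig
            assert g.data[idx] == pytest.approx((fp - fm) / (2 * eps), rel=1e-4)

    def test_second_order_gradient_of_linear_function(self):
        # d/dc of the gradient-norm penalty of a c-scaled linear map
        c = ad.parameter(np.array(2.0))
        x = ad.Tensor(np.random.default_rng(1).random((3, 1, 1, 1)), requires_grad=True)
        s = ad.sum_(ad.mul(ad.broadcast_to(ad.reshape(c, (1, 1, 1, 1)), x.shape), x))
        (gx,) = ad.grad(s, [x])
        norm = ad.sqrt(ad.sum_(ad.mul(gx, gx), axis=(1, 2, 3)))
        pen = ad.mean(ad.power(norm - ad.Tensor(1.0), 2.0))
        (gc,) = ad.grad(pen, [c])
        # pen(c) = (c-1)^2 on single-pixel inputs -> d/dc = 2(c-1) = 2
        assert pen.data == pytest.approx(1.0)
        assert gc.data == pytest.approx(2.0)


class TestGradientPenalty:
    @staticmethod
    def _linear_critic(scale):
        return lambda x: ad.mul(ad.sum_(x, axis=(1, 2, 3)), ad.Tensor(np.array(scale)))

    def test_unit_gradient_critic_gives_zero(self):
        r = np.random.default_rng(0).random((4, 1, 1, 1))
        f = np.random.default_rng(1).random((4, 1, 1, 1))
        assert gradient_penalty(self._linear_critic(1.0), r, f, seed=0) == pytest.approx(0.0, abs=1e-12)

    def test_doubled_critic_gives_one_and_ten_weighted(self):
        r = np.random.default_rng(0).random((4, 1, 1, 1))
        f = np.random.default_rng(1).random((4, 1, 1, 1))
        gp = gradient_penalty(self._linear_critic(2.0), r, f, seed=0)
        assert gp == pytest.approx(1.0)
        assert LossWeights().gp_weight * gp == pytest.approx(10.0)

    @pytest.mark.parametrize("c", [0.5, 1.0, 2.0])
    def test_scaling_law_of_linear_critic(self, c):
        r = np.random.default_rng(2).random((6, 1, 1, 1))
        f = np.random.default_rng(3).random((6, 1, 1, 1))
        assert gradient_penalty(self._linear_critic(c), r, f, seed=1) == pytest.approx((c - 1) ** 2)

    def test_nonnegative_for_random_critic(self):
        spec = CriticSpec(filters=(4, 8), kernel_size=3)
        crit = ConvCritic(spec, seed=0)
        r = np.random.default_rng(4).random((2, 1, 8, 8))
        f = np.random.default_rng(5).random((2, 1, 8, 8))
        assert gradient_penalty(lambda x: crit.forward(x), r, f, seed=2) >= 0.0

    def test_shape_mismatch_rejected(self):
        with pytest.raises(Exception, match="shape|Shape"):
            gradient_penalty(self._linear_critic(1.0), np.zeros((2, 1, 4, 4)), np.zeros((2, 1, 3, 3)), 0)


class TestGeneratorLoss:
    def test_weighted_sum_arithmetic(self):
        terms = {"adversarial": 1.0, "perceptual": 0.001, "l1": 0.01, "nmse": 0.01, "psnr": 0.01}
        assert generator_loss(terms, LossWeights()) == pytest.approx(5.0)

    def test_default_weights(self):
        w = LossWeights()
        assert (w.w_adversarial, w.w_perceptual, w.w_l1, w.w_nmse, w.w_psnr) == (
            1.0,
            1000.0,
            100.0,
            100.0,
            100.0,
        )
        assert w.gp_weight == 10.0

    def test_nan_component_names_culprit(self):
        terms = {"adversarial": 0.0, "perceptual": float("nan"), "l1": 0.0, "nmse": 0.0, "psnr": 0.0}
        with pytest.raises(LossError, match="perceptual"):
            generator_loss(terms, LossWeights())


class TestGenerator:
    def test_spatial_dimensions_preserved(self):
        gen = ShallowCNNGenerator(GeneratorSpec(n_filters=2), seed=0)
        for size in (16, 20, 33):
            out = gen.forward(ad.Tensor(np.random.default_rng(0).random((1, 1, size, size))))
            assert out.data.shape == (1, 1, size, size)

    def test_zero_fusion_residual_path_preserves_input(self):
        gen = ShallowCNNGenerator(GeneratorSpec(n_filters=2), seed=0)
        gen.final.weight.data[:] = 0.0
        gen.final.bias.data[:] = 0.0
        x = np.random.default_rng(1).random((1, 1, 12, 12)) * 0.9
        out = gen.forward(ad.Tensor(x))
        assert np.allclose(out.data, np.clip(x, 0, 1))

    def test_output_in_unit_interval(self):
        gen = ShallowCNNGenerator(GeneratorSpec(n_filters=2), seed=3)
        out = gen.forward(ad.Tensor(np.random.default_rng(2).random((2, 1, 16, 16))))
        assert out.data.min() >= 0.0 and out.data.max() <= 1.0

    def test_default_spec_matches_architecture(self):
        spec = GeneratorSpec()
        assert spec.kernel_sizes == (15, 13, 11, 9, 7, 5, 3)
        assert CriticSpec().filters == (32, 64, 128, 256)
        assert CriticSpec().kernel_size == 5 and CriticSpec().stride == 2


class TestCritic:
    def test_scalar_score_per_image(self):
        crit = ConvCritic(CriticSpec(filters=(4, 8)), seed=0)
        out = crit.forward(ad.Tensor(np.random.default_rng(0).random((3, 1, 16, 16))))
        assert out.data.shape == (3,)

    def test_spectral_norm_bounds_weight_spectrum(self):
        crit = ConvCritic(CriticSpec(filters=(4, 8, 16)), seed=1)
        for layer in crit.layers:
            w = layer.normalized_weight().data
            sigma = np.linalg.norm(w.reshape(w.shape[0], -1), 2)
            assert sigma <= 1.0 + 1e-3


class TestTraining:
    def test_defaults(self):
        cfg = TrainConfig()
        assert cfg.learning_rate == 0.0002
        assert cfg.batch_size == 1
        assert cfg.train_fraction == 0.75

    def test_smoke_run_finite_history_and_loss_decomposition(self):
        rng = np.random.default_rng(0)
        pairs = [(rng.random((16, 16)) * 0.8,) * 2 for _ in range(6)]
        model = train_harmonizer(
            pairs,
            TrainConfig(steps=8, seed=2, augment=False),
            LossWeights(),
            GeneratorSpec(n_filters=2),
            CriticSpec(filters=(4, 8)),
        )
        h = model.history
        assert len(h) == 8
        assert np.isfinite(h[["l_total", "critic_loss", "gradient_penalty"]].to_numpy()).all()
        w = LossWeights()
        recomposed = (
            w.w_adversarial * h.l_adversarial
            + w.w_perceptual * h.l_perceptual
            + w.w_l1 * h.l_l1
            + w.w_nmse * h.l_nmse
            + w.w_psnr * h.l_psnr
        )
        assert np.allclose(recomposed, h.l_total, atol=1e-6)

    def test_split_recorded(self):
        rng = np.random.default_rng(1)
        pairs = [(rng.random((16, 16)) * 0.8,) * 2 for _ in range(8)]
        model = train_harmonizer(
            pairs,
            TrainConfig(steps=2, seed=0, augment=False),
            generator_spec=GeneratorSpec(n_filters=2),
            critic_spec=CriticSpec(filters=(4, 8)),
        )
        assert len(model.train_indices) == 6
        assert len(model.test_indices) == 2
        assert sorted(model.train_indices + model.test_indices) == list(range(8))

    def test_empty_pairs_rejected(self):
        with pytest.raises(DataError):
            train_harmonizer([], TrainConfig(steps=1))

    def test_out_of_range_pairs_rejected(self):
        with pytest.raises(ScalingError):
            train_harmonizer([(np.full((8, 8), 2.0), np.full((8, 8), 2.0))], TrainConfig(steps=1))


@pytest.fixture(scope="module")
def model():
    rng = np.random.default_rng(3)
    pairs = [(rng.random((16, 16)) * 0.8,) * 2 for _ in range(4)]
    return train_harmonizer(
        pairs,
        TrainConfig(steps=2, seed=1, augment=False),
        generator_spec=GeneratorSpec(n_filters=2),
        critic_spec=CriticSpec(filters=(4, 8)),
    )


class TestInference:
    def test_shape_and_range_preserved(self, model):
        img = np.random.default_rng(0).random((16, 16))
        out = harmonize_images(model, img)
        assert out.shape == img.shape
        assert out.min() >= 0.0 and out.max() <= 1.0

    def test_volume_processed_slice_wise(self, model):
        vol = np.random.default_rng(1).random((16, 16, 5))
        out = harmonize_images(model, vol)
        assert out.shape == vol.shape
        single = harmonize_images(model, vol[:, :, 2])
        assert np.array_equal(out[:, :, 2], single)

    def test_inference_deterministic(self, model):
        img = np.random.default_rng(2).random((16, 16))
        assert np.array_equal(harmonize_images(model, img), harmonize_images(model, img))

    def test_out_of_range_input_rejected(self, model):
        with pytest.raises(ScalingError):
            harmonize_images(model, np.full((16, 16), 1.5))

    def test_save_load_roundtrip(self, model, tmp_path):
        from ctharmony.gan_harmonize import HarmonizerModel

        path = tmp_path / "model.json"
        model.save(path)
        clone = HarmonizerModel.load(path)
        img = np.random.default_rng(4).random((16, 16))
        assert np.allclose(harmonize_images(clone, img), harmonize_images(model, img))
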