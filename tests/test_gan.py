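"""Feature extraction and WGAN-GP training."""

import numpy as np
import pytest

import methylgan as mg
from methylgan import autodiff as ad
from methylgan.autodiff import Tensor
from methylgan.gan import CriticFn, FeatureBatch, GanConfig, gradient_penalty


class LinearCritic:
    def __init__(self, w):
        self.w = Tensor(np.asarray(w, dtype=float).reshape(-1, 1))

    def __call__(self, x):
        return ad.matmul(x, self.w)


@pytest.fixture
def gaussian_features():
    rng = np.random.default_rng(0)
    vals = rng.normal([2.0, -1.0], [0.7, 0.4], size=(64, 2))
    return FeatureBatch(vals, np.ones(64, int), np.array(["real"] * 64), (1, 2))


class TestFeatureBatch:
    def test_shape_validation(self):
        with pytest.raises(ValueError, match="values"):
            FeatureBatch(np.ones((3, 5)), np.ones(3), np.array(["real"] * 3),
                         (2, 2))

    def test_row_reshape_round_trip(self, gaussian_features):
        from methylgan.finetune import reshape_to_layer
        maps = reshape_to_layer(gaussian_features, (1, 2))
        assert np.array_equal(maps.reshape(64, 2), gaussian_features.values)

    def test_save_load_round_trip(self, tmp_path, gaussian_features):
        gaussian_features.save(tmp_path / "fb.npz")
        fb = FeatureBatch.load(tmp_path / "fb.npz")
        assert np.array_equal(fb.values, gaussian_features.values)
        assert fb.layer_shape == (1, 2)


class TestExtractFeatures:
    def test_flattening_arithmetic_and_tags(self, trained_tiny):
        recs = trained_tiny["records"][:12]
        fb = mg.extract_features(trained_tiny["state"], recs, block_index=3)
        c, p = trained_tiny["state"].spec.block_output_shape(3)
        assert fb.values.shape == (12, c * p)
        assert fb.layer_shape == (c, p)
        assert np.all(fb.source == "real")
        assert fb.labels.tolist() == [r.label for r in recs]

    def test_deterministic_with_dropout_off(self, trained_tiny):
        recs = trained_tiny["records"][:6]
        a = mg.extract_features(trained_tiny["state"], recs, 3)
        b = mg.extract_features(trained_tiny["state"], recs, 3)
        assert np.array_equal(a.values, b.values)

    def test_channel_major_flattening_order(self, trained_tiny):
        """Flat element c*positions + p equals map element (c, p)."""
        from methylgan.network import forward_logits
        recs = trained_tiny["records"][:3]
        X, _ = mg.encode_batch(recs)
        maps = forward_logits(trained_tiny["state"], X, upto_block=3).data
        fb = mg.extract_features(trained_tiny["state"], recs, 3)
        c, p = fb.layer_shape
        assert fb.values[1][2 * p + 5] == maps[1, 5, 2]  # (c=2, p=5)

    def test_invalid_block_index(self, trained_tiny):
        with pytest.raises(ValueError):
            mg.extract_features(trained_tiny["state"],
                                trained_tiny["records"][:2], 6)


class TestGradientPenalty:
    def test_unit_norm_linear_critic_penalty_zero(self):
        rng = np.random.default_rng(1)
        gp = gradient_penalty(LinearCritic([0.6, 0.8]), rng.normal(size=(12, 2)),
                              rng.normal(size=(12, 2)), lam=10.0)
        assert gp == pytest.approx(0.0, abs=1e-12)

    def test_constant_critic_penalty_equals_lambda(self):
        rng = np.random.default_rng(2)
        gp = gradient_penalty(LinearCritic([0.0, 0.0]), rng.normal(size=(8, 2)),
                              rng.normal(size=(8, 2)), lam=7.5)
        assert gp == pytest.approx(7.5, abs=1e-12)

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError):
            gradient_penalty(LinearCritic([1.0]), np.ones((4, 1)),
                             np.ones((3, 1)), lam=1.0)

    def test_matches_finite_difference_gradient_norms(self):
        """Penalty recomputed from finite-difference input gradients of a
        random tiny critic agrees to 1e-4."""
        rng = np.random.default_rng(3)
        d = 3
        critic = CriticFn(d, (5, 4), np.random.default_rng(4))
        real = rng.normal(size=(6, d))
        fake = rng.normal(size=(6, d))
        lam, seed = 10.0, 17
        gp = gradient_penalty(critic, real, fake, lam, seed=seed)
        # reproduce the interpolates exactly, then finite-difference D
        eps_draw = np.random.default_rng(seed).random((6, 1))
        x_hat = eps_draw * real + (1 - eps_draw) * fake

        def D(x):
            return critic(Tensor(np.atleast_2d(x))).data.ravel()

        h = 1e-5
        norms = []
        for row in x_hat:
            g = np.array([(D(row + h * np.eye(d)[j]) -
                           D(row - h * np.eye(d)[j])) / (2 * h)
                          for j in range(d)]).ravel()
            norms.append(np.linalg.norm(g))
        gp_fd = lam * np.mean((np.array(norms) - 1) ** 2)
        assert gp == pytest.approx(gp_fd, abs=1e-4)


class TestTrainWganGp:
    def _config(self, **kw):
        base = dict(noise_dim=4, hidden_sizes=(8, 8), total_epochs=10,
                    checkpoint_interval=5, batch_size=8, seed=0)
        base.update(kw)
        return GanConfig(**base)

    def test_checkpoint_epochs_are_interval_multiples(self, gaussian_features):
        cks = mg.train_wgan_gp(gaussian_features, self._config())
        assert [c.epoch for c in cks] == [5, 10]

    def test_mixed_class_input_rejected(self, gaussian_features):
        mixed = FeatureBatch(gaussian_features.values,
                             np.r_[np.zeros(32, int), np.ones(32, int)],
                             gaussian_features.source, (1, 2))
        with pytest.raises(ValueError, match="per class"):
            mg.train_wgan_gp(mixed, self._config())

    def test_too_few_rows_rejected(self, gaussian_features):
        with pytest.raises(ValueError, match="rows"):
            mg.train_wgan_gp(gaussian_features, self._config(batch_size=64))

    def test_same_seed_identical_checkpoints(self, gaussian_features):
        a = mg.train_wgan_gp(gaussian_features, self._config())
        b = mg.train_wgan_gp(gaussian_features, self._config())
        for ca, cb in zip(a, b):
            for k in ca.generator_params:
                assert np.array_equal(ca.generator_params[k],
                                      cb.generator_params[k])

    def test_interval_must_divide_epochs(self):
        with pytest.raises(ValueError, match="divide"):
            self._config(total_epochs=12, checkpoint_interval=5)

    def test_untrained_critic_symmetric_on_same_distribution(self):
        """A freshly initialized critic carries no real-vs-fake signal: its
        mean score difference over same-distribution halves is ~0 on average."""
        diffs = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            a = rng.normal(size=(64, 3))
            b = rng.normal(size=(64, 3))
            critic = CriticFn(3, (16, 16), np.random.default_rng(100 + seed))
            diffs.append(critic(Tensor(a)).data.mean()
                         - critic(Tensor(b)).data.mean())
        assert abs(np.mean(diffs)) < 0.2


@pytest.fixture(scope="module")
def checkpoint():
    rng = np.random.default_rng(5)
    vals = rng.normal(size=(32, 6))
    fb = FeatureBatch(vals, np.zeros(32, int), np.array(["real"] * 32), (2, 3))
    cfg = GanConfig(noise_dim=4, hidden_sizes=(8, 8), total_epochs=5,
                    checkpoint_interval=5, batch_size=8, seed=1)
    return mg.train_wgan_gp(fb, cfg)[0]


class TestGenerateSynthetic:
    def test_construction_contract(self, checkpoint):
        fb = mg.generate_synthetic(checkpoint, 17, class_label=1,
                                   layer_shape=(2, 3), seed=3)
        assert fb.values.shape == (17, 6)
        assert np.all(fb.source == "synthetic")
        assert np.all(fb.labels == 1)

    def test_deterministic_given_seed(self, checkpoint):
        a = mg.generate_synthetic(checkpoint, 5, 0, (2, 3), seed=9)
        b = mg.generate_synthetic(checkpoint, 5, 0, (2, 3), seed=9)
        assert np.array_equal(a.values, b.values)

    def test_incompatible_layer_shape_rejected(self, checkpoint):
        with pytest.raises(ValueError, match="incompatible"):
            mg.generate_synthetic(checkpoint, 5, 0, (2, 4), seed=0)

    def test_checkpoint_save_load(self, tmp_path, checkpoint):
        checkpoint.save(tmp_path / "ck.npz")
        loaded = mg.GanCheckpoint.load(tmp_path / "ck.npz")
        a = mg.generate_synthetic(checkpoint, 4, 0, (2, 3), seed=1)
        b = mg.generate_synthetic(loaded, 4, 0, (2, 3), seed=1)
        assert np.array_equal(a.values, b.values)
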