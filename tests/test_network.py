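"""Base classifier: conv primitive, activations, training loop, inference."""

import numpy as np
import pytest

import methylgan as mg
from methylgan.network import (ConvBlockSpec, ModelState, NetworkSpec,
                               TrainingConfig, _sgd_epochs, activate,
                               conv_valid, init_params)
from methylgan.seqio import SequenceRecord


def conv_oracle(X, W):
    """Nested-loop evaluation of the valid cross-correlation."""
    F, M, N = W.shape
    H = X.shape[0]
    out = np.zeros((F, H - M + 1))
    for f in range(F):
        for i in range(H - M + 1):
            out[f, i] = sum(W[f, m, n] * X[i + m, n]
                            for m in range(M) for n in range(N))
    return out


class TestConvValid:
    def test_identity_kernel(self):
        X = np.arange(6, dtype=float).reshape(6, 1)
        W = np.ones((1, 1, 1))
        assert np.allclose(conv_valid(X, W), X.T)

    def test_all_ones_sum(self):
        assert conv_valid(np.ones((2, 2)), np.ones((1, 2, 2))).item() == 4.0

    def test_matches_nested_loop_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            H = rng.integers(3, 10)
            width = rng.integers(1, 6)
            M = rng.integers(1, H + 1)
            N = rng.integers(1, width + 1)
            F = rng.integers(1, 4)
            X = rng.normal(size=(H, width))
            W = rng.normal(size=(F, M, N))
            assert np.allclose(conv_valid(X, W), conv_oracle(X, W), atol=1e-6)

    def test_kernel_too_large_raises(self):
        with pytest.raises(ValueError):
            conv_valid(np.ones((2, 2)), np.ones((1, 3, 2)))

    def test_bias_added_per_filter(self):
        X = np.ones((3, 2))
        W = np.ones((2, 2, 2))
        out = conv_valid(X, W, bias=np.array([1.0, -1.0]))
        assert np.allclose(out, [[5, 5], [3, 3]])


class TestActivate:
    def test_leaky_relu_negative_branch(self):
        assert activate(-1.0, "leaky_relu", a=0.01) == -0.01

    def test_leaky_relu_positive_identity(self):
        assert activate(2.5, "leaky_relu", a=0.01) == 2.5

    def test_sigmoid_symmetry_point(self):
        assert activate(0.0, "sigmoid") == 0.5

    def test_sigmoid_complement_identity(self):
        x = np.random.default_rng(1).normal(size=20)
        assert np.allclose(activate(x, "sigmoid") + activate(-x, "sigmoid"), 1)

    def test_invalid_slope_rejected(self):
        with pytest.raises(ValueError):
            activate(1.0, "leaky_relu", a=-0.1)


class TestSpecValidation:
    def test_exactly_five_blocks(self):
        with pytest.raises(ValueError, match="five"):
            NetworkSpec(conv_blocks=(ConvBlockSpec(3, 4, 0.1),) * 4)

    def test_kernel_must_fit(self):
        with pytest.raises(ValueError, match="fit"):
            NetworkSpec(conv_blocks=(ConvBlockSpec(11, 4, 0.1),) * 5)

    def test_block_output_shape_arithmetic(self, tiny_spec):
        # five kernel-3 blocks on length 41: 39, 37, 35, 33, 31
        assert tiny_spec.block_output_shape(3) == (4, 35)
        assert tiny_spec.flat_dim == 4 * 31


def _first_base_dataset(n, rng):
    """Linearly separable toy: label = indicator of 'A' at position 0."""
    recs = []
    for i in range(n):
        seq = rng.choice(list("ACGT"), size=41)
        seq[20] = "A"
        seq[0] = "A" if i % 2 == 0 else rng.choice(list("CGT"))
        recs.append(SequenceRecord(f"r{i}", "".join(seq), int(seq[0] == "A")))
    return recs


class TestTrainStage1:
    def test_separable_toy_reaches_high_auc(self):
        """A position-wise (kernel-1) network must fully learn a label that
        is a single input position's base identity."""
        rng = np.random.default_rng(5)
        recs = _first_base_dataset(400, rng)
        split = mg.make_splits(recs, seed=6)
        spec = NetworkSpec(conv_blocks=(ConvBlockSpec(1, 4, 0.1),) * 5,
                           fc_widths=(8, 8))
        cfg = TrainingConfig(max_epochs=60, patience=60, seed=7,
                             learning_rate=3e-3)
        state, history = mg.train_stage1(recs, split, spec, cfg)
        assert max(history.val_auc) >= 0.99

    def test_same_seed_identical_history_and_params(self, tiny_spec,
                                                    motif_dataset):
        split = mg.make_splits(motif_dataset, seed=1)
        cfg = TrainingConfig(max_epochs=3, patience=3, seed=2)
        s1, h1 = mg.train_stage1(motif_dataset, split, tiny_spec, cfg)
        s2, h2 = mg.train_stage1(motif_dataset, split, tiny_spec, cfg)
        assert h1.val_auc == h2.val_auc
        for name in s1.params:
            assert np.array_equal(s1.params[name]["W"], s2.params[name]["W"])

    def test_single_class_validation_rejected(self, tiny_spec):
        rng = np.random.default_rng(8)
        recs = _first_base_dataset(40, rng)
        split = mg.make_splits(recs, seed=0)
        # rebuild a split whose validation ids are all one class
        pos_ids = frozenset(r.identifier for r in recs if r.label == 1)
        bad = mg.DatasetSplit(train_ids=frozenset(r.identifier for r in recs)
                              - pos_ids, val_ids=pos_ids,
                              test_ids=frozenset(), seed=0)
        with pytest.raises(ValueError, match="both classes"):
            mg.train_stage1(recs, bad, tiny_spec,
                            TrainingConfig(max_epochs=1, patience=1))


class TestEarlyStoppingRule:
    def test_peak_then_patience_exhausted(self, tiny_spec):
        """A trace peaking at epoch 3 with patience 2 stops after epoch 5
        and restores the epoch-3 parameters."""
        rng = np.random.default_rng(0)
        state = ModelState(tiny_spec, init_params(tiny_spec, rng))
        trace = [0.6, 0.7, 0.9, 0.8, 0.85, 0.95, 0.99]
        calls = []
        snapshots = {}

        def val_fn(st):
            epoch = len(calls) + 1
            calls.append(epoch)
            snapshots[epoch] = st.params["out"]["W"].copy()
            return trace[epoch - 1]

        X = rng.normal(size=(8, 41, 4))
        y = rng.integers(0, 2, 8).astype(float)
        cfg = TrainingConfig(max_epochs=7, patience=2, seed=1)
        history = _sgd_epochs(state, ["out"], lambda r: iter([(X, y)]),
                              val_fn, cfg, rng, 1e-3)
        assert calls == [1, 2, 3, 4, 5]
        assert history.best_epoch == 3
        assert np.array_equal(state.params["out"]["W"], snapshots[3])

    def test_returned_model_attains_best_recorded_auc(self, trained_tiny):
        """Reloading the returned checkpoint reproduces the best val AUC."""
        state, history = trained_tiny["state"], trained_tiny["history"]
        recs, split = trained_tiny["records"], trained_tiny["split"]
        X, y = mg.encode_batch(mg.subset(recs, split.val_ids))
        auc = mg.roc_auc(y.astype(int), mg.predict_proba(state, X))[0]
        assert auc == pytest.approx(max(history.val_auc), abs=1e-12)


class TestPredictProba:
    def test_outputs_strictly_in_unit_interval(self, trained_tiny):
        X, _ = mg.encode_batch(trained_tiny["records"][:20])
        p = mg.predict_proba(trained_tiny["state"], X)
        assert np.all((p > 0) & (p < 1))

    def test_purity_repeated_record(self, trained_tiny):
        X, _ = mg.encode_batch([trained_tiny["records"][0]] * 5)
        p = mg.predict_proba(trained_tiny["state"], X)
        assert np.all(p == p[0])

    def test_order_equivariance(self, trained_tiny):
        X, _ = mg.encode_batch(trained_tiny["records"][:10])
        perm = np.random.default_rng(3).permutation(10)
        p = mg.predict_proba(trained_tiny["state"], X)
        assert np.allclose(mg.predict_proba(trained_tiny["state"], X[perm]),
                           p[perm])

    def test_shape_mismatch_raises(self, trained_tiny):
        with pytest.raises(ValueError):
            mg.predict_proba(trained_tiny["state"], np.ones((2, 41, 3)))


def test_checkpoint_save_load_round_trip(tmp_path, trained_tiny):
    state = trained_tiny["state"]
    state.save(tmp_path / "model.npz")
    loaded = ModelState.load(tmp_path / "model.npz")
    X, _ = mg.encode_batch(trained_tiny["records"][:8])
    assert np.array_equal(mg.predict_proba(state, X),
                          mg.predict_proba(loaded, X))
    assert loaded.spec == state.spec
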