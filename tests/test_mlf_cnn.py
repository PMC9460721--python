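import dataclasses

import numpy as np
import pytest

from seizpred.mlf_cnn import (
    MLFCNN,
    ModelConfig,
    build_model,
    cross_validate,
    predict,
    train_fold,
)

# small configuration used throughout: 32x32 inputs, fusion at 8x8
SMALL = ModelConfig(
    input_shape=(32, 32, 2),
    block_convs=(1, 1, 1, 1, 1),
    block_widths=(4, 4, 8, 8, 8),
    projection_channels=8,
    fusion_size=8,
    fc_sizes=(32, 16),
    dropout_rates=(0.25, 0.25),
    epochs=10,
    batch_size=16,
    learning_rate=1e-3,
    seed=0,
)


def separable(n, rng, size=32, c=2):
    """Images whose bright horizontal band position encodes the class."""
    X = (rng.random((n, size, size, c)) * 0.3).astype(np.float32)
    y = rng.integers(0, 2, n)
    for i, label in enumerate(y):
        rows = slice(4, 9) if label else slice(20, 25)
        X[i, rows, :, :] += 0.6
    return np.clip(X, 0, 1), y


class TestConfig:
    def test_defaults_match_contract(self):
        cfg = ModelConfig()
        assert cfg.block_convs == (2, 2, 3, 2, 2)
        assert cfg.block_widths == (64, 128, 256, 512, 512)
        assert cfg.epochs == 50
        assert cfg.fusion_size == 32

    def test_indivisible_input_rejected(self):
        with pytest.raises(ValueError, match="divisible"):
            ModelConfig(input_shape=(100, 100, 2))

    def test_bad_fusion_rejected(self):
        with pytest.raises(ValueError):
            ModelConfig(input_shape=(128, 128, 2), fusion_size=16)


class TestArchitecture:
    def test_softmax_normalized(self, rng):
        model = build_model(SMALL)
        X = rng.random((3, 32, 32, 2)).astype(np.float32)
        probs = model.forward(X)
        assert probs.shape == (3, 2)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)
        assert np.isfinite(probs).all()

    def test_five_fusion_maps_same_shape(self, rng):
        model = build_model(SMALL)
        X = rng.random((2, 32, 32, 2)).astype(np.float32)
        maps = model.fusion_maps(X)
        assert len(maps) == 5
        for m in maps:
            assert m.shape == (2, 8, 8, SMALL.projection_channels)

    def test_param_count_arithmetic_oracle(self):
        cfg = SMALL
        model = build_model(cfg)
        h = cfg.input_shape[0]
        # independent layer-by-layer sum
        expected = 0
        c_prev = cfg.input_shape[2]
        for n_convs, width in zip(cfg.block_convs, cfg.block_widths):
            for _ in range(n_convs):
                expected += 9 * c_prev * width + width
                c_prev = width
        for width in cfg.block_widths:
            expected += width * cfg.projection_channels + cfg.projection_channels
        sizes = [h // 2 ** (k + 1) for k in range(5)]
        for s in sizes:
            f = cfg.fusion_size // s
            if f > 1:
                expected += (
                    cfg.projection_channels * f * f * cfg.projection_channels
                    + cfg.projection_channels
                )
        flat = cfg.fusion_size**2 * 5 * cfg.projection_channels
        expected += flat * cfg.fc_sizes[0] + cfg.fc_sizes[0]
        expected += cfg.fc_sizes[0] * cfg.fc_sizes[1] + cfg.fc_sizes[1]
        expected += cfg.fc_sizes[1] * cfg.n_classes + cfg.n_classes
        assert model.count_params() == expected

    def test_default_config_param_count(self):
        cfg = ModelConfig(input_shape=(128, 128, 18))
        model = build_model(cfg)
        expected = 0
        c_prev = 18
        for n_convs, width in zip(cfg.block_convs, cfg.block_widths):
            for _ in range(n_convs):
                expected += 9 * c_prev * width + width
                c_prev = width
        for width in cfg.block_widths:
            expected += width * 64 + 64
        for s in [64, 32, 16, 8, 4]:
            f = 32 // s
            if f > 1:
                expected += 64 * f * f * 64 + 64
        expected += 32 * 32 * 320 * 256 + 256
        expected += 256 * 64 + 64
        expected += 64 * 2 + 2
        assert model.count_params() == expected

    def test_shape_mismatch_rejected(self, rng):
        model = build_model(SMALL)
        with pytest.raises(ValueError, match="shape"):
            model.forward(rng.random((2, 64, 64, 2)).astype(np.float32))

    def test_gradient_check_small(self):
        # numerical gradient on a tiny model, one conv weight slice
        cfg = ModelConfig(
            input_shape=(32, 32, 1),
            block_convs=(1, 1, 1, 1, 1),
            block_widths=(2, 2, 2, 2, 2),
            projection_channels=2,
            fusion_size=8,
            fc_sizes=(8, 4),
            dropout_rates=(0.0, 0.0),
            epochs=1,
            seed=3,
        )
        model = build_model(cfg)
        rng = np.random.default_rng(0)
        X = rng.random((2, 32, 32, 1)).astype(np.float32)
        y = np.array([0, 1])
        onehot = np.eye(2, dtype=np.float32)[y]

        def loss():
            p = model.forward(X.astype(np.float64).astype(np.float32), train=False)
            return float(-np.log(p[np.arange(2), y]).mean())

        model.forward(X, train=False)
        model.backward(onehot)
        w = model.head[0].w  # first dense layer
        g_analytic = model.head[0].gw
        eps = 1e-2
        rows = [(0, 0), (5, 3), (100, 7)]
        for i, j in rows:
            orig = w[i, j]
            w[i, j] = orig + eps
            lp = loss()
            w[i, j] = orig - eps
            lm = loss()
            w[i, j] = orig
            num = (lp - lm) / (2 * eps)
            assert num == pytest.approx(float(g_analytic[i, j]), abs=2e-3)


class TestTraining:
    def test_learns_separable_within_10_epochs(self):
        accs = []
        for seed in (0, 1, 2):
            rng = np.random.default_rng(100 + seed)
            X, y = separable(120, rng)
            cfg = dataclasses.replace(SMALL, seed=seed)
            model = build_model(cfg)
            tm = train_fold(model, (X, y), None, cfg)
            accs.append(tm.history[-1]["train_acc"])
        assert np.median(accs) >= 0.95

    def test_monotone_learning_loss(self):
        losses_1, losses_10 = [], []
        for seed in (0, 1, 2):
            rng = np.random.default_rng(200 + seed)
            X, y = separable(120, rng)
            cfg = dataclasses.replace(SMALL, seed=seed)
            tm = train_fold(build_model(cfg), (X, y), None, cfg)
            losses_1.append(tm.history[0]["train_loss"])
            losses_10.append(tm.history[9]["train_loss"])
        assert np.median(losses_10) < np.median(losses_1)

    def test_zero_epochs(self, rng):
        X, y = separable(20, rng)
        cfg = dataclasses.replace(SMALL, epochs=0)
        tm = train_fold(build_model(cfg), (X, y), None, cfg)
        assert tm.history == []

    def test_single_class_rejected(self, rng):
        X, y = separable(20, rng)
        y[:] = 1
        with pytest.raises(ValueError, match="single class"):
            train_fold(build_model(SMALL), (X, y), None, SMALL)

    def test_deterministic_same_seed(self, rng):
        X, y = separable(60, rng)
        cfg = dataclasses.replace(SMALL, epochs=3)
        tm1 = train_fold(build_model(cfg), (X, y), None, cfg)
        tm2 = train_fold(build_model(cfg), (X, y), None, cfg)
        assert abs(tm1.history[-1]["train_loss"] - tm2.history[-1]["train_loss"]) < 1e-6

    def test_history_records_validation(self, rng):
        X, y = separable(40, rng)
        cfg = dataclasses.replace(SMALL, epochs=2)
        tm = train_fold(build_model(cfg), (X[:30], y[:30]), (X[30:], y[30:]), cfg)
        assert len(tm.history) == 2
        assert {"val_loss", "val_acc"} <= set(tm.history[0])


class TestPredict:
    def test_rows_sum_to_one(self, rng):
        model = build_model(SMALL)
        X = rng.random((7, 32, 32, 2)).astype(np.float32)
        probs, labels = predict(model, (X, None))
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)
        assert set(labels) <= {0, 1}

    def test_duplicated_input_identical_output(self, rng):
        model = build_model(SMALL)
        x = rng.random((1, 32, 32, 2)).astype(np.float32)
        X = np.concatenate([x, x])
        probs, labels = predict(model, (X, None))
        np.testing.assert_array_equal(probs[0], probs[1])
        assert labels[0] == labels[1]

    def test_heldout_accuracy_on_separable(self, rng):
        X, y = separable(160, rng)
        tm = train_fold(build_model(SMALL), (X[:120], y[:120]), None, SMALL)
        _, pred = predict(tm, (X[120:], None))
        assert (pred == y[120:]).mean() >= 0.9


class TestCrossValidate:
    def test_fold_structure(self, rng):
        X, y = separable(60, rng)
        cfg = dataclasses.replace(SMALL, epochs=1)
        results = cross_validate((X, y), k=5, config=cfg, seed=0)
        assert len(results) == 5
        all_idx = np.concatenate([r.val_indices for r in results])
        assert sorted(all_idx) == list(range(60))
        for r in results:
            assert len(r.val_indices) == 12
            assert r.confusion.total == 12

    def test_stratification(self, rng):
        X, y = separable(100, rng)
        cfg = dataclasses.replace(SMALL, epochs=0)
        results = cross_validate((X, y), k=5, config=cfg, seed=0)
        global_ratio = y.mean()
        for r in results:
            fold_ratio = y[r.val_indices].mean()
            assert abs(fold_ratio * len(r.val_indices) - global_ratio * len(r.val_indices)) <= 1.0

    def test_too_few_samples(self, rng):
        X, y = separable(4, rng)
        with pytest.raises(ValueError):
            cross_validate((X, y), k=5, config=SMALL, seed=0)

    def test_scrambled_labels_near_chance(self):
        rng = np.random.default_rng(7)
        X, y = separable(100, rng)
        y_perm = rng.permutation(y)
        cfg = dataclasses.replace(SMALL, epochs=5)
        results = cross_validate((X, y_perm), k=5, config=cfg, seed=1)
        pooled = sum((r.confusion for r in results), start=results[0].confusion.__class__())
        acc = (pooled.tp + pooled.tn) / pooled.total
        assert 0.3 <= acc <= 0.7  # wide bounds for a 100-sample control
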