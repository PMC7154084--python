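"""Decoder training, early stopping, aggregation, and the NN engine."""

import numpy as np
import pytest

from megdecode import decoders, evaluate, nnet


def _gaussian_classes(rng, n_per_class=100, d=10, gap=5.0, n_classes=2):
    X, y = [], []
    for k in range(n_classes):
        mu = np.zeros(d)
        mu[k % d] = gap * k
        X.append(rng.standard_normal((n_per_class, d)) + mu)
        y.append(np.full(n_per_class, k))
    X, y = np.concatenate(X), np.concatenate(y)
    perm = rng.permutation(len(y))
    return X[perm], y[perm]


def _split(X, y, frac=0.7):
    n = int(len(y) * frac)
    m = int(len(y) * 0.85)
    return (X[:n], y[:n]), (X[n:m], y[n:m]), (X[m:], y[m:])


class TestTrainAnn:
    def test_separable_classes_high_accuracy(self, rng):
        X, y = _gaussian_classes(rng, 100, 10, gap=5.0)
        (Xtr, ytr), (Xva, yva), (Xte, yte) = _split(X, y)
        cfg = decoders.AnnConfig(input_dim=10, output_classes=2, seed=0)
        model = decoders.train_ann(Xtr, ytr, Xva, yva, cfg)
        acc = np.mean(model.predict(Xte) == yte)
        assert acc >= 0.95

    def test_shuffled_labels_chance_level(self, rng):
        X, y = _gaussian_classes(rng, 100, 10, gap=5.0)
        y = rng.permutation(y)
        (Xtr, ytr), (Xva, yva), (Xte, yte) = _split(X, y)
        cfg = decoders.AnnConfig(input_dim=10, output_classes=2, seed=0)
        model = decoders.train_ann(Xtr, ytr, Xva, yva, cfg)
        acc = 100 * np.mean(model.predict(Xte) == yte)
        lo, hi = evaluate.binomial_chance_interval(len(yte), 2, conf=0.99)
        assert lo <= acc <= hi

    def test_xor_nonlinearity(self, rng):
        """XOR data defeats any linear rule; the hidden layer solves it."""
        n = 400
        X = rng.uniform(-1, 1, size=(n, 2)) + np.sign(
            rng.standard_normal((n, 2))) * 1.5
        y = ((X[:, 0] > 0) ^ (X[:, 1] > 0)).astype(int)
        (Xtr, ytr), (Xva, yva), (Xte, yte) = _split(X, y)
        # XOR sits on a loss plateau early in training: give SGD a higher
        # rate and a longer patience than the defaults tuned for RMS features
        cfg = decoders.AnnConfig(input_dim=2, output_classes=2,
                                 hidden_nodes=32, learning_rate=0.5,
                                 max_epochs=500, early_stop_patience=30,
                                 seed=1)
        model = decoders.train_ann(Xtr, ytr, Xva, yva, cfg)
        assert np.mean(model.predict(Xte) == yte) >= 0.9

    def test_missing_class_rejected(self, rng):
        X, y = _gaussian_classes(rng, 20, 5, n_classes=2)
        cfg = decoders.AnnConfig(input_dim=5, output_classes=3, seed=0)
        with pytest.raises(ValueError, match="absent"):
            decoders.train_ann(X, y, X, y, cfg)

    def test_probabilities_normalized(self, rng):
        X, y = _gaussian_classes(rng, 30, 5)
        cfg = decoders.AnnConfig(input_dim=5, output_classes=2, seed=0,
                                 max_epochs=5)
        model = decoders.train_ann(X, y, X, y, cfg)
        p = model.predict_proba(X)
        assert np.all(p >= 0) and np.all(p <= 1)
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-6)

    def test_early_stop_returns_best_validation_snapshot(self, rng):
        X, y = _gaussian_classes(rng, 60, 8, gap=1.0)
        (Xtr, ytr), (Xva, yva), _ = _split(X, y)
        cfg = decoders.AnnConfig(input_dim=8, output_classes=2, seed=0,
                                 max_epochs=60)
        model = decoders.train_ann(Xtr, ytr, Xva, yva, cfg)
        hist = model.history
        assert hist["best_val_loss"] <= hist["val_loss"][-1] + 1e-12
        assert len(hist["val_loss"]) <= cfg.max_epochs

    def test_hidden_width_plateau(self):
        """Test accuracy is non-decreasing in hidden width then flat: a
        nonlinear teacher task shows 64 -> 256 gains but nothing substantial
        past 256, averaged over 3 seeds."""
        def teacher_task(r, n=1500, d=15, width=48, K=5):
            W1 = r.standard_normal((d, width))
            W2 = r.standard_normal((width, K))
            X = r.standard_normal((n, d))
            return X, np.argmax(np.tanh(X @ W1) @ W2, axis=1)

        accs = {w: [] for w in (64, 128, 256, 512)}
        for seed in range(3):
            r = np.random.default_rng(seed)
            X, y = teacher_task(r)
            (Xtr, ytr), (Xva, yva), (Xte, yte) = _split(X, y)
            for w in accs:
                cfg = decoders.AnnConfig(input_dim=15, output_classes=5,
                                         hidden_nodes=w, seed=seed,
                                         max_epochs=60)
                m = decoders.train_ann(Xtr, ytr, Xva, yva, cfg)
                accs[w].append(np.mean(m.predict(Xte) == yte))
        means = {w: np.mean(v) for w, v in accs.items()}
        assert means[128] >= means[64] - 0.02
        assert means[256] >= means[128] - 0.02
        assert abs(means[512] - means[256]) <= 0.03


def _blob_images(rng, n_per_class=200, size=20):
    """Class 0: bright blob upper-left; class 1: lower-right."""
    X, y = [], []
    for k in range(2):
        for _ in range(n_per_class):
            img = rng.random((size, size, 3)) * 0.2
            r0 = 2 if k == 0 else size - 8
            img[r0:r0 + 6, r0:r0 + 6, :] += 0.8
            X.append(img)
            y.append(k)
    X, y = np.asarray(X), np.asarray(y)
    perm = rng.permutation(len(y))
    return X[perm], y[perm]


class TestTrainCnn:
    def test_separable_blobs_high_accuracy(self, rng):
        X, y = _blob_images(rng)
        (Xtr, ytr), (Xva, yva), (Xte, yte) = _split(X, y)
        cfg = decoders.CnnConfig(input_size=(20, 20, 3), output_classes=2,
                                 seed=0, max_epochs=20)
        model = decoders.train_cnn(Xtr, ytr, Xva, yva, cfg)
        assert np.mean(model.predict(Xte) == yte) >= 0.95

    def test_shuffled_labels_chance_level(self, rng):
        X, y = _blob_images(rng, n_per_class=100)
        y = rng.permutation(y)
        (Xtr, ytr), (Xva, yva), (Xte, yte) = _split(X, y)
        cfg = decoders.CnnConfig(input_size=(20, 20, 3), output_classes=2,
                                 seed=0, max_epochs=10)
        model = decoders.train_cnn(Xtr, ytr, Xva, yva, cfg)
        acc = 100 * np.mean(model.predict(Xte) == yte)
        lo, hi = evaluate.binomial_chance_interval(len(yte), 2, conf=0.99)
        assert lo <= acc <= hi

    def test_deterministic_under_fixed_seed(self, rng):
        X, y = _blob_images(rng, n_per_class=30)
        cfg = decoders.CnnConfig(input_size=(20, 20, 3), output_classes=2,
                                 seed=7, max_epochs=3)
        h1 = decoders.train_cnn(X[:40], y[:40], X[40:], y[40:], cfg).history
        h2 = decoders.train_cnn(X[:40], y[:40], X[40:], y[40:], cfg).history
        assert h1["val_loss"] == h2["val_loss"]
        assert h1["train_loss"] == h2["train_loss"]

    def test_split_leakage_hard_error(self, rng):
        X, y = _blob_images(rng, n_per_class=10)
        cfg = decoders.CnnConfig(input_size=(20, 20, 3), output_classes=2,
                                 seed=0, max_epochs=1)
        prov = [{"kind": "augmented", "parent": "p0", "id": "c0"}]
        split_of = {"p0": "test", "c0": "train"}
        with pytest.raises(ValueError, match="leakage"):
            decoders.train_cnn(X[:20], y[:20], X[20:], y[20:], cfg,
                               provenance=prov, split_of=split_of)


class TestAggregateTrial:
    def test_unanimous_sensors(self):
        p = np.tile([0.97, 0.01, 0.02], (5, 1))
        pred, scores, tie = decoders.aggregate_trial(p)
        assert pred == 0 and not tie

    def test_hand_computed_two_class_example(self):
        p = np.array([[0.9, 0.1], [0.6, 0.4], [0.2, 0.8]])
        pred, scores, tie = decoders.aggregate_trial(p)
        expect0 = -(np.log(0.9) + np.log(0.6) + np.log(0.2)) / 3
        expect1 = -(np.log(0.1) + np.log(0.4) + np.log(0.8)) / 3
        assert scores[0] == pytest.approx(expect0)
        assert scores[1] == pytest.approx(expect1)
        assert pred == 0 and not tie

    def test_uniform_probabilities_tie_flagged(self):
        p = np.full((4, 3), 1 / 3)
        pred, _, tie = decoders.aggregate_trial(p)
        assert pred == 0 and tie

    def test_permutation_invariance_over_sensors(self, rng):
        p = rng.dirichlet(np.ones(4), size=6)
        pred1, s1, _ = decoders.aggregate_trial(p)
        pred2, s2, _ = decoders.aggregate_trial(p[::-1])
        assert pred1 == pred2
        np.testing.assert_allclose(s1, s2)

    def test_zero_probability_floored_not_inf(self):
        p = np.array([[1.0, 0.0], [1.0, 0.0]])
        pred, scores, _ = decoders.aggregate_trial(p)
        assert np.isfinite(scores).all() and pred == 0

    def test_unnormalized_rows_rejected(self):
        with pytest.raises(ValueError):
            decoders.aggregate_trial(np.array([[0.5, 0.2]]))

    def test_mean_prob_alternative_agrees_on_clear_case(self):
        p = np.array([[0.9, 0.1], [0.8, 0.2]])
        a, _, _ = decoders.aggregate_trial(p)
        b, _, _ = decoders.aggregate_trial_mean_prob(p)
        assert a == b == 0


class TestEngine:
    def test_conv_gradients_match_finite_differences(self):
        rng = np.random.default_rng(0)
        net = nnet.Network([
            nnet.Conv2D(1, 2, 3, 1, rng), nnet.ReLU(), nnet.MaxPool2D(2),
            nnet.Flatten(), nnet.Dense(8, 3, rng)])
        X = rng.standard_normal((2, 6, 6, 1))
        y = np.array([0, 2])
        net.loss_and_backward(X, y)
        W = net.layers[0].W
        g = net.layers[0].grads[0]
        eps = 1e-6
        for idx in [(0, 0, 0, 0), (1, 2, 0, 1), (2, 1, 0, 0)]:
            W[idx] += eps
            lp = net.loss(X, y)
            W[idx] -= 2 * eps
            lm = net.loss(X, y)
            W[idx] += eps
            assert (lp - lm) / (2 * eps) == pytest.approx(g[idx], rel=1e-3, abs=1e-6)

    def test_gradient_clipping_bounds_global_norm(self):
        rng = np.random.default_rng(0)
        net = nnet.Network([nnet.Dense(4, 3, rng)])
        X = 100 * rng.standard_normal((8, 4))
        net.loss_and_backward(X, np.array([0, 1, 2, 0, 1, 2, 0, 1]))
        nnet._clip(net, 1.0)
        total = np.sqrt(sum(float(np.sum(g**2))
                            for l in net.layers for g in l.grads))
        assert total <= 1.0 + 1e-9
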