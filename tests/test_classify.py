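import numpy as np
import pytest

from seizeeg.classify import (
    CNNClassifier,
    CNNSpec,
    TrainConfig,
    avg_pool,
    build_cnn,
    max_pool,
    model_from_dict,
    model_to_dict,
    predict,
    train,
)
from seizeeg.io import FeatureMatrix


def _blobs(n=400, seed=0, sep=4.0):
    """Two well-separated Gaussian blobs in 10-D."""
    rng = np.random.default_rng(seed)
    y = rng.integers(0, 2, size=n)
    X = rng.standard_normal((n, 10)) + sep * y[:, None] * np.linspace(0.3, 1.0, 10)
    return X, y


class TestPooling:
    def test_max_hand_example(self):
        np.testing.assert_array_equal(max_pool([1, 3, 2, 5]), [3, 3, 5])

    def test_avg_hand_example(self):
        np.testing.assert_array_equal(avg_pool([1, 3, 2, 5]), [2.0, 2.5, 3.5])

    def test_constant_input(self):
        np.testing.assert_array_equal(max_pool(np.full(6, 2.0)), np.full(5, 2.0))
        np.testing.assert_array_equal(avg_pool(np.full(6, 2.0)), np.full(5, 2.0))

    def test_window_too_large(self):
        with pytest.raises(ValueError):
            max_pool([1.0], size=2)


class TestSpec:
    def test_shape_walkthrough(self):
        # 10 -> conv 9 -> pool 8 -> conv 7 -> pool 6; flatten 6*32 = 192
        spec = CNNSpec()
        assert spec.shape_walkthrough() == [10, 9, 8, 7, 6]
        assert spec.flat_dim == 192

    def test_collapsing_spec_rejected(self):
        with pytest.raises(ValueError, match="collapses"):
            CNNSpec(input_len=2)


class TestForward:
    def test_probabilities_sum_to_one(self):
        clf = CNNClassifier(epochs=1, seed=0)
        X, y = _blobs(64)
        clf.fit(X, y)
        probs = clf.predict_proba(X[:10])
        assert probs.shape == (10, 2)
        assert np.all(probs >= 0)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_same_seed_same_initial_outputs(self):
        X, y = _blobs(64)
        outs = []
        for _ in range(2):
            clf = CNNClassifier(epochs=1, seed=42)
            clf.fit(X, y)
            outs.append(clf.predict_proba(X[:5]))
        np.testing.assert_array_equal(outs[0], outs[1])

    def test_first_layer_matches_naive_cross_correlation(self):
        """Conv output = explicit loop of kernel dot products + bias."""
        clf = CNNClassifier(epochs=1, seed=3)
        X, y = _blobs(32)
        clf.fit(X, y)
        conv = clf.layers_[0]
        x = (X[:4] - clf.x_mean_) / clf.x_std_
        got = conv.forward(x[:, None, :], training=False)
        W, b = conv.W, conv.b
        expected = np.empty_like(got)
        for bi in range(4):
            for f in range(W.shape[0]):
                for i in range(10 - W.shape[2] + 1):
                    expected[bi, f, i] = np.dot(W[f, 0], x[bi, i : i + W.shape[2]]) + b[f]
        np.testing.assert_allclose(got, expected, atol=1e-5)


class TestTraining:
    def test_separable_blobs_high_heldout_accuracy(self):
        X, y = _blobs(400, seed=0)
        fm = FeatureMatrix([f"f{i}" for i in range(10)], X, y)
        model = build_cnn(seed=0)
        model, train_idx, test_idx = train(model, fm, TrainConfig(epochs=100, seed=0))
        acc = np.mean(model.predict(X[test_idx]) == y[test_idx])
        assert acc >= 0.95
        assert model.loss_curve_[-1] < model.loss_curve_[0]

    def test_train_set_accuracy_at_least_heldout(self):
        X, y = _blobs(400, seed=1)
        fm = FeatureMatrix([f"f{i}" for i in range(10)], X, y)
        model, train_idx, test_idx = train(
            build_cnn(seed=1), fm, TrainConfig(epochs=100, seed=1)
        )
        acc_train = np.mean(model.predict(X[train_idx]) == y[train_idx])
        acc_test = np.mean(model.predict(X[test_idx]) == y[test_idx])
        assert acc_train >= acc_test - 0.05

    def test_shuffled_labels_near_chance(self):
        X, y = _blobs(400, seed=0)
        y_shuf = np.random.default_rng(0).permutation(y)
        fm = FeatureMatrix([f"f{i}" for i in range(10)], X, y_shuf)
        model, _, test_idx = train(build_cnn(seed=0), fm, TrainConfig(epochs=60, seed=0))
        acc = np.mean(model.predict(X[test_idx]) == y_shuf[test_idx])
        assert abs(acc - 0.5) <= 0.15

    def test_zero_epochs_rejected(self):
        with pytest.raises(ValueError):
            TrainConfig(epochs=0)

    def test_single_class_rejected(self):
        X, _ = _blobs(40)
        with pytest.raises(ValueError, match="class"):
            CNNClassifier(epochs=1).fit(X, np.zeros(40, dtype=int))

    def test_predict_deterministic(self):
        X, y = _blobs(100, seed=2)
        clf = CNNClassifier(epochs=10, seed=0).fit(X, y)
        probs, labels = predict(clf, X[:20])
        probs2, labels2 = predict(clf, X[:20])
        np.testing.assert_array_equal(probs, probs2)
        np.testing.assert_array_equal(labels, labels2)

    def test_dimension_mismatch_rejected(self):
        X, y = _blobs(60)
        clf = CNNClassifier(epochs=1, seed=0).fit(X, y)
        with pytest.raises(ValueError):
            clf.predict(X[:, :7])


class TestSerialization:
    def test_round_trip_predictions_identical(self):
        X, y = _blobs(120, seed=4)
        clf = CNNClassifier(epochs=20, seed=0).fit(X, y)
        restored = model_from_dict(model_to_dict(clf))
        np.testing.assert_allclose(
            restored.predict_proba(X), clf.predict_proba(X), atol=1e-12
        )

    def test_version_check(self):
        X, y = _blobs(60)
        state = model_to_dict(CNNClassifier(epochs=1, seed=0).fit(X, y))
        state["version"] = 99
        with pytest.raises(ValueError, match="version"):
            model_from_dict(state)
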