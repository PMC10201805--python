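import hashlib
import json

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import seizeeg as sz
from seizeeg.classify import CNNClassifier, TrainConfig, build_cnn, train
from seizeeg.evaluate import (
    CaseReport,
    ConfusionCounts,
    confusion,
    evaluate_feature_matrix,
    metrics,
    run_case,
)
from seizeeg.io import FeatureMatrix
from seizeeg.synth import SynthConfig, generate_dataset


class TestConfusion:
    def test_perfect_agreement(self):
        c = confusion([1, 1, 0, 0], [1, 1, 0, 0])
        assert (c.TP, c.TN, c.FP, c.FN) == (2, 2, 0, 0)

    def test_total_inversion(self):
        c = confusion([1, 0], [0, 1])
        assert c.TP == 0 and c.TN == 0 and c.FP == 1 and c.FN == 1

    def test_counting_example(self):
        y_true = [1] * 10 + [0] * 10
        y_pred = [1] * 9 + [0] + [1, 1] + [0] * 8
        c = confusion(y_true, y_pred)
        assert (c.TP, c.FN, c.TN, c.FP) == (9, 1, 8, 2)

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            confusion([1, 0], [1])

    def test_non_binary_rejected(self):
        with pytest.raises(ValueError, match="binary"):
            confusion([0, 2], [0, 1])


class TestMetrics:
    def test_hand_arithmetic(self):
        rep = metrics(ConfusionCounts(TP=9, FN=1, TN=8, FP=2))
        assert rep.accuracy == pytest.approx(0.85)
        assert rep.sensitivity == pytest.approx(0.9)
        assert rep.specificity == pytest.approx(0.8)
        assert rep.precision == pytest.approx(9 / 11)

    def test_perfect_counts(self):
        rep = metrics(ConfusionCounts(TP=5, FN=0, TN=5, FP=0))
        assert (rep.accuracy, rep.sensitivity, rep.specificity, rep.precision) == (1, 1, 1, 1)

    def test_undefined_precision_marked(self):
        rep = metrics(ConfusionCounts(TP=0, FP=0, TN=3, FN=1))
        assert rep.precision is None
        assert rep.specificity == 1.0

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            metrics(ConfusionCounts(0, 0, 0, 0))

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.tuples(st.integers(0, 1), st.integers(0, 1)), min_size=1, max_size=50))
    def test_integer_identities(self, pairs):
        """accuracy*total and sensitivity*(TP+FN) recover integer counts."""
        y_true = [a for a, _ in pairs]
        y_pred = [b for _, b in pairs]
        c = confusion(y_true, y_pred)
        rep = metrics(c)
        assert rep.accuracy * c.total == pytest.approx(c.TP + c.TN)
        if rep.sensitivity is not None:
            assert rep.sensitivity * (c.TP + c.FN) == pytest.approx(c.TP)

    def test_report_json_round_trip(self):
        rep = metrics(ConfusionCounts(TP=3, FN=1, TN=4, FP=2), case_id="case4")
        back = sz.MetricsReport.from_dict(json.loads(json.dumps(rep.to_dict())))
        assert back == rep


def _param_hash(model: CNNClassifier) -> str:
    h = hashlib.sha256()
    for layer in model.layers_:
        for p in layer.params:
            h.update(np.ascontiguousarray(getattr(layer, p)).tobytes())
    return h.hexdigest()


class TestLeakFreedom:
    def test_test_fold_labels_cannot_touch_training(self):
        """For a fixed split, fitted stages are a function of training rows only:
        flipping every test-fold label changes neither the selected features
        nor the trained CNN parameters."""
        rng = np.random.default_rng(0)
        y = rng.integers(0, 2, 200)
        X = rng.standard_normal((200, 10)) + 2.0 * y[:, None]
        names = [f"f{i}" for i in range(10)]
        train_idx, test_idx = np.arange(150), np.arange(150, 200)

        y_perm = y.copy()
        y_perm[test_idx] = 1 - y_perm[test_idx]

        hashes, selections = [], []
        for labels in (y, y_perm):
            sel = sz.OOBPermutationRFE(
                k_final=5, n_trees=15, seed=0, feature_names=names
            ).fit(X[train_idx], labels[train_idx])
            model = CNNClassifier(
                spec=sz.CNNSpec(input_len=5), epochs=10, seed=0
            ).fit(sel.transform(X[train_idx]), labels[train_idx])
            hashes.append(_param_hash(model))
            selections.append(sel.selected_names_)
        assert hashes[0] == hashes[1]
        assert selections[0] == selections[1]


@pytest.fixture(scope="module")
def tiny_case_segments():
    return generate_dataset(12, base_cfg=SynthConfig(n_samples=256), seed=0)


class TestRunCase:
    def test_end_to_end_small_and_deterministic(self, tiny_case_segments):
        kwargs = dict(
            case_id="synthetic", n_repeats=2, seed=0, n_trees=20, epochs=15
        )
        rep1 = run_case(tiny_case_segments, **kwargs)
        rep2 = run_case(tiny_case_segments, **kwargs)
        assert rep1.to_dict() == rep2.to_dict()
        assert rep1.n_repeats == 2
        assert len(rep1.repeats) == 2
        assert all(len(s) == 10 for s in rep1.selected_features)
        assert 0.0 <= rep1.mean_accuracy <= 1.0

    def test_case_report_json_round_trip(self, tiny_case_segments):
        rep = run_case(
            tiny_case_segments, case_id="x", n_repeats=2, seed=1, n_trees=15, epochs=10
        )
        back = CaseReport.from_dict(json.loads(json.dumps(rep.to_dict())))
        assert back.to_dict() == rep.to_dict()

    def test_unlabeled_segments_rejected(self, tiny_case_segments):
        seg = tiny_case_segments[0].with_label(None)
        with pytest.raises(ValueError, match="label"):
            run_case([seg], n_repeats=1)

    def test_global_selection_scope(self):
        rng = np.random.default_rng(0)
        y = rng.integers(0, 2, 80)
        X = rng.standard_normal((80, 12)) + 1.5 * y[:, None]
        fm = FeatureMatrix([f"f{i}" for i in range(12)], X, y)
        rep = evaluate_feature_matrix(
            fm, n_repeats=2, seed=0, k_final=10, n_trees=15, epochs=10,
            selection_scope="global",
        )
        # one global selection reused across repeats
        assert rep.selected_features[0] == rep.selected_features[1]
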