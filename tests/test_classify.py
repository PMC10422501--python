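import numpy as np
import pytest

from egopool.classify import (
    ConfusionMatrix,
    accuracy,
    average_precision,
    decision_values,
    lopo_evaluate,
    per_class_precision,
    predict,
    train_ovr,
)
from egopool.errors import DataError, ParameterError, TrainingError
from egopool.manifest_io import ClipRecord, DatasetManifest

HAND_MATRIX = ConfusionMatrix(np.array([[3, 1], [2, 4]]), ("a", "b"))


def _blobs(seed=0, n_per_class=20, spread=0.2, separation=4.0):
    """Two Gaussian blobs with a guaranteed margin (separation >> spread)."""
    rng = np.random.default_rng(seed)
    x0 = rng.normal([0.0, 0.0], spread, size=(n_per_class, 2))
    x1 = rng.normal([separation, separation], spread, size=(n_per_class, 2))
    features = np.vstack([x0, x1])
    labels = ["a"] * n_per_class + ["b"] * n_per_class
    return features, labels


class TestMetrics:
    def test_hand_worked_matrix(self):
        assert accuracy(HAND_MATRIX) == pytest.approx(70.0)
        np.testing.assert_allclose(per_class_precision(HAND_MATRIX), [60.0, 80.0])
        assert average_precision(HAND_MATRIX) == pytest.approx(70.0)

    def test_identity_matrix_is_perfect(self):
        conf = ConfusionMatrix(np.eye(3, dtype=int) * 5, ("a", "b", "c"))
        assert accuracy(conf) == 100.0
        np.testing.assert_allclose(per_class_precision(conf), 100.0)

    def test_all_off_diagonal_is_zero_accuracy(self):
        conf = ConfusionMatrix(np.array([[0, 5], [5, 0]]), ("a", "b"))
        assert accuracy(conf) == 0.0

    def test_never_predicted_class_has_zero_precision(self):
        conf = ConfusionMatrix(np.array([[3, 0], [2, 0]]), ("a", "b"))
        np.testing.assert_allclose(per_class_precision(conf), [60.0, 0.0])

    def test_ap_invariant_to_consistent_class_permutation(self):
        permuted = ConfusionMatrix(
            HAND_MATRIX.counts[::-1, ::-1].copy(), ("b", "a")
        )
        assert average_precision(permuted) == pytest.approx(
            average_precision(HAND_MATRIX)
        )

    def test_accuracy_is_exactly_trace_over_total(self, rng):
        counts = rng.integers(0, 20, size=(4, 4))
        conf = ConfusionMatrix(counts, ("a", "b", "c", "d"))
        assert accuracy(conf) == pytest.approx(
            100.0 * counts.trace() / counts.sum()
        )


class TestTrainPredict:
    def test_separable_blobs_reach_perfect_training_accuracy(self):
        features, labels = _blobs()
        model = train_ovr(features, labels, cost=1.0, seed=0)
        assert (predict(model, features) == np.asarray(labels)).all()

    def test_single_class_training_rejected(self):
        with pytest.raises(TrainingError):
            train_ovr(np.ones((5, 2)), ["a"] * 5)

    def test_nan_features_rejected(self):
        with pytest.raises(DataError):
            train_ovr(np.array([[np.nan, 0.0], [1.0, 1.0]]), ["a", "b"])

    def test_duplicating_rows_leaves_decision_function_stable(self):
        features, labels = _blobs(seed=3)
        model = train_ovr(features, labels, seed=0)
        doubled = train_ovr(
            np.vstack([features, features]), labels + labels, seed=0
        )
        probe = np.array([[1.0, 1.0], [3.0, 3.0], [0.5, 2.0]])
        np.testing.assert_allclose(
            np.argmax(decision_values(model, probe), axis=1),
            np.argmax(decision_values(doubled, probe), axis=1),
        )

    def test_tie_on_symmetric_model_goes_to_first_class(self):
        features, labels = _blobs(seed=1)
        model = train_ovr(features, labels, seed=0)
        # the binary expansion makes the two scorers exactly opposite, so a
        # point on the separating hyperplane scores a tie
        scores = decision_values(model, np.zeros((1, 2)))
        if scores[0, 0] == scores[0, 1]:
            assert predict(model, np.zeros((1, 2)))[0] == model.classes[0]
        # regardless, symmetric zero scorers tie to the first class
        model.weights[:] = 0.0
        model.biases[:] = 0.0
        assert predict(model, np.zeros((1, 2)))[0] == model.classes[0]

    def test_dimension_mismatch_rejected(self):
        features, labels = _blobs()
        model = train_ovr(features, labels)
        with pytest.raises(ParameterError):
            predict(model, np.zeros((1, 5)))


def _manifest(n_subjects=5, n_classes=2, clips=2):
    records = [
        ClipRecord(f"s{s}c{c}k{k}", "/none", f"subj{s}", f"class{c}", 30.0)
        for s in range(n_subjects)
        for c in range(n_classes)
        for k in range(clips)
    ]
    return DatasetManifest.from_records(records)


def _separable_features(manifest, d=10, seed=0):
    rng = np.random.default_rng(seed)
    centers = {
        cls: np.eye(d)[i] * 5.0 for i, cls in enumerate(manifest.classes)
    }
    return {
        r.clip_id: centers[r.label] + rng.normal(0, 0.1, d)
        for r in manifest.records
    }


class TestLOPO:
    def test_one_fold_per_subject_and_each_clip_tested_once(self):
        manifest = _manifest(n_subjects=5)
        result = lopo_evaluate(manifest, _separable_features(manifest))
        assert len(result.fold_log) == 5
        assert sum(f.n_test for f in result.fold_log) == len(manifest)
        assert result.confusion.n_samples == len(manifest)

    def test_separable_signal_identical_across_subjects_scores_100(self):
        manifest = _manifest()
        result = lopo_evaluate(manifest, _separable_features(manifest))
        assert result.accuracy == 100.0
        assert result.average_precision == 100.0

    def test_uninformative_features_score_near_chance(self):
        """Monte-Carlo null check: with label-free random features the mean
        LOPO accuracy over replicates sits near 1/N_c.  The tolerance is
        wider than a plain binomial interval because predictions within a
        fold share one model and are therefore positively correlated."""
        manifest = _manifest(n_subjects=6, n_classes=3, clips=3)
        chance = 100.0 / len(manifest.classes)
        accuracies = []
        for replicate in range(5):
            rng = np.random.default_rng(1000 + replicate)
            features = {
                r.clip_id: rng.normal(size=10) for r in manifest.records
            }
            accuracies.append(lopo_evaluate(manifest, features, seed=0).accuracy)
        assert abs(np.mean(accuracies) - chance) <= 10.0

    def test_requires_two_subjects(self):
        manifest = _manifest(n_subjects=1)
        with pytest.raises(ParameterError):
            lopo_evaluate(manifest, _separable_features(manifest))

    def test_single_class_training_fold_aborts_unless_allowed(self):
        records = [
            ClipRecord("a", "/n", "s1", "x", 30.0),
            ClipRecord("b", "/n", "s1", "x", 30.0),
            ClipRecord("c", "/n", "s2", "y", 30.0),
            ClipRecord("d", "/n", "s2", "x", 30.0),
        ]
        manifest = DatasetManifest.from_records(records)
        features = {r.clip_id: np.ones(4) for r in records}
        with pytest.raises(TrainingError):
            lopo_evaluate(manifest, features)
        result = lopo_evaluate(manifest, features, skip_single_class_folds=True)
        assert len(result.fold_log) == 1

    def test_missing_features_reported(self):
        manifest = _manifest(n_subjects=2)
        with pytest.raises(ParameterError, match="missing features"):
            lopo_evaluate(manifest, {})
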