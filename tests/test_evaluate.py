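import numpy as np
import pytest
from sklearn.metrics import f1_score

import harlearn as hl
from harlearn.errors import InputError, SpecError, TrainingError


def _separable(rng, n=60, n_classes=3, d=4, sep=8.0):
    y = rng.integers(0, n_classes, size=n)
    centers = rng.normal(size=(n_classes, d)) * sep
    X = centers[y] + rng.normal(0, 0.2, size=(n, d))
    return X, y


class TestTrainSVM:
    def test_separable_perfect_training_accuracy(self, rng):
        X, y = _separable(rng)
        clf = hl.train_svm(X, y, C=1.0, seed=0)
        assert (clf.predict(X) == y).mean() == 1.0
        assert clf.decision_scores(X).shape == (len(X), 3)

    def test_duplicated_columns_same_predictions(self, rng):
        X, y = _separable(rng)
        a = hl.train_svm(X, y, C=1.0, seed=0).predict(X)
        b = hl.train_svm(np.hstack([X, X]) / 2, y, C=1.0, seed=0).predict(
            np.hstack([X, X]) / 2)
        assert (a == b).mean() > 0.98

    def test_deterministic(self, rng):
        X, y = _separable(rng)
        a = hl.train_svm(X, y, C=0.1, seed=7).decision_scores(X)
        b = hl.train_svm(X, y, C=0.1, seed=7).decision_scores(X)
        np.testing.assert_array_equal(a, b)

    def test_single_class_rejected(self, rng):
        with pytest.raises(TrainingError):
            hl.train_svm(rng.normal(size=(10, 2)), np.zeros(10, dtype=int))

    def test_binary_scores_two_columns(self, rng):
        X, y = _separable(rng, n_classes=2)
        scores = hl.train_svm(X, y).decision_scores(X)
        assert scores.shape == (len(X), 2)
        assert (scores.argmax(axis=1) == hl.train_svm(X, y).predict(X)).all()


class TestTuneC:
    def test_singleton_grid(self, rng):
        X, y = _separable(rng)
        assert hl.tune_C(X, y, grid=(0.5,)) == 0.5

    def test_easy_data_ties_return_smallest(self, rng):
        X, y = _separable(rng, n=90, sep=50.0)
        assert hl.tune_C(X, y, grid=(0.1, 1.0, 10.0), seed=0) == 0.1

    def test_matches_exhaustive_reevaluation(self, rng):
        from sklearn.model_selection import StratifiedKFold
        X = rng.normal(size=(60, 3))
        y = rng.integers(0, 2, size=60)       # noisy: C actually matters
        grid = (1e-3, 1e-1, 1e1)
        picked = hl.tune_C(X, y, grid=grid, seed=3)
        skf = StratifiedKFold(n_splits=3, shuffle=True, random_state=3)
        splits = list(skf.split(X, y))
        scores = {}
        for C in grid:
            vals = []
            for tr, va in splits:
                clf = hl.train_svm(X[tr], y[tr], C=C, seed=3)
                rep = hl.compute_metrics(y[va], clf.predict(X[va]), 2)
                vals.append(rep.average_f1)
            scores[C] = np.mean(vals)
        best = max(scores.values())
        assert scores[picked] == pytest.approx(best)
        assert picked == min(C for C in grid
                             if scores[C] == pytest.approx(best))


class TestComputeMetrics:
    def test_perfect_prediction(self):
        rep = hl.compute_metrics([0, 1, 2, 1], [0, 1, 2, 1], 3)
        assert rep.accuracy == rep.weighted_f1 == rep.average_f1 == 1.0

    def test_worked_two_class_example(self):
        # 3 of class 0 all correct, 1 of class 1 predicted as 0
        rep = hl.compute_metrics([0, 0, 0, 1], [0, 0, 0, 0], 2)
        assert rep.accuracy == 0.75
        assert rep.per_class_f1[0] == pytest.approx(6 / 7)
        assert rep.per_class_f1[1] == 0.0
        assert rep.average_f1 == pytest.approx(3 / 7)          # ~0.4286
        assert rep.weighted_f1 == pytest.approx(0.75 * 6 / 7)  # ~0.643

    def test_absent_class_still_averaged(self):
        rep = hl.compute_metrics([1, 1], [1, 1], 3)
        assert rep.per_class_f1[0] == rep.per_class_f1[2] == 0.0
        assert rep.average_f1 == pytest.approx(1 / 3)

    def test_label_permutation_symmetry(self, rng):
        y_true = rng.integers(0, 4, size=50)
        y_pred = rng.integers(0, 4, size=50)
        rep = hl.compute_metrics(y_true, y_pred, 4)
        perm = rng.permutation(4)
        rep_p = hl.compute_metrics(perm[y_true], perm[y_pred], 4)
        np.testing.assert_allclose(np.sort(rep.per_class_f1),
                                   np.sort(rep_p.per_class_f1))
        assert rep.average_f1 == pytest.approx(rep_p.average_f1)

    def test_matches_sklearn_on_random_vectors(self, rng):
        for _ in range(100):
            n_classes = int(rng.integers(2, 6))
            n = int(rng.integers(1, 60))
            y_true = rng.integers(0, n_classes, size=n)
            y_pred = rng.integers(0, n_classes, size=n)
            rep = hl.compute_metrics(y_true, y_pred, n_classes)
            labels = np.arange(n_classes)
            np.testing.assert_allclose(
                rep.per_class_f1,
                f1_score(y_true, y_pred, labels=labels, average=None,
                         zero_division=0))
            assert rep.accuracy == pytest.approx((y_true == y_pred).mean())
            assert rep.average_f1 == pytest.approx(rep.per_class_f1.mean())
            assert rep.confusion.sum() == n
            assert np.trace(rep.confusion) / n == pytest.approx(rep.accuracy)

    def test_out_of_range_label_rejected(self):
        with pytest.raises(InputError):
            hl.compute_metrics([0, 3], [0, 1], 3)


class TestRankChannels:
    def test_simple_ordering(self):
        rng = np.random.default_rng(0)
        values = rng.normal(size=(1000, 3)) * np.array([1.0, np.sqrt(3), np.sqrt(2)])
        rec = hl.SensorRecording(values=values, labels=np.zeros(1000, dtype=int),
                                 sample_rate_hz=30.0, channel_names=list("abc"))
        assert hl.rank_channels_by_variance([rec], 2) == [1, 2]

    def test_full_rank_is_permutation(self, small_recording):
        ranked = hl.rank_channels_by_variance([small_recording], 6)
        assert sorted(ranked) == list(range(6))

    def test_matches_sort_oracle_with_tie_rule(self, rng):
        values = rng.normal(size=(500, 8))
        values[:, 5] = values[:, 2]          # exact tie between 2 and 5
        rec = hl.SensorRecording(values=values, labels=np.zeros(500, dtype=int),
                                 sample_rate_hz=30.0,
                                 channel_names=[f"c{i}" for i in range(8)])
        ranked = hl.rank_channels_by_variance([rec], 8)
        var = values.var(axis=0)
        expected = sorted(range(8), key=lambda i: (-var[i], i))
        assert ranked == expected
        assert ranked.index(2) < ranked.index(5)

    def test_n_too_large_rejected(self, small_recording):
        with pytest.raises(SpecError):
            hl.rank_channels_by_variance([small_recording], 7)


class TestLateFusion:
    def test_identical_scores_identical_predictions(self, rng):
        scores = rng.normal(size=(20, 4))
        np.testing.assert_array_equal(hl.late_fusion(scores, scores),
                                      scores.argmax(axis=1))

    def test_probability_averaging_arithmetic(self):
        # probabilities (.6,.4) and (.2,.8) -> fused (.4,.6) -> class 1
        a = np.array([[0.6, 0.4]])
        b = np.array([[0.2, 0.8]])
        assert hl.fuse_probabilities(a, b)[0] == 1

    def test_matches_rowwise_oracle(self, rng):
        from scipy.special import softmax
        a = rng.normal(size=(50, 5))
        b = rng.normal(size=(50, 5)) * 10      # deliberately different scales
        fused = hl.late_fusion(a, b)
        oracle = ((softmax(a / a.std(), axis=1)
                   + softmax(b / b.std(), axis=1)) / 2).argmax(axis=1)
        np.testing.assert_array_equal(fused, oracle)

    def test_scale_invariant_per_model(self, rng):
        a = rng.normal(size=(30, 4))
        b = rng.normal(size=(30, 4))
        np.testing.assert_array_equal(hl.late_fusion(a, b),
                                      hl.late_fusion(5.0 * a, b))

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(SpecError):
            hl.late_fusion(rng.normal(size=(5, 3)), rng.normal(size=(5, 4)))


@pytest.fixture(scope="module")
def subjects():
    recs = []
    for i, sid in enumerate(["alice", "bob", "carol"]):
        spec = hl.benchmark_spec(seed=20 + i, total_duration=120.0)
        rec = hl.generate_recording(spec)
        rec.subject_id = sid
        recs.append(rec)
    return recs


class TestLOSO:
    def test_three_subjects_three_folds_mean_aggregate(self, subjects):
        cfg = hl.benchmark_config()
        report = hl.loso_cv(subjects, "hc", cfg, seed=0)
        assert set(report.per_subject) == {"alice", "bob", "carol"}
        folds = list(report.per_subject.values())
        assert report.accuracy == pytest.approx(
            np.mean([r.accuracy for r in folds]))
        assert report.average_f1 == pytest.approx(
            np.mean([r.average_f1 for r in folds]))
        assert report.average_f1 > 0.8      # easy conditions, held-out subject

    def test_identical_subjects_equal_folds(self):
        recs = []
        for sid in ["s1", "s2"]:
            rec = hl.generate_recording(hl.benchmark_spec(seed=33,
                                                          total_duration=120.0))
            rec.subject_id = sid
            recs.append(rec)
        report = hl.loso_cv(recs, "hc", hl.benchmark_config(), seed=0)
        a, b = report.per_subject.values()
        assert a.accuracy == pytest.approx(b.accuracy)
        assert a.average_f1 == pytest.approx(b.average_f1)

    def test_no_held_out_frames_in_training_fits(self, subjects, monkeypatch):
        import harlearn.pipeline as pipeline
        seen = []
        original = pipeline.learn_features

        def audited(method, train, test, config=None, seed=None):
            seen.append((set(train.subjects.tolist()), set(test.subjects.tolist())))
            return original(method, train, test, config, seed)

        monkeypatch.setattr(pipeline, "learn_features", audited)
        hl.loso_cv(subjects, "hc", hl.benchmark_config(), seed=0)
        assert len(seen) == 3
        for train_subjects, test_subjects in seen:
            assert len(test_subjects) == 1
            assert train_subjects.isdisjoint(test_subjects)
            assert train_subjects | test_subjects == {"alice", "bob", "carol"}

    def test_single_subject_rejected(self, subjects):
        with pytest.raises(SpecError):
            hl.loso_cv(subjects[:1], "hc", hl.benchmark_config())
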