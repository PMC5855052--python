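"""Linear-SVM evaluation protocol, metrics, LOSO CV and late fusion.

All feature families are compared through the same classifier: a linear
soft-margin SVM trained one-vs-rest, whose cost parameter C is tuned per
method by stratified cross-validation on the training split.  Performance is
summarized by overall accuracy, the weighted F1-score (class F1-scores
weighted by true-class proportions) and the average F1-score (unweighted
mean of per-class one-vs-all F1-scores) — the latter is robust to a dominant
background class.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import softmax
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import LinearSVC

from .errors import InputError, SpecError, TrainingError

DEFAULT_C_GRID: tuple[float, ...] = (1e-3, 1e-2, 1e-1, 1.0, 1e1, 1e2, 1e3)


@dataclass
class EvalReport:
    """Metrics of one evaluation run.

    ``confusion`` has true classes on rows; ``average_f1`` is the unweighted
    mean of ``per_class_f1`` and ``weighted_f1`` the true-class-proportion
    weighted sum.
    """

    accuracy: float
    weighted_f1: float
    average_f1: float
    per_class_f1: np.ndarray
    confusion: np.ndarray
    C_used: float | None = None


class SVMClassifier:
    """One-vs-rest linear soft-margin SVM with per-class decision scores."""

    def __init__(self, C: float = 1.0, seed: int = 0):
        self.C = C
        self.seed = seed
        self._svc = LinearSVC(C=C, random_state=seed, max_iter=5000)
        self._binary = False

    def fit(self, X: np.ndarray, y: np.ndarray) -> "SVMClassifier":
        X = np.asarray(X, dtype=float)
        if not np.all(np.isfinite(X)):
            raise InputError("features must be finite")
        classes = np.unique(y)
        if len(classes) < 2:
            raise TrainingError("need at least two classes to train the SVM")
        self._binary = len(classes) == 2
        self.classes_ = classes
        self._svc.fit(X, y)
        return self

    def decision_scores(self, X: np.ndarray) -> np.ndarray:
        """(n, n_classes) per-class decision values (binary: +/- the margin)."""
        d = self._svc.decision_function(X)
        if self._binary:
            d = np.column_stack([-d, d])
        return d

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """Per-class probability estimates via softmax over decision values."""
        return softmax(self.decision_scores(X), axis=1)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self._svc.predict(X)


def train_svm(X: np.ndarray, y: np.ndarray, C: float = 1.0,
              seed: int = 0) -> SVMClassifier:
    """Fit the one-vs-rest linear SVM used by every feature method."""
    return SVMClassifier(C=C, seed=seed).fit(X, y)


def compute_metrics(y_true: np.ndarray, y_pred: np.ndarray,
                    n_classes: int) -> EvalReport:
    """Confusion matrix, accuracy, per-class / weighted / average F1.

    Conventions: a class with no true positives but some false positives or
    negatives gets F1 = 0; a class absent from both ``y_true`` and
    ``y_pred`` also gets F1 = 0 and still enters the average — the class
    inventory is fixed by ``n_classes``, not by the fold at hand.
    """
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.shape != y_pred.shape or y_true.size < 1:
        raise InputError("y_true and y_pred must be equal-length, non-empty")
    for name, arr in (("y_true", y_true), ("y_pred", y_pred)):
        if arr.min() < 0 or arr.max() >= n_classes:
            raise InputError(f"{name} contains labels outside [0, {n_classes})")
    cm = np.zeros((n_classes, n_classes), dtype=int)
    np.add.at(cm, (y_true, y_pred), 1)

    tp = np.diag(cm).astype(float)
    fp = cm.sum(axis=0) - tp
    fn = cm.sum(axis=1) - tp
    denom = 2 * tp + fp + fn
    f1 = np.divide(2 * tp, denom, out=np.zeros(n_classes), where=denom > 0)

    total = cm.sum()
    accuracy = float(tp.sum() / total)
    proportions = cm.sum(axis=1) / total
    return EvalReport(
        accuracy=accuracy,
        weighted_f1=float((proportions * f1).sum()),
        average_f1=float(f1.mean()),
        per_class_f1=f1,
        confusion=cm,
    )


def tune_C(X: np.ndarray, y: np.ndarray,
           grid: tuple[float, ...] = DEFAULT_C_GRID, n_folds: int = 3,
           seed: int = 0) -> float:
    """Pick the grid value maximizing average F1 under stratified CV.

    Ties go to the smallest C (the grid is scanned in ascending order with a
    strict improvement rule).
    """
    if not grid:
        raise SpecError("C grid must be non-empty")
    grid = tuple(sorted(grid))
    if len(grid) == 1:
        return grid[0]
    y = np.asarray(y)
    n_classes = int(y.max()) + 1
    counts = np.bincount(y, minlength=n_classes)
    n_folds = max(2, min(n_folds, counts[counts > 0].min()))
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    splits = list(skf.split(X, y))
    best_c, best_score = grid[0], -1.0
    for C in grid:
        scores = []
        for tr, va in splits:
            clf = train_svm(X[tr], y[tr], C=C, seed=seed)
            rep = compute_metrics(y[va], clf.predict(X[va]), n_classes)
            scores.append(rep.average_f1)
        score = float(np.mean(scores))
        if score > best_score:
            best_c, best_score = C, score
    return best_c


def evaluate_features(X_train: np.ndarray, y_train: np.ndarray,
                      X_test: np.ndarray, y_test: np.ndarray,
                      C: float | None = None,
                      grid: tuple[float, ...] = DEFAULT_C_GRID,
                      n_classes: int | None = None,
                      seed: int = 0) -> tuple[EvalReport, np.ndarray]:
    """Tune (optionally), train and evaluate the SVM on one feature family.

    Returns the report and the per-class decision scores on the test set
    (inputs for late fusion).
    """
    if n_classes is None:
        n_classes = int(max(np.max(y_train), np.max(y_test))) + 1
    if C is None:
        C = tune_C(X_train, y_train, grid=grid, seed=seed)
    clf = train_svm(X_train, y_train, C=C, seed=seed)
    scores = clf.decision_scores(X_test)
    # scores are over clf.classes_; spread onto the full class inventory
    full = np.full((len(X_test), n_classes), -np.inf)
    full[:, clf.classes_] = scores
    preds = clf.classes_[scores.argmax(axis=1)]
    report = compute_metrics(y_test, preds, n_classes)
    report.C_used = C
    return report, full


@dataclass
class LOSOReport:
    """Aggregate of a leave-one-subject-out run: unweighted means of the
    per-subject metrics, plus the per-subject breakdown and the summed
    confusion matrix."""

    accuracy: float
    weighted_f1: float
    average_f1: float
    per_class_f1: np.ndarray
    confusion: np.ndarray
    per_subject: dict[str, EvalReport]


def loso_cv(recordings, method: str, config=None, seed: int = 0) -> LOSOReport:
    """Leave-one-subject-out cross-validation of one feature method.

    For each subject: the feature method (and its normalization constants /
    codebooks / network weights) and the SVM are fit on all *other*
    subjects' frames, then evaluated on the held-out subject.  Recordings
    are repaired (forward fill) and segmented per the config before each
    fold.  Final metrics are the unweighted mean over subjects; a subject
    exhibiting a class unseen in training is still evaluated (the fixed
    class inventory F1 convention applies).
    """
    from .io import PipelineConfig
    from .pipeline import learn_features
    from .segment import (FrameSet, energy_peak_segment, forward_fill,
                          sliding_window_segment)

    config = config or PipelineConfig()
    subjects = sorted({r.subject_id for r in recordings})
    if len(subjects) < 2:
        raise SpecError("LOSO needs at least two subjects")

    def frames_of(recs) -> FrameSet:
        sets = []
        for r in recs:
            r = forward_fill(r)
            if config.segment_mode == "energy":
                sets.append(energy_peak_segment(r, config.window,
                                                config.theta_high, config.theta_low))
            else:
                sets.append(sliding_window_segment(r, config.window, config.stride))
        return FrameSet.concatenate(sets)

    n_classes = int(max(r.labels.max() for r in recordings)) + 1
    per_subject: dict[str, EvalReport] = {}
    for held_out in subjects:
        train_fs = frames_of([r for r in recordings if r.subject_id != held_out])
        test_fs = frames_of([r for r in recordings if r.subject_id == held_out])
        f_train, f_test = learn_features(method, train_fs, test_fs, config, seed=seed)
        report, _ = evaluate_features(
            f_train.X, f_train.labels, f_test.X, f_test.labels,
            C=config.svm_c, grid=tuple(config.c_grid),
            n_classes=n_classes, seed=seed)
        per_subject[held_out] = report

    reports = list(per_subject.values())
    return LOSOReport(
        accuracy=float(np.mean([r.accuracy for r in reports])),
        weighted_f1=float(np.mean([r.weighted_f1 for r in reports])),
        average_f1=float(np.mean([r.average_f1 for r in reports])),
        per_class_f1=np.mean([r.per_class_f1 for r in reports], axis=0),
        confusion=np.sum([r.confusion for r in reports], axis=0),
        per_subject=per_subject,
    )


def rank_channels_by_variance(recordings, n: int) -> list[int]:
    """Indices of the ``n`` highest-variance channels, decreasing.

    Variance is computed over all recordings pooled (missing values
    ignored); ties prefer the lower original index.
    """
    if not isinstance(recordings, (list, tuple)):
        recordings = [recordings]
    values = np.concatenate([r.values for r in recordings])
    S = values.shape[1]
    if not 1 <= n <= S:
        raise SpecError(f"n={n} outside [1, {S}]")
    var = np.nanvar(values, axis=0)
    order = np.lexsort((np.arange(S), -var))
    return [int(i) for i in order[:n]]


def fuse_probabilities(probs_a: np.ndarray, probs_b: np.ndarray) -> np.ndarray:
    """Average two per-class probability matrices elementwise and predict.

    The prediction is the argmax of the averaged rows (ties resolve to the
    lowest class index).
    """
    probs_a = np.asarray(probs_a, dtype=float)
    probs_b = np.asarray(probs_b, dtype=float)
    if probs_a.shape != probs_b.shape:
        raise SpecError(f"score shapes differ: {probs_a.shape} vs {probs_b.shape}")
    return ((probs_a + probs_b) / 2.0).argmax(axis=1)


def scores_to_probabilities(scores: np.ndarray) -> np.ndarray:
    """Map one SVM's decision values to per-class probability estimates.

    A softmax with per-model temperature: decision values are divided by
    their own dispersion (standard deviation over finite entries) first.
    Without this, the model whose decision values happen to live on the
    larger scale produces near-binary probabilities and single-handedly
    decides every fused vote, defeating the point of averaging.
    """
    scores = np.asarray(scores, dtype=float)
    finite = scores[np.isfinite(scores)]
    sd = finite.std() if finite.size else 0.0
    return softmax(scores / (sd if sd > 0 else 1.0), axis=1)


def late_fusion(scores_a: np.ndarray, scores_b: np.ndarray) -> np.ndarray:
    """Average two SVMs' class scores and predict.

    Decision values are first made commensurable with
    :func:`scores_to_probabilities`, then averaged elementwise; the
    prediction is the argmax (ties resolve to the lowest class index).
    """
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    if scores_a.shape != scores_b.shape:
        raise SpecError(f"score shapes differ: {scores_a.shape} vs {scores_b.shape}")
    return fuse_probabilities(scores_to_probabilities(scores_a),
                              scores_to_probabilities(scores_b))
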