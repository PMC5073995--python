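"""Confusion metrics, stratified k-fold and leave-one-out evaluation.

The positive class is the disease class: sensitivity (= recall) is the
ability to identify subjects who have the disorder, specificity the
ability to identify those who do not.  F-measure — the harmonic mean of
precision and recall — is the model-selection criterion throughout, with
ties broken by the higher recall.

Cross-validated metrics are, by default, computed by *pooling* the
held-out predictions of all folds into a single confusion table; per-fold
averaging of the derived metrics is available as an option (it is unstable
at small fold sizes, and coincides with pooling for accuracy-type counts).
Feature scaling is always re-fit on the training rows of each fold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .volume_io import SubjectMatrix, minmax_scale

__all__ = [
    "MetricsReport",
    "FoldAssignment",
    "confusion_metrics",
    "stratified_folds",
    "cross_validate",
    "loo_validate",
    "select_best",
]


@dataclass(frozen=True)
class MetricsReport:
    """Confusion counts and the derived classification metrics."""

    tp: int
    fp: int
    tn: int
    fn: int
    precision: float
    recall: float
    f_measure: float
    sensitivity: float
    specificity: float
    positive_class: str

    @classmethod
    def from_counts(
        cls, tp: int, fp: int, tn: int, fn: int, positive_class: str
    ) -> "MetricsReport":
        """Derive precision/recall/F/sensitivity/specificity; 0/0 := 0."""

        def ratio(num: int, den: int) -> float:
            return num / den if den else 0.0

        precision = ratio(tp, tp + fp)
        recall = ratio(tp, tp + fn)
        f = (
            2.0 * precision * recall / (precision + recall)
            if precision + recall
            else 0.0
        )
        return cls(
            tp=int(tp),
            fp=int(fp),
            tn=int(tn),
            fn=int(fn),
            precision=precision,
            recall=recall,
            f_measure=f,
            sensitivity=recall,
            specificity=ratio(tn, tn + fp),
            positive_class=str(positive_class),
        )

    @property
    def n_evaluated(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / self.n_evaluated if self.n_evaluated else 0.0


def confusion_metrics(
    y_true: np.ndarray, y_pred: np.ndarray, positive_class: str
) -> MetricsReport:
    """Confusion counts of a prediction against truth.

    ``positive_class`` is the disease label; any label outside the set seen
    in the inputs' two classes is a hard error.
    """
    y_true = np.asarray(y_true).astype(str)
    y_pred = np.asarray(y_pred).astype(str)
    if len(y_true) == 0 or len(y_true) != len(y_pred):
        raise ValueError("y_true and y_pred must be equal-length and non-empty")
    labels = set(y_true) | set(y_pred)
    if str(positive_class) not in labels:
        raise ValueError(f"positive class {positive_class!r} not among labels {sorted(labels)}")
    if len(labels) > 2:
        raise ValueError(f"more than two labels present: {sorted(labels)}")
    pos_true = y_true == str(positive_class)
    pos_pred = y_pred == str(positive_class)
    tp = int(np.sum(pos_true & pos_pred))
    fp = int(np.sum(~pos_true & pos_pred))
    tn = int(np.sum(~pos_true & ~pos_pred))
    fn = int(np.sum(pos_true & ~pos_pred))
    return MetricsReport.from_counts(tp, fp, tn, fn, positive_class)


@dataclass(frozen=True)
class FoldAssignment:
    """Fold id per subject for k non-overlapping, class-balanced partitions."""

    fold_id: np.ndarray
    k: int
    seed: int

    def test_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.fold_id == fold)

    def train_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.fold_id != fold)


def stratified_folds(labels: np.ndarray, k: int, seed: int = 0) -> FoldAssignment:
    """Partition subjects into k folds of quasi-equal size and class mix.

    Fold sizes differ by at most one subject, and each class's per-fold
    count differs by at most one from an even split; every subject appears
    in exactly one fold.  With ``k == len(labels)`` this degenerates to
    leave-one-out.  Reproducible from ``seed``.

    Implementation: fold target sizes are fixed first (remainder to the
    lowest fold ids); each class then deals a floor share to every fold and
    its remainder, one each, to the folds with the most remaining capacity
    (ties to the lowest fold id), which keeps both invariants at once.
    """
    labels = np.asarray(labels)
    n = len(labels)
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > n:
        raise ValueError(f"k={k} exceeds the number of subjects {n}")
    if k == n:
        return FoldAssignment(np.arange(n, dtype=np.int64), k, seed)
    classes, counts = np.unique(labels, return_counts=True)
    if k > counts.min():
        raise ValueError(
            f"k={k} exceeds the smallest class count {counts.min()}"
        )

    rng = np.random.default_rng(seed)
    base, rem = divmod(n, k)
    target = np.array([base + 1 if i < rem else base for i in range(k)])
    assigned = np.zeros(k, dtype=np.int64)
    fold_id = np.empty(n, dtype=np.int64)

    for c, m in zip(classes, counts):
        share, extra = divmod(int(m), k)
        quota = np.full(k, share, dtype=np.int64)
        capacity = target - assigned - quota
        # folds with the most remaining room take this class's remainder
        order = np.lexsort((np.arange(k), -capacity))
        quota[order[:extra]] += 1
        idx = np.flatnonzero(labels == c)
        rng.shuffle(idx)
        bounds = np.concatenate([[0], np.cumsum(quota)])
        for f in range(k):
            fold_id[idx[bounds[f] : bounds[f + 1]]] = f
        assigned += quota

    if not np.array_equal(np.sort(assigned), np.sort(target)):  # pragma: no cover
        raise AssertionError("fold size invariant violated")
    return FoldAssignment(fold_id, k, seed)


def _fit_predict(train_x, train_y, test_x, params):
    from .classify import train_svm  # deferred: avoid an import cycle

    scaled_train, scaled_test = minmax_scale(train_x, test_x)
    model = train_svm(scaled_train, train_y, params)
    return model.predict(scaled_test)


def cross_validate_arrays(
    values: np.ndarray,
    labels: np.ndarray,
    params,
    folds: FoldAssignment,
    positive_class: str,
    pooled: bool = True,
) -> MetricsReport:
    """k-fold CV on a plain array; see :func:`cross_validate`."""
    labels = np.asarray(labels).astype(str)
    y_pred = np.empty(len(labels), dtype=labels.dtype)
    per_fold: list[MetricsReport] = []
    for f in range(folds.k):
        tr = folds.train_indices(f)
        te = folds.test_indices(f)
        if len(np.unique(labels[tr])) < 2:
            raise ValueError(f"training split of fold {f} is missing a class")
        y_pred[te] = _fit_predict(values[tr], labels[tr], values[te], params)
        if not pooled:
            per_fold.append(confusion_metrics(labels[te], y_pred[te], positive_class))
    pooled_report = confusion_metrics(labels, y_pred, positive_class)
    if pooled:
        return pooled_report
    return MetricsReport(
        tp=pooled_report.tp,
        fp=pooled_report.fp,
        tn=pooled_report.tn,
        fn=pooled_report.fn,
        precision=float(np.mean([r.precision for r in per_fold])),
        recall=float(np.mean([r.recall for r in per_fold])),
        f_measure=float(np.mean([r.f_measure for r in per_fold])),
        sensitivity=float(np.mean([r.sensitivity for r in per_fold])),
        specificity=float(np.mean([r.specificity for r in per_fold])),
        positive_class=str(positive_class),
    )


def cross_validate(
    m: SubjectMatrix,
    params,
    folds: FoldAssignment,
    positive_class: str = "positive",
    pooled: bool = True,
) -> MetricsReport:
    """Cross-validated confusion metrics for one SVM parameter point.

    Per fold, min-max scaling and the SVM are fit on the training rows only
    and applied to the held-out rows; metrics pool the held-out predictions
    across folds (or average per-fold metrics when ``pooled=False``).
    """
    return cross_validate_arrays(
        m.values, m.labels, params, folds, positive_class, pooled
    )


def loo_validate(
    m: SubjectMatrix, params, positive_class: str = "positive"
) -> MetricsReport:
    """Leave-one-out evaluation: k-fold with k = N, pooled confusion."""
    n = m.n_subjects
    if n < 3:
        raise ValueError("leave-one-out needs at least 3 subjects")
    folds = FoldAssignment(np.arange(n, dtype=np.int64), n, 0)
    return cross_validate_arrays(
        m.values, m.labels, params, folds, positive_class, pooled=True
    )


def select_best(records: list) -> object:
    """Argmax by F-measure, ties by recall, remaining ties by input order.

    ``records`` may be MetricsReport objects or tuples whose last element
    is a MetricsReport.
    """
    if not records:
        raise ValueError("select_best needs at least one record")

    def metrics_of(r):
        return r if isinstance(r, MetricsReport) else r[-1]

    best = records[0]
    for r in records[1:]:
        mb, mr = metrics_of(best), metrics_of(r)
        if (mr.f_measure, mr.recall) > (mb.f_measure, mb.recall):
            best = r
    return best
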