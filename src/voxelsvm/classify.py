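"""SVM grid search, linear-weight feature ranking, and the elimination loop.

The main loop interleaves three stages over the active voxel set:

(c) spatial clustering — voxels must belong to a spatially connected
    cluster of at least ``min_cluster_size`` voxels to stay active;
(d) parameter search — every SVM parameter point in the grid is scored by
    cross-validated F-measure on the active voxels;
(e) elimination — a linear SVM is fit on all active voxels and the R
    voxels with the smallest absolute weight |w_j| are removed (the weight
    magnitude of a linear SVM measures a feature's contribution to the
    decision, the ranking rule of SVM recursive feature elimination).

The loop repeats until no more than R voxels remain (a final evaluation is
still performed) or clustering leaves no voxels.  The best iteration is
the one with the highest cross-validated F-measure, ties broken by recall
and then by the earlier iteration.

Ranking always uses a linear SVM regardless of the kernel used for
accuracy evaluation.  By default the whole cohort participates in feature
selection and parameter search (cross-validation then measures the
classification step only — the historical protocol this package mirrors);
:func:`nested_cross_validate` repeats selection inside each training fold
for a leakage-free estimate.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from itertools import product

import numpy as np
from sklearn.svm import SVC, NuSVC

from .evaluate import (
    FoldAssignment,
    MetricsReport,
    confusion_metrics,
    cross_validate_arrays,
    select_best,
    stratified_folds,
)
from .spatial import ClusterLabeling, DbscanParams, grid_dbscan, size_filter
from .volume_io import SubjectMatrix, minmax_scale

__all__ = [
    "SvmParams",
    "WeightVector",
    "IterationRecord",
    "IterationTrace",
    "KERNELS",
    "enumerate_param_grid",
    "train_svm",
    "linear_rank_weights",
    "rfe_step",
    "run_framework",
    "nested_cross_validate",
]

KERNELS = ("linear", "rbf", "polynomial", "sigmoid")
SVM_TYPES = ("C_SVM", "nu_SVM")
DEGREES = (3, 4, 5, 6, 7)
C_VALUES = (2.0, 4.0, 10.0, 12.0, 15.0, 20.0)
GAMMAS = (0.001, 0.003, 0.01, 0.03, 0.05, 0.1)
COEF0S = (0.01, 0.1, 1.0, 5.0, 10.0, 15.0, 20.0)
NUS = (0.2, 0.29, 0.4, 0.5)


@dataclass(frozen=True)
class SvmParams:
    """One point of the SVM parameter grid.

    Fields irrelevant to the kernel/type are None (the canonical
    placeholder): e.g. a linear C-SVM carries only ``C``; gamma, degree and
    coef0 matter only to the kernels that use them; ``nu`` replaces ``C``
    for nu-SVM.
    """

    kernel: str
    svm_type: str = "C_SVM"
    degree: int | None = None
    C: float | None = None
    gamma: float | None = None
    coef0: float | None = None
    nu: float | None = None

    def __post_init__(self) -> None:
        if self.kernel not in KERNELS:
            raise ValueError(f"unknown kernel {self.kernel!r}")
        if self.svm_type not in SVM_TYPES:
            raise ValueError(f"unknown svm type {self.svm_type!r}")

    def describe(self) -> str:
        parts = [self.kernel, self.svm_type]
        for name in ("degree", "C", "gamma", "coef0", "nu"):
            v = getattr(self, name)
            if v is not None:
                parts.append(f"{name}={v}")
        return " ".join(parts)


def _relevant_axes(kernel: str, svm_type: str) -> dict[str, tuple]:
    axes: dict[str, tuple] = {}
    if kernel == "polynomial":
        axes["degree"] = DEGREES
    if kernel in ("rbf", "polynomial", "sigmoid"):
        axes["gamma"] = GAMMAS
    if kernel in ("polynomial", "sigmoid"):
        axes["coef0"] = COEF0S
    if svm_type == "C_SVM":
        axes["C"] = C_VALUES
    else:
        axes["nu"] = NUS
    return axes


def enumerate_param_grid(
    kernels: tuple[str, ...] = KERNELS,
    svm_types: tuple[str, ...] = SVM_TYPES,
) -> list[SvmParams]:
    """The full deterministic parameter grid.

    Cartesian product over the axes relevant to each (kernel, svm type)
    pair: linear varies only the margin parameter (C or nu); rbf adds
    gamma; sigmoid adds gamma and coef0; polynomial adds degree, gamma and
    coef0.
    """
    grid: list[SvmParams] = []
    seen = set()
    for kernel in kernels:
        for svm_type in svm_types:
            axes = _relevant_axes(kernel, svm_type)
            names = list(axes)
            for combo in product(*(axes[n] for n in names)):
                p = SvmParams(kernel=kernel, svm_type=svm_type, **dict(zip(names, combo)))
                if p not in seen:
                    seen.add(p)
                    grid.append(p)
    return grid


_SKLEARN_KERNEL = {
    "linear": "linear",
    "rbf": "rbf",
    "polynomial": "poly",
    "sigmoid": "sigmoid",
}


def train_svm(train: np.ndarray, labels: np.ndarray, params: SvmParams):
    """Fit a libsvm-backed SVM; returns a model with ``predict``.

    The polynomial kernel has the form (gamma * <x, x'> + coef0)^degree.
    The matrix is expected on the [-1, 1] scaling convention.  Solver
    failures are re-raised with the parameter point attached.
    """
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("training labels must contain both classes")
    common = dict(
        kernel=_SKLEARN_KERNEL[params.kernel],
        degree=params.degree if params.degree is not None else 3,
        gamma=params.gamma if params.gamma is not None else "scale",
        coef0=params.coef0 if params.coef0 is not None else 0.0,
    )
    if params.svm_type == "C_SVM":
        model = SVC(C=params.C if params.C is not None else 1.0, **common)
    else:
        model = NuSVC(nu=params.nu if params.nu is not None else 0.5, **common)
    try:
        model.fit(np.asarray(train, dtype=float), labels)
    except Exception as exc:  # surface non-convergence with context
        raise RuntimeError(f"SVM fit failed for ({params.describe()}): {exc}") from exc
    return model


@dataclass
class WeightVector:
    """Linear-SVM weights over the active voxels; |w_j| is the ranking score."""

    w: np.ndarray

    def __post_init__(self) -> None:
        self.w = np.asarray(self.w, dtype=float).ravel()
        if not np.isfinite(self.w).all():
            raise ValueError("weights must be finite")


def linear_rank_weights(
    train: np.ndarray, labels: np.ndarray, C: float = 1.0
) -> WeightVector:
    """Weight vector of a linear C-SVM fit on all active voxels."""
    params = SvmParams(kernel="linear", svm_type="C_SVM", C=C)
    model = train_svm(train, labels, params)
    return WeightVector(model.coef_[0])


def rfe_step(w: WeightVector, R: int) -> np.ndarray:
    """Indices surviving removal of the R smallest-|w| columns.

    Ties in |w| are broken by ascending column index (the earlier index is
    dropped first); survivors keep their original order.  R >= n removes
    everything.
    """
    if R < 1:
        raise ValueError("R must be >= 1")
    absw = np.abs(w.w)
    n = len(absw)
    if R >= n:
        return np.empty(0, dtype=np.int64)
    order = np.lexsort((np.arange(n), absw))  # ascending |w|, ties by index
    dropped = set(order[:R].tolist())
    return np.array([j for j in range(n) if j not in dropped], dtype=np.int64)


@dataclass
class IterationRecord:
    """State of one pass through the cluster / evaluate / eliminate loop."""

    iteration: int
    n_voxels: int
    n_clusters: int
    params: SvmParams
    metrics: MetricsReport
    active_columns: np.ndarray
    labeling: ClusterLabeling


@dataclass
class IterationTrace:
    """Full history of the elimination loop."""

    records: list[IterationRecord] = field(default_factory=list)
    terminated_empty: bool = False

    @property
    def best_index(self) -> int:
        if not self.records:
            raise ValueError("empty trace has no best iteration")
        best = 0
        for i, r in enumerate(self.records[1:], start=1):
            rb = self.records[best].metrics
            rm = r.metrics
            if (rm.f_measure, rm.recall) > (rb.f_measure, rb.recall):
                best = i
        return best

    @property
    def best(self) -> IterationRecord:
        return self.records[self.best_index]


def _evaluate_grid(
    values: np.ndarray,
    labels: np.ndarray,
    grid: list[SvmParams],
    folds: FoldAssignment,
    positive_class: str,
) -> tuple[SvmParams, MetricsReport]:
    scored = [
        (p, cross_validate_arrays(values, labels, p, folds, positive_class))
        for p in grid
    ]
    best = select_best(scored)
    return best[0], best[1]


def run_framework(
    m: SubjectMatrix,
    R: int = 100,
    params: DbscanParams = DbscanParams(),
    grid: list[SvmParams] | None = None,
    cv_folds: int = 10,
    seed: int = 0,
    rank_C: float = 1.0,
    positive_class: str = "positive",
) -> IterationTrace:
    """Run the cluster / grid-search / eliminate loop to completion.

    ``m`` should already be filtered to informative voxels (compose with
    :func:`~voxelsvm.feature_filter.ig_filter` first).  Returns the full
    iteration trace; ``trace.best`` is the iteration with the highest
    cross-validated F-measure (recall, then earlier iteration, on ties).
    ``trace.terminated_empty`` flags a run whose active set died out at the
    clustering stage.  ``active_columns`` in each record index into the
    columns of ``m``.
    """
    if grid is None:
        grid = enumerate_param_grid()
    if not grid:
        raise ValueError("parameter grid is empty")
    folds = stratified_folds(m.labels, cv_folds, seed)
    trace = IterationTrace()
    active = np.arange(m.n_voxels, dtype=np.int64)
    iteration = 0
    while True:
        labeling = grid_dbscan(m.coords[active], params)
        retained, keep = size_filter(labeling, params.min_cluster_size)
        active = active[keep]
        if len(active) == 0:
            trace.terminated_empty = True
            break
        iteration += 1
        values = m.values[:, active]
        best_params, metrics = _evaluate_grid(
            values, m.labels, grid, folds, positive_class
        )
        trace.records.append(
            IterationRecord(
                iteration=iteration,
                n_voxels=len(active),
                n_clusters=retained.n_clusters,
                params=best_params,
                metrics=metrics,
                active_columns=active.copy(),
                labeling=retained,
            )
        )
        if len(active) <= R:
            break
        scaled, _ = minmax_scale(values)
        w = linear_rank_weights(scaled, m.labels, C=rank_C)
        survivors = rfe_step(w, R)
        if len(survivors) == 0:
            break
        active = active[survivors]
    return trace


def nested_cross_validate(
    m: SubjectMatrix,
    R: int = 100,
    params: DbscanParams = DbscanParams(),
    grid: list[SvmParams] | None = None,
    outer_folds: int = 10,
    inner_folds: int = 10,
    seed: int = 0,
    rank_C: float = 1.0,
    positive_class: str = "positive",
    apply_ig: bool = True,
) -> MetricsReport:
    """Leakage-free extension: feature selection repeated inside each fold.

    For every outer fold the whole selection pipeline — information-gain
    filtering (unless ``apply_ig=False``), clustering, grid search,
    elimination — runs on the training rows only; the resulting best voxel
    set and parameters classify the held-out rows.  Pooled confusion over
    all held-out predictions.  Folds whose training rows yield no
    informative voxels or no retained cluster fall back to the training
    majority class.
    """
    from .feature_filter import ig_filter  # deferred: avoid an import cycle

    labels = np.asarray(m.labels).astype(str)
    outer = stratified_folds(labels, outer_folds, seed)
    y_pred = np.empty(len(labels), dtype=labels.dtype)
    for f in range(outer.k):
        tr = outer.train_indices(f)
        te = outer.test_indices(f)
        m_train = SubjectMatrix(
            m.values[tr], m.coords, labels[tr], m.subject_ids[tr], m.geometry
        )
        fold_cols = np.arange(m.n_voxels, dtype=np.int64)
        if apply_ig:
            ig = ig_filter(m_train)
            if len(ig.selected) == 0:
                classes, counts = np.unique(labels[tr], return_counts=True)
                y_pred[te] = classes[np.argmax(counts)]
                continue
            fold_cols = ig.selected
            m_train = m_train.subset_columns(fold_cols)
        trace = run_framework(
            m_train,
            R=R,
            params=params,
            grid=grid,
            cv_folds=inner_folds,
            seed=seed + 1,
            rank_C=rank_C,
            positive_class=positive_class,
        )
        if not trace.records:
            # no informative clusters in this fold: majority-class fallback
            classes, counts = np.unique(labels[tr], return_counts=True)
            y_pred[te] = classes[np.argmax(counts)]
            continue
        best = trace.best
        cols = fold_cols[best.active_columns]
        scaled_tr, scaled_te = minmax_scale(m.values[tr][:, cols], m.values[te][:, cols])
        model = train_svm(scaled_tr, labels[tr], best.params)
        y_pred[te] = model.predict(scaled_te)
    return confusion_metrics(labels, y_pred, positive_class)
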