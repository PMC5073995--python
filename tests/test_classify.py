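import numpy as np
import pytest

from voxelsvm import (
    DbscanParams,
    SvmParams,
    enumerate_param_grid,
    linear_rank_weights,
    minmax_scale,
    rfe_step,
    run_framework,
    train_svm,
)
from voxelsvm.classify import WeightVector
from conftest import make_matrix


def oracle_grid_size():
    """Brute-force enumeration of the grid under the relevance rules."""
    total = 0
    for kernel in ("linear", "rbf", "polynomial", "sigmoid"):
        for svm_type in ("C_SVM", "nu_SVM"):
            n = 1
            if kernel == "polynomial":
                n *= 5  # degrees
            if kernel in ("rbf", "polynomial", "sigmoid"):
                n *= 6  # gammas
            if kernel in ("polynomial", "sigmoid"):
                n *= 7  # coef0
            n *= 6 if svm_type == "C_SVM" else 4  # C or nu
            total += n
    return total


class TestParamGrid:
    def test_linear_c_svm_varies_only_c(self):
        grid = enumerate_param_grid(("linear",), ("C_SVM",))
        assert len(grid) == 6
        assert {p.C for p in grid} == {2.0, 4.0, 10.0, 12.0, 15.0, 20.0}
        assert all(p.gamma is None and p.degree is None for p in grid)

    def test_polynomial_c_svm_is_full_product(self):
        grid = enumerate_param_grid(("polynomial",), ("C_SVM",))
        assert len(grid) == 5 * 6 * 7 * 6

    def test_full_grid_size_matches_enumeration_oracle(self):
        assert len(enumerate_param_grid()) == oracle_grid_size() == 2590

    def test_grid_is_deterministic_and_deduplicated(self):
        a = enumerate_param_grid()
        b = enumerate_param_grid()
        assert a == b
        assert len(set(a)) == len(a)


def separable_fixture(rng, n=20):
    x = rng.normal(size=(n, 2))
    y = np.where(x[:, 0] + 0.2 * x[:, 1] > 0, "positive", "control")
    x[y == "positive", 0] += 2.0
    x[y == "control", 0] -= 2.0
    return x, y


class TestTrainSvm:
    def test_linear_separable_is_perfect_on_training_data(self, rng):
        x, y = separable_fixture(rng)
        model = train_svm(x, y, SvmParams(kernel="linear", C=2.0))
        assert (model.predict(x) == y).all()

    def test_label_inversion_inverts_predictions(self, rng):
        x, y = separable_fixture(rng)
        params = SvmParams(kernel="linear", C=2.0)
        pred = train_svm(x, y, params).predict(x)
        flipped = np.where(y == "positive", "control", "positive")
        pred_flipped = train_svm(x, flipped, params).predict(x)
        assert (
            (pred == "positive") == (pred_flipped == "control")
        ).all()

    def test_polynomial_kernel_beats_linear_on_ring_data(self, rng):
        # classes separated by a quadratic boundary: linear provably errs
        x = rng.uniform(-1, 1, size=(60, 2))
        r = (x**2).sum(axis=1)
        y = np.where(r < 0.4, "positive", "control")
        if len(np.unique(y)) < 2:  # pragma: no cover - deterministic guard
            y[0] = "positive"
        lin = train_svm(x, y, SvmParams(kernel="linear", C=15.0))
        poly = train_svm(
            x, y, SvmParams(kernel="polynomial", degree=4, gamma=0.1, coef0=1.0, C=15.0)
        )
        acc_lin = (lin.predict(x) == y).mean()
        acc_poly = (poly.predict(x) == y).mean()
        assert acc_lin < 1.0
        assert acc_poly >= acc_lin

    def test_nu_svm_trains(self, rng):
        x, y = separable_fixture(rng)
        model = train_svm(x, y, SvmParams(kernel="rbf", svm_type="nu_SVM", nu=0.2, gamma=0.1))
        assert set(model.predict(x)) <= {"positive", "control"}

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            train_svm(np.zeros((4, 2)), np.array(["a"] * 4), SvmParams(kernel="linear", C=2.0))


class TestLinearRankWeights:
    def test_informative_column_gets_largest_weight(self, rng):
        n = 30
        y = np.array(["positive"] * 15 + ["control"] * 15)
        x = rng.normal(size=(n, 8)) * 0.1
        x[:, 3] = np.where(y == "positive", 1.0, -1.0) + 0.05 * rng.normal(size=n)
        w = linear_rank_weights(x, y, C=1.0)
        assert np.argmax(np.abs(w.w)) == 3

    def test_duplicated_column_shares_weight(self, rng):
        n = 20
        y = np.array(["positive"] * 10 + ["control"] * 10)
        sig = np.where(y == "positive", 1.0, -1.0) + 0.1 * rng.normal(size=n)
        x = np.column_stack([sig, rng.normal(size=n), sig])
        w = linear_rank_weights(x, y, C=1.0)
        assert abs(w.w[0]) == pytest.approx(abs(w.w[2]), rel=1e-6)

    def test_zero_columns_get_zero_weight(self, rng):
        n = 16
        y = np.array(["positive"] * 8 + ["control"] * 8)
        x = np.zeros((n, 3))
        x[:, 1] = np.where(y == "positive", 1.0, -1.0)
        scaled, _ = minmax_scale(x)
        w = linear_rank_weights(scaled, y, C=1.0)
        assert w.w[0] == 0.0 and w.w[2] == 0.0


class TestRfeStep:
    def test_keeps_largest_magnitudes(self):
        w = WeightVector(np.array([0.9, -0.1, 0.5, 0.05]))
        assert rfe_step(w, 2).tolist() == [0, 2]

    def test_removing_everything_gives_empty_set(self):
        w = WeightVector(np.array([0.3, 0.1]))
        assert rfe_step(w, 2).tolist() == []
        assert rfe_step(w, 5).tolist() == []

    def test_ties_drop_earlier_index_first(self):
        w = WeightVector(np.array([0.5, 0.5, 0.5, 0.5]))
        assert rfe_step(w, 2).tolist() == [2, 3]

    @pytest.mark.parametrize("trial", range(20))
    def test_matches_sort_oracle(self, trial):
        rng = np.random.default_rng(300 + trial)
        n = int(rng.integers(5, 40))
        w = rng.normal(size=n)
        R = int(rng.integers(1, n))
        survivors = rfe_step(WeightVector(w), R)
        order = sorted(range(n), key=lambda j: (abs(w[j]), j))
        expected = sorted(set(range(n)) - set(order[:R]))
        assert survivors.tolist() == expected


def clustered_matrix(rng, n_sub=12, block=None):
    """Matrix whose columns form one compact 5x5x2 voxel block (50 voxels)."""
    if block is None:
        block = [(x, y, z) for x in range(5) for y in range(5) for z in range(2)]
    coords = np.array(block)
    y = np.array(["positive"] * (n_sub // 2) + ["control"] * (n_sub - n_sub // 2))
    values = 0.2 * rng.normal(size=(n_sub, len(coords)))
    signal = np.where(y == "positive", 2.0, -2.0)
    for j in range(5):
        values[:, j] = signal + 0.1 * rng.normal(size=n_sub)
    return make_matrix(values, coords=coords, labels=y)


SMALL_GRID = [SvmParams(kernel="linear", C=c) for c in (2.0, 15.0)]
SMALL_DBSCAN = DbscanParams(min_cluster_size=10)


class TestRunFramework:
    def test_small_start_runs_single_iteration(self, rng):
        m = clustered_matrix(rng)
        trace = run_framework(m, R=100, params=SMALL_DBSCAN, grid=SMALL_GRID, cv_folds=3, seed=0)
        assert len(trace.records) == 1
        assert trace.records[0].n_voxels == 50

    def test_iteration_bound_and_strict_decrease(self, rng):
        # 4x5x10 block = 200 voxels, R = 60 -> at most ceil(200/60)+1 = 5 iters
        block = [(x, y, z) for x in range(4) for y in range(5) for z in range(10)]
        m = clustered_matrix(rng, n_sub=12, block=block)
        trace = run_framework(m, R=60, params=SMALL_DBSCAN, grid=SMALL_GRID, cv_folds=3, seed=0)
        counts = [r.n_voxels for r in trace.records]
        assert len(counts) <= int(np.ceil(200 / 60)) + 1
        assert all(a > b for a, b in zip(counts, counts[1:]))

    def test_every_active_voxel_belongs_to_retained_cluster(self, rng):
        block = [(x, y, z) for x in range(4) for y in range(5) for z in range(10)]
        m = clustered_matrix(rng, n_sub=12, block=block)
        trace = run_framework(m, R=60, params=SMALL_DBSCAN, grid=SMALL_GRID, cv_folds=3, seed=0)
        for r in trace.records:
            assert (r.labeling.cluster_id > 0).all()
            assert min(r.labeling.sizes.values()) >= SMALL_DBSCAN.min_cluster_size
            assert sum(r.labeling.sizes.values()) == r.n_voxels

    def test_scattered_voxels_terminate_empty(self, rng):
        coords = np.array([[0, 0, 0], [10, 10, 10], [20, 20, 20]])
        y = np.array(["positive"] * 3 + ["control"] * 3)
        m = make_matrix(rng.normal(size=(6, 3)), coords=coords, labels=y)
        trace = run_framework(m, params=DbscanParams(), grid=SMALL_GRID, cv_folds=3, seed=0)
        assert trace.terminated_empty
        assert trace.records == []

    def test_trace_reproducible_for_fixed_seed(self, rng):
        block = [(x, y, z) for x in range(4) for y in range(5) for z in range(6)]
        m = clustered_matrix(rng, n_sub=12, block=block)
        t1 = run_framework(m, R=40, params=SMALL_DBSCAN, grid=SMALL_GRID, cv_folds=3, seed=5)
        t2 = run_framework(m, R=40, params=SMALL_DBSCAN, grid=SMALL_GRID, cv_folds=3, seed=5)
        assert [r.n_voxels for r in t1.records] == [r.n_voxels for r in t2.records]
        assert [r.metrics.f_measure for r in t1.records] == [
            r.metrics.f_measure for r in t2.records
        ]
        assert all(
            np.array_equal(a.active_columns, b.active_columns)
            for a, b in zip(t1.records, t2.records)
        )

    def test_perfect_feature_yields_perfect_f(self, rng):
        m = clustered_matrix(rng)
        trace = run_framework(m, params=SMALL_DBSCAN, grid=SMALL_GRID, cv_folds=3, seed=1)
        assert trace.best.metrics.f_measure == pytest.approx(1.0)
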