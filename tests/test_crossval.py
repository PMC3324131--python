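import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from genosl import crossval as cv
from genosl.crossval import (
    CVRiskTable,
    FoldParameterError,
    ONE_MINUS_R,
    SQE,
    cross_validated_risk,
    fold_risks_from_column,
    level_one_column,
    make_folds,
    rank_learners,
    risk,
)

from conftest import make_dataset


class TestMakeFolds:
    def test_equal_singleton_folds(self):
        f = make_folds(10, 10, seed=0)
        sizes = np.bincount(f.fold_index, minlength=10)
        assert (sizes == 1).all()

    def test_102_patients_4_folds(self):
        f = make_folds(102, 4, seed=1)
        sizes = sorted(np.bincount(f.fold_index, minlength=4), reverse=True)
        assert sizes == [26, 26, 25, 25]

    def test_5_patients_2_folds(self):
        f = make_folds(5, 2, seed=2)
        assert sorted(np.bincount(f.fold_index), reverse=True) == [3, 2]

    def test_reproducible(self):
        a = make_folds(50, 3, seed=9)
        b = make_folds(50, 3, seed=9)
        np.testing.assert_array_equal(a.fold_index, b.fold_index)

    @pytest.mark.parametrize("n,k", [(10, 1), (10, 11), (5, 0)])
    def test_invalid_k_rejected(self, n, k):
        with pytest.raises(FoldParameterError):
            make_folds(n, k, seed=0)

    @given(n=st.integers(4, 80), k=st.integers(2, 10), seed=st.integers(0, 1000))
    @settings(max_examples=60, deadline=None)
    def test_partition_property(self, n, k, seed):
        if k > n:
            return
        f = make_folds(n, k, seed)
        sizes = np.bincount(f.fold_index, minlength=k)
        assert sizes.sum() == n
        assert sizes.max() - sizes.min() <= 1


class TestRisk:
    def test_identity_predictions(self):
        y = np.array([0.0, 1.0, 2.0])
        assert risk(SQE, y, y) == 0.0
        assert risk(ONE_MINUS_R, y, y) == pytest.approx(0.0, abs=1e-12)

    def test_sqe_simple(self):
        assert risk(SQE, [0.0, 2.0], [1.0, 1.0]) == 1.0

    def test_anticorrelated_hits_upper_bound(self):
        y = np.array([0.0, 1.0, 3.0])
        assert risk(ONE_MINUS_R, y, -y) == pytest.approx(2.0)

    def test_constant_pred_convention(self, caplog):
        with caplog.at_level("WARNING"):
            val = risk(ONE_MINUS_R, [0.0, 1.0, 2.0], [1.0, 1.0, 1.0])
        assert val == 1.0
        assert "constant" in caplog.text

    @given(
        data=st.lists(
            st.tuples(
                st.floats(-10, 10, allow_nan=False),
                st.floats(-10, 10, allow_nan=False),
            ),
            min_size=3,
            max_size=30,
        ),
        a=st.floats(0.1, 5),
        b=st.floats(-3, 3),
    )
    @settings(max_examples=100, deadline=None)
    def test_one_minus_r_bounds_and_affine_invariance(self, data, a, b):
        y = np.array([d[0] for d in data])
        pred = np.array([d[1] for d in data])
        r = risk(ONE_MINUS_R, y, pred)
        assert -1e-9 <= r <= 2 + 1e-9
        r2 = risk(ONE_MINUS_R, y, a * pred + b)
        assert r2 == pytest.approx(r, abs=1e-7)

    def test_sqe_not_affine_invariant(self):
        y = np.array([0.0, 1.0, 2.0])
        pred = np.array([0.1, 0.9, 2.2])
        assert risk(SQE, y, 2 * pred + 1) != pytest.approx(risk(SQE, y, pred))


class _OracleLearner:
    """Returns the true outcome for any requested rows (cheating on purpose)."""

    def __init__(self, dataset):
        self.dataset = dataset

    def fit(self, dataset, indices):
        return self

    def predict(self, X):
        # match rows of X back to the full design
        full = self.dataset.X
        idx = [int(np.flatnonzero((full == row).all(axis=1))[0]) for row in X]
        return self.dataset.y[idx]


class _MeanLearner:
    def __init__(self, mean):
        self.mean = mean

    def predict(self, X):
        return np.full(len(X), self.mean)


class TestCrossValidatedRisk:
    def _dataset(self, rng, n=40):
        X = (rng.random((n, 3)) < 0.5).astype(int)
        y = 3.0 * rng.normal(size=n)
        return make_dataset(X, y)

    def test_oracle_learner_zero_risk(self, rng):
        # unique rows so the oracle can find them
        n = 32
        X = np.array([[int(c) for c in f"{i:05b}"] for i in range(n)])
        y = rng.normal(size=n)
        ds = make_dataset(X, y)
        oracle = _OracleLearner(ds)
        folds = make_folds(n, 4, seed=0)
        res = cross_validated_risk(oracle.fit, ds, folds, SQE)
        assert res.mean_risk == pytest.approx(0.0, abs=1e-12)
        res_r = cross_validated_risk(oracle.fit, ds, folds, ONE_MINUS_R)
        assert res_r.mean_risk == pytest.approx(0.0, abs=1e-9)

    def test_mean_learner_matches_closed_form(self, rng):
        ds = self._dataset(rng)
        folds = make_folds(ds.n, 5, seed=3)

        def fit(dataset, indices):
            return _MeanLearner(dataset.y[indices].mean())

        res = cross_validated_risk(fit, ds, folds, SQE)
        # independent closed form per split
        expected = []
        for f in range(5):
            tr, va = folds.training_indices(f), folds.validation_indices(f)
            mu = ds.y[tr].mean()
            expected.append(np.mean((ds.y[va] - mu) ** 2))
        np.testing.assert_allclose(res.fold_risks, expected, atol=1e-12)
        assert res.mean_risk == pytest.approx(np.mean(expected))

    def test_mean_equals_average_of_fold_risks(self, rng):
        ds = self._dataset(rng)
        folds = make_folds(ds.n, 4, seed=1)

        def fit(dataset, indices):
            return _MeanLearner(dataset.y[indices].mean())

        res = cross_validated_risk(fit, ds, folds, SQE)
        assert res.mean_risk == pytest.approx(res.fold_risks.mean())

    def test_level_one_column_identical_across_losses(self, rng):
        ds = self._dataset(rng)
        folds = make_folds(ds.n, 4, seed=1)

        def fit(dataset, indices):
            return _MeanLearner(dataset.y[indices].mean())

        col = level_one_column(fit, ds, folds)
        a = fold_risks_from_column(col, ds.y, folds, SQE)
        b = fold_risks_from_column(col, ds.y, folds, ONE_MINUS_R)
        # losses score the same column; only the risks differ
        assert not np.allclose(a, b)
        np.testing.assert_array_equal(col, level_one_column(fit, ds, folds))

    def test_fit_failure_names_fold(self, rng):
        ds = self._dataset(rng)
        folds = make_folds(ds.n, 3, seed=0)

        def fit(dataset, indices):
            raise RuntimeError("boom")

        with pytest.raises(RuntimeError, match="fold 0"):
            cross_validated_risk(fit, ds, folds, SQE)


class TestRankLearners:
    def test_printed_tie_example(self):
        risks = {
            "lm1": 0.216,
            "lm2": 1.218,
            "rf": 0.258,
            "dsa": 0.283,
            "cart": 0.264,
            "sl": 0.216,
        }
        ranks = rank_learners(risks)
        assert ranks == {
            "lm1": 1.5,
            "lm2": 6.0,
            "rf": 3.0,
            "dsa": 5.0,
            "cart": 4.0,
            "sl": 1.5,
        }

    def test_all_equal(self):
        ranks = rank_learners({c: 0.5 for c in "abcd"})
        assert all(r == 2.5 for r in ranks.values())

    def test_strictly_increasing(self):
        ranks = rank_learners({"a": 0.1, "b": 0.2, "c": 0.3})
        assert [ranks[c] for c in "abc"] == [1.0, 2.0, 3.0]

    @given(st.lists(st.floats(0, 10, allow_nan=False), min_size=1, max_size=12))
    @settings(max_examples=100, deadline=None)
    def test_rank_sum_property(self, values):
        ranks = rank_learners({f"l{i}": v for i, v in enumerate(values)})
        L = len(values)
        assert sum(ranks.values()) == pytest.approx(L * (L + 1) / 2)


class TestCVRiskTable:
    def test_table_consistency_and_csv(self, tmp_path):
        fold_risks = {"lm1": np.array([0.2, 0.3]), "cart": np.array([0.4, 0.5])}
        table = CVRiskTable.from_fold_risks(fold_risks, k=2, loss=SQE)
        assert table.ranks["lm1"] == 1.0
        assert table.mean_risks["cart"] == pytest.approx(0.45)
        path = tmp_path / "t.csv"
        table.to_csv(path)
        assert "lm1" in path.read_text()

    def test_inconsistent_mean_rejected(self):
        with pytest.raises(ValueError, match="mean"):
            CVRiskTable(
                learner_names=["a"],
                fold_risks={"a": np.array([0.0, 1.0])},
                mean_risks={"a": 0.9},
                k=2,
                loss=SQE,
            )
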