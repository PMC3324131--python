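import numpy as np
import pytest
from sklearn.tree import DecisionTreeRegressor

from genosl import learners as L
from genosl.learners import (
    BooleanTree,
    PolynomialTerm,
    _anneal,
    _dsa_candidates,
    _dsa_search,
    _eval_node,
    fit_cart,
    fit_dsa,
    fit_fixed_boolean,
    fit_lm_interact,
    fit_lm_main,
    fit_logicreg,
    fit_random_forest,
)
from genosl.synthetic_data import generate_planted_boolean, generate_planted_polynomial

from conftest import make_dataset


class TestLinearModels:
    def test_noiseless_main_effect_recovered(self, rng):
        X = (rng.random((60, 3)) < 0.5).astype(int)
        y = 1.0 + 2.0 * X[:, 0]
        m = fit_lm_main(make_dataset(X, y))
        np.testing.assert_allclose(m.coef[:2], [1.0, 2.0], atol=1e-10)
        np.testing.assert_allclose(m.coef[2:], 0.0, atol=1e-10)

    def test_matches_pseudoinverse_oracle(self, rng):
        # independent normal-equations oracle via pinv
        X = (rng.random((50, 10)) < 0.4).astype(int)
        y = rng.normal(size=50)
        m = fit_lm_main(make_dataset(X, y))
        D = np.column_stack([np.ones(50), X])
        oracle = np.linalg.pinv(D) @ y
        np.testing.assert_allclose(m.coef, oracle, atol=1e-8)

    def test_all_zero_column_contributes_nothing(self, rng):
        X = (rng.random((40, 3)) < 0.5).astype(int)
        X[:, 1] = 0
        y = rng.normal(size=40)
        full = fit_lm_main(make_dataset(X, y))
        dropped = fit_lm_main(make_dataset(X[:, [0, 2]], y))
        np.testing.assert_allclose(
            full.predict(X.astype(float)),
            dropped.predict(X[:, [0, 2]].astype(float)),
            atol=1e-8,
        )

    def test_lm2_parameter_count_p10(self, rng):
        X = (rng.random((102, 10)) < 0.5).astype(int)
        m = fit_lm_interact(make_dataset(X, rng.normal(size=102)))
        assert len(m.coef) == 1 + 10 + 45

    def test_lm2_recovers_pure_interaction(self, rng):
        X = (rng.random((2000, 4)) < 0.5).astype(int)
        y = X[:, 0] * X[:, 1]
        m = fit_lm_interact(make_dataset(X, y))
        pred = m.predict(X.astype(float))
        np.testing.assert_allclose(pred, y, atol=1e-8)

    def test_lm2_rank_deficient_overfits_in_sample(self, rng):
        X = (rng.random((40, 10)) < 0.5).astype(int)
        y = rng.normal(size=40)
        m = fit_lm_interact(make_dataset(X, y))
        resid = y - m.predict(X.astype(float))
        # 56 parameters > 40 observations: interpolation (up to design collinearity)
        assert np.mean(resid**2) < np.var(y) * 0.05


class TestCart:
    def test_cp_one_gives_grand_mean(self, rng):
        X = (rng.random((80, 3)) < 0.5).astype(int)
        y = rng.normal(size=80)
        m = fit_cart(make_dataset(X, y), cp=1.0)
        np.testing.assert_allclose(m.predict(X.astype(float)), y.mean(), atol=1e-10)
        assert m.selected_features == frozenset()

    def test_first_split_and_leaf_means(self, rng):
        X = (rng.random((500, 3)) < 0.5).astype(int)
        y = 1.0 + 3.0 * X[:, 0] + rng.normal(0, 0.1, 500)
        m = fit_cart(make_dataset(X, y), cp=0.05)
        assert "v1" in m.selected_features
        pred = m.predict(X.astype(float))
        for v in (0, 1):
            mask = X[:, 0] == v
            np.testing.assert_allclose(
                pred[mask].mean(), y[mask].mean(), atol=0.05
            )

    def test_default_cp(self):
        assert L.DEFAULT_CP == 0.01

    def test_training_mse_monotone_in_cp(self, rng):
        X = (rng.random((200, 5)) < 0.5).astype(int)
        y = X[:, 0] + 0.5 * X[:, 1] + rng.normal(0, 0.5, 200)
        ds = make_dataset(X, y)
        mses = []
        for cp in (1.0, 0.3, 0.1, 0.03, 0.01, 0.001):
            m = fit_cart(ds, cp=cp)
            mses.append(np.mean((y - m.predict(X.astype(float))) ** 2))
        assert all(a >= b - 1e-12 for a, b in zip(mses, mses[1:]))


class TestRandomForest:
    def test_constant_outcome(self, rng):
        X = (rng.random((50, 4)) < 0.5).astype(int)
        ds = make_dataset(X, np.full(50, 3.25))
        m = fit_random_forest(ds, n_trees=20, seed=1)
        np.testing.assert_allclose(m.predict(X.astype(float)), 3.25, atol=1e-12)

    def test_default_m_try(self):
        assert L.default_m_try(10) == 3
        assert L.default_m_try(2) == 1

    def test_m_try_out_of_range(self, tiny_dataset):
        with pytest.raises(L.LearnerParameterError):
            fit_random_forest(tiny_dataset, n_trees=5, m_try=99)

    def test_seed_variability_shrinks_with_more_trees(self, cohort):
        diffs = {}
        for nt in (50, 1000):
            a = fit_random_forest(cohort, n_trees=nt, seed=1).predict(cohort.X)
            b = fit_random_forest(cohort, n_trees=nt, seed=2).predict(cohort.X)
            diffs[nt] = np.mean(np.abs(a - b))
        assert diffs[1000] < diffs[50]

    def test_single_tree_bridge_to_cart(self, rng):
        # no bootstrap, m_try = p, one tree == one unpruned tree
        X = (rng.random((120, 4)) < 0.5).astype(int)
        y = X[:, 0] + rng.normal(0, 0.4, 120)
        ds = make_dataset(X, y)
        rf = fit_random_forest(ds, n_trees=1, m_try=4, seed=0, bootstrap=False)
        tree = DecisionTreeRegressor(min_samples_leaf=5, random_state=0).fit(X, y)
        np.testing.assert_allclose(
            rf.predict(X.astype(float)), tree.predict(X.astype(float)), atol=1e-12
        )


class TestDSA:
    def test_maxsize_zero_intercept_only(self, tiny_dataset):
        m = fit_dsa(tiny_dataset, maxsize=0)
        np.testing.assert_allclose(
            m.predict(tiny_dataset.X), tiny_dataset.y.mean(), atol=1e-12
        )
        assert m.selected_features == frozenset()

    def test_default_maxsize(self):
        assert L.default_maxsize(10) == 20

    def test_rss_non_increasing_in_size(self, rng):
        X = (rng.random((150, 6)) < 0.5).astype(float)
        y = X[:, 0] + 0.5 * X[:, 1] * X[:, 2] + rng.normal(0, 0.3, 150)
        best = _dsa_search(X, y, maxsize=8, candidates=_dsa_candidates(6, 2, 2))
        sizes = sorted(best)
        rss = [best[s][1] for s in sizes]
        assert all(a >= b - 1e-9 for a, b in zip(rss, rss[1:]))

    def test_recovers_planted_single_term(self):
        term = PolynomialTerm.from_indices([0])
        ds = generate_planted_polynomial(500, [(term, 2.0)], noise_sd=0.1, seed=3)
        m = fit_dsa(ds, seed=3)
        assert m.selected_features == frozenset({"v1"})
        assert [t.indices for t in m.terms] == [(0,)]

    def test_interaction_order_bounded(self, rng):
        cands = _dsa_candidates(5, maxorderint=2, maxsumofpow=2)
        assert max(len(c) for c in cands) == 2
        assert len(cands) == 5 + 10


class TestBooleanTree:
    def test_evaluate_and(self):
        t = BooleanTree.combine("and", BooleanTree.leaf(0), BooleanTree.leaf(2))
        X = np.array([[1, 0, 1], [1, 0, 0], [0, 1, 1], [1, 1, 1]])
        np.testing.assert_array_equal(t.evaluate(X), [1, 0, 0, 1])

    def test_negated_leaf(self):
        t = BooleanTree.leaf(1, negated=True)
        X = np.array([[0, 1], [0, 0]])
        np.testing.assert_array_equal(t.evaluate(X), [0, 1])

    def test_n_leaves_and_variables(self):
        t = BooleanTree.combine(
            "or",
            BooleanTree.combine("and", BooleanTree.leaf(0), BooleanTree.leaf(3)),
            BooleanTree.leaf(0, negated=True),
        )
        assert t.n_leaves == 3
        assert t.variables == frozenset({0, 3})


class TestLogicReg:
    def test_one_leaf_equals_simple_ols(self, rng):
        X = (rng.random((100, 3)) < 0.5).astype(int)
        y = 0.3 + 1.1 * X[:, 0] + rng.normal(0, 0.2, 100)
        ds = make_dataset(X, y)
        m = fit_fixed_boolean(ds, BooleanTree.leaf(0))
        D = np.column_stack([np.ones(100), X[:, 0]])
        b = np.linalg.lstsq(D, y, rcond=None)[0]
        np.testing.assert_allclose([m.b0, m.b1], b, atol=1e-10)
        np.testing.assert_allclose(m.predict(ds.X), D @ b, atol=1e-10)

    def test_anneal_best_by_size_consistent(self, rng):
        X = (rng.random((80, 4)) < 0.5).astype(float)
        y = 1.5 * (X[:, 0] * X[:, 1]) + rng.normal(0, 0.3, 80)
        best = _anneal(X, y, np.random.default_rng(0), max_leaves=4, n_iter=500)
        ybar = y.mean()
        syy = float(((y - ybar) ** 2).sum())
        from genosl.learners import _simple_fit

        for size, (rss, node) in best.items():
            assert sum(1 for _ in _iter_leaves_count(node)) == size
            refit_rss, _, _ = _simple_fit(_eval_node(node, X), y, syy, ybar)
            assert np.isclose(refit_rss, rss)

    def test_deterministic_given_seed(self, rng):
        X = (rng.random((60, 4)) < 0.5).astype(int)
        y = X[:, 0].astype(float) + rng.normal(0, 0.3, 60)
        ds = make_dataset(X, y)
        a = fit_logicreg(ds, n_iter=300, seed=5)
        b = fit_logicreg(ds, n_iter=300, seed=5)
        assert a.tree == b.tree
        np.testing.assert_allclose(a.predict(ds.X), b.predict(ds.X))

    def test_pure_noise_selects_trivial_model(self):
        small = 0
        for seed in range(7):
            rng = np.random.default_rng(100 + seed)
            X = (rng.random((120, 5)) < 0.5).astype(int)
            y = rng.normal(size=120)
            m = fit_logicreg(make_dataset(X, y), n_iter=1000, seed=seed)
            if m.tree.n_leaves <= 1 or abs(m.b1) < 0.2 * y.std():
                small += 1
        assert small >= 4  # majority of seeds

    def test_recovers_planted_and(self):
        rule = BooleanTree.combine("and", BooleanTree.leaf(0), BooleanTree.leaf(2))
        ds = generate_planted_boolean(400, rule, effect=1.5, noise_sd=0.2, seed=11)
        m = fit_logicreg(ds, n_iter=4000, seed=11)
        assert _truth_table_equivalent(m.tree, rule)


def _iter_leaves_count(node):
    from genosl.learners import _iter_leaves

    return _iter_leaves(node)


def _truth_table_equivalent(tree: BooleanTree, target: BooleanTree) -> bool:
    variables = sorted(tree.variables | target.variables)
    p = max(variables) + 1
    # enumerate assignments of the participating variables only
    X = np.zeros((2 ** len(variables), p), dtype=int)
    for col, var in enumerate(variables):
        X[:, var] = [(row >> col) & 1 for row in range(2 ** len(variables))]
    return bool(np.array_equal(tree.evaluate(X), target.evaluate(X)))


class TestContract:
    @pytest.mark.parametrize("name", L.LEARNER_NAMES)
    def test_predict_on_training_data_is_finite(self, name, cohort):
        params = {}
        if name == "rf":
            params = {"n_trees": 30}
        if name == "dsa":
            params = {"maxsize": 3, "inner_folds": 3}
        if name == "logicreg":
            params = {"n_iter": 300, "max_leaves": 4}
        m = L.fit_learner(name, cohort, seed=0, **params)
        pred = m.predict(cohort.X)
        assert np.isfinite(pred).all()
        assert pred.min() > cohort.y.min() - 3 * cohort.y.std()
        assert pred.max() < cohort.y.max() + 3 * cohort.y.std()
        assert m.selected_features <= set(cohort.mutation_labels)

    def test_unknown_learner_rejected(self, tiny_dataset):
        with pytest.raises(L.LearnerParameterError):
            L.fit_learner("boosting", tiny_dataset)

    def test_seed_derivation_stable(self):
        assert L.derive_seed(7, "rf") == L.derive_seed(7, "rf")
        assert L.derive_seed(7, "rf") != L.derive_seed(8, "rf")
        assert L.derive_seed(7, "rf") != L.derive_seed(7, "dsa")
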