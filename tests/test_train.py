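"""Chi-square selection, SVM fitting, bagging, voting, cross-validation."""

import numpy as np
import pytest

from ensloc import train as T
from ensloc.features import FeatureVector


def brute_force_chi2(X, y, n_bins):
    """Independent per-feature contingency chi-square (explicit loops)."""
    n = len(y)
    scores = []
    for j in range(X.shape[1]):
        col = X[:, j]
        qs = [np.quantile(col, q) for q in np.linspace(0, 1, n_bins + 1)[1:-1]]
        edges = sorted(set(qs))
        bins = [sum(1 for e in edges if v > e) for v in col]
        used = sorted(set(bins))
        if len(used) < 2:
            scores.append(0.0)
            continue
        stat = 0.0
        for b in used:
            for label in (0, 1):
                obs = sum(1 for bb, yy in zip(bins, y) if bb == b and yy == label)
                row = sum(1 for bb in bins if bb == b)
                colsum = sum(1 for yy in y if yy == label)
                exp = row * colsum / n
                if exp > 0:
                    stat += (obs - exp) ** 2 / exp
        scores.append(stat)
    return np.array(scores)


def make_ts(Xp, Xn, name="toy"):
    return T.TrainingSet(Xp, Xn, name, "testhash")


class TestChi2:
    def test_identical_feature_scores_zero(self):
        rng = np.random.default_rng(0)
        col = rng.normal(size=50)
        X = np.concatenate([col, col])[:, None]
        y = np.array([1] * 50 + [0] * 50)
        assert T.chi2_scores(X, y)[0] == pytest.approx(0.0, abs=1e-9)

    def test_perfect_binary_separator_scores_n(self):
        # closed-form 2x2 contingency: complete separation gives chi2 = n
        X = np.concatenate([np.ones(50), np.zeros(50)])[:, None]
        y = np.array([1] * 50 + [0] * 50)
        assert T.chi2_scores(X, y)[0] == pytest.approx(100.0)

    def test_constant_feature_never_beats_discriminating_one(self):
        rng = np.random.default_rng(1)
        Xp = np.column_stack([np.full(30, 5.0), rng.normal(2, 1, 30)])
        Xn = np.column_stack([np.full(30, 5.0), rng.normal(-2, 1, 30)])
        sel = T.chi2_select(make_ts(Xp, Xn), k=1)
        assert sel.tolist() == [1]

    def test_ranking_matches_brute_force(self):
        rng = np.random.default_rng(4)
        for trial in range(5):
            n, p = 60, 12
            X = rng.normal(size=(n, p))
            X[:, :4] += rng.normal(0, 2, size=4) * rng.integers(0, 2, size=(n, 4))
            y = rng.integers(0, 2, size=n)
            if len(np.unique(y)) < 2:
                continue
            mine = T.chi2_scores(X, y, 4)
            oracle = brute_force_chi2(X, y, 4)
            np.testing.assert_allclose(mine, oracle, rtol=1e-9, atol=1e-9)

    def test_invalid_args_rejected(self):
        ts = make_ts(np.ones((3, 2)), np.zeros((3, 2)))
        with pytest.raises(ValueError):
            T.chi2_select(ts, k=0)
        with pytest.raises(ValueError):
            T.chi2_select(ts, n_bins=1)


class TestTrainBinary:
    def test_separable_toy_reaches_perfect_accuracy(self):
        rng = np.random.default_rng(2)
        Xp = rng.normal(3, 0.5, size=(20, 2))
        Xn = rng.normal(-3, 0.5, size=(20, 2))
        ts = make_ts(Xp, Xn)
        model = T.train_binary(ts, np.array([0, 1]))
        assert np.mean(model.predict(ts.X) == ts.y) == 1.0

    def test_label_flip_negates_decision_function(self):
        rng = np.random.default_rng(3)
        Xp = rng.normal(1, 1, size=(15, 3))
        Xn = rng.normal(-1, 1, size=(15, 3))
        m1 = T.train_binary(make_ts(Xp, Xn), np.arange(3))
        m2 = T.train_binary(make_ts(Xn, Xp), np.arange(3))
        np.testing.assert_allclose(
            m1.decision(np.vstack([Xp, Xn])),
            -m2.decision(np.vstack([Xp, Xn])),
            rtol=1e-4,
            atol=1e-6,
        )

    def test_single_class_rejected(self):
        class SingleClass(T.TrainingSet):
            @property
            def y(self):
                return np.ones(len(self.X), dtype=int)

        ts = SingleClass(np.ones((4, 2)), np.ones((4, 2)), "x", "h")
        with pytest.raises(ValueError, match="single class"):
            T.train_binary(ts, np.array([0]))

    def test_matches_dual_qp_oracle(self):
        # 20-point toy problem: solve the SVM dual QP independently
        from scipy.optimize import minimize

        rng = np.random.default_rng(5)
        Xp = rng.normal(1.0, 1.0, size=(10, 2))
        Xn = rng.normal(-1.0, 1.0, size=(10, 2))
        ts = make_ts(Xp, Xn)
        C = 1.0
        model = T.train_binary(ts, np.array([0, 1]), cost=C)

        Z = (ts.X[:, :2] - model.mu) / model.sd
        y = np.where(ts.y == 1, 1.0, -1.0)
        Q = (y[:, None] * y[None, :]) * (Z @ Z.T)

        def neg_dual(a):
            return 0.5 * a @ Q @ a - a.sum()

        cons = {"type": "eq", "fun": lambda a: a @ y}
        res = minimize(
            neg_dual,
            np.full(20, 0.01),
            bounds=[(0, C)] * 20,
            constraints=cons,
            method="SLSQP",
            options={"maxiter": 2000, "ftol": 1e-14},
        )
        assert res.success
        alpha = res.x
        w = (alpha * y) @ Z
        sv = (alpha > 1e-6) & (alpha < C - 1e-6)
        b = np.mean(y[sv] - Z[sv] @ w)
        np.testing.assert_allclose(
            model.decision(ts.X), Z @ w + b, atol=1e-4, rtol=0
        )


class TestBagging:
    def _toy_ts(self, n=60, seed=0):
        rng = np.random.default_rng(seed)
        Xp = rng.normal(2, 1, size=(n, 5))
        Xn = rng.normal(-2, 1, size=(n, 5))
        return make_ts(Xp, Xn)

    def test_default_geometry_25_bags_of_1000(self):
        ts = self._toy_ts()
        model = T.train_bagged(ts, seed=1, k_features=3)
        assert len(model.bags) == 25
        assert model.vote_threshold == 13
        assert all(b.trained_on == 1000 for b in model.bags)

    def test_single_bag_degenerates_to_its_model(self):
        ts = self._toy_ts()
        model = T.train_bagged(ts, n_bags=1, seed=2, k_features=3)
        assert model.vote_threshold == 1
        X = ts.X
        np.testing.assert_array_equal(model.predict(X), model.bags[0].predict(X))

    def test_fixed_seed_reproduces_bags_and_votes(self):
        ts = self._toy_ts()
        m1 = T.train_bagged(ts, seed=11, k_features=3)
        m2 = T.train_bagged(ts, seed=11, k_features=3)
        assert m1.bag_seeds == m2.bag_seeds
        for b1, b2 in zip(m1.bags, m2.bags):
            np.testing.assert_array_equal(b1.selected_features, b2.selected_features)
            np.testing.assert_allclose(b1.weights, b2.weights)
        np.testing.assert_array_equal(m1.votes(ts.X), m2.votes(ts.X))

    def test_even_bag_count_breaks_ties_negative(self):
        ts = self._toy_ts()
        model = T.train_bagged(ts, n_bags=4, seed=3, k_features=3)
        assert model.vote_threshold == 3  # floor(4/2)+1

    def test_plurality_vote_matches_counting_oracle(self):
        # stub bags that vote according to a prescribed pattern
        rng = np.random.default_rng(8)
        for _ in range(200):
            pattern = rng.integers(0, 2, size=25).astype(bool)
            bags = [
                T.LinearModel(
                    selected_features=np.array([0]),
                    weights=np.array([0.0]),
                    bias=1.0 if v else -1.0,
                    mu=np.array([0.0]),
                    sd=np.array([1.0]),
                    trained_on=1,
                )
                for v in pattern
            ]
            ens = T.BagEnsemble("stub", bags, vote_threshold=13)
            oracle = sum(pattern) >= 13
            assert bool(ens.predict(np.zeros((1, 1)))[0]) == oracle

    def test_predict_bagged_rejects_registry_mismatch(self):
        ts = self._toy_ts()
        model = T.train_bagged(ts, n_bags=3, seed=5, k_features=2)
        fv = FeatureVector(np.zeros(5), "otherhash")
        with pytest.raises(ValueError, match="registry"):
            T.predict_bagged(model, fv)

    def test_duplicating_positive_support_never_hurts_their_recall(self):
        rng = np.random.default_rng(13)
        Xp = rng.normal(1.2, 1, size=(40, 4))
        Xn = rng.normal(-1.2, 1, size=(40, 4))
        ts = make_ts(Xp, Xn)
        m1 = T.train_bagged(ts, n_bags=5, seed=4, k_features=4, per_class_draw=100)
        base_recall = m1.predict(Xp).mean()
        ts2 = make_ts(np.vstack([Xp, Xp]), Xn)
        m2 = T.train_bagged(ts2, n_bags=5, seed=4, k_features=4, per_class_draw=100)
        assert m2.predict(Xp).mean() >= base_recall - 1e-12


class TestCrossValidate:
    def test_report_formulas(self):
        r = T.CVReport("x", 10, tp=9, fp=0, tn=5, fn=1)
        assert r.recall == pytest.approx(0.9)
        assert r.precision == pytest.approx(1.0)
        assert r.confusion == (9, 0, 5, 1)

    def test_undefined_ratios_reported_absent(self):
        r = T.CVReport("x", 10, tp=0, fp=0, tn=5, fn=0)
        assert r.recall is None and r.precision is None

    def test_too_small_class_rejected_with_minimum(self):
        ts = make_ts(np.random.default_rng(0).normal(size=(5, 2)), np.ones((30, 2)))
        with pytest.raises(ValueError, match=">= 10"):
            T.cross_validate(ts, folds=10)

    def test_separable_problem_cross_validates_cleanly(self):
        rng = np.random.default_rng(21)
        Xp = rng.normal(3, 0.7, size=(40, 4))
        Xn = rng.normal(-3, 0.7, size=(40, 4))
        ts = make_ts(Xp, Xn)
        r = T.cross_validate(ts, folds=5, seed=1, n_bags=3, k_features=2, per_class_draw=50)
        assert r.recall >= 0.95 and r.precision >= 0.95


class TestModelFiles:
    def test_save_load_roundtrip(self, tmp_path):
        rng = np.random.default_rng(17)
        ts = make_ts(rng.normal(1, 1, (30, 4)), rng.normal(-1, 1, (30, 4)))
        model = T.train_bagged(ts, n_bags=3, seed=9, k_features=2, per_class_draw=40)
        path = tmp_path / "model.json"
        T.save_ensemble(model, path)
        loaded = T.load_ensemble(path)
        assert loaded.vote_threshold == model.vote_threshold
        assert loaded.bag_seeds == model.bag_seeds
        X = ts.X
        np.testing.assert_array_equal(loaded.predict(X), model.predict(X))
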