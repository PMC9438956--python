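"""Multinomial model: scoring, weighting, loss, SGD fitting, odds factors."""

import numpy as np
import pytest

from gipredict.mn import (DegenerateClassError, MNModel, TrainingConfig,
                          canonicalize_gauge, class_weights, fit_mn,
                          odds_factor, weighted_cross_entropy)


def _binary_model(intercept, slope):
    return MNModel(("pos", "ref"), "ref",
                   np.array([[intercept, slope]]), ("x",))


class TestPredictProba:
    def test_zero_coefficients_uniform(self):
        m = MNModel(("a", "b", "c"), "c", np.zeros((2, 3)), ("x1", "x2"))
        p = m.predict_proba(np.array([[0.3, -1.2]]))
        assert np.allclose(p, 1 / 3)
        assert p.sum() == pytest.approx(1.0, abs=1e-12)

    def test_intercept_odds_correspondence(self):
        # odds of 2.31 vs reference: p = 2.31 / 3.31
        m = _binary_model(np.log(2.31), 0.0)
        p = m.predict_proba(np.array([[5.0]]))
        assert p[0, 0] == pytest.approx(2.31 / 3.31, abs=1e-9)
        assert p[0, 0] == pytest.approx(0.698, abs=1e-3)

    def test_rows_sum_to_one(self):
        rng = np.random.default_rng(0)
        m = MNModel(("a", "b", "c", "d"), "b", rng.normal(size=(3, 6)),
                    tuple("vwxyz"))
        p = m.predict_proba(rng.normal(size=(50, 5)))
        assert np.allclose(p.sum(axis=1), 1.0, atol=1e-12)
        assert (p > 0).all()

    def test_feature_length_mismatch_rejected(self):
        m = _binary_model(0.0, 1.0)
        with pytest.raises(ValueError):
            m.predict_proba(np.zeros((2, 3)))

    def test_non_finite_features_rejected(self):
        m = _binary_model(0.0, 1.0)
        with pytest.raises(ValueError):
            m.predict_proba(np.array([[np.nan]]))


class TestClassWeights:
    def test_balanced_counts_give_unit_weights(self):
        w = class_weights({"a": 50, "b": 50}, "inverse_frequency")
        assert w == {"a": 1.0, "b": 1.0}
        w4 = class_weights({c: 10 for c in "abcd"}, "inverse_frequency")
        assert all(v == 1.0 for v in w4.values())

    def test_imbalanced_counts(self):
        w = class_weights({"a": 90, "b": 10}, "inverse_frequency")
        assert w["a"] == pytest.approx(100 / 180)
        assert w["b"] == pytest.approx(5.0)

    def test_zero_count_class_raises(self):
        with pytest.raises(DegenerateClassError):
            class_weights({"a": 5, "b": 0}, "inverse_frequency")

    def test_uniform_and_explicit(self):
        assert class_weights({"a": 9, "b": 1}, "uniform") == {"a": 1.0,
                                                             "b": 1.0}
        assert class_weights({"a": 9}, {"a": 2.5}) == {"a": 2.5}


class TestWeightedCrossEntropy:
    def test_perfect_prediction_zero_loss(self):
        probs = np.eye(3)[[0, 1, 2, 1]]
        y = np.array([0, 1, 2, 1])
        assert weighted_cross_entropy(probs, y, np.ones(3)) == pytest.approx(
            0.0, abs=1e-9)

    def test_uniform_three_class(self):
        probs = np.full((10, 3), 1 / 3)
        y = np.zeros(10, dtype=int)
        loss = weighted_cross_entropy(probs, y, np.ones(3))
        assert loss == pytest.approx(np.log(3), abs=1e-12)

    def test_linear_in_weights(self):
        rng = np.random.default_rng(1)
        probs = rng.dirichlet(np.ones(3), size=20)
        y = rng.integers(0, 3, size=20)
        w = rng.uniform(0.5, 2.0, size=3)
        assert weighted_cross_entropy(probs, y, 2 * w) == pytest.approx(
            2 * weighted_cross_entropy(probs, y, w))


class TestOddsFactor:
    @pytest.mark.parametrize("coef,factor", [
        (0.0, 1.0),
        (np.log(2.31), 2.31),
        (1.0, np.e),
    ])
    def test_exponentiation(self, coef, factor):
        assert odds_factor(coef) == pytest.approx(factor, rel=1e-9)


class TestFitMN:
    def test_binary_parameter_recovery(self):
        """Coefficients of a known binary model are recovered at n=20k."""
        rng = np.random.default_rng(11)
        n = 20_000
        x = rng.normal(size=(n, 1))
        logit = -1.0 + 1.5 * x[:, 0]
        p = 1.0 / (1.0 + np.exp(-logit))
        y = np.where(rng.random(n) < p, "pos", "ref")
        cfg = TrainingConfig(seed=2, class_weight_scheme="uniform")
        m = fit_mn(x, y, classes=("pos", "ref"), reference_class="ref",
                   config=cfg)
        assert m.coefficients[0, 0] == pytest.approx(-1.0, abs=0.1)
        assert m.coefficients[0, 1] == pytest.approx(1.5, abs=0.1)

    def test_matches_convex_optimizer_oracle_loss(self):
        """SGD reaches the optimum of a generic convex solver on a toy
        problem (loss agreement to 3 decimals)."""
        from sklearn.linear_model import LogisticRegression

        rng = np.random.default_rng(3)
        X = rng.normal(size=(50, 2))
        y = np.where(X[:, 0] + 0.5 * rng.normal(size=50) > 0, "a", "b")
        cfg = TrainingConfig(seed=0, class_weight_scheme="uniform",
                             l2_penalty=0.0, n_epochs=2000,
                             learning_rate=0.3, lr_decay=0.0,
                             batch_size=50, average_tail=0.0)
        m = fit_mn(X, y, classes=("a", "b"), reference_class="b", config=cfg)
        oracle = LogisticRegression(penalty=None, max_iter=5000).fit(X, y)
        y_idx = (y != "a").astype(int)  # index into classes ("a", "b")
        ours = weighted_cross_entropy(m.predict_proba(X), y_idx, np.ones(2))
        order = [list(oracle.classes_).index(c) for c in ("a", "b")]
        theirs = weighted_cross_entropy(
            oracle.predict_proba(X)[:, order], y_idx, np.ones(2))
        assert ours == pytest.approx(theirs, abs=1e-3)

    def test_two_by_two_contingency_closed_form(self):
        """With one binary feature and no penalty, the slope equals the
        log odds ratio of the 2x2 table."""
        x = np.array([1] * 40 + [0] * 60, dtype=float)[:, None]
        y = np.array(["d"] * 30 + ["v"] * 10 + ["d"] * 15 + ["v"] * 45)
        cfg = TrainingConfig(seed=1, class_weight_scheme="uniform",
                             l2_penalty=0.0, n_epochs=600,
                             learning_rate=0.2)
        m = fit_mn(x, y, classes=("d", "v"), reference_class="v", config=cfg)
        odds_ratio = (30 / 10) / (15 / 45)
        assert m.coefficients[0, 1] == pytest.approx(np.log(odds_ratio),
                                                     abs=0.02)
        assert m.coefficients[0, 0] == pytest.approx(np.log(15 / 45),
                                                     abs=0.02)

    def test_balanced_data_weighting_is_immaterial(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(2000, 2))
        y = np.where(X[:, 0] > 0, "a", "b")  # exactly balanced-ish
        cfg_u = TrainingConfig(seed=5, class_weight_scheme="uniform")
        cfg_i = TrainingConfig(seed=5, class_weight_scheme="inverse_frequency")
        mu = fit_mn(X, y, config=cfg_u)
        mi = fit_mn(X, y, config=cfg_i)
        assert np.allclose(mu.coefficients, mi.coefficients, atol=0.15)

    def test_full_batch_loss_non_increasing(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(200, 2))
        y = np.where(X[:, 0] + X[:, 1] > 0, "a", "b")
        cfg = TrainingConfig(seed=7, learning_rate=0.01, n_epochs=40,
                             batch_size=200, class_weight_scheme="uniform",
                             average_tail=0.0)
        m = fit_mn(X, y, config=cfg, loss_history=True)
        h = np.array(m.training_meta["loss_history"])
        assert np.all(np.diff(h) <= 1e-9)

    def test_single_class_rejected(self):
        with pytest.raises(DegenerateClassError):
            fit_mn(np.zeros((5, 1)), ["a"] * 5)

    def test_reproducible_under_seed(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(300, 3))
        y = np.where(X[:, 0] > 0.2, "a", "b")
        m1 = fit_mn(X, y, config=TrainingConfig(seed=9, n_epochs=20))
        m2 = fit_mn(X, y, config=TrainingConfig(seed=9, n_epochs=20))
        assert np.array_equal(m1.coefficients, m2.coefficients)


class TestModelUtilities:
    def test_json_roundtrip(self, tmp_path):
        m = MNModel(("a", "b", "c"), "c",
                    np.array([[0.1, -2.0, 3.0], [1.0, 0.5, -0.5]]),
                    ("x1", "x2"), {"note": "test"})
        path = tmp_path / "model.json"
        m.to_json(path)
        m2 = MNModel.from_json(path)
        assert m2.classes == m.classes
        assert np.array_equal(m2.coefficients, m.coefficients)
        assert m2.training_meta["note"] == "test"

    def test_gauge_canonicalization_preserves_predictions(self):
        rng = np.random.default_rng(10)
        names = ("lid", "c:AA", "c:AB", "c:BB")
        coef = rng.normal(size=(2, 5))
        m = MNModel(("x", "y", "ref"), "ref", coef, names)
        mc = canonicalize_gauge(m, ["c:AA", "c:AB", "c:BB"])
        # inputs with a valid one-hot combo block
        X = np.zeros((3, 4))
        X[:, 0] = rng.normal(size=3)
        X[[0, 1, 2], [1, 2, 3]] = 1.0
        assert np.allclose(m.predict_proba(X), mc.predict_proba(X),
                           atol=1e-12)
        assert np.allclose(mc.coefficients[:, 4], 0.0)

    def test_odds_factor_table_layout(self):
        m = MNModel(("a", "ref"), "ref", np.array([[np.log(2.0), 1.0]]),
                    ("x",))
        table = m.odds_factors()
        assert table.loc["intercept", "a"] == pytest.approx(2.0)
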