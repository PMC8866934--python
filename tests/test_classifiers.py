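"""Categorical naive Bayes and the uniform train/predict contract."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import ctcstrat as cs
from ctcstrat.classifiers import _bin_value
from ctcstrat.errors import AnalysisError


def nb_oracle_posterior(model, x):
    """Brute-force Bayes rule with the model's own smoothed tables:
    direct products of probabilities, no log space."""
    post = np.exp(model.log_prior).astype(float)
    for name, v in zip(model.feature_names, np.asarray(x, float)):
        cat = _bin_value(v, model.edges[name], model.n_categories(name) - 1)
        post = post * np.exp(model.log_cond[name][cat])
    return post / post.sum()


class TestFitNB:
    def test_hand_computed_smoothed_conditionals(self):
        # one feature, k=2 bins -> edge at the median 0.5; 3 categories with
        # the missing one; alpha=1 Laplace smoothing over n_class=3 rows.
        X = np.array([[0.0], [0.0], [1.0], [1.0], [0.0], [1.0]])
        y = np.array([0, 0, 0, 1, 1, 1], bool)
        model = cs.fit_nb(X, y, k_bins=2, alpha=1.0, feature_names=["f"])
        table = np.exp(model.log_cond["f"])
        # class False saw bins (0,0,1): (2+1)/(3+3), (1+1)/6, (0+1)/6
        assert table[:, 0] == pytest.approx([3 / 6, 2 / 6, 1 / 6])
        # class True saw bins (1,0,1)
        assert table[:, 1] == pytest.approx([2 / 6, 3 / 6, 1 / 6])
        assert np.exp(model.log_prior) == pytest.approx([0.5, 0.5])

    def test_conditional_rows_sum_to_one(self, rng):
        X = rng.normal(size=(20, 3))
        y = rng.random(20) < 0.5
        y[:2], y[-2:] = False, True
        model = cs.fit_nb(X, y)
        for f in model.feature_names:
            assert np.exp(model.log_cond[f]).sum(axis=0) == pytest.approx([1, 1])

    def test_single_class_training_rejected(self):
        with pytest.raises(AnalysisError):
            cs.fit_nb(np.zeros((4, 1)), np.ones(4, bool))

    def test_uninformative_feature_falls_back_to_prior(self):
        X = np.array([[1.0], [2.0]] * 4)
        y = np.array([0] * 6 + [1] * 2, bool)  # 3:1 prior for False
        model = cs.fit_nb(X, y, k_bins=2)
        label, post = cs.predict_nb(model, [1.0])
        assert label is False
        # both classes saw the same bin proportions; up to the smoothing
        # pseudo-counts the posterior is the prior
        assert post == pytest.approx(np.exp(model.log_prior), abs=0.05)


class TestPredictNB:
    def test_empty_feature_set_returns_prior(self):
        model = cs.fit_nb(np.zeros((6, 0)), [0, 0, 0, 0, 1, 1], feature_names=[])
        label, post = cs.predict_nb(model, [])
        assert label is False
        assert post == pytest.approx([4 / 6, 2 / 6])

    def test_symmetric_counts_give_half_half_and_negative_tie_break(self):
        X = np.array([[0.0], [1.0], [0.0], [1.0]])
        y = np.array([0, 0, 1, 1], bool)
        model = cs.fit_nb(X, y, k_bins=2)
        label, post = cs.predict_nb(model, [0.0])
        assert post == pytest.approx([0.5, 0.5])
        assert label is False  # exact posterior tie resolves to the negative class

    def test_posterior_sums_to_one_and_matches_direct_product(self, rng):
        X = rng.normal(size=(15, 4))
        y = np.array([0, 1] * 7 + [0], bool)
        model = cs.fit_nb(X, y)
        for _ in range(20):
            x = rng.normal(size=4)
            label, post = cs.predict_nb(model, x)
            assert post.sum() == pytest.approx(1.0, abs=1e-12)
            assert post == pytest.approx(nb_oracle_posterior(model, x), abs=1e-12)
            assert label == bool(np.argmax(post)) or post[0] == post[1]

    def test_missing_and_out_of_range_values_handled(self, rng):
        X = rng.normal(size=(12, 2))
        y = np.array([0, 1] * 6, bool)
        model = cs.fit_nb(X, y)
        for x in ([np.nan, 0.0], [1e9, -1e9]):
            _, post = cs.predict_nb(model, x)
            assert np.isfinite(post).all()

    def test_feature_order_invariance(self, rng):
        X = pd.DataFrame(rng.normal(size=(14, 3)), columns=["a", "b", "c"])
        y = np.array([0, 1] * 7, bool)
        m1 = cs.fit_nb(X, y)
        m2 = cs.fit_nb(X[["c", "a", "b"]], y)
        x = {"a": 0.3, "b": -1.2, "c": 0.8}
        _, p1 = cs.predict_nb(m1, x)
        _, p2 = cs.predict_nb(m2, x)
        assert p1 == pytest.approx(p2, abs=1e-12)

    def test_monotone_transform_invariance(self, rng):
        X = rng.normal(size=(16, 2))
        y = np.array([0, 1] * 8, bool)
        m1 = cs.fit_nb(X, y)
        m2 = cs.fit_nb(np.exp(X), y)
        x = rng.normal(size=2)
        _, p1 = cs.predict_nb(m1, x)
        _, p2 = cs.predict_nb(m2, np.exp(x))
        assert p1 == pytest.approx(p2, abs=1e-12)

    def test_large_alpha_limit_is_prior_argmax(self, rng):
        X = rng.normal(size=(12, 3))
        y = np.array([0] * 8 + [1] * 4, bool)
        model = cs.fit_nb(X, y, alpha=1e6)
        for _ in range(10):
            label, post = cs.predict_nb(model, rng.normal(size=3))
            assert label is False
            assert post[0] == pytest.approx(8 / 12, abs=1e-3)

    def test_absent_feature_rejected(self, rng):
        model = cs.fit_nb(pd.DataFrame({"a": [0.0, 1, 0, 1]}), [0, 0, 1, 1])
        with pytest.raises(KeyError):
            cs.predict_nb(model, {"b": 1.0})


class TestFitPredictContract:
    X_SEP = np.array([[0.0, 0], [0.5, 1], [1, 0], [9, 1], [9.5, 0], [10, 1],
                      [0.2, 1], [9.8, 0]])
    Y_SEP = np.array([0, 0, 0, 1, 1, 1, 0, 1], bool)

    @pytest.mark.parametrize("family", ["naive_bayes", "logistic_regression",
                                        "decision_tree", "random_forest"])
    def test_linearly_separable_toy(self, family):
        spec = cs.ClassifierSpec(family, {"n_estimators": 25} if family == "random_forest" else {})
        assert fitp(spec, self.X_SEP, self.Y_SEP, [9.2, 0]) is True
        assert fitp(spec, self.X_SEP, self.Y_SEP, [0.4, 1]) is False

    def test_random_forest_deterministic_under_seed(self, rng):
        X = rng.normal(size=(16, 3))
        y = np.array([0, 1] * 8, bool)
        spec = cs.ClassifierSpec("random_forest", {"n_estimators": 15}, seed=42)
        x = rng.normal(size=3)
        assert fitp(spec, X, y, x) == fitp(spec, X, y, x)

    def test_xor_pattern_separates_tree_from_logistic(self, rng):
        base = np.array([[0, 0], [0, 1], [1, 0], [1, 1]], float)
        X = np.vstack([base + rng.normal(0, 0.05, (4, 2)) for _ in range(8)])
        y = np.array([0, 1, 1, 0] * 8, bool)
        probe = np.array([0.0, 1.0])
        tree = fitp(cs.ClassifierSpec("decision_tree"), X, y, probe)
        forest = fitp(cs.ClassifierSpec("random_forest", {"n_estimators": 30}), X, y, probe)
        assert tree is True and forest is True
        # logistic regression cannot represent XOR: it errs on at least one corner
        lr_preds = [fitp(cs.ClassifierSpec("logistic_regression"), X, y, p)
                    for p in base]
        assert lr_preds != [False, True, True, False]

    def test_unknown_family_rejected(self):
        with pytest.raises(ValueError, match="unknown classifier family"):
            cs.ClassifierSpec("svm")

    def test_family_aliases_are_canonical(self):
        assert cs.ClassifierSpec("nb").family == "naive_bayes"
        assert cs.ClassifierSpec("rf").family == "random_forest"


def fitp(spec, X, y, x):
    return cs.fit_predict(spec, X, y, x)
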