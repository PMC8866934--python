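"""Youden-cutoff selection, LOO prediction and contingency metrics."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import ctcstrat as cs
from ctcstrat.errors import AnalysisError
from ctcstrat.singlevar import HIGH, LOW


def brute_force_cutoff(values, target):
    """Exhaustive scan over all midpoints x orientations (independent oracle)."""
    values = np.asarray(values, float)
    target = np.asarray(target, bool)
    distinct = np.unique(values)
    best = None
    for cut in (distinct[:-1] + distinct[1:]) / 2:
        for orient in (HIGH, LOW):
            pred = values > cut if orient == HIGH else values <= cut
            sens = (pred & target).sum() / target.sum()
            spec = (~pred & ~target).sum() / (~target).sum()
            j = sens + spec - 1
            if best is None or j > best[0] + 1e-12:
                best = (j, cut, orient)
    return best


class TestBestCutoff:
    def test_perfect_separation(self):
        r = cs.best_cutoff([1, 2, 3, 4], [0, 0, 1, 1])
        assert (r.cutoff, r.orientation, r.youden_j) == (2.5, HIGH, pytest.approx(1.0))

    def test_reversed_orientation(self):
        r = cs.best_cutoff([1, 2, 3, 4], [1, 1, 0, 0])
        assert (r.cutoff, r.orientation, r.youden_j) == (2.5, LOW, pytest.approx(1.0))

    def test_j_identity_holds(self):
        r = cs.best_cutoff([1, 2, 2, 3, 5, 8], [0, 1, 0, 1, 1, 0])
        assert r.youden_j == pytest.approx(r.sensitivity + r.specificity - 1)

    def test_constant_values_degenerate_with_warning(self):
        with pytest.warns(UserWarning, match="constant"):
            r = cs.best_cutoff([2, 2, 2, 2], [0, 0, 1, 1])
        assert r.youden_j == 0.0

    def test_single_class_target_rejected(self):
        with pytest.raises(AnalysisError):
            cs.best_cutoff([1, 2, 3], [1, 1, 1])

    @given(st.data())
    def test_matches_brute_force_scan(self, data):
        n = data.draw(st.integers(4, 50))
        values = data.draw(st.lists(st.integers(0, 20), min_size=n, max_size=n))
        target = data.draw(st.lists(st.booleans(), min_size=n, max_size=n))
        if all(target) or not any(target) or len(set(values)) < 2:
            return
        r = cs.best_cutoff(np.array(values, float), target)
        j, cut, orient = brute_force_cutoff(values, target)
        assert r.youden_j == pytest.approx(j, abs=1e-12)
        # identical deterministic tie-break: smallest cutoff, then HIGH
        assert r.cutoff == pytest.approx(cut)
        assert r.orientation == orient


class TestContingencyMetrics:
    def test_all_correct_gives_unit_metrics(self):
        m = cs.contingency_metrics([1, 0, 1], [1, 0, 1])
        assert (m.ppv, m.npv, m.sensitivity, m.specificity, m.accuracy) == (
            1.0, 1.0, 1.0, 1.0, 1.0)

    def test_undefined_ratio_flagged_not_zeroed(self):
        m = cs.contingency_metrics([0, 0, 0], [1, 1, 0])
        assert np.isnan(m.ppv)
        assert "ppv" in m.undefined

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            cs.contingency_metrics([1, 0], [1])

    @given(st.tuples(*[st.integers(0, 30)] * 4))
    def test_identities_on_random_tables(self, counts):
        tp, fp, fn, tn = counts
        m = cs.BinaryMetrics(tp=tp, fp=fp, fn=fn, tn=tn)
        if tp + fp:
            assert m.ppv == pytest.approx(tp / (tp + fp))
        if tn + fn:
            assert m.npv == pytest.approx(tn / (tn + fn))
        if tp + fn:
            assert m.sensitivity == pytest.approx(tp / (tp + fn))
        if tn + fp:
            assert m.specificity == pytest.approx(tn / (tn + fp))
        if sum(counts):
            assert m.accuracy == pytest.approx((tp + tn) / sum(counts))


class TestLooSingleVariable:
    def _matrix(self, values, y, extra=None):
        import pandas as pd

        X = pd.DataFrame({"feat": values},
                         index=[f"P{i}" for i in range(len(values))])
        if extra is not None:
            X["noise"] = extra
        return cs.CohortMatrix(X=X, y=np.asarray(y, bool), target="BM",
                               cell_class="eCTC",
                               os_months=np.arange(len(values), dtype=float) + 1,
                               os_event=np.ones(len(values), bool))

    def test_perfectly_separable_feature_predicts_all_correct(self):
        m = self._matrix([1, 2, 3, 10, 11, 12, 1.5, 10.5],
                         [0, 0, 0, 1, 1, 1, 0, 1])
        res = cs.loo_single_variable(m, "feat")
        assert (res.predictions == m.y).all()
        assert res.metrics.accuracy == 1.0

    def test_loo_matches_per_fold_oracle(self, rng):
        values = rng.normal(size=12).round(2)
        y = rng.random(12) < 0.5
        if y.all() or not y.any() or y.sum() < 3 or (~y).sum() < 3:
            y = np.array([0, 1, 0, 1, 0, 1, 0, 1, 0, 1, 0, 1], bool)
        m = self._matrix(values, y)
        res = cs.loo_single_variable(m, "feat")
        for i in range(12):
            mask = np.ones(12, bool)
            mask[i] = False
            j, cut, orient = brute_force_cutoff(values[mask], y[mask])
            pred = values[i] > cut if orient == HIGH else values[i] <= cut
            # oracle tie-breaks may pick a different optimal cutoff; both must
            # achieve the same J on the training fold
            assert res.cutoffs[i].youden_j == pytest.approx(j, abs=1e-12)

    def test_prediction_independent_of_held_out_row(self):
        values = [1, 2, 3, 4, 10, 11, 12, 13]
        y = [0, 0, 0, 0, 1, 1, 1, 1]
        base = cs.loo_single_variable(self._matrix(values, y), "feat")
        # move patient 0 far away: every OTHER fold changes, fold 0 does not
        moved = [200.0] + values[1:]
        res = cs.loo_single_variable(self._matrix(moved, y), "feat")
        assert res.cutoffs[0].cutoff == base.cutoffs[0].cutoff

    def test_uninvolved_feature_permutation_is_inert(self, rng):
        values = list(rng.normal(size=10))
        y = [0, 1] * 5
        noise = rng.normal(size=10)
        a = cs.loo_single_variable(self._matrix(values, y, extra=noise), "feat")
        b = cs.loo_single_variable(
            self._matrix(values, y, extra=rng.permutation(noise)), "feat")
        assert (a.predictions == b.predictions).all()

    def test_too_few_patients_per_level_rejected(self):
        m = self._matrix([1, 2, 3, 4, 5, 6], [1, 1, 1, 1, 0, 0])
        with pytest.raises(AnalysisError, match=">= 3"):
            cs.loo_single_variable(m, "feat")
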