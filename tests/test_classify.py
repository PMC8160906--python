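"""Repeated-holdout random-forest classification, voting, aggregation."""

import numpy as np
import pandas as pd
import pytest

from somnoscreen.classify import (
    ClassifierEval,
    Metrics,
    RepeatedHoldoutForest,
    VotingResult,
    _majority,
    aggregate_configurations,
    blind_test,
    evaluate_model,
    filter_models,
    vote3,
)

def _separable(rng, n_per=30, gap=5.0):
    x = np.concatenate([rng.normal(0, 1, n_per), rng.normal(gap, 1, n_per)])
    y = np.repeat([0, 1], n_per)
    return x, y


class TestMetrics:
    def test_derived_from_confusion(self):
        m = Metrics(tn=40, fp=10, fn=5, tp=45)
        assert m.accuracy == pytest.approx(85 / 100)
        assert m.sensitivity == pytest.approx(45 / 50)
        assert m.specificity == pytest.approx(40 / 50)
        p = 45 / 55
        s = 45 / 50
        assert m.f1 == pytest.approx(2 * p * s / (p + s), abs=1e-15)

    def test_quadruple_recomputable_exactly(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            tn, fp, fn, tp = rng.integers(1, 50, 4)
            m = Metrics(int(tn), int(fp), int(fn), int(tp))
            assert abs(m.accuracy - (tp + tn) / (tn + fp + fn + tp)) < 1e-12
            prec, sens = tp / (tp + fp), tp / (tp + fn)
            assert abs(m.f1 - 2 * prec * sens / (prec + sens)) < 1e-12

    def test_empty_class_metrics_undefined(self):
        m = Metrics(tn=0, fp=0, fn=2, tp=8)
        assert np.isnan(m.specificity)
        assert m.sensitivity == pytest.approx(0.8)


class TestRepeatedHoldout:
    def test_separable_validation_accuracy(self):
        rng = np.random.default_rng(1)
        x, y = _separable(rng)
        clf = evaluate_model(x, y, n_iter=50, seed=0, n_estimators=10)
        assert clf.validation_metrics_.accuracy >= 0.99

    def test_permuted_labels_chance_level(self):
        rng = np.random.default_rng(2)
        x, y = _separable(rng)
        y_perm = rng.permutation(y)
        clf = evaluate_model(x, y_perm, n_iter=300, seed=0, n_estimators=10)
        assert clf.validation_metrics_.accuracy == pytest.approx(0.5, abs=0.1)

    def test_point_duplication_stability(self):
        """Duplicating every training point leaves the frozen ensemble's
        blind-test metrics essentially unchanged.  (Holdout *validation*
        metrics are not comparable: duplicated rows leak across the 65/35
        split and inflate them.)"""
        for seed in (100, 101, 102):
            rng = np.random.default_rng(seed)
            x, y = _separable(rng, gap=3.0)
            c1 = evaluate_model(x, y, n_iter=300, seed=0, n_estimators=10)
            c2 = evaluate_model(np.repeat(x, 2), np.repeat(y, 2), n_iter=300, seed=0, n_estimators=10)
            xt, yt = _separable(rng, n_per=250, gap=3.0)
            m1, m2 = blind_test(c1, xt, yt), blind_test(c2, xt, yt)
            assert abs(m1.accuracy - m2.accuracy) <= 0.02

    def test_blind_test_on_separable(self):
        rng = np.random.default_rng(4)
        x, y = _separable(rng)
        clf = evaluate_model(x, y, n_iter=50, seed=0, n_estimators=10)
        xt, yt = _separable(rng, n_per=15)
        m = blind_test(clf, xt, yt)
        assert m.accuracy >= 0.95

    def test_single_test_subject_metrics_degenerate(self):
        rng = np.random.default_rng(5)
        x, y = _separable(rng)
        clf = evaluate_model(x, y, n_iter=20, seed=0, n_estimators=5)
        m = blind_test(clf, np.array([5.0]), np.array([1]))
        assert m.accuracy in (0.0, 1.0)

    def test_test_order_invariance(self):
        rng = np.random.default_rng(6)
        x, y = _separable(rng)
        clf = evaluate_model(x, y, n_iter=20, seed=0, n_estimators=5)
        xt, yt = _separable(rng, n_per=10)
        m1 = blind_test(clf, xt, yt)
        perm = rng.permutation(xt.size)
        m2 = blind_test(clf, xt[perm], yt[perm])
        assert m1 == m2

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="classes"):
            RepeatedHoldoutForest(n_iter=5).fit(np.arange(10.0).reshape(-1, 1), np.zeros(10, int))

    def test_seed_determinism(self):
        rng = np.random.default_rng(7)
        x, y = _separable(rng, gap=1.5)
        m1 = evaluate_model(x, y, n_iter=30, seed=9, n_estimators=5).validation_metrics_
        m2 = evaluate_model(x, y, n_iter=30, seed=9, n_estimators=5).validation_metrics_
        assert m1 == m2


def _eval_with(val: Metrics, test: Metrics) -> ClassifierEval:
    return ClassifierEval(model=None, classifier=None, validation=val, test=test, n_iterations=10)


class TestFilter:
    def test_below_accuracy_excluded(self):
        m69 = Metrics(tn=34, fp=16, fn=15, tp=35)  # accuracy 0.69
        good = Metrics(tn=40, fp=10, fn=10, tp=40)
        assert filter_models([_eval_with(m69, good)]) == []

    def test_exact_boundaries_included(self):
        # accuracy exactly 0.70, specificity exactly 0.50 (inclusive >=)
        m = Metrics(tn=25, fp=25, fn=5, tp=45)
        assert m.accuracy == pytest.approx(0.70)
        assert m.specificity == pytest.approx(0.50)
        e = _eval_with(m, m)
        assert filter_models([e]) == [e]

    def test_low_sensitivity_excluded(self):
        low_sens = Metrics(tn=60, fp=0, fn=30, tp=20)  # sens 0.4, acc 0.73
        good = Metrics(tn=40, fp=10, fn=10, tp=40)
        assert filter_models([_eval_with(low_sens, good)]) == []

    def test_empty_input(self):
        assert filter_models([]) == []


class TestMajorityRule:
    def test_two_to_one_majority(self):
        votes = pd.DataFrame([[1.0, 1.0, 0.0]])
        assert _majority(votes).iloc[0] == 1.0

    def test_tie_with_abstention_goes_abnormal(self):
        votes = pd.DataFrame([[1.0, 0.0, np.nan]])
        assert _majority(votes).iloc[0] == 1.0

    def test_zero_votes_excluded(self):
        votes = pd.DataFrame([[np.nan, np.nan, np.nan]])
        assert np.isnan(_majority(votes).iloc[0])


class TestVote3:
    def _make_eval(self, feats, y, labels, seed):
        from somnoscreen.modeling import fit_bilinear

        model = fit_bilinear(feats, y, labels, float(y.median()))
        out = model.predict_frame(feats).dropna()
        yb = (y >= y.median()).astype(int)
        clf = evaluate_model(out.to_numpy(), yb.loc[out.index].to_numpy(), n_iter=20, seed=seed,
                             n_estimators=5)
        test_m = blind_test(clf, out.to_numpy(), yb.loc[out.index].to_numpy())
        return ClassifierEval(model=model, classifier=clf, validation=clf.validation_metrics_,
                              test=test_m, n_iterations=20)

    def test_three_identical_perfect_models(self):
        rng = np.random.default_rng(8)
        feats = pd.DataFrame(rng.standard_normal((60, 3)), columns=["F1", "F2", "F3"],
                             index=[f"S{i}" for i in range(60)])
        y = pd.Series(feats["F1"] * 3.0 + 10.0, index=feats.index)  # perfectly predictable
        evals = [self._make_eval(feats, y, ("F1", "F2", "F3"), seed) for seed in (0, 0, 0)]
        yb = (y >= y.median()).astype(int)
        res = vote3(evals, feats, yb, test_ids=list(feats.index[:12]))
        assert res.coverage == 1.0
        assert res.test.accuracy == evals[0].test.accuracy >= 0.9

    def test_fallback_single_model(self):
        rng = np.random.default_rng(9)
        feats = pd.DataFrame(rng.standard_normal((60, 3)), columns=["F1", "F2", "F3"],
                             index=[f"S{i}" for i in range(60)])
        y = pd.Series(feats["F1"] + 0.1 * rng.standard_normal(60), index=feats.index)
        e = self._make_eval(feats, y, ("F1", "F2", "F3"), 0)
        yb = (y >= y.median()).astype(int)
        res = vote3([e], feats, yb, test_ids=list(feats.index[:12]))
        assert res.fallback_single

    def test_no_admissible_models_rejected(self):
        with pytest.raises(ValueError):
            vote3([], pd.DataFrame(), pd.Series(dtype=float), [])


class TestAggregate:
    def _fragment(self, acc):
        tp = int(round(20 * acc))
        m = Metrics(tn=tp, fp=20 - tp, fn=20 - tp, tp=tp)
        return VotingResult(combo_labels=(("F1", "F2", "F3"),), validation=m, test=m, coverage=1.0)

    def test_identical_fragments_mean_equals_fragment(self):
        frags = [self._fragment(0.8)] * 5
        rep = aggregate_configurations("PSG", 1.0, "none", frags)
        assert rep.test_mean["accuracy"] == pytest.approx(0.8)

    def test_arithmetic_mean(self):
        frags = [self._fragment(a) for a in (0.8, 0.9, 0.7, 0.85, 0.75)]
        rep = aggregate_configurations("PSG", 1.0, "none", frags)
        assert rep.test_mean["accuracy"] == pytest.approx(0.80)
        assert rep.test_min["accuracy"] == pytest.approx(0.70)
        assert rep.test_max["accuracy"] == pytest.approx(0.90)

    def test_order_invariance(self):
        frags = [self._fragment(a) for a in (0.8, 0.9, 0.7, 0.85, 0.75)]
        r1 = aggregate_configurations("PSG", 1.0, "none", frags)
        r2 = aggregate_configurations("PSG", 1.0, "none", frags[::-1])
        assert r1.test_mean == r2.test_mean

    def test_exactly_five_required(self):
        with pytest.raises(ValueError, match="5"):
            aggregate_configurations("PSG", 1.0, "none", [self._fragment(0.8)] * 4)
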