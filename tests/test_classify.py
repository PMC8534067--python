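"""Classifier CV protocol, metrics, model selection, permutation test."""

import numpy as np
import pytest

import oculoml.classify as clf
import oculoml.simulate as sim


def separable_data(n=40, seed=0):
    rng = np.random.default_rng(seed)
    x = rng.normal(size=(n, 3))
    y = np.array(["control"] * (n // 2) + ["dyslexic"] * (n // 2))
    x[y == "dyslexic", 0] += 10.0  # one perfectly separating feature
    return x, y


def null_data(n=40, p=5, seed=0):
    rng = np.random.default_rng(seed)
    return rng.normal(size=(n, p)), np.array(
        ["control", "dyslexic"] * (n // 2))


class TestComputeMetrics:
    def test_hand_computed_confusion_table(self):
        m = clf.compute_metrics(clf.ConfusionCounts(tp=3, fn=1, tn=2, fp=2))
        assert m.accuracy == pytest.approx(62.5)
        assert m.sensitivity == pytest.approx(75.0)
        assert m.specificity == pytest.approx(50.0)
        assert m.undefined == ()

    def test_all_correct(self):
        m = clf.compute_metrics(clf.ConfusionCounts(tp=4, fn=0, tn=6, fp=0))
        assert (m.accuracy, m.sensitivity, m.specificity) == (100., 100., 100.)

    def test_all_predicted_positive(self):
        m = clf.compute_metrics(clf.ConfusionCounts(tp=5, fn=0, tn=0, fp=5))
        assert m.sensitivity == pytest.approx(100.0)
        assert m.specificity == pytest.approx(0.0)

    def test_empty_positive_class_flagged_not_zeroed(self):
        m = clf.compute_metrics(clf.ConfusionCounts(tp=0, fn=0, tn=5, fp=1))
        assert np.isnan(m.sensitivity)
        assert "sensitivity" in m.undefined

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            clf.ConfusionCounts(tp=-1, fn=0, tn=1, fp=0)


class TestRunCV:
    def test_separable_data_gives_perfect_linear_accuracy(self):
        x, y = separable_data()
        roster = [s for s in clf.build_roster(0)
                  if s.name in ("logistic_regression", "linear_svm", "lda")]
        evals = clf.run_cv(x, y, roster, k=5, seed=0)
        for e in evals.values():
            assert e.mean_accuracy == pytest.approx(100.0)

    def test_constant_column_causes_no_failure(self):
        x, y = separable_data()
        x = np.hstack([x, np.ones((len(y), 1))])
        roster = [s for s in clf.build_roster(0)
                  if s.name == "logistic_regression"]
        evals = clf.run_cv(x, y, roster, k=5, seed=0)
        assert np.isfinite(evals["logistic_regression"].mean_accuracy)

    def test_fold_metrics_average_to_reported_means(self):
        x, y = null_data(seed=1)
        roster = [s for s in clf.build_roster(0) if s.name == "lda"]
        e = clf.run_cv(x, y, roster, k=5, seed=1)["lda"]
        assert e.mean_accuracy == pytest.approx(
            np.mean([f.metrics.accuracy for f in e.folds]))

    def test_too_few_subjects_per_class_rejected(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=(8, 2))
        y = np.array(["dyslexic"] * 3 + ["control"] * 5)
        roster = [clf.build_roster(0)[0]]
        with pytest.raises(ValueError):
            clf.run_cv(x, y, roster, k=5, seed=0)

    def test_degenerate_fold_single_class_rejected(self):
        x, y = null_data(n=10, seed=3)
        folds = [(np.flatnonzero(y == "control"),
                  np.flatnonzero(y == "dyslexic"))]
        roster = [clf.build_roster(0)[0]]
        with pytest.raises(ValueError, match="degenerate"):
            clf.run_cv(x, y, roster, folds=folds)


class TestLeakageGuard:
    def test_test_fold_labels_never_reach_training(self):
        # mutate every fold's test labels: standardization parameters and
        # fitted models must be bit-identical
        x, y = null_data(n=30, seed=4)
        ybin = (y == "dyslexic").astype(int)
        folds = clf.make_folds(ybin, k=5, seed=4)
        roster = [s for s in clf.build_roster(0)
                  if s.name in ("logistic_regression", "lda")]
        base = clf.run_cv(x, ybin, roster, folds=folds, seed=4)
        for fold_i in range(5):
            y_mut = ybin.copy()
            y_mut[folds[fold_i][1]] = 1 - y_mut[folds[fold_i][1]]
            mut = clf.run_cv(x, y_mut, roster, folds=folds, seed=4)
            for name in base:
                fb = base[name].folds[fold_i]
                fm = mut[name].folds[fold_i]
                np.testing.assert_array_equal(fb.scaler_mean, fm.scaler_mean)
                np.testing.assert_array_equal(fb.scaler_scale, fm.scaler_scale)
                np.testing.assert_array_equal(fb.model_fingerprint,
                                              fm.model_fingerprint)


class TestSelectBest:
    def make_eval(self, name, acc, sens, spec):
        return clf.CVEvaluation(model=name, folds=[], mean_accuracy=acc,
                                mean_sensitivity=sens, mean_specificity=spec,
                                seed=0)

    def test_accuracy_decides_first(self):
        evals = {"a": self.make_eval("a", 80.0, 82.5, 77.5),
                 "b": self.make_eval("b", 71.57, 54.29, 76.67)}
        assert clf.select_best(evals, ["b", "a"]) == "a"

    def test_sensitivity_breaks_accuracy_ties(self):
        evals = {"a": self.make_eval("a", 75.0, 85.0, 60.0),
                 "b": self.make_eval("b", 75.0, 80.0, 90.0)}
        assert clf.select_best(evals, ["b", "a"]) == "a"

    def test_full_tie_resolves_by_roster_order(self):
        evals = {"a": self.make_eval("a", 75.0, 80.0, 70.0),
                 "b": self.make_eval("b", 75.0, 80.0, 70.0)}
        assert clf.select_best(evals, ["b", "a"]) == "b"
        assert clf.select_best(evals, ["a", "b"]) == "a"


class TestPermutationTest:
    @pytest.fixture
    def lr_spec(self):
        return next(s for s in clf.build_roster(0)
                    if s.name == "logistic_regression")

    def test_observed_below_all_permuted_gives_p_one(self, lr_spec):
        x, y = null_data(n=20, seed=5)
        res = clf.permutation_test(x, y, lr_spec, n_permutations=19, seed=5,
                                   observed=0.0)
        assert res.p_value == 1.0

    def test_observed_above_all_permuted_gives_p_zero(self, lr_spec):
        x, y = separable_data(n=30, seed=6)
        res = clf.permutation_test(x, y, lr_spec, n_permutations=19, seed=6)
        assert res.observed_accuracy == pytest.approx(100.0)
        assert res.p_value == 0.0

    def test_bias_corrected_estimator_never_zero(self, lr_spec):
        x, y = separable_data(n=30, seed=7)
        res = clf.permutation_test(x, y, lr_spec, n_permutations=19, seed=7,
                                   bias_corrected=True)
        assert res.p_value == pytest.approx(1 / 20)

    def test_invalid_replicate_count_rejected(self, lr_spec):
        x, y = null_data(seed=8)
        with pytest.raises(ValueError):
            clf.permutation_test(x, y, lr_spec, n_permutations=0)

    def test_deterministic_given_seed(self, lr_spec):
        x, y = null_data(n=16, p=3, seed=9)
        a = clf.permutation_test(x, y, lr_spec, n_permutations=9, seed=11)
        b = clf.permutation_test(x, y, lr_spec, n_permutations=9, seed=11)
        np.testing.assert_array_equal(a.permuted_accuracies,
                                      b.permuted_accuracies)
        assert a.p_value == b.p_value


class TestRosterCompleteness:
    def test_eleven_families_with_explicit_hyperparameters(self):
        roster = clf.build_roster(0)
        assert len(roster) == 11
        assert sum(s.linear for s in roster) == 4
        for s in roster:
            assert s.params, s.name  # every spec records its settings
            model = s.factory(0)
            assert model is not s.factory(0)  # fresh estimator per call

    def test_rbf_kernel_width_is_the_documented_value(self):
        roster = {s.name: s for s in clf.build_roster(0)}
        assert roster["rbf_svm"].params["gamma"] == 0.01
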