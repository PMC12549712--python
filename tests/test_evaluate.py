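"""Statistics oracles: metrics arithmetic, McNemar, robustness area, power."""

import numpy as np
import pytest

from atlaspd.evaluate import (
    RobustnessCurve,
    anova_power,
    anova_sample_size,
    auc_robustness_from_curve,
    cohens_d,
    cohens_f_from_eta2,
    evaluate_classifier,
    mcnemar_test,
    noise_robustness,
)


class _FixedProba:
    """Deterministic predictor stub emitting preset class probabilities."""

    def __init__(self, proba, classes=("HC", "HY1", "HY2")):
        self.proba = np.asarray(proba, dtype=float)
        self.classes_ = np.asarray(classes)

    def predict_proba(self, X):
        return self.proba

    def predict(self, X):
        return self.classes_[self.proba.argmax(axis=1)]


class TestEvaluateClassifier:
    def test_perfect_predictor(self):
        y = np.array(["HC", "HY1", "HY2"] * 6)
        proba = np.zeros((18, 3))
        lut = {"HC": 0, "HY1": 1, "HY2": 2}
        for i, lab in enumerate(y):
            proba[i, lut[lab]] = 1.0
        rep = evaluate_classifier(_FixedProba(proba), np.zeros((18, 1, 1)), y,
                                  bootstrap_n=100, seed=0)
        assert rep.accuracy == 1.0
        assert all(v == 1.0 for v in rep.auc.values())
        assert rep.ci["accuracy"] == (1.0, 1.0)

    def test_hand_computed_confusion_metrics(self):
        """3x3 confusion with known counts: check sensitivity/specificity
        against direct count arithmetic."""
        # actual -> predicted, 12 samples
        y = np.array(["HC"] * 4 + ["HY1"] * 4 + ["HY2"] * 4)
        pred = np.array(["HC", "HC", "HC", "HY1",
                          "HY1", "HY1", "HC", "HY2",
                          "HY2", "HY2", "HY2", "HY2"])
        proba = np.zeros((12, 3))
        lut = {"HC": 0, "HY1": 1, "HY2": 2}
        for i, p in enumerate(pred):
            proba[i, lut[p]] = 1.0
        rep = evaluate_classifier(_FixedProba(proba), np.zeros((12, 1, 1)), y,
                                  bootstrap_n=10, seed=0)
        assert rep.accuracy == pytest.approx(9 / 12)
        assert rep.sensitivity["HC"] == pytest.approx(3 / 4)
        assert rep.sensitivity["HY1"] == pytest.approx(2 / 4)
        assert rep.sensitivity["HY2"] == pytest.approx(4 / 4)
        # specificity HC: of 8 non-HC, predicted HC once -> 7/8
        assert rep.specificity["HC"] == pytest.approx(7 / 8)
        assert rep.confusion.sum(axis=1).tolist() == [4, 4, 4]

    def test_uniform_predictor_auc_half(self):
        rng = np.random.default_rng(0)
        y = np.array(["HC", "HY1", "HY2"] * 40)
        proba = rng.dirichlet(np.ones(3), size=len(y))
        rep = evaluate_classifier(_FixedProba(proba), np.zeros((len(y), 1, 1)),
                                  y, bootstrap_n=10, seed=0)
        for v in rep.auc.values():
            assert v == pytest.approx(0.5, abs=0.12)

    def test_absent_class_auc_missing(self):
        y = np.array(["HC", "HY1"] * 5)
        proba = np.tile([0.5, 0.4, 0.1], (10, 1))
        rep = evaluate_classifier(_FixedProba(proba), np.zeros((10, 1, 1)), y,
                                  bootstrap_n=10, seed=0)
        assert rep.auc["HY2"] is None


class TestMcNemar:
    def test_identical_errors_null(self):
        y = np.array([0, 1, 2, 0, 1, 2])
        p = np.array([0, 1, 1, 0, 1, 2])
        r = mcnemar_test(p, p, y)
        assert r.statistic == 0.0 and r.p_value == 1.0

    def test_corrected_statistic_formula(self):
        """b=10, c=2 with continuity correction: chi2 = 49/12."""
        y = np.zeros(40, dtype=int)
        a = np.zeros(40, dtype=int)
        b = np.zeros(40, dtype=int)
        b[:10] = 1   # A right, B wrong on 10
        a[10:12] = 1  # B right, A wrong on 2
        r = mcnemar_test(a, b, y)
        assert r.b == 10 and r.c == 2
        assert r.statistic == pytest.approx(49 / 12)

    def test_exact_binomial_branch(self):
        """b=2, c=1: two-sided exact p from Binom(3, 1/2) = 1.0."""
        y = np.zeros(10, dtype=int)
        a = np.zeros(10, dtype=int)
        b = np.zeros(10, dtype=int)
        b[:2] = 1
        a[2:3] = 1
        r = mcnemar_test(a, b, y)
        assert r.exact
        assert r.p_value == pytest.approx(1.0)

    def test_matches_statsmodels_asymptotic(self):
        """Independent cross-check of the corrected chi-square statistic."""
        from statsmodels.stats.contingency_tables import mcnemar as sm_mcnemar

        rng = np.random.default_rng(1)
        y = rng.integers(0, 3, 200)
        a = np.where(rng.random(200) < 0.8, y, (y + 1) % 3)
        b = np.where(rng.random(200) < 0.6, y, (y + 2) % 3)
        r = mcnemar_test(a, b, y)
        table = [[0, r.b], [r.c, 0]]
        sm = sm_mcnemar(table, exact=False, correction=True)
        assert r.statistic == pytest.approx(float(sm.statistic))
        if not r.exact:
            assert r.p_value == pytest.approx(float(sm.pvalue))


class TestRobustness:
    def test_trapezoid_oracle_on_hand_curve(self):
        assert auc_robustness_from_curve([0.0, 0.5], [1.0, 0.5]) == pytest.approx(0.75)
        assert auc_robustness_from_curve([0.0, 0.25, 0.5],
                                         [1.0, 1.0, 1.0]) == pytest.approx(1.0)

    def test_sigma_zero_reproduces_clean_accuracy(self, toy_sequences):
        from atlaspd.baselines import BaselineClassifier

        X, y = toy_sequences
        clf = BaselineClassifier("rf", mode="flatten").fit(X, y)
        clean = float((clf.predict(X) == y).mean())
        curve = noise_robustness(clf, X, y, sigmas=(0.0, 0.3), reps=2, seed=0)
        assert curve.accuracy[0] == clean

    def test_constant_prediction_model_flat_curve(self):
        class Constant:
            classes_ = np.asarray(["HC", "HY1", "HY2"])

            def predict_proba(self, X):
                return np.tile([1.0, 0.0, 0.0], (len(X), 1))

        y = np.array(["HC"] * 3 + ["HY1"] * 3 + ["HY2"] * 3)
        X = np.zeros((9, 2, 5))
        curve = noise_robustness(Constant(), X, y, sigmas=(0.0, 0.2, 0.4),
                                 reps=3, seed=0)
        np.testing.assert_allclose(curve.accuracy, 1 / 3)
        assert curve.auc_robustness == pytest.approx(1 / 3)

    def test_grid_must_start_at_zero_and_increase(self):
        with pytest.raises(ValueError):
            RobustnessCurve(np.array([0.1, 0.2]), np.array([1.0, 1.0]),
                            np.array([1.0, 1.0]), 1.0, 1)

    def test_negative_sigma_rejected(self, toy_sequences):
        from atlaspd.baselines import BaselineClassifier

        X, y = toy_sequences
        clf = BaselineClassifier("knn", mode="flatten").fit(X, y)
        with pytest.raises(ValueError):
            noise_robustness(clf, X, y, sigmas=(-0.1, 0.0), reps=1)


class TestEffectSizesAndPower:
    def test_clinical_score_effect_size(self):
        """Motor-score contrast between the two patient stages: pooled-sd
        standardized difference reproduces the reported very large effect."""
        d = cohens_d(11.0, 3.9, 80, 22.7, 4.1, 80)
        assert d == pytest.approx(2.93, abs=0.01)

    def test_cohens_d_trivials(self):
        assert cohens_d(1.0, 1.0, 10, 1.0, 1.0, 10) == 0.0
        assert cohens_d(0.0, 1.0, 10, 1.0, 1.0, 10) == pytest.approx(1.0)

    def test_f_from_eta2(self):
        assert cohens_f_from_eta2(0.205) == pytest.approx(0.508, abs=5e-4)
        assert cohens_f_from_eta2(0.0) == 0.0
        assert cohens_f_from_eta2(0.5) == pytest.approx(1.0)

    def test_a_priori_sample_size_111(self):
        assert anova_sample_size(f=0.30, k=3, alpha=0.05, power=0.80) == 111

    def test_posthoc_power_large_effect(self):
        assert anova_power(f=0.508, k=3, n_total=240, alpha=0.05) > 0.99

    def test_power_increasing_in_n(self):
        powers = [anova_power(0.3, 3, n) for n in range(30, 300, 30)]
        assert all(a < b for a, b in zip(powers, powers[1:]))

    def test_sample_size_power_consistency(self):
        for f in (0.2, 0.3, 0.5):
            n = anova_sample_size(f, k=3, power=0.80)
            assert anova_power(f, 3, n) >= 0.80
            assert anova_power(f, 3, n - 3) < 0.80

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            cohens_f_from_eta2(1.0)
        with pytest.raises(ValueError):
            anova_power(0.0, 3, 100)
        with pytest.raises(ValueError):
            cohens_d(0, 0.0, 5, 1, 1.0, 5)


class TestBootstrapCoverage:
    def test_ci_covers_known_accuracy(self):
        """A Bernoulli(0.8) predictor's 95% bootstrap CI should cover the
        true accuracy in roughly 95% of replicates."""
        rng = np.random.default_rng(42)
        n, true_acc, n_rep = 200, 0.8, 500
        covered = 0
        for _ in range(n_rep):
            correct = rng.random(n) < true_acc
            boots = np.empty(200)
            for j in range(200):
                idx = rng.integers(0, n, n)
                boots[j] = correct[idx].mean()
            lo, hi = np.percentile(boots, [2.5, 97.5])
            covered += lo <= true_acc <= hi
        assert 0.93 * n_rep <= covered <= 0.97 * n_rep
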