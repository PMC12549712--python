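"""Classifier contracts: splits, probability outputs, determinism, search."""

import numpy as np
import pytest

from atlaspd.models import AtlasPDClassifier, LSTMClassifier, ModelSpec, split_dataset
from atlaspd.search import SearchSpace, bayes_search


class TestModelSpec:
    def test_defaults_match_tuned_configuration(self):
        spec = ModelSpec()
        assert (spec.d_model, spec.n_heads, spec.n_transformer_layers) == (128, 4, 2)
        assert spec.learning_rate == pytest.approx(8e-4)
        assert spec.lstm_hidden == (128, 64)
        assert spec.dropout == (0.3, 0.4)
        assert spec.epochs == 120 and spec.l2_lambda == 0.001

    def test_head_divisibility_enforced(self):
        with pytest.raises(ValueError, match="divisible"):
            ModelSpec(d_model=100, n_heads=3)

    def test_dropout_range_enforced(self):
        with pytest.raises(ValueError, match="dropout"):
            ModelSpec(dropout=(0.3, 1.0))


class TestSplitDataset:
    def test_240_balanced_gives_168_36_36(self):
        y = np.repeat(["HC", "HY1", "HY2"], 80)
        tr, va, te = split_dataset(y, seed=42)
        assert (len(tr), len(va), len(te)) == (168, 36, 36)
        assert len(tr) + len(va) == 204  # combined CV pool

    def test_each_split_internally_balanced(self):
        y = np.repeat(["HC", "HY1", "HY2"], 80)
        tr, va, te = split_dataset(y, seed=0)
        for idx, per_class in ((tr, 56), (va, 12), (te, 12)):
            labs, counts = np.unique(y[idx], return_counts=True)
            assert counts.tolist() == [per_class] * 3

    def test_disjoint_and_exhaustive(self):
        y = np.repeat(["HC", "HY1", "HY2"], 20)
        tr, va, te = split_dataset(y, seed=3)
        union = np.concatenate([tr, va, te])
        assert len(union) == len(y)
        assert len(np.unique(union)) == len(y)

    def test_largest_remainder_on_unbalanced_toy(self):
        """Classes of 6 and 4 at (0.7, 0.15, 0.15): hand-enumerated
        largest-remainder allocation gives per-class (4,1,1) and (3,1,0)."""
        y = np.array(["a"] * 6 + ["b"] * 4)
        tr, va, te = split_dataset(y, seed=0, min_class_count=2)
        counts = {s: {lab: int(np.sum(y[idx] == lab)) for lab in ("a", "b")}
                  for s, idx in (("tr", tr), ("va", va), ("te", te))}
        assert counts["tr"] == {"a": 4, "b": 3}
        assert counts["va"] == {"a": 1, "b": 1}
        assert counts["te"] == {"a": 1, "b": 0}

    def test_same_seed_same_split(self):
        y = np.repeat(["HC", "HY1", "HY2"], 10)
        a = split_dataset(y, seed=5)
        b = split_dataset(y, seed=5)
        for i, j in zip(a, b):
            np.testing.assert_array_equal(i, j)

    def test_tiny_class_rejected(self):
        y = np.array(["HC"] * 10 + ["HY1"] * 2)
        with pytest.raises(ValueError, match="fewer than"):
            split_dataset(y)


class TestSequenceClassifiers:
    def test_probabilities_sum_to_one(self, toy_sequences):
        X, y = toy_sequences
        clf = AtlasPDClassifier(d_model=16, n_heads=2, n_transformer_layers=1,
                                lstm_hidden=16, epochs=3, batch_size=12)
        clf.fit(X, y)
        p = clf.predict_proba(X)
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-6)
        assert p.shape == (len(y), 3)
        assert list(clf.classes_) == ["HC", "HY1", "HY2"]

    def test_learns_separable_toy(self, toy_sequences):
        X, y = toy_sequences
        clf = AtlasPDClassifier(d_model=16, n_heads=2, n_transformer_layers=1,
                                lstm_hidden=16, epochs=15, batch_size=12,
                                learning_rate=3e-3)
        clf.fit(X, y)
        assert (clf.predict(X) == y).mean() > 0.9

    def test_lstm_learns_separable_toy(self, toy_sequences):
        X, y = toy_sequences
        clf = LSTMClassifier(hidden=(16, 8), epochs=20, batch_size=12,
                             learning_rate=5e-3)
        clf.fit(X, y)
        assert (clf.predict(X) == y).mean() > 0.9

    def test_repeat_run_identical_history(self, toy_sequences):
        X, y = toy_sequences
        kw = dict(d_model=16, n_heads=2, n_transformer_layers=1, lstm_hidden=16,
                  epochs=4, batch_size=12)
        a = AtlasPDClassifier(**kw).fit(X, y)
        b = AtlasPDClassifier(**kw).fit(X, y)
        np.testing.assert_allclose(a.history_.train_loss, b.history_.train_loss,
                                   rtol=1e-6)
        np.testing.assert_allclose(a.predict_proba(X), b.predict_proba(X),
                                   rtol=1e-5, atol=1e-6)

    def test_checkpoint_equals_history_max(self, toy_sequences):
        X, y = toy_sequences
        clf = AtlasPDClassifier(d_model=16, n_heads=2, n_transformer_layers=1,
                                lstm_hidden=16, epochs=8, batch_size=12)
        clf.fit(X, y)
        assert clf.best_val_accuracy_ == pytest.approx(clf.history_.val_acc.max())

    def test_patience_zero_rejected(self, toy_sequences):
        X, y = toy_sequences
        clf = AtlasPDClassifier(epochs=2, patience=0)
        with pytest.raises(ValueError, match="patience"):
            clf.fit(X, y)

    def test_penultimate_features_shape(self, toy_sequences):
        X, y = toy_sequences
        clf = AtlasPDClassifier(d_model=16, n_heads=2, n_transformer_layers=1,
                                lstm_hidden=12, epochs=2, batch_size=12)
        clf.fit(X, y)
        feats = clf.penultimate_features(X[:5])
        assert feats.shape == (5, 12)


class TestBayesSearch:
    def test_singleton_space_single_evaluation(self):
        space = SearchSpace(transformer_layers=(2, 2), attention_heads=(4, 4),
                            learning_rate=(1e-3, 1e-3), hidden_dims=(128, 128),
                            dropout=(0.3, 0.3))
        calls = []
        cfg, trace = bayes_search(lambda c: calls.append(c) or 1.0, space)
        assert len(calls) == 1
        assert cfg["d_model"] == 128 and cfg["n_heads"] == 4

    def test_finds_quadratic_optimum(self):
        """Known-optimum objective: the incumbent should land near the best
        5% of a dense grid evaluation."""
        space = SearchSpace()

        def objective(cfg):
            lr = np.log10(cfg["learning_rate"])
            return -(lr + 3.0) ** 2 - (cfg["d_model"] - 256) ** 2 / 1e4

        cfg, trace = bayes_search(objective, space, n_iter=25, seed=0)
        rng = np.random.default_rng(1)
        grid = [objective(space.decode(space.sample(rng))) for _ in range(2000)]
        threshold = np.quantile(grid, 0.95)
        assert max(trace.score) >= threshold

    def test_incumbent_non_decreasing(self):
        space = SearchSpace()
        rng = np.random.default_rng(2)
        _, trace = bayes_search(lambda c: rng.random(), space, n_iter=12, seed=3)
        inc = trace.incumbent.to_numpy()
        assert np.all(np.diff(inc) >= 0)

    def test_cv_objective_scores_candidate_config(self, toy_sequences):
        from atlaspd.search import cv_accuracy_objective

        X, y = toy_sequences
        obj = cv_accuracy_objective((X, y), folds=2, seed=0, epochs=2,
                                    base_params={"lstm_hidden": 8,
                                                 "batch_size": 12})
        score = obj({"d_model": 8, "n_heads": 2, "n_transformer_layers": 1,
                     "learning_rate": 2e-3, "dropout_rate": 0.2})
        assert 0.0 <= score <= 1.0

    def test_sampled_configs_respect_divisibility(self):
        space = SearchSpace()
        rng = np.random.default_rng(4)
        for _ in range(50):
            cfg = space.decode(space.sample(rng))
            assert cfg["d_model"] % cfg["n_heads"] == 0
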