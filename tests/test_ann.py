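"""MLP classifier: gradient correctness, training contracts, confidence
rule, LOOCV harness, reporting."""

import numpy as np
import pytest

from painprint.ann import (CVResult, MLPConfig, MLPModel, UNKNOWN,
                           classification_report, fold_seed, loocv,
                           loss_and_grad, predict_with_confidence, train)
from painprint.features import FeatureMatrix


def _toy_separable(n=10, d=2, margin=3.0, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, d))
    X[: n // 2] += margin
    X[n // 2:] -= margin
    y = ["pos"] * (n // 2) + ["neg"] * (n - n // 2)
    return X, y


def _model_from(weights_shapes_seed=0, d=4, h=3, k=2, confidence=0.05):
    rng = np.random.default_rng(weights_shapes_seed)
    return MLPModel(W1=rng.normal(size=(d, h)), b1=rng.normal(size=h),
                    W2=rng.normal(size=(h, k)), b2=rng.normal(size=k),
                    classes=[f"c{j}" for j in range(k)],
                    config=MLPConfig(confidence_level=confidence))


class TestGradient:
    def test_analytic_matches_finite_differences(self, rng):
        """Backprop gradient vs central finite differences on random small
        networks (relative error < 1e-5)."""
        for trial in range(5):
            n, d, h, k = 7, 5, 3, 2
            X = rng.normal(size=(n, d))
            T = np.zeros((n, k))
            T[np.arange(n), rng.integers(0, k, n)] = 1.0
            params = [rng.normal(scale=0.7, size=s)
                      for s in [(d, h), (h,), (h, k), (k,)]]
            _, grads = loss_and_grad(tuple(params), X, T)
            eps = 1e-6
            for p, g in zip(params, grads):
                flat_p = p.ravel()
                for idx in range(0, flat_p.size, max(1, flat_p.size // 5)):
                    orig = flat_p[idx]
                    flat_p[idx] = orig + eps
                    lp, _ = loss_and_grad(tuple(params), X, T)
                    flat_p[idx] = orig - eps
                    lm, _ = loss_and_grad(tuple(params), X, T)
                    flat_p[idx] = orig
                    fd = (lp - lm) / (2 * eps)
                    assert g.ravel()[idx] == pytest.approx(fd, rel=1e-5, abs=1e-9)


class TestTrain:
    def test_separable_toy_reaches_low_rmse_and_full_accuracy(self):
        X, y = _toy_separable()
        model = train(MLPConfig(max_epochs=5_000, seed=3), X, y)
        assert model.history[-1] < 0.1
        out = model.forward(X)
        pred = [model.classes[i] for i in np.argmax(out, axis=1)]
        assert pred == y

    def test_shuffled_labels_generalize_at_chance(self):
        """Permutation control: training on shuffled labels must not
        predict held-out points above chance."""
        rng = np.random.default_rng(5)
        X, y = _toy_separable(n=40, d=2, margin=0.0, seed=5)  # no structure at all
        correct = 0
        total = 0
        for rep in range(5):
            y_shuf = list(rng.permutation(y))
            model = train(MLPConfig(max_epochs=2_000, seed=rep), X[:30], y_shuf[:30])
            out = model.forward(X[30:])
            pred = [model.classes[i] for i in np.argmax(out, axis=1)]
            correct += sum(p == t for p, t in zip(pred, y_shuf[30:]))
            total += 10
        assert 0.25 <= correct / total <= 0.75

    def test_same_seed_identical_weights(self):
        X, y = _toy_separable()
        a = train(MLPConfig(max_epochs=500, seed=11), X, y)
        b = train(MLPConfig(max_epochs=500, seed=11), X, y)
        np.testing.assert_array_equal(a.W1, b.W1)
        np.testing.assert_array_equal(a.W2, b.W2)

    def test_architecture_shapes(self):
        X, y = _toy_separable(d=6)
        m = train(MLPConfig(n_hidden=3, max_epochs=50, seed=0), X, y)
        assert m.W1.shape == (6, 3) and m.b1.shape == (3,)
        assert m.W2.shape == (3, 2) and m.b2.shape == (2,)

    def test_history_eventually_decreasing(self):
        X, y = _toy_separable()
        m = train(MLPConfig(max_epochs=3_000, seed=2), X, y)
        # after the initial transient the running-min envelope keeps falling
        h = m.history
        assert h[-1] < h[len(h) // 4]

    def test_single_class_rejected(self):
        X = np.zeros((5, 2))
        with pytest.raises(ValueError, match="2 classes"):
            train(MLPConfig(max_epochs=10), X, ["a"] * 5)

    def test_outputs_in_unit_interval(self):
        X, y = _toy_separable()
        m = train(MLPConfig(max_epochs=500, seed=0), X, y)
        out = m.forward(np.random.default_rng(0).normal(size=(20, 2)) * 10)
        assert np.all((out > 0) & (out < 1))


class TestConfidenceRule:
    @pytest.mark.parametrize("activations,expected", [
        ((0.98, 0.02), "c0"),
        ((0.60, 0.40), UNKNOWN),
        ((0.97, 0.96), UNKNOWN),     # ambiguous double-accept
    ])
    def test_documented_decisions(self, activations, expected, monkeypatch):
        model = _model_from(d=2, k=2)
        monkeypatch.setattr(MLPModel, "forward",
                            lambda self, x: np.asarray([activations]))
        assert predict_with_confidence(model, np.zeros(2), 0.05) == expected

    def test_reject_rate_monotone_in_confidence_level(self, rng):
        """Raising the confidence level toward 0.5 (looser rule) never
        increases the UNKNOWN count on a fixed model and data."""
        model = _model_from(d=4, k=3)
        X = rng.normal(size=(200, 4)) * 2
        levels = [0.01, 0.05, 0.1, 0.2, 0.3, 0.45]
        unknowns = [sum(predict_with_confidence(model, x, a) == UNKNOWN for x in X)
                    for a in levels]
        assert all(u1 >= u2 for u1, u2 in zip(unknowns, unknowns[1:]))

    def test_dimension_mismatch_rejected(self):
        model = _model_from(d=4)
        with pytest.raises(ValueError, match="expected 4"):
            predict_with_confidence(model, np.zeros(3))


class TestLoocv:
    def _matrix(self, n=12, d=6, margin=4.0, seed=0):
        rng = np.random.default_rng(seed)
        vals = rng.uniform(5, 10, size=(n, d))
        vals[: n // 2, :3] += margin
        labels = ["a"] * (n // 2) + ["b"] * (n - n // 2)
        return FeatureMatrix(vals, [f"mz_{j}.0" for j in range(d)],
                             [f"s{i}" for i in range(n)], labels)

    def test_separable_matrix_fully_recovered(self):
        cv = loocv(self._matrix(margin=6.0), MLPConfig(seed=1))
        assert cv.success_percentage == 100.0

    def test_single_member_class_rejected(self):
        m = FeatureMatrix(np.random.default_rng(0).uniform(0, 9, (3, 2)),
                          ["mz_1.0", "mz_2.0"], ["s0", "s1", "s2"],
                          ["a", "a", "b"])
        with pytest.raises(ValueError, match="single member"):
            loocv(m, MLPConfig(max_epochs=10))

    def test_fold_seeds_deterministic_and_distinct(self):
        seeds = [fold_seed(7, i) for i in range(10)]
        assert seeds == [fold_seed(7, i) for i in range(10)]
        assert len(set(seeds)) == 10
        assert all(0 <= s < 2 ** 31 for s in seeds)

    def test_global_prep_differs_on_leak_sensitive_data(self):
        """A feature whose variance crosses the s^2 > 1 threshold only when
        the held-out sample is included must change the fold's feature set,
        so per-fold and global preprocessing give different results."""
        rng = np.random.default_rng(3)
        n = 12
        vals = rng.uniform(4, 10, size=(n, 5))
        # leak-sensitive column: nearly constant except one extreme sample
        vals[:, 2] = 5.0 + rng.normal(0, 0.05, n)
        vals[0, 2] = 10.0
        labels = ["a"] * 6 + ["b"] * 6
        m = FeatureMatrix(vals, [f"mz_{j}.0" for j in range(5)],
                          [f"s{i}" for i in range(n)], labels)
        cfg = MLPConfig(max_epochs=2_000, seed=9)
        per_fold = loocv(m, cfg, global_prep=False)
        global_ = loocv(m, cfg, global_prep=True)
        assert per_fold.feature_counts != global_.feature_counts

    def test_counts_sum_to_n(self):
        cv = loocv(self._matrix(), MLPConfig(max_epochs=1_000, seed=2))
        tab = cv.confusion()
        assert int(tab.to_numpy().sum()) == cv.n


class TestReport:
    def test_paper_style_rounding(self):
        cv = CVResult(sample_ids=[f"s{i}" for i in range(30)],
                      true_labels=["a"] * 15 + ["b"] * 15,
                      predicted=["a"] * 13 + ["b"] * 2 + ["b"] * 13 + [UNKNOWN, "a"],
                      classes=["a", "b"])
        text, tab = classification_report(cv)
        assert cv.n_correct == 26
        assert "87%" in text                      # 26/30 -> 86.7 -> 87
        assert int(tab.loc["b", UNKNOWN]) == 1

    def test_all_unknown_scores_zero(self):
        cv = CVResult(sample_ids=["s0", "s1"], true_labels=["a", "b"],
                      predicted=[UNKNOWN, UNKNOWN], classes=["a", "b"])
        assert cv.success_percentage == 0.0
        assert cv.n_unknown == 2

    def test_none_correct_scores_zero(self):
        cv = CVResult(sample_ids=["s0", "s1"], true_labels=["a", "b"],
                      predicted=["b", "a"], classes=["a", "b"])
        assert cv.success_percentage == 0.0
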