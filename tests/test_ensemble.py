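import numpy as np
import pandas as pd
import pytest

from cachalot import ensemble as en


def oracle_metrics(y_true, y_pred):
    """Independent brute-force oracle: enumerate the confusion matrix by
    looping over pairs, then apply the textbook formulas."""
    tp = fp = tn = fn = 0
    for t, p in zip(y_true, y_pred):
        if t == 1 and p == 1:
            tp += 1
        elif t == 0 and p == 1:
            fp += 1
        elif t == 0 and p == 0:
            tn += 1
        else:
            fn += 1
    n = tp + fp + tn + fn
    acc = (tp + tn) / n
    sens = tp / (tp + fn)
    spec = tn / (tn + fp)
    prec = tp / (tp + fp) if tp + fp else float("nan")
    f1 = 2 * prec * sens / (prec + sens) if prec == prec and prec + sens else 0.0
    pe = ((tp + fn) * (tp + fp) + (tn + fp) * (tn + fn)) / n**2
    kappa = (acc - pe) / (1 - pe) if pe < 1 else 1.0
    return acc, kappa, sens, spec, sens + spec - 1, f1


def simple_data(n=200, p=4, seed=0, signal=2.5):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, p))
    eta = signal * X[:, 0] - signal * X[:, 1]
    y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(int)
    return pd.DataFrame(X, columns=[f"x{i}" for i in range(p)]), y


class TestMetrics:
    def test_perfect_prediction_all_ones(self):
        m = en.compute_metrics([1, 0, 1, 0], [1, 0, 1, 0])
        assert all(v == 1.0 for v in m.as_dict().values())

    def test_hand_computed_confusion_matrix(self):
        y_true = [1] * 100 + [0] * 100
        y_pred = [1] * 90 + [0] * 10 + [1] * 20 + [0] * 80
        m = en.compute_metrics(y_true, y_pred)
        assert m.accuracy == pytest.approx(0.85)
        assert m.sensitivity == pytest.approx(0.90)
        assert m.specificity == pytest.approx(0.80)
        assert m.tss == pytest.approx(0.70)
        assert m.f1 == pytest.approx(2 * (90 / 110) * 0.9 / ((90 / 110) + 0.9))
        assert m.kappa == pytest.approx(0.70)

    def test_agrees_with_bruteforce_oracle(self, rng):
        for _ in range(200):
            n = int(rng.integers(10, 60))
            y_true = rng.integers(0, 2, n)
            y_pred = rng.integers(0, 2, n)
            if len(np.unique(y_true)) < 2:
                continue
            m = en.compute_metrics(y_true, y_pred)
            exp = oracle_metrics(y_true, y_pred)
            got = [m.accuracy, m.kappa, m.sensitivity, m.specificity, m.tss, m.f1]
            np.testing.assert_allclose(got, exp, atol=1e-12)

    def test_tss_identity_always_holds(self, rng):
        for _ in range(50):
            y_true = rng.integers(0, 2, 40)
            y_pred = rng.integers(0, 2, 40)
            if len(np.unique(y_true)) < 2:
                continue
            m = en.compute_metrics(y_true, y_pred)
            assert m.tss == pytest.approx(m.sensitivity + m.specificity - 1,
                                          abs=1e-12)

    def test_coinflip_kappa_near_zero(self, rng):
        y_true = rng.integers(0, 2, 20000)
        y_pred = rng.integers(0, 2, 20000)
        m = en.compute_metrics(y_true, y_pred)
        assert abs(m.kappa) < 0.03
        assert abs(m.tss) < 0.03

    def test_single_class_truth_warns_nan(self):
        with pytest.warns(UserWarning):
            m = en.compute_metrics([1, 1, 1], [1, 0, 1])
        assert np.isnan(m.specificity)
        with pytest.raises(ValueError):
            en.compute_metrics([], [])


class TestPartitionAndCV:
    def test_split_sizes_stratified_deterministic(self):
        X, y = simple_data(100, seed=1)
        Xtr, Xval, ytr, yval = en.partition_data(X, y, 0.8, seed=4)
        assert len(Xtr) == 80 and len(Xval) == 20
        assert abs(ytr.mean() - yval.mean()) < 0.06
        Xtr2, _, ytr2, _ = en.partition_data(X, y, 0.8, seed=4)
        pd.testing.assert_frame_equal(Xtr, Xtr2)
        with pytest.raises(ValueError):
            en.partition_data(X.head(5), y[:5])

    def test_crossvalidate_fold_count_and_separable_accuracy(self):
        X, y = simple_data(150, seed=2, signal=6.0)
        cv = en.crossvalidate(en.default_registry()["RF"].make(0), X, y,
                              folds=10, repeats=3, seed=0)
        assert len(cv) == 30
        assert cv["accuracy"].mean() >= 0.9

    def test_label_permutation_tss_near_zero(self, rng):
        X, y = simple_data(300, seed=3)
        yperm = rng.permutation(y)
        cv = en.crossvalidate(en.default_registry()["LDA"].make(0), X, yperm,
                              folds=5, repeats=2, seed=0)
        assert abs(cv["tss"].mean()) < 0.15


class TestRegistry:
    def test_fourteen_unique_algorithms(self):
        reg = en.default_registry()
        assert len(reg) == 14
        cats = {s.category for s in reg.values()}
        assert {"Ensemble", "Regression", "Bayesian", "Decision tree",
                "Instance-based", "Dimensionality reduction", "SVM"} == cats

    def test_all_algorithms_beat_chance_on_signal(self):
        X, y = simple_data(250, seed=5, signal=4.0)
        Xtr, Xval, ytr, yval = en.partition_data(X, y, 0.8, seed=0)
        results = en.fit_all_algorithms(Xtr, ytr, Xval, yval, seed=0,
                                        with_cv=False)
        assert len(results) == 14
        tab = en.metrics_table(results)
        assert len(tab) == 14
        assert (tab["accuracy"] > 0.5).all()

    def test_failing_algorithm_isolated(self):
        X, y = simple_data(100, seed=6)
        Xtr, Xval, ytr, yval = en.partition_data(X, y, 0.8, seed=0)
        reg = dict(en.default_registry())

        def broken(seed):
            raise RuntimeError("boom")

        reg["BAD"] = en.AlgorithmSpec("BAD", "Ensemble", broken)
        results = en.fit_all_algorithms(Xtr, ytr, Xval, yval, reg, seed=0,
                                        with_cv=False)
        failures = [r for r in results if r.failed]
        assert len(failures) == 1 and failures[0].algorithm == "BAD"
        assert len(en.metrics_table(results)) == 14


class TestTuning:
    def test_grid_evaluated_ties_to_smallest(self):
        X, y = simple_data(150, seed=7, signal=5.0)
        Xtr, Xval, ytr, yval = en.partition_data(X, y, 0.8, seed=0)
        res = en.tune_random_forest(Xtr, ytr, Xval, yval, mtry_grid=[1, 2, 4],
                                    folds=4, repeats=1, seed=0)
        assert len(res.cv_summary) == 3
        assert res.extra["mtry"] in (1, 2, 4)
        assert res.holdout.accuracy > 0.5

    def test_single_informative_predictor_prefers_small_mtry(self, rng):
        n, p = 400, 9
        X = pd.DataFrame(rng.normal(size=(n, p)),
                         columns=[f"x{i}" for i in range(p)])
        y = (X["x0"] > 0).astype(int).to_numpy()
        Xtr, Xval, ytr, yval = en.partition_data(X, y, 0.8, seed=1)
        res = en.tune_random_forest(Xtr, ytr, Xval, yval, mtry_grid=[1, 3, 9],
                                    folds=4, repeats=1, seed=1)
        assert res.extra["mtry"] <= 3


class TestStacking:
    def test_stack_probabilities_bounded_and_accurate(self):
        X, y = simple_data(200, seed=8, signal=4.0)
        Xtr, Xval, ytr, yval = en.partition_data(X, y, 0.8, seed=0)
        reg = {k: v for k, v in en.default_registry().items()
               if k in ("RF", "LDA", "NB", "KNN")}
        stack = en.stack_models(Xtr, ytr, reg, seed=0, folds=5)
        p = stack.predict_proba(Xval)[:, 1]
        assert ((p >= 0) & (p <= 1)).all()
        m = en.compute_metrics(yval, stack.predict(Xval))
        best_single = max(
            en.metrics_table(en.fit_all_algorithms(
                Xtr, ytr, Xval, yval, reg, seed=0, with_cv=False))["accuracy"])
        assert m.accuracy >= best_single - 0.1

    def test_stack_tracks_a_perfect_base_model(self, rng):
        # one predictor determines the label; the perfect learner is a
        # depth-limited tree, the others see only noise
        n = 300
        X = pd.DataFrame({"sig": rng.normal(size=n),
                          "n1": rng.normal(size=n), "n2": rng.normal(size=n)})
        y = (X["sig"] > 0).astype(int).to_numpy()
        Xtr, Xval, ytr, yval = en.partition_data(X, y, 0.8, seed=2)
        reg = {k: v for k, v in en.default_registry().items()
               if k in ("C5.0", "NB", "KNN")}
        stack = en.stack_models(Xtr, ytr, reg, seed=0, folds=5)
        acc = en.compute_metrics(yval, stack.predict(Xval)).accuracy
        assert acc >= 0.98 - 0.02


class TestComparisonMapsImportance:
    def test_identical_metrics_no_difference(self):
        a = pd.DataFrame({m: np.full(10, 0.9) for m in en.METRIC_NAMES})
        out = en.compare_methods(a, a.copy())
        assert (out["p_value"] == 1.0).all()

    def test_disjoint_support_detected(self, rng):
        a = pd.DataFrame({m: 0.97 + 0.01 * rng.random(10)
                          for m in en.METRIC_NAMES})
        b = pd.DataFrame({m: 0.80 + 0.01 * rng.random(10)
                          for m in en.METRIC_NAMES})
        out = en.compare_methods(a, b, labels=("tuned", "stack"))
        assert (out["p_value"] < 0.05).all()
        assert (out["higher"] == "tuned").all()
        flipped = en.compare_methods(b, a, labels=("stack", "tuned"))
        assert (flipped["higher"] == "tuned").all()
        np.testing.assert_allclose(flipped["p_value"], out["p_value"])

    def test_aggregate_runs_mean_cv_values(self):
        maps = en.aggregate_runs([np.full((2, 2), 0.4), np.full((2, 2), 0.6)])
        np.testing.assert_allclose(maps.mean, 0.5)
        expected_cv = 100 * np.std([0.4, 0.6], ddof=1) / 0.5
        np.testing.assert_allclose(maps.cv_percent, expected_cv)
        assert expected_cv == pytest.approx(28.28, abs=0.01)
        same = en.aggregate_runs([np.ones((2, 2)), np.ones((2, 2))])
        np.testing.assert_allclose(same.cv_percent, 0.0)
        zero = en.aggregate_runs([np.zeros((1, 1)), np.zeros((1, 1))])
        assert np.isnan(zero.cv_percent).all()

    def test_predict_grid_constant_and_bounds(self, env_stack):
        X, y = simple_data(200, seed=9, signal=3.0)
        X.columns = ["sst", "ssh", "u", "v"]
        model = en.default_registry()["RF"].make(0).fit(X.to_numpy(), y)
        layer = en.predict_grid(model, env_stack, ["sst", "ssh", "u", "v"])
        ok = np.isfinite(layer)
        assert ((layer[ok] >= 0) & (layer[ok] <= 1)).all()

    def test_importance_ranks_generative_predictor_first(self):
        X, y = simple_data(400, seed=10, signal=4.0)
        Xtr, Xval, ytr, yval = en.partition_data(X, y, 0.8, seed=0)
        model = en.default_registry()["RF"].make(0).fit(Xtr.to_numpy(), ytr)
        imp = en.variable_importance(model, Xval, yval, list(X.columns), seed=0)
        assert set(imp.index[:2]) == {"x0", "x1"}     # generative pair on top
        assert imp[["x2", "x3"]].abs().max() < 0.05   # noise near zero

    def test_importance_invariant_to_predictor_order(self):
        X, y = simple_data(200, seed=11, signal=4.0)
        Xtr, Xval, ytr, yval = en.partition_data(X, y, 0.8, seed=0)
        model = en.default_registry()["LDA"].make(0).fit(Xtr.to_numpy(), ytr)
        imp = en.variable_importance(model, Xval, yval, list(X.columns), seed=5)
        cols = list(X.columns)[::-1]
        model2 = en.default_registry()["LDA"].make(0).fit(
            Xtr[cols].to_numpy(), ytr)
        imp2 = en.variable_importance(model2, Xval[cols], yval, cols, seed=5)
        assert list(imp.sort_index().index) == list(imp2.sort_index().index)
        np.testing.assert_allclose(imp.sort_index(), imp2.sort_index(),
                                   atol=0.05)
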