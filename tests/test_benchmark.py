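"""Benchmark harness: splits, PLS-LDA, metric formulas, t-test, augmentation runs."""

import dataclasses

import numpy as np
import pytest

from nirgan import (
    PLSLDA,
    ModelSpec,
    SimulatorConfig,
    SpectraDataset,
    SyntheticBatch,
    metrics_from_predictions,
    paired_ttest,
    run_benchmark,
    simulate_dataset,
    stratified_split,
    tune_fit,
)
from nirgan.benchmark import StratificationError, default_model_specs


def brute_force_metrics(truth, predicted, classes):
    """Independent loop-based implementation of the confusion-matrix metrics."""
    n = len(truth)
    acc = sum(1 for t, p in zip(truth, predicted) if t == p) / n
    recalls, precisions, f1s = [], [], []
    for c in classes:
        tp = sum(1 for t, p in zip(truth, predicted) if t == c and p == c)
        fn = sum(1 for t, p in zip(truth, predicted) if t == c and p != c)
        fp = sum(1 for t, p in zip(truth, predicted) if t != c and p == c)
        if tp + fn == 0:
            continue
        rec = tp / (tp + fn)
        prec = tp / (tp + fp) if tp + fp else 0.0
        recalls.append(rec)
        precisions.append(prec)
        f1s.append(2 * prec * rec / (prec + rec) if prec + rec else 0.0)
    p_o = acc
    p_e = sum(
        (sum(1 for t in truth if t == c) / n) * (sum(1 for p in predicted if p == c) / n)
        for c in classes
    )
    kappa = 0.0 if abs(1 - p_e) < 1e-15 else (p_o - p_e) / (1 - p_e)
    return acc, np.mean(recalls), np.mean(precisions), np.mean(f1s), kappa


class TestStratifiedSplit:
    def test_exact_arithmetic_balanced(self):
        ds = simulate_dataset(dataclasses.replace(SimulatorConfig(), n_per_class=10, seed=0))
        split = stratified_split(ds, 0.8, seed=0)
        for lab in ds.classes:
            assert (ds.labels[split.train] == lab).sum() == 8
            assert (ds.labels[split.test] == lab).sum() == 2

    def test_default_dataset_counts(self, default_dataset):
        split = stratified_split(default_dataset, 0.8, seed=1)
        assert split.train.size in (467, 468)
        assert split.train.size + split.test.size == 584
        assert np.intersect1d(split.train, split.test).size == 0

    def test_determinism(self, default_dataset):
        a = stratified_split(default_dataset, 0.8, seed=5)
        b = stratified_split(default_dataset, 0.8, seed=5)
        np.testing.assert_array_equal(a.train, b.train)
        np.testing.assert_array_equal(a.test, b.test)

    def test_tiny_class_rejected(self):
        ds = SpectraDataset(
            X=np.full((5, 3), 0.5),
            wavelengths=np.array([900.0, 1000.0, 1100.0]),
            labels=np.array(["UM", "UM", "HM", "HM", "MS"], dtype=object),
        )
        with pytest.raises(StratificationError):
            stratified_split(ds, 0.8, seed=0)


class TestPlsLda:
    def test_separable_gaussians_perfect_accuracy(self, rng):
        n = 40
        X = np.vstack([rng.normal(0, 0.1, (n, 10)), rng.normal(3, 0.1, (n, 10))])
        y = np.array(["UM"] * n + ["MS"] * n)
        model = PLSLDA(n_components=2).fit(X, y)
        assert (model.predict(X) == y).mean() == 1.0

    def test_first_latent_matches_svd_oracle(self, rng):
        """The first PLS weight vector is the dominant left singular vector of
        X_c^T Y_c."""
        X = rng.normal(size=(60, 8))
        y = np.array((["UM", "HM", "MS"] * 20))
        model = PLSLDA(n_components=3).fit(X, y)
        Y = np.eye(3)[np.unique(y, return_inverse=True)[1]]
        Xc = X - X.mean(axis=0)
        Yc = Y - Y.mean(axis=0)
        u, s, vt = np.linalg.svd(Xc.T @ Yc)
        w1 = model.pls_.x_weights_[:, 0]
        cos = abs(float(w1 @ u[:, 0]) / (np.linalg.norm(w1) * np.linalg.norm(u[:, 0])))
        # NIPALS iterates to its own tolerance, so agreement is ~1e-5, not machine eps
        assert cos == pytest.approx(1.0, abs=1e-5)

    def test_shuffled_labels_near_chance(self, rng):
        ds = simulate_dataset(dataclasses.replace(SimulatorConfig(), n_per_class=50, seed=8))
        y = ds.labels.copy()
        rng.shuffle(y)
        model = PLSLDA(n_components=5).fit(ds.X[:160], y[:160])
        acc = (model.predict(ds.X[160:]) == y[160:]).mean()
        assert 0.1 < acc < 0.45

    def test_excessive_components_rejected(self, rng):
        X = rng.normal(size=(10, 4))
        y = np.array(["UM", "MS"] * 5)
        with pytest.raises(ValueError):
            PLSLDA(n_components=12).fit(X, y)


class TestTuneFit:
    def test_single_point_grid_chosen_and_refit(self, rng):
        X = np.vstack([rng.normal(0, 0.2, (20, 5)), rng.normal(2, 0.2, (20, 5))])
        y = np.array(["UM"] * 20 + ["MS"] * 20)
        spec = ModelSpec("KNN", lambda s: __import__("sklearn.neighbors", fromlist=["KNeighborsClassifier"]).KNeighborsClassifier(), {"n_neighbors": [3]})
        model, params = tune_fit(spec, X, y, cv_folds=5, seed=0)
        assert params == {"n_neighbors": 3}
        assert (model.predict(X) == y).mean() == 1.0

    def test_reasonable_setting_beats_crippled(self):
        ds = simulate_dataset(dataclasses.replace(SimulatorConfig(), n_per_class=40, seed=3))
        from sklearn.ensemble import RandomForestClassifier

        spec = ModelSpec("RF", lambda s: RandomForestClassifier(random_state=s),
                         {"n_estimators": [1, 100]})
        _, params = tune_fit(spec, ds.X, ds.labels, cv_folds=5, seed=0)
        assert params["n_estimators"] == 100

    def test_same_seed_same_selection(self):
        ds = simulate_dataset(dataclasses.replace(SimulatorConfig(), n_per_class=25, seed=3))
        spec = default_model_specs()[2]  # KNN
        _, p1 = tune_fit(spec, ds.X, ds.labels, seed=7)
        _, p2 = tune_fit(spec, ds.X, ds.labels, seed=7)
        assert p1 == p2

    def test_degenerate_folds_rejected(self, rng):
        X = rng.normal(size=(8, 3))
        y = np.array(["UM"] * 6 + ["MS"] * 2)
        with pytest.raises(StratificationError):
            tune_fit(default_model_specs()[2], X, y, cv_folds=5, seed=0)


class TestMetrics:
    def test_perfect_predictions(self):
        y = np.array(["UM", "HM", "MS", "MUS"] * 5)
        rep = metrics_from_predictions(y, y)
        assert rep.accuracy == 1.0 and rep.f1 == 1.0 and rep.kappa == 1.0

    def test_worked_binary_case(self):
        """Confusion [[5,1],[2,4]]: acc 0.75, class-1 P=5/7, R=5/6, F1~0.7692, kappa 0.5."""
        truth = np.array(["A"] * 6 + ["B"] * 6)
        pred = np.array(["A"] * 5 + ["B"] + ["A"] * 2 + ["B"] * 4)
        rep = metrics_from_predictions(truth, pred, classes=["A", "B"])
        np.testing.assert_array_equal(rep.confusion, [[5, 1], [2, 4]])
        assert rep.accuracy == pytest.approx(0.75)
        tp, fn, fp = 5, 1, 2
        assert tp / (tp + fp) == pytest.approx(5 / 7)
        assert tp / (tp + fn) == pytest.approx(5 / 6)
        prec_a, rec_a = 5 / 7, 5 / 6
        f1_a = 2 * prec_a * rec_a / (prec_a + rec_a)
        assert f1_a == pytest.approx(0.76923, abs=1e-4)
        assert rep.kappa == pytest.approx(0.5)

    def test_collapse_to_one_class(self):
        truth = np.array(["UM", "HM", "MS", "MUS"] * 10)
        pred = np.array(["UM"] * 40)
        rep = metrics_from_predictions(truth, pred, classes=["UM", "HM", "MS", "MUS"])
        assert rep.accuracy == pytest.approx(0.25)
        assert rep.kappa == pytest.approx(0.0)

    def test_oracle_equivalence_random_confusions(self, rng):
        classes = ["UM", "HM", "MS", "MUS"]
        for _ in range(200):
            n = int(rng.integers(8, 60))
            truth = rng.choice(classes, size=n)
            pred = rng.choice(classes, size=n)
            if len(set(truth)) < 4:
                continue
            rep = metrics_from_predictions(truth, pred, classes=classes)
            acc, rec, prec, f1, kappa = brute_force_metrics(truth, pred, classes)
            assert rep.accuracy == pytest.approx(acc, abs=1e-12)
            assert rep.recall == pytest.approx(rec, abs=1e-12)
            assert rep.precision == pytest.approx(prec, abs=1e-12)
            assert rep.f1 == pytest.approx(f1, abs=1e-12)
            assert rep.kappa == pytest.approx(kappa, abs=1e-12)

    def test_accuracy_equals_confusion_trace(self, rng):
        classes = ["UM", "HM", "MS", "MUS"]
        truth = rng.choice(classes, size=50)
        pred = rng.choice(classes, size=50)
        rep = metrics_from_predictions(truth, pred, classes=classes)
        assert rep.accuracy == np.trace(rep.confusion) / rep.confusion.sum()

    def test_confusion_row_sums_are_class_counts(self, rng):
        classes = ["UM", "HM", "MS", "MUS"]
        truth = rng.choice(classes, size=80)
        pred = rng.choice(classes, size=80)
        rep = metrics_from_predictions(truth, pred, classes=classes)
        for i, c in enumerate(classes):
            assert rep.confusion[i].sum() == (truth == c).sum()

    def test_absent_class_warns_and_excluded(self):
        truth = np.array(["UM", "HM"] * 5)
        pred = np.array(["UM", "HM"] * 5)
        with pytest.warns(UserWarning, match="MS"):
            rep = metrics_from_predictions(truth, pred, classes=["UM", "HM", "MS"])
        assert rep.recall == 1.0

    def test_auc_macro_matches_sklearn(self, rng):
        from sklearn.metrics import roc_auc_score

        classes = ["UM", "HM", "MS", "MUS"]
        truth = rng.choice(classes, size=100)
        scores = rng.dirichlet(np.ones(4), size=100)
        pred = np.array(classes)[scores.argmax(axis=1)]
        rep = metrics_from_predictions(truth, pred, scores, classes)
        y_idx = np.array([classes.index(t) for t in truth])
        expected = roc_auc_score(y_idx, scores, multi_class="ovr", average="macro",
                                 labels=list(range(4)))
        assert rep.auc == pytest.approx(expected, abs=1e-10)


class TestPairedTtest:
    def test_identical_vectors_convention(self):
        assert paired_ttest([0.9, 0.8, 0.7], [0.9, 0.8, 0.7]) == (0.0, 1.0)

    def test_constant_shift_degenerate(self):
        t, p = paired_ttest([2.0, 3.0, 4.0], [1.0, 2.0, 3.0])
        assert t == np.inf and p == 0.0
        t, p = paired_ttest([1.0, 2.0, 3.0], [2.0, 3.0, 4.0])
        assert t == -np.inf and p == 0.0

    def test_matches_textbook_formula(self, rng):
        a = rng.normal(0.9, 0.05, size=8)
        b = rng.normal(0.85, 0.05, size=8)
        t, p = paired_ttest(a, b)
        d = a - b
        t_hand = d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))
        assert t == pytest.approx(t_hand, rel=1e-10)
        from scipy import stats

        assert p == pytest.approx(2 * stats.t.sf(abs(t_hand), len(d) - 1), rel=1e-10)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            paired_ttest([1.0], [1.0])


@pytest.fixture(scope="module")
def small_dataset():
    return simulate_dataset(dataclasses.replace(SimulatorConfig(), n_per_class=30, seed=6))


class TestRunBenchmark:
    def test_empty_synthetic_is_noop(self, small_dataset):
        """Augmenting with zero rows reproduces the baseline reports exactly."""
        empty = SyntheticBatch(
            spectra=np.empty((0, small_dataset.n_bands)),
            labels=np.array([], dtype=object),
            source_epoch=0,
        )
        specs = [m for m in default_model_specs(small=True) if m.name in ("KNN", "PLS-LDA")]
        res = run_benchmark(small_dataset, empty, seeds=[0, 1], models=specs)
        for seed in (0, 1):
            for name in ("KNN", "PLS-LDA"):
                a = res.reports[(seed, name, "original")]
                b = res.reports[(seed, name, "original+synthetic")]
                assert a.as_dict() == b.as_dict()
        for name in ("KNN", "PLS-LDA"):
            assert res.ttests[name] == (0.0, 1.0)

    def test_report_cardinality(self, small_dataset):
        synth = SyntheticBatch(
            spectra=np.full((8, small_dataset.n_bands), 0.5),
            labels=np.array(["UM", "HM", "MS", "MUS"] * 2, dtype=object),
            source_epoch=1,
        )
        res = run_benchmark(small_dataset, synth, seeds=[0, 1, 2],
                            models=default_model_specs(small=True))
        assert len(res.reports) == 3 * 4 * 2

    def test_feature_mismatch_rejected(self, small_dataset):
        synth = SyntheticBatch(
            spectra=np.full((4, 99), 0.5),
            labels=np.array(["UM", "HM", "MS", "MUS"], dtype=object),
            source_epoch=1,
        )
        with pytest.raises(ValueError, match="bands"):
            run_benchmark(small_dataset, synth, seeds=[0])

    def test_shuffled_labels_chance_level(self, rng):
        """With permuted labels every model hovers at the 25% chance rate."""
        ds = simulate_dataset(dataclasses.replace(SimulatorConfig(), n_per_class=40, seed=9))
        labels = ds.labels.copy()
        rng.shuffle(labels)
        shuffled = SpectraDataset(X=ds.X, wavelengths=ds.wavelengths, labels=labels)
        empty = SyntheticBatch(spectra=np.empty((0, ds.n_bands)),
                               labels=np.array([], dtype=object), source_epoch=0)
        res = run_benchmark(shuffled, empty, seeds=[0, 1, 2],
                            models=default_model_specs(small=True))
        for name in res.model_names:
            acc = res.mean_metric(name, "original")
            assert 0.15 <= acc <= 0.35
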