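"""Baseline-versus-augmented classification benchmark.

The experimental protocol: for each of several random seeds the real dataset
is split 8:2 by stratified sampling without replacement; four classifiers
(SVM, RF, KNN, PLS-LDA) are tuned by stratified 5-fold cross-validation on
the training portion, first on the original training rows alone and then on
the original rows plus all GAN-generated rows; both fits are evaluated on
the same held-out real test set; a paired t-test across seeds decides
whether augmentation changed each model's accuracy.  Synthetic rows never
enter a test set.

Accuracy, macro recall/precision/F1 and Cohen's kappa are computed directly
from the one-vs-rest confusion-matrix counts (TP, FN, FP, TN); AUC is the
macro-averaged one-vs-rest area under the ROC curve.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.cross_decomposition import PLSRegression
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

from .cwgan import SyntheticBatch
from .spectra_sim import SpectraDataset

MODEL_NAMES = ("SVM", "RF", "KNN", "PLS-LDA")


class StratificationError(ValueError):
    """A class is too small for the requested split or folds."""


@dataclass(frozen=True)
class SplitSpec:
    """One stratified train/test partition of the real dataset."""

    seed: int
    train: np.ndarray
    test: np.ndarray
    train_frac: float = 0.8


def stratified_split(dataset: SpectraDataset, train_frac: float = 0.8, seed: int = 0) -> SplitSpec:
    """Per-class sampling without replacement; deterministic given the seed.

    The per-class training count is ``round(n_class * train_frac)``, clipped
    so both sides keep at least one sample.
    """
    if not 0.0 < train_frac < 1.0:
        raise ValueError("train_frac must be in (0, 1)")
    rng = np.random.default_rng(seed)
    train_idx, test_idx = [], []
    for lab in dataset.classes:
        idx = np.flatnonzero(dataset.labels == lab)
        if idx.size < 2:
            raise StratificationError(f"class {lab!r} has {idx.size} sample(s); need >= 2")
        perm = rng.permutation(idx)
        n_train = int(np.clip(round(idx.size * train_frac), 1, idx.size - 1))
        train_idx.append(perm[:n_train])
        test_idx.append(perm[n_train:])
    return SplitSpec(
        seed=seed,
        train=np.sort(np.concatenate(train_idx)),
        test=np.sort(np.concatenate(test_idx)),
        train_frac=train_frac,
    )


class PLSLDA(BaseEstimator, ClassifierMixin):
    """Partial least squares scores followed by linear discriminant analysis.

    PLS2 latent variables are extracted against the one-hot class indicator
    matrix (maximising feature-label covariance); an LDA classifier is then
    fitted on the latent scores.  Posterior estimates come from the LDA.
    """

    def __init__(self, n_components: int = 10):
        self.n_components = n_components

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        if self.n_components > min(X.shape[1], X.shape[0] - 1):
            raise ValueError(
                f"n_components={self.n_components} exceeds min(n_features, n_train - 1)"
            )
        Y = np.eye(len(self.classes_))[y_idx]
        self.pls_ = PLSRegression(n_components=self.n_components, scale=False)
        self.pls_.fit(X, Y)
        self.lda_ = LinearDiscriminantAnalysis()
        self.lda_.fit(self.pls_.transform(X), y)
        return self

    def predict(self, X):
        return self.lda_.predict(self.pls_.transform(np.asarray(X, dtype=float)))

    def predict_proba(self, X):
        return self.lda_.predict_proba(self.pls_.transform(np.asarray(X, dtype=float)))


@dataclass(frozen=True)
class ModelSpec:
    """A named classifier with its hyperparameter grid and a factory."""

    name: str
    make: Callable[[int], BaseEstimator]
    grid: dict

    def __post_init__(self) -> None:
        if self.name not in MODEL_NAMES:
            raise ValueError(f"model name must be one of {MODEL_NAMES}")
        if not self.grid:
            raise ValueError("hyperparameter grid must be non-empty")


def default_model_specs(small: bool = False) -> list[ModelSpec]:
    """The four benchmark classifiers with their documented default grids.

    ``small=True`` trims the grids to one or two points per model for quick
    scarce-data experiments.
    """
    if small:
        grids = {
            "SVM": {"C": [10.0], "gamma": ["scale"]},
            "RF": {"n_estimators": [100]},
            "KNN": {"n_neighbors": [3, 5]},
            "PLS-LDA": {"n_components": [6, 10]},
        }
    else:
        grids = {
            "SVM": {"C": [0.1, 1.0, 10.0, 100.0], "gamma": ["scale", 0.01, 0.001]},
            "RF": {"n_estimators": [100, 300], "max_features": ["sqrt", 0.33]},
            "KNN": {"n_neighbors": [3, 5, 7, 11]},
            "PLS-LDA": {"n_components": list(range(2, 16))},
        }
    return [
        ModelSpec("SVM", lambda s: SVC(kernel="rbf", decision_function_shape="ovr"), grids["SVM"]),
        ModelSpec("RF", lambda s: RandomForestClassifier(random_state=s, n_jobs=1), grids["RF"]),
        ModelSpec("KNN", lambda s: KNeighborsClassifier(), grids["KNN"]),
        ModelSpec("PLS-LDA", lambda s: PLSLDA(), grids["PLS-LDA"]),
    ]


def tune_fit(spec: ModelSpec, X, y, cv_folds: int = 5, seed: int = 0):
    """Grid search by stratified k-fold CV accuracy; ties broken by grid order.

    Returns (refit best estimator, chosen hyperparameters).
    """
    y = np.asarray(y)
    _, counts = np.unique(y, return_counts=True)
    if counts.min() < cv_folds:
        raise StratificationError(
            f"smallest class has {counts.min()} samples; cannot form {cv_folds} stratified folds"
        )
    cv = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    search = GridSearchCV(
        spec.make(seed), spec.grid, scoring="accuracy", cv=cv, refit=True, n_jobs=1
    )
    search.fit(np.asarray(X, dtype=float), y)
    return search.best_estimator_, dict(search.best_params_)


def class_scores(model, X, classes: list) -> np.ndarray:
    """Per-class posterior scores aligned with ``classes``, rows summing to 1.

    Uses ``predict_proba`` when the model provides it; otherwise one-vs-rest
    decision values are mapped through a row-wise softmax (a documented
    monotone transform — ranks, and hence AUC, are preserved).
    """
    X = np.asarray(X, dtype=float)
    try:
        raw = model.predict_proba(X)
    except AttributeError:
        dv = model.decision_function(X)
        if dv.ndim == 1:
            dv = np.column_stack([-dv, dv])
        z = dv - dv.max(axis=1, keepdims=True)
        raw = np.exp(z)
        raw = raw / raw.sum(axis=1, keepdims=True)
    out = np.zeros((X.shape[0], len(classes)))
    col = {c: j for j, c in enumerate(classes)}
    for j_model, c in enumerate(model.classes_):
        out[:, col[c]] = raw[:, j_model]
    return out


@dataclass
class MetricsReport:
    """The benchmark metric suite for one (seed, model, condition) cell."""

    accuracy: float
    recall: float  # macro
    precision: float  # macro
    f1: float  # macro
    auc: float  # macro one-vs-rest; nan when scores are unavailable
    kappa: float
    confusion: np.ndarray  # (n_classes, n_classes), rows = truth
    classes: list = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "recall": self.recall,
            "precision": self.precision,
            "f1": self.f1,
            "auc": self.auc,
            "kappa": self.kappa,
        }


def metrics_from_predictions(
    truth, predicted, class_scores: np.ndarray | None = None, classes: list | None = None
) -> MetricsReport:
    """Metric suite from one-vs-rest confusion-matrix counts.

    Acc = (TP+TN)/(TP+FN+FP+TN) over all samples; per-class
    Recall = TP/(TP+FN), Precision = TP/(TP+FP),
    F1 = 2*Precision*Recall/(Precision+Recall), macro-averaged; Cohen's
    kappa = (p_o - p_e)/(1 - p_e) with p_e from the marginal products.  A
    class absent from the truth is excluded from the macro averages with a
    warning.
    """
    truth = np.asarray(truth)
    predicted = np.asarray(predicted)
    if truth.shape != predicted.shape:
        raise ValueError("truth and predictions must have equal length")
    if classes is None:
        classes = sorted(set(truth) | set(predicted))
    k = len(classes)
    idx = {c: i for i, c in enumerate(classes)}
    confusion = np.zeros((k, k), dtype=int)
    for t, p in zip(truth, predicted):
        confusion[idx[t], idx[p]] += 1
    total = confusion.sum()
    accuracy = float(np.trace(confusion) / total)

    recalls, precisions, f1s = [], [], []
    for i in range(k):
        tp = confusion[i, i]
        fn = confusion[i].sum() - tp
        fp = confusion[:, i].sum() - tp
        if tp + fn == 0:
            warnings.warn(
                f"class {classes[i]!r} absent from the truth; excluded from macro averages",
                stacklevel=2,
            )
            continue
        rec = tp / (tp + fn)
        prec = tp / (tp + fp) if tp + fp > 0 else 0.0
        f1 = 2 * prec * rec / (prec + rec) if prec + rec > 0 else 0.0
        recalls.append(rec)
        precisions.append(prec)
        f1s.append(f1)

    p_o = accuracy
    p_e = float((confusion.sum(axis=1) * confusion.sum(axis=0)).sum() / total**2)
    kappa = 0.0 if np.isclose(p_e, 1.0) else float((p_o - p_e) / (1.0 - p_e))

    auc = float("nan")
    if class_scores is not None:
        class_scores = np.asarray(class_scores, dtype=float)
        if np.abs(class_scores.sum(axis=1) - 1.0).max() > 1e-6:
            raise ValueError("class score rows must sum to 1")
        aucs = []
        for i, c in enumerate(classes):
            y_bin = (truth == c).astype(int)
            if 0 < y_bin.sum() < len(y_bin):
                aucs.append(roc_auc_score(y_bin, class_scores[:, i]))
        if aucs:
            auc = float(np.mean(aucs))

    return MetricsReport(
        accuracy=accuracy,
        recall=float(np.mean(recalls)),
        precision=float(np.mean(precisions)),
        f1=float(np.mean(f1s)),
        auc=auc,
        kappa=kappa,
        confusion=confusion,
        classes=list(classes),
    )


def paired_ttest(metric_a, metric_b) -> tuple[float, float]:
    """Two-sided paired t-test on the per-seed differences a - b.

    Conventions for the degenerate cases: all differences exactly zero gives
    (t, p) = (0, 1); non-zero differences with zero variance give a signed
    infinite t with p = 0.
    """
    a = np.asarray(metric_a, dtype=float)
    b = np.asarray(metric_b, dtype=float)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("need two equally sized vectors of length >= 2")
    d = a - b
    if np.all(d == 0.0):
        return 0.0, 1.0
    if np.std(d, ddof=1) == 0.0:
        return float(np.sign(d.mean()) * np.inf), 0.0
    t, p = stats.ttest_rel(a, b)
    return float(t), float(p)


@dataclass
class BenchmarkResult:
    """All per-cell reports plus the per-model paired-test outcome."""

    reports: dict[tuple[int, str, str], MetricsReport]
    ttests: dict[str, tuple[float, float]]  # model -> (t, p) on accuracy, augmented - baseline
    seeds: list[int]
    model_names: list[str]
    conditions: tuple[str, str] = ("original", "original+synthetic")

    def mean_metric(self, model: str, condition: str, metric: str = "accuracy") -> float:
        vals = [
            getattr(self.reports[(s, model, condition)], metric) for s in self.seeds
        ]
        return float(np.mean(vals))

    def to_frame(self):
        import pandas as pd

        rows = []
        for (seed, model, condition), rep in self.reports.items():
            rows.append({"seed": seed, "model": model, "condition": condition, **rep.as_dict()})
        return pd.DataFrame(rows)


def run_benchmark(
    original: SpectraDataset,
    synthetic: SyntheticBatch,
    seeds: list[int],
    models: list[ModelSpec] | None = None,
    train_frac: float = 0.8,
    cv_folds: int = 5,
    train_per_class: int | None = None,
) -> BenchmarkResult:
    """The full augmentation experiment.

    Per seed: one stratified split of the real data; per model: tune and fit
    on the original training rows (condition "original"), then on the
    original training rows plus every synthetic row (condition
    "original+synthetic"); evaluate both on the same real test set.
    ``train_per_class`` optionally subsamples the real training rows to a
    fixed per-class count — the scarce-data variant.  Finishes with a paired
    t-test on accuracy per model across seeds.
    """
    models = default_model_specs() if models is None else models
    if synthetic.spectra.size and synthetic.spectra.shape[1] != original.n_bands:
        raise ValueError(
            f"synthetic spectra have {synthetic.spectra.shape[1]} bands, "
            f"original has {original.n_bands}"
        )
    reports: dict[tuple[int, str, str], MetricsReport] = {}
    classes = original.classes
    for seed in seeds:
        split = stratified_split(original, train_frac, seed)
        train_idx = split.train
        if train_per_class is not None:
            rng = np.random.default_rng(seed + 10_000)
            kept = []
            for lab in classes:
                lab_idx = train_idx[original.labels[train_idx] == lab]
                kept.append(rng.choice(lab_idx, size=min(train_per_class, lab_idx.size), replace=False))
            train_idx = np.sort(np.concatenate(kept))
        # structural test purity: test rows are real-data indices by construction
        assert np.intersect1d(train_idx, split.test).size == 0
        X_tr, y_tr = original.X[train_idx], original.labels[train_idx]
        X_te, y_te = original.X[split.test], original.labels[split.test]
        X_aug = np.vstack([X_tr, synthetic.spectra.astype(float)])
        y_aug = np.concatenate([y_tr, synthetic.labels])
        for m_i, spec in enumerate(models):
            tune_seed = (seed * 1000 + m_i * 7 + 1) % (2**31)
            for condition, (X_fit, y_fit) in (
                ("original", (X_tr, y_tr)),
                ("original+synthetic", (X_aug, y_aug)),
            ):
                model, _ = tune_fit(spec, X_fit, y_fit, cv_folds=cv_folds, seed=tune_seed)
                pred = model.predict(X_te)
                scores = class_scores(model, X_te, classes)
                reports[(seed, spec.name, condition)] = metrics_from_predictions(
                    y_te, pred, scores, classes
                )
    ttests = {}
    if len(seeds) >= 2:
        for spec in models:
            base = [reports[(s, spec.name, "original")].accuracy for s in seeds]
            aug = [reports[(s, spec.name, "original+synthetic")].accuracy for s in seeds]
            ttests[spec.name] = paired_ttest(aug, base)
    return BenchmarkResult(
        reports=reports,
        ttests=ttests,
        seeds=list(seeds),
        model_names=[m.name for m in models],
    )
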