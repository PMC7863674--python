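"""Multi-algorithm presence/pseudo-absence classification bench.

For each pseudo-absence run the design (presences labelled 1,
pseudo-absences 0, covariates 0-1 scaled) is split 80/20 stratified;
fourteen supervised learners spanning seven families are fitted with
10-fold x 3 repeated cross-validation and evaluated on the held-out 20%
with six metrics (accuracy, kappa, sensitivity, specificity, TSS, F1).
The best learner — a random forest in practice — is tuned over the
``mtry`` grid (features considered per split), and a stacked ensemble
(logistic meta-learner on the base models' out-of-fold probabilities)
provides the alternative predictor. Per-run probability maps are
averaged across runs, with a coefficient-of-variation surface as the
uncertainty product.

Several of the original learners come from the R ecosystem and are
registered here through their nearest scikit-learn equivalents; each
:class:`AlgorithmSpec` records ``exact`` or ``equivalent`` accordingly
and the registry is pluggable.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import kruskal
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.calibration import CalibratedClassifierCV
from sklearn.discriminant_analysis import (LinearDiscriminantAnalysis,
                                           QuadraticDiscriminantAnalysis)
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import (RepeatedStratifiedKFold, StratifiedKFold,
                                     cross_val_predict, train_test_split)
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import SplineTransformer, StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .grids import EnvStack

log = logging.getLogger(__name__)

METRIC_NAMES = ["accuracy", "kappa", "sensitivity", "specificity", "tss", "f1"]


# --------------------------------------------------------------------------
# metrics

@dataclass
class EvaluationMetrics:
    accuracy: float
    kappa: float
    sensitivity: float
    specificity: float
    tss: float
    f1: float

    def as_dict(self) -> dict[str, float]:
        return {k: getattr(self, k) for k in METRIC_NAMES}


def compute_metrics(y_true, y_pred) -> EvaluationMetrics:
    """Six presence/absence metrics from the confusion matrix.

    Positive class is presence (1). With a single-class truth vector the
    undefined entries (sensitivity or specificity, hence TSS) come back
    as NaN with a warning rather than raising.
    """
    y_true = np.asarray(y_true).astype(int)
    y_pred = np.asarray(y_pred).astype(int)
    if y_true.size == 0 or y_true.size != y_pred.size:
        raise ValueError("label vectors must be non-empty and equal length")
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    tn = int(np.sum((y_true == 0) & (y_pred == 0)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))
    n = tp + tn + fp + fn
    acc = (tp + tn) / n
    sens = tp / (tp + fn) if tp + fn else np.nan
    spec = tn / (tn + fp) if tn + fp else np.nan
    if np.isnan(sens) or np.isnan(spec):
        warnings.warn("single-class truth: sensitivity/specificity undefined",
                      stacklevel=2)
    tss = sens + spec - 1.0
    prec = tp / (tp + fp) if tp + fp else np.nan
    f1 = (2 * prec * sens / (prec + sens)
          if np.isfinite(prec) and np.isfinite(sens) and (prec + sens) > 0 else 0.0
          if tp + fn else np.nan)
    p_yes = ((tp + fn) / n) * ((tp + fp) / n)
    p_no = ((tn + fp) / n) * ((tn + fn) / n)
    pe = p_yes + p_no
    kap = (acc - pe) / (1 - pe) if pe < 1 else (1.0 if acc == 1.0 else 0.0)
    return EvaluationMetrics(acc, kap, sens, spec, tss, f1)


# --------------------------------------------------------------------------
# MARS-style learner (adaptive hinge basis + logistic fit)

class HingeBasisLogistic(BaseEstimator, ClassifierMixin):
    """Degree-1 adaptive-regression-splines classifier.

    Forward pass in the MARS spirit: hinge pairs max(x-k, 0)/max(k-x, 0)
    at candidate quantile knots are added greedily while they improve the
    training log-likelihood, then a ridge-regularized logistic model is
    fitted on the selected basis.
    """

    def __init__(self, max_terms: int = 12, n_knots: int = 5, C: float = 1.0):
        self.max_terms = max_terms
        self.n_knots = n_knots
        self.C = C

    def _basis(self, X, terms):
        cols = [np.ones(X.shape[0])]
        for j, knot in terms:
            cols.append(np.maximum(X[:, j] - knot, 0.0))
            cols.append(np.maximum(knot - X[:, j], 0.0))
        return np.column_stack(cols)

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y).astype(int)
        self.classes_ = np.unique(y)
        qs = np.linspace(0.1, 0.9, self.n_knots)
        candidates = [(j, float(k)) for j in range(X.shape[1])
                      for k in np.quantile(X[:, j], qs)]
        terms: list[tuple[int, float]] = []
        lr = LogisticRegression(C=self.C, max_iter=500)

        def score(ts):
            b = self._basis(X, ts)
            m = lr.fit(b, y)
            p = np.clip(m.predict_proba(b)[:, 1], 1e-9, 1 - 1e-9)
            return float(np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))

        best = score(terms)
        while len(terms) < self.max_terms and candidates:
            gains = [(score(terms + [c]), c) for c in candidates]
            top, cand = max(gains, key=lambda g: g[0])
            if top <= best + 1e-5:
                break
            best = top
            terms.append(cand)
            candidates.remove(cand)
        self.terms_ = terms
        self.model_ = LogisticRegression(C=self.C, max_iter=500).fit(
            self._basis(X, terms), y)
        return self

    def predict_proba(self, X):
        return self.model_.predict_proba(self._basis(np.asarray(X, dtype=float),
                                                     self.terms_))

    def predict(self, X):
        return self.model_.predict(self._basis(np.asarray(X, dtype=float),
                                               self.terms_))


# --------------------------------------------------------------------------
# registry

@dataclass
class AlgorithmSpec:
    name: str
    category: str
    factory: object            # callable(seed) -> unfitted estimator
    fidelity: str = "exact"    # "exact" | "equivalent"
    note: str = ""

    def make(self, seed: int):
        return self.factory(seed)


def default_registry(n_estimators: int = 100) -> dict[str, AlgorithmSpec]:
    """The fourteen-learner registry, keyed by short name.

    R-ecosystem learners without scikit-learn counterparts are registered
    as documented nearest-equivalents (fidelity ``equivalent``).
    """

    def rf(seed):
        return RandomForestClassifier(n_estimators=n_estimators, random_state=seed)

    def gbm(seed):
        return GradientBoostingClassifier(random_state=seed)

    def gam(seed):
        return make_pipeline(
            SplineTransformer(n_knots=5, degree=3),
            LogisticRegression(max_iter=1000, C=1.0))

    def mars(seed):
        return HingeBasisLogistic()

    def nb(seed):
        return GaussianNB()

    def bayesglm(seed):
        return make_pipeline(StandardScaler(),
                             LogisticRegression(max_iter=1000, C=1.0))

    def lmt(seed):
        return GradientBoostingClassifier(max_depth=1, random_state=seed)

    def c50(seed):
        return DecisionTreeClassifier(criterion="entropy", random_state=seed)

    def knn(seed):
        return make_pipeline(StandardScaler(),
                             KNeighborsClassifier(n_neighbors=5))

    def kknn(seed):
        return make_pipeline(StandardScaler(),
                             KNeighborsClassifier(n_neighbors=7, weights="distance"))

    def lda(seed):
        return LinearDiscriminantAnalysis()

    def qda(seed):
        return QuadraticDiscriminantAnalysis(reg_param=1e-3)

    # Platt-scaled SVMs so they expose probabilities for stacking/maps
    def svm_radial(seed):
        return make_pipeline(StandardScaler(), CalibratedClassifierCV(
            SVC(kernel="rbf", random_state=seed), method="sigmoid",
            cv=5, ensemble=False))

    def svm_linear(seed):
        return make_pipeline(StandardScaler(), CalibratedClassifierCV(
            SVC(kernel="linear", random_state=seed), method="sigmoid",
            cv=5, ensemble=False))

    specs = [
        AlgorithmSpec("RF", "Ensemble", rf),
        AlgorithmSpec("GBM", "Ensemble", gbm),
        AlgorithmSpec("GAM", "Regression", gam, "equivalent",
                      "spline-basis additive logistic model"),
        AlgorithmSpec("MARS", "Regression", mars, "equivalent",
                      "greedy hinge-basis logistic (degree-1 adaptive splines)"),
        AlgorithmSpec("NB", "Bayesian", nb),
        AlgorithmSpec("BayesGLM", "Bayesian", bayesglm, "equivalent",
                      "ridge logistic regression (Gaussian-prior GLM)"),
        AlgorithmSpec("LMT", "Decision tree", lmt, "equivalent",
                      "gradient-boosted stumps in place of logistic model trees"),
        AlgorithmSpec("C5.0", "Decision tree", c50, "equivalent",
                      "entropy CART in place of C5.0"),
        AlgorithmSpec("KNN", "Instance-based", knn),
        AlgorithmSpec("KKNN", "Instance-based", kknn, "equivalent",
                      "distance-weighted KNN"),
        AlgorithmSpec("LDA", "Dimensionality reduction", lda),
        AlgorithmSpec("QDA", "Dimensionality reduction", qda),
        AlgorithmSpec("SVMradial", "SVM", svm_radial),
        AlgorithmSpec("SVMlinear", "SVM", svm_linear),
    ]
    return {s.name: s for s in specs}


# --------------------------------------------------------------------------
# fitting machinery

@dataclass
class FitResult:
    algorithm: str
    run: int
    model: object
    cv_summary: pd.DataFrame | None
    holdout: EvaluationMetrics | None
    importances: pd.Series | None = None
    error: str | None = None
    extra: dict = field(default_factory=dict)

    @property
    def failed(self) -> bool:
        return self.error is not None


def partition_data(X: pd.DataFrame, y: np.ndarray, train_fraction: float = 0.8,
                   seed: int = 0):
    """Stratified train/validation split preserving class balance."""
    if len(X) < 10:
        raise ValueError("need at least 10 rows to split")
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    return train_test_split(X, np.asarray(y), train_size=train_fraction,
                            stratify=y, random_state=seed)


def crossvalidate(estimator, X, y, folds: int = 10, repeats: int = 3,
                  seed: int = 0) -> pd.DataFrame:
    """Repeated stratified k-fold metrics: one row per fold-fit.

    Returns a DataFrame of the six metrics with ``folds * repeats`` rows;
    summarize with ``.mean()`` / ``.std()``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    cv = RepeatedStratifiedKFold(n_splits=folds, n_repeats=repeats,
                                 random_state=seed)
    rows = []
    for tr, te in cv.split(X, y):
        m = clone(estimator).fit(X[tr], y[tr])
        rows.append(compute_metrics(y[te], m.predict(X[te])).as_dict())
    return pd.DataFrame(rows)


def fit_one(spec: AlgorithmSpec, X_train, y_train, X_val, y_val, run: int,
            seed: int, folds: int = 10, repeats: int = 3,
            with_cv: bool = True) -> FitResult:
    """Fit one registered learner: CV on the training split, metrics on
    the held-out split; failures are captured, not raised."""
    try:
        est = spec.make(seed)
        cv = crossvalidate(est, X_train, y_train, folds, repeats, seed) if with_cv else None
        model = clone(est).fit(np.asarray(X_train, dtype=float),
                               np.asarray(y_train).astype(int))
        holdout = compute_metrics(y_val, model.predict(np.asarray(X_val, dtype=float)))
        return FitResult(spec.name, run, model, cv, holdout)
    except Exception as exc:  # noqa: BLE001 - per-algorithm isolation contract
        log.warning("algorithm %s failed on run %d: %s", spec.name, run, exc)
        return FitResult(spec.name, run, None, None, None, error=str(exc))


def fit_all_algorithms(X_train, y_train, X_val, y_val,
                       registry: dict[str, AlgorithmSpec] | None = None,
                       run: int = 1, seed: int = 0, folds: int = 10,
                       repeats: int = 3, with_cv: bool = True) -> list[FitResult]:
    """Fit every learner in the registry on one run's split."""
    registry = registry or default_registry()
    return [fit_one(spec, X_train, y_train, X_val, y_val, run, seed,
                    folds, repeats, with_cv)
            for spec in registry.values()]


def metrics_table(results: list[FitResult]) -> pd.DataFrame:
    """Held-out metrics of successful fits, one row per (algorithm, run)."""
    rows = []
    for r in results:
        if r.failed or r.holdout is None:
            continue
        row = {"algorithm": r.algorithm, "run": r.run}
        row.update(r.holdout.as_dict())
        rows.append(row)
    return pd.DataFrame(rows)


def select_best(table: pd.DataFrame) -> str:
    """Best algorithm: highest mean of the six metrics, ties by TSS."""
    agg = table.groupby("algorithm")[METRIC_NAMES].mean()
    score = agg.mean(axis=1)
    best = agg.loc[score == score.max()].sort_values("tss", ascending=False)
    return str(best.index[0])


def tune_random_forest(X_train, y_train, X_val, y_val,
                       mtry_grid: list[int] | None = None, run: int = 1,
                       seed: int = 0, folds: int = 10, repeats: int = 3,
                       n_estimators: int = 100,
                       n_estimators_final: int | None = None) -> FitResult:
    """Tune the forest's ``mtry`` (features tried per split) by CV accuracy.

    Evaluates every grid value with repeated stratified CV on the
    training split, picks the best mean accuracy (ties to the smallest
    mtry), refits on the full training split and reports held-out
    metrics plus permutation importances. ``n_estimators_final`` lets the
    refitted model grow a larger forest than the CV sweep.
    """
    X_train = np.asarray(X_train, dtype=float)
    p = X_train.shape[1]
    if mtry_grid is None:
        # caret's default mtry grid: floor of 3 values evenly spanning [2, p]
        mtry_grid = sorted({int(m) for m in np.linspace(2, max(2, p), 3)})
    mtry_grid = [m for m in mtry_grid if 1 <= m <= p]
    cv_rows = []
    best_mtry, best_acc = None, -np.inf
    for m in mtry_grid:
        est = RandomForestClassifier(n_estimators=n_estimators, max_features=m,
                                     random_state=seed)
        cv = crossvalidate(est, X_train, y_train, folds, repeats, seed)
        acc = float(cv["accuracy"].mean())
        cv_rows.append({"mtry": m, "cv_accuracy_mean": acc,
                        "cv_accuracy_sd": float(cv["accuracy"].std())})
        if acc > best_acc + 1e-12:  # strict improvement; ties keep smaller mtry
            best_mtry, best_acc = m, acc
    model = RandomForestClassifier(n_estimators=n_estimators_final or n_estimators,
                                   max_features=best_mtry,
                                   random_state=seed).fit(
        X_train, np.asarray(y_train).astype(int))
    holdout = compute_metrics(np.asarray(y_val).astype(int),
                              model.predict(np.asarray(X_val, dtype=float)))
    res = FitResult("RF_tuned", run, model, pd.DataFrame(cv_rows), holdout)
    res.extra["mtry"] = best_mtry
    return res


# --------------------------------------------------------------------------
# stacking

class StackedModel:
    """Logistic meta-learner over base-model probabilities."""

    def __init__(self, base_models: dict[str, object], meta: LogisticRegression):
        self.base_models = base_models
        self.meta = meta

    def _base_probs(self, X):
        X = np.asarray(X, dtype=float)
        return np.column_stack([m.predict_proba(X)[:, 1]
                                for m in self.base_models.values()])

    def predict_proba(self, X):
        return self.meta.predict_proba(self._base_probs(X))

    def predict(self, X):
        return self.meta.predict(self._base_probs(X))


def stack_models(X_train, y_train,
                 registry: dict[str, AlgorithmSpec] | None = None,
                 seed: int = 0, folds: int = 10) -> StackedModel:
    """Stacked generalization over the registry's learners.

    Each base learner's out-of-fold probabilities on the training split
    (common stratified folds) feed a logistic meta-learner; the bases
    are then refitted on the full training split for prediction. Base
    learners that fail are skipped.
    """
    registry = registry or default_registry()
    X = np.asarray(X_train, dtype=float)
    y = np.asarray(y_train).astype(int)
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    oof_cols, fitted = {}, {}
    for spec in registry.values():
        try:
            oof = cross_val_predict(spec.make(seed), X, y, cv=cv,
                                    method="predict_proba")[:, 1]
            fitted[spec.name] = clone(spec.make(seed)).fit(X, y)
            oof_cols[spec.name] = oof
        except Exception as exc:  # noqa: BLE001
            log.warning("stacking skips %s: %s", spec.name, exc)
    if len(oof_cols) < 2:
        raise ValueError("need at least two base models with OOF predictions")
    z = np.column_stack(list(oof_cols.values()))
    if np.allclose(z.std(axis=0), 0):
        warnings.warn("base probabilities are constant; meta fit degenerate",
                      stacklevel=2)
    meta = LogisticRegression(max_iter=1000).fit(z, y)
    return StackedModel(fitted, meta)


# --------------------------------------------------------------------------
# comparison, maps, importance

def compare_methods(metrics_a: pd.DataFrame, metrics_b: pd.DataFrame,
                    labels: tuple[str, str] = ("A", "B")) -> pd.DataFrame:
    """Rank-based (Kruskal-Wallis) comparison of two methods per metric.

    Expects one row per run; returns statistic, p-value and the sign of
    the mean difference for each of the six metrics.
    """
    rows = []
    for m in METRIC_NAMES:
        a = metrics_a[m].dropna().to_numpy()
        b = metrics_b[m].dropna().to_numpy()
        if len(a) < 3 or len(b) < 3:
            raise ValueError("need at least 3 runs per method")
        if len(a) == len(b) and np.allclose(a, b):
            stat, p = 0.0, 1.0
        else:
            try:
                stat, p = kruskal(a, b)
            except ValueError:  # all values identical across both groups
                stat, p = 0.0, 1.0
        diff = float(a.mean() - b.mean())
        rows.append({"metric": m, "statistic": float(stat), "p_value": float(p),
                     "higher": labels[0] if diff > 0 else labels[1] if diff < 0
                     else "tie"})
    return pd.DataFrame(rows)


def predict_grid(model, stack: EnvStack, variables: list[str],
                 scaling: dict[str, tuple[float, float]] | None = None) -> np.ndarray:
    """Per-cell presence probability over an environmental stack.

    ``scaling`` replays the 0-1 scaling fitted on the model design; cells
    with any missing covariate propagate as NaN.
    """
    from .envlayers import apply_scaling

    cols = []
    for name in variables:
        layer = stack[name]
        if scaling and name in scaling:
            layer = apply_scaling(layer, scaling[name])
        cols.append(layer.ravel())
    design = np.column_stack(cols)
    ok = np.isfinite(design).all(axis=1)
    out = np.full(design.shape[0], np.nan)
    if ok.any():
        out[ok] = model.predict_proba(design[ok])[:, 1]
    return out.reshape(stack.shape)


@dataclass
class PredictionMaps:
    mean: np.ndarray
    cv_percent: np.ndarray
    n_runs: int
    method: str = ""
    season: str | None = None


def aggregate_runs(layers: list[np.ndarray], method: str = "",
                   season: str | None = None) -> PredictionMaps:
    """Cellwise mean and coefficient of variation across replicate maps.

    CV = sample SD / mean, in percent; NaN where the mean is zero
    (flagged, not an error) and where any input is missing.
    """
    arr = np.stack([np.asarray(a, dtype=float) for a in layers])
    mean = arr.mean(axis=0)
    sd = arr.std(axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cv = np.where(mean != 0, 100.0 * sd / mean, np.nan)
    return PredictionMaps(mean=mean, cv_percent=cv, n_runs=arr.shape[0],
                          method=method, season=season)


def variable_importance(model, X_val, y_val, variables: list[str],
                        n_permutations: int = 10, seed: int = 0) -> pd.Series:
    """Permutation importance: mean drop in held-out accuracy when one
    predictor is shuffled, over ``n_permutations`` shuffles."""
    X = np.asarray(X_val, dtype=float)
    y = np.asarray(y_val).astype(int)
    rng = np.random.default_rng(seed)
    base = float(np.mean(model.predict(X) == y))
    drops = {}
    for j, name in enumerate(variables):
        d = []
        for _ in range(n_permutations):
            Xp = X.copy()
            Xp[:, j] = rng.permutation(Xp[:, j])
            d.append(base - float(np.mean(model.predict(Xp) == y)))
        drops[name] = float(np.mean(d))
    return pd.Series(drops).sort_values(ascending=False)
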