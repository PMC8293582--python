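"""The reduce stage: five feature-selection methods and shared-testset scoring.

Each selector consumes the merged sample set routed to it, returns its
top-K features ranked by importance (with the sign of each feature's
association with the outcome), and carries a fitted predictor so every
method can be scored on the one shared test pool (set id 0).

Methods span the three classical families:

* filter      — mutual information (kNN estimator) between feature and label;
* wrapper     — recursive feature elimination with a linear SVM;
* embedded    — lasso and ridge regression of the 0/1 outcome with
                cross-validated regularization, and a random forest scored
                by permutation importance on a held-out internal split.

Estimator numerics are scikit-learn's; this module owns the selection,
ranking and sign conventions around them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.feature_selection import mutual_info_classif
from sklearn.inspection import permutation_importance
from sklearn.linear_model import LassoCV, LinearRegression, RidgeCV, lasso_path
from sklearn.metrics import accuracy_score, f1_score
from sklearn.model_selection import train_test_split
from sklearn.svm import LinearSVC

__all__ = [
    "SelectorSpec",
    "RankEntry",
    "RankedFeatureList",
    "SelectorResult",
    "ModelPerformance",
    "DEFAULT_SELECTOR_IDS",
    "select_filter_mi",
    "select_svm_rfe",
    "select_lasso",
    "select_ridge",
    "select_random_forest",
    "run_selector",
    "evaluate_performance",
]

DEFAULT_SELECTOR_IDS = ("filter_mi", "svm_rfe", "lasso", "ridge", "random_forest")


@dataclass(frozen=True)
class SelectorSpec:
    """Identity, hyperparameters and list length K of one selector."""

    selector_id: str
    k: int = 10
    params: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("K must be >= 1")


@dataclass(frozen=True)
class RankEntry:
    feature: str
    rank: int
    importance: float
    sign: str  # "+" or "-"


@dataclass
class RankedFeatureList:
    selector_id: str
    entries: list[RankEntry]

    @property
    def features(self) -> list[str]:
        return [e.feature for e in self.entries]


@dataclass
class SelectorResult:
    """Ranked list plus the fitted predictor used for shared-testset scoring."""

    ranked: RankedFeatureList
    predict: Callable[[np.ndarray], np.ndarray]


@dataclass(frozen=True)
class ModelPerformance:
    selector_id: str
    accuracy: float
    f_score: float
    n_test: int


# ---------------------------------------------------------------- helpers


def _check_labels(y: np.ndarray, selector_id: str) -> None:
    if len(np.unique(y)) < 2:
        raise ValueError(f"{selector_id}: train labels are single-class (degenerate)")


def _standardize(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd = np.where(sd == 0.0, 1.0, sd)
    return (X - mu) / sd, mu, sd


def _assoc_signs(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Point-biserial association sign of each column with the binary label."""
    yc = y - y.mean()
    cov = (X - X.mean(axis=0)).T @ yc
    return np.where(cov < 0, -1.0, 1.0)


def _build_list(
    selector_id: str,
    feature_names: Sequence[str],
    importance: np.ndarray,
    signs: np.ndarray,
    k: int,
) -> RankedFeatureList:
    """Top-K by importance, descending; ties kept in column order (stable)."""
    order = np.argsort(-importance, kind="stable")[: min(k, len(feature_names))]
    entries = [
        RankEntry(
            feature=feature_names[j],
            rank=r + 1,
            importance=float(max(importance[j], 0.0)),
            sign="-" if signs[j] < 0 else "+",
        )
        for r, j in enumerate(order)
    ]
    return RankedFeatureList(selector_id=selector_id, entries=entries)


def _threshold_predictor(model, columns: np.ndarray | None, mu, sd) -> Callable:
    def predict(X: np.ndarray) -> np.ndarray:
        Z = (X - mu) / sd if mu is not None else X
        if columns is not None:
            Z = Z[:, columns]
        return (model.predict(Z) > 0.5).astype(int)

    return predict


# ---------------------------------------------------------------- selectors


def select_filter_mi(X: np.ndarray, y: np.ndarray, spec: SelectorSpec,
                     feature_names: Sequence[str]) -> SelectorResult:
    """Rank by mutual information with the outcome (kNN estimator, 3 neighbors).

    The estimator's internal seeded jitter breaks duplicate-value
    degeneracy. Signs come from point-biserial correlation. The companion
    predictor is an ordinary least-squares fit on the selected features,
    thresholded at 0.5.
    """
    _check_labels(y, spec.selector_id)
    mi = mutual_info_classif(
        X,
        y,
        n_neighbors=int(spec.params.get("k_neighbors", 3)),
        discrete_features=False,
        random_state=spec.seed,
    )
    mi[X.std(axis=0) == 0.0] = 0.0  # constant columns carry no information
    ranked = _build_list(spec.selector_id, feature_names, mi, _assoc_signs(X, y), spec.k)
    name_to_col = {n: j for j, n in enumerate(feature_names)}
    cols = np.array([name_to_col[f] for f in ranked.features], dtype=int)
    ols = LinearRegression().fit(X[:, cols], y)
    return SelectorResult(ranked=ranked, predict=_threshold_predictor(ols, cols, None, None))


def select_svm_rfe(X: np.ndarray, y: np.ndarray, spec: SelectorSpec,
                   feature_names: Sequence[str]) -> SelectorResult:
    """Recursive feature elimination with a linear SVM, one feature per step.

    At each step the feature with the smallest |coefficient| is dropped
    (ties broken by column order) until K remain; the survivors are ranked
    by |coefficient| of the final fit, whose coefficient signs are reported.
    Features are standardized before fitting.
    """
    _check_labels(y, spec.selector_id)
    Z, mu, sd = _standardize(X)
    C = float(spec.params.get("C", 1.0))
    max_iter = int(spec.params.get("max_iter", 10_000))
    active = np.arange(Z.shape[1])
    model = None
    while True:
        model = LinearSVC(C=C, dual=False, max_iter=max_iter).fit(Z[:, active], y)
        if len(active) <= spec.k:
            break
        drop = int(np.argmin(np.abs(model.coef_[0])))
        active = np.delete(active, drop)
    coef = model.coef_[0]
    importance = np.zeros(Z.shape[1])
    signs = np.ones(Z.shape[1])
    importance[active] = np.abs(coef)
    signs[active] = np.where(coef < 0, -1.0, 1.0)
    names = list(feature_names)
    order = np.argsort(-importance[active], kind="stable")
    entries = [
        RankEntry(
            feature=names[active[j]],
            rank=r + 1,
            importance=float(importance[active[j]]),
            sign="-" if signs[active[j]] < 0 else "+",
        )
        for r, j in enumerate(order)
    ]
    ranked = RankedFeatureList(selector_id=spec.selector_id, entries=entries)
    svm_cols = active.copy()

    def predict(Xnew: np.ndarray) -> np.ndarray:
        Znew = (Xnew - mu) / sd
        return model.predict(Znew[:, svm_cols]).astype(int)

    return SelectorResult(ranked=ranked, predict=predict)


def _regularized_linear(X, y, spec, feature_names, penalty: str) -> SelectorResult:
    Z, mu, sd = _standardize(X)
    if penalty == "l1":
        grid = np.asarray(spec.params.get("lambda_grid", np.logspace(-5, 0, 41)))
        model = LassoCV(alphas=np.sort(grid)[::-1], cv=int(spec.params.get("cv", 5))).fit(Z, y)
        coef = model.coef_
        if np.all(coef == 0.0):
            warnings.warn(
                f"{spec.selector_id}: all coefficients zero at the selected penalty; "
                "ranking by activation order along the path",
                stacklevel=2,
            )
            alphas, coefs, _ = lasso_path(Z, y, alphas=np.sort(grid)[::-1])
            n_alphas = len(alphas)
            first_active = np.full(Z.shape[1], np.inf)
            for j in range(Z.shape[1]):
                nz = np.nonzero(coefs[j] != 0.0)[0]
                if nz.size:
                    first_active[j] = nz[0]
            # earlier activation along the path = larger importance; never active = 0
            importance = np.where(np.isinf(first_active), 0.0, n_alphas - first_active)
        else:
            importance = np.abs(coef)
    else:
        grid = np.asarray(spec.params.get("lambda_grid", np.logspace(-3, 3, 41)))
        model = RidgeCV(alphas=np.sort(grid)).fit(Z, y)
        coef = model.coef_
        importance = np.abs(coef)
    signs = np.where(coef < 0, -1.0, np.where(coef > 0, 1.0, _assoc_signs(Z, y)))
    ranked = _build_list(spec.selector_id, feature_names, importance, signs, spec.k)
    return SelectorResult(ranked=ranked, predict=_threshold_predictor(model, None, mu, sd))


def select_lasso(X: np.ndarray, y: np.ndarray, spec: SelectorSpec,
                 feature_names: Sequence[str]) -> SelectorResult:
    """L1-regularized least squares on the 0/1 outcome; penalty chosen by CV.

    Importance is |coefficient| at the selected penalty; if the selected
    penalty zeroes everything, features are ranked by activation order
    along the regularization path (with a warning).
    """
    _check_labels(y, spec.selector_id)
    return _regularized_linear(X, y, spec, feature_names, "l1")


def select_ridge(X: np.ndarray, y: np.ndarray, spec: SelectorSpec,
                 feature_names: Sequence[str]) -> SelectorResult:
    """L2 counterpart of :func:`select_lasso`; the ranking is always total."""
    _check_labels(y, spec.selector_id)
    return _regularized_linear(X, y, spec, feature_names, "l2")


def select_random_forest(X: np.ndarray, y: np.ndarray, spec: SelectorSpec,
                         feature_names: Sequence[str]) -> SelectorResult:
    """Gini forest ranked by permutation importance on a held-out split.

    The forest trains on 80% of its sample set; importance is the mean
    decrease in accuracy over repeated permutations of each feature on the
    remaining 20%, which avoids the training-set bias of impurity-based
    scores. Negative permutation means (pure noise) are clipped to zero in
    the report.
    """
    _check_labels(y, spec.selector_id)
    X_fit, X_val, y_fit, y_val = train_test_split(
        X, y, test_size=0.2, random_state=spec.seed, stratify=y
    )
    forest = RandomForestClassifier(
        n_estimators=int(spec.params.get("n_trees", 50)),
        criterion="gini",
        random_state=spec.seed,
        n_jobs=1,
    ).fit(X_fit, y_fit)
    perm = permutation_importance(
        forest,
        X_val,
        y_val,
        n_repeats=int(spec.params.get("n_permutation_repeats", 5)),
        random_state=spec.seed,
        scoring="accuracy",
        n_jobs=1,
    )
    ranked = _build_list(
        spec.selector_id, feature_names, perm.importances_mean, _assoc_signs(X, y), spec.k
    )

    def predict(Xnew: np.ndarray) -> np.ndarray:
        return forest.predict(Xnew).astype(int)

    return SelectorResult(ranked=ranked, predict=predict)


_DISPATCH = {
    "filter_mi": select_filter_mi,
    "svm_rfe": select_svm_rfe,
    "lasso": select_lasso,
    "ridge": select_ridge,
    "random_forest": select_random_forest,
}


def run_selector(spec: SelectorSpec, X: np.ndarray, y: np.ndarray,
                 feature_names: Sequence[str]) -> SelectorResult:
    try:
        fn = _DISPATCH[spec.selector_id]
    except KeyError:
        raise ValueError(f"unknown selector_id {spec.selector_id!r}") from None
    return fn(X, y, spec, feature_names)


def evaluate_performance(
    result: SelectorResult,
    X_test: np.ndarray,
    y_test: np.ndarray,
    positive_label: int = 1,
) -> ModelPerformance:
    """Accuracy and F-score of one selector's predictor on the shared test pool.

    F-score is the harmonic mean of precision and recall for the configured
    positive class (default: the overweight label 1). If the predictor
    emits no positives, the F-score is 0 (with a warning).
    """
    if len(y_test) == 0 or len(np.unique(y_test)) < 2:
        raise ValueError("test pool must be non-empty with both classes")
    pred = np.asarray(result.predict(X_test))
    acc = float(accuracy_score(y_test, pred))
    if not np.any(pred == positive_label):
        warnings.warn(
            f"{result.ranked.selector_id}: no predicted positives; F-score set to 0",
            stacklevel=2,
        )
        f = 0.0
    else:
        f = float(f1_score(y_test, pred, pos_label=positive_label, zero_division=0))
    return ModelPerformance(
        selector_id=result.ranked.selector_id,
        accuracy=acc,
        f_score=f,
        n_test=int(len(y_test)),
    )
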