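"""Feature-selection engines for multiclass cancer-type prediction.

Three rankers are provided, each pairing a multiclass classifier with its
natural feature-selection mechanism:

* linear SVM with recursive feature elimination (SVM-RFE): repeatedly fit
  one-vs-rest linear SVMs, score each surviving feature j by the sum over
  classes k of the squared weight w_kj^2, and discard the lowest-scoring
  feature(s); the reverse elimination order is the importance ranking;
* L1-regularised multinomial logistic regression: sweep the penalty
  strength lambda and read feature selection off the active set;
* random forest with permutation importance on out-of-bag samples and
  backward elimination of the least important fraction.

A frequency-matched random classifier serves as the chance baseline.
"""

from __future__ import annotations

import copy
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import LinearSVC
from sklearn.tree import DecisionTreeClassifier

from .matrix import LabeledDataset

__all__ = [
    "ModelFit", "FeatureRanking", "RegularizationPath", "PathPoint",
    "tune_svm_cost", "fit_predict_svm", "svm_rfe_rank",
    "l1_logreg_path", "rf_backward_eliminate", "random_baseline",
    "default_schedule",
]


@dataclass
class ModelFit:
    """A fitted multiclass model restricted to a known feature set."""

    model_kind: str
    estimator: object
    feature_ids: list[int]
    params: dict = field(default_factory=dict)

    def predict(self, dataset: LabeledDataset) -> np.ndarray:
        X = dataset.matrix.subset_features(self.feature_ids).values.astype(np.float64)
        return np.asarray(self.estimator.predict(X))


@dataclass
class FeatureRanking:
    """Feature ids ordered most-important-first, with the importance score
    each feature had when it was eliminated."""

    feature_ids: list[int]
    importances: list[float]
    method: str
    seed: int | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.feature_ids)) != len(self.feature_ids):
            raise ValueError("ranking must not contain duplicate feature ids")
        if len(self.importances) != len(self.feature_ids):
            raise ValueError("importances must align with feature_ids")

    def __len__(self) -> int:
        return len(self.feature_ids)

    def top(self, n: int) -> list[int]:
        return self.feature_ids[:n]


@dataclass
class PathPoint:
    lam: float
    active_feature_ids: list[int]
    model: ModelFit
    converged: bool
    test_accuracy: float | None = None

    @property
    def n_active(self) -> int:
        return len(self.active_feature_ids)


@dataclass
class RegularizationPath:
    points: list[PathPoint]

    def __post_init__(self) -> None:
        lams = [p.lam for p in self.points]
        if any(b >= a for a, b in zip(lams, lams[1:])):
            raise ValueError("lambda values must be strictly decreasing along the path")

    def __len__(self) -> int:
        return len(self.points)


def _svc(cost: float, seed: int = 0) -> LinearSVC:
    # liblinear one-vs-rest linear SVM; fixed random_state for determinism
    return LinearSVC(C=cost, random_state=seed, max_iter=5000)


def _check_multiclass(dataset: LabeledDataset) -> None:
    if len(dataset.classes) < 2:
        raise ValueError("training set must contain at least two classes")


def tune_svm_cost(train: LabeledDataset, grid: Sequence[float],
                  n_folds: int = 10, seed: int = 0) -> float:
    """Pick the SVM cost C maximising mean stratified k-fold CV accuracy.

    Ties are broken towards the smallest cost. If the smallest class has
    fewer members than ``n_folds``, the fold count is reduced (with a
    warning) so every fold sees every class.
    """
    _check_multiclass(train)
    if not grid:
        raise ValueError("cost grid must be non-empty")
    y = train.labels
    min_class = int(np.unique(y, return_counts=True)[1].min())
    folds = min(n_folds, min_class)
    if folds < 2:
        raise ValueError("smallest class must have at least 2 members for cross-validation")
    if folds < n_folds:
        warnings.warn(f"reduced CV folds from {n_folds} to {folds} "
                      f"(smallest class has {min_class} members)")
    X = train.matrix.values.astype(np.float64)
    skf = StratifiedKFold(n_splits=folds, shuffle=False)
    best_cost, best_acc = None, -1.0
    for cost in sorted(grid):
        accs = []
        for tr, te in skf.split(X, y):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", ConvergenceWarning)
                clf = _svc(cost, seed).fit(X[tr], y[tr])
            accs.append(float(np.mean(clf.predict(X[te]) == y[te])))
        acc = float(np.mean(accs))
        if acc > best_acc:
            best_cost, best_acc = cost, acc
    return best_cost


def fit_predict_svm(train: LabeledDataset, cost: float = 1.0, seed: int = 0) -> ModelFit:
    """Fit a one-vs-rest linear SVM; prediction is the argmax of the
    per-class decision values. Deterministic given data and cost."""
    _check_multiclass(train)
    X = train.matrix.values.astype(np.float64)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        clf = _svc(cost, seed).fit(X, train.labels)
    return ModelFit(
        model_kind="linear_svm",
        estimator=clf,
        feature_ids=[f.feature_id for f in train.matrix.features],
        params={"cost": cost, "seed": seed},
    )


def default_schedule(n_surviving: int, chunk_threshold: int = 1000,
                     chunk_fraction: float = 0.1) -> int:
    """Features to drop this iteration: one at a time once fewer than
    ``chunk_threshold`` survive, else 10 % per iteration for tractability
    on matrices with thousands of columns."""
    if n_surviving < chunk_threshold:
        return 1
    return max(1, int(n_surviving * chunk_fraction))


def svm_rfe_rank(train: LabeledDataset, cost: float = 1.0,
                 schedule: Callable[[int], int] | None = None,
                 seed: int = 0) -> FeatureRanking:
    """Multiclass SVM recursive feature elimination.

    Each iteration fits the one-vs-rest linear SVM on the surviving
    features, scores feature j by sum_k w_kj^2 over the K one-vs-rest
    weight vectors, and eliminates the lowest-scoring feature(s) per the
    schedule (score ties broken towards the earlier column). The least
    important feature is discarded first and the most important last, so
    the ranking is the reverse elimination order.
    """
    _check_multiclass(train)
    if train.matrix.n_features < 1:
        raise ValueError("need at least one feature to rank")
    if schedule is None:
        schedule = default_schedule
    X = train.matrix.values.astype(np.float64)
    y = train.labels
    fids = [f.feature_id for f in train.matrix.features]
    surviving = list(range(len(fids)))
    eliminated: list[tuple[int, float]] = []  # (column, score at elimination)

    while len(surviving) > 1:
        n_drop = schedule(len(surviving))
        if n_drop >= len(surviving):
            raise ValueError(
                f"schedule would eliminate {n_drop} of {len(surviving)} surviving features")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            clf = _svc(cost, seed).fit(X[:, surviving], y)
        w = np.atleast_2d(clf.coef_)
        scores = (w ** 2).sum(axis=0)
        # ascending score, stable on ties -> earlier surviving column first
        order = np.argsort(scores, kind="stable")
        for pos in order[:n_drop].tolist():
            eliminated.append((surviving[pos], float(scores[pos])))
        drop = set(order[:n_drop].tolist())
        surviving = [c for i, c in enumerate(surviving) if i not in drop]

    if surviving:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            clf = _svc(cost, seed).fit(X[:, surviving], y)
        w = np.atleast_2d(clf.coef_)
        eliminated.append((surviving[0], float((w ** 2).sum(axis=0)[0])))

    ranked = list(reversed(eliminated))
    return FeatureRanking(
        feature_ids=[fids[c] for c, _ in ranked],
        importances=[s for _, s in ranked],
        method="svm_rfe",
        seed=seed,
        provenance={"cost": cost},
    )


def l1_logreg_path(train: LabeledDataset, lambdas: Sequence[float] | None = None,
                   n_lambdas: int = 100, lambda_min_ratio: float = 1e-2,
                   max_iter: int = 300, seed: int = 0) -> RegularizationPath:
    """L1-penalised multinomial logistic regression swept over a descending
    lambda grid with warm starts.

    ``lambda`` is the per-sample penalty weight (glmnet convention); the
    solver's inverse regularisation is C = 1 / (n_samples * lambda). The
    default grid spans [lambda_max * lambda_min_ratio, lambda_max]
    log-spaced, where lambda_max is the smallest value shrinking every
    coefficient to zero (largest absolute class-centred gradient).
    Non-convergence at a grid point is recorded and the path continues.
    """
    _check_multiclass(train)
    X = train.matrix.values.astype(np.float64)
    y = train.labels
    n = X.shape[0]
    if lambdas is None:
        classes = np.unique(y)
        onehot = (y[:, None] == classes[None, :]).astype(np.float64)
        resid = onehot - onehot.mean(axis=0, keepdims=True)
        lambda_max = float(np.abs(X.T @ resid).max()) / n
        lambda_max = max(lambda_max, 1e-6)
        lambdas = np.geomspace(lambda_max, lambda_max * lambda_min_ratio, n_lambdas)
    lambdas = list(lambdas)
    if any(lam <= 0 for lam in lambdas):
        raise ValueError("lambda values must be positive")
    if any(b >= a for a, b in zip(lambdas, lambdas[1:])):
        raise ValueError("lambda grid must be sorted strictly descending")

    fids = [f.feature_id for f in train.matrix.features]
    clf = LogisticRegression(penalty="l1", solver="saga", warm_start=True,
                             max_iter=max_iter, tol=1e-3, random_state=seed)
    points: list[PathPoint] = []
    for lam in lambdas:
        clf.C = 1.0 / (n * lam)
        converged = True
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always", ConvergenceWarning)
            clf.fit(X, y)
            converged = not any(issubclass(w.category, ConvergenceWarning) for w in caught)
        active = np.flatnonzero(np.any(np.abs(clf.coef_) > 1e-12, axis=0))
        fit = ModelFit(
            model_kind="l1_logreg",
            estimator=copy.deepcopy(clf),
            feature_ids=list(fids),
            params={"lambda": float(lam)},
        )
        points.append(PathPoint(
            lam=float(lam),
            active_feature_ids=[fids[j] for j in active],
            model=fit,
            converged=converged,
        ))
    return RegularizationPath(points)


def _oob_permutation_importance(X: np.ndarray, y: np.ndarray, n_trees: int,
                                rng: np.random.Generator) -> tuple[np.ndarray, float]:
    """Breiman-style permutation importance on out-of-bag samples of a
    bagged forest of sqrt(p)-feature decision trees.

    Returns (per-feature mean accuracy drop over trees, forest OOB error
    from majority vote of OOB predictions)."""
    n, p = X.shape
    importances = np.zeros(p)
    classes = np.unique(y)
    votes = np.zeros((n, len(classes)), dtype=np.int64)
    class_pos = {c: i for i, c in enumerate(classes)}
    n_scored = 0
    for _ in range(n_trees):
        boot = rng.integers(0, n, n)
        oob = np.setdiff1d(np.arange(n), boot, assume_unique=False)
        tree = DecisionTreeClassifier(
            max_features="sqrt", random_state=int(rng.integers(2 ** 31)))
        tree.fit(X[boot], y[boot])
        if oob.size == 0:
            continue
        pred = tree.predict(X[oob])
        for s, c in zip(oob, pred):
            votes[s, class_pos[c]] += 1
        base_acc = float(np.mean(pred == y[oob]))
        used = np.unique(tree.tree_.feature)
        used = used[used >= 0]  # leaves are -2
        for j in used:
            Xp = X[oob].copy()
            Xp[:, j] = Xp[rng.permutation(oob.size), j]
            importances[j] += base_acc - float(np.mean(tree.predict(Xp) == y[oob]))
        n_scored += 1
    if n_scored == 0:
        raise ValueError("no tree had out-of-bag samples; increase sample size")
    importances /= n_scored
    seen = votes.sum(axis=1) > 0
    oob_pred = classes[np.argmax(votes[seen], axis=1)]
    oob_error = float(np.mean(oob_pred != y[seen])) if seen.any() else float("nan")
    return importances, oob_error


def rf_backward_eliminate(train: LabeledDataset, n_trees: int = 1000,
                          drop_fraction: float = 0.2,
                          seed: int = 0) -> FeatureRanking:
    """Backward elimination guided by random-forest permutation importance.

    Importance is computed once on the full feature set (out-of-bag
    permutation, averaged over trees); the least important ``drop_fraction``
    of surviving features is then dropped per iteration, refitting the
    forest each time only to track the out-of-bag error. The ranking is the
    reverse elimination order, i.e. descending initial importance with ties
    broken towards the earlier column.
    """
    _check_multiclass(train)
    if not (0.0 < drop_fraction < 1.0):
        raise ValueError("drop_fraction must lie in (0, 1)")
    if train.matrix.n_features < 2:
        raise ValueError("need at least two features to eliminate")
    X = train.matrix.values.astype(np.float64)
    y = train.labels
    fids = [f.feature_id for f in train.matrix.features]
    rng = np.random.default_rng(seed)
    importances, oob0 = _oob_permutation_importance(X, y, n_trees, rng)

    # descending importance, stable ties -> earlier column first
    order = np.argsort(-importances, kind="stable")
    oob_trace: list[tuple[int, float]] = [(len(fids), oob0)]
    surviving = order.tolist()
    while len(surviving) > 1:
        n_drop = max(1, int(len(surviving) * drop_fraction))
        if n_drop >= len(surviving):
            n_drop = len(surviving) - 1
        surviving = surviving[:-n_drop]
        _, oob = _oob_permutation_importance(X[:, surviving], y, n_trees, rng)
        oob_trace.append((len(surviving), oob))

    return FeatureRanking(
        feature_ids=[fids[j] for j in order],
        importances=[float(importances[j]) for j in order],
        method="rf_backward",
        seed=seed,
        provenance={"n_trees": n_trees, "drop_fraction": drop_fraction,
                    "oob_trace": oob_trace},
    )


def random_baseline(class_counts: Sequence[int] | dict[int, int],
                    n_predictions: int, seed: int = 0) -> np.ndarray:
    """Chance predictions: i.i.d. class draws with probabilities
    proportional to training-class sizes. Against labels drawn from the
    same distribution the expected accuracy is sum_i p_i^2."""
    if isinstance(class_counts, dict):
        classes = np.array(sorted(class_counts))
        counts = np.array([class_counts[c] for c in classes], dtype=np.float64)
    else:
        counts = np.asarray(class_counts, dtype=np.float64)
        classes = np.arange(1, len(counts) + 1)
    if (counts <= 0).any():
        raise ValueError("class counts must be positive")
    p = counts / counts.sum()
    rng = np.random.default_rng(seed)
    return rng.choice(classes, size=n_predictions, p=p)
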