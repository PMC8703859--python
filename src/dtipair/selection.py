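"""Recursive feature elimination with cross-validated subset scoring.

Within each stratified CV fold, the ranking kernel is fit on the training
split, the current feature subset is scored by balanced accuracy on the
held-out split, and the ``step`` weakest features (by the training-split
ranking) are dropped — down to a single feature. Mean test score per subset
size, averaged over the k folds, selects the winning size (ties go to the
smaller size). The elimination is then repeated on the full data to name
the selected set at that size, and the kernel is refit on it to expose
signed importances. Keeping the held-out split out of each fold's ranking
is what makes the per-size scores honest: on label-free data they hover at
chance instead of inflating.

Four ranking kernels are supported: a linear SVM (LSVM), a random forest
(RF), and l1- / l2-penalized logistic regression (LR1 / LR2). Linear kernels
rank by absolute coefficient; the forest by impurity-based importance.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator, clone
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import LinearSVC

__all__ = [
    "KERNEL_IDS",
    "SelectionResult",
    "balanced_accuracy",
    "make_kernel",
    "kernel_importances",
    "rank_features",
    "rfe_path",
    "select_best",
    "run_rfecv",
    "RFECVSelector",
]

KERNEL_IDS = ("lsvm", "rf", "lr1", "lr2")


def balanced_accuracy(y_true, y_pred) -> float:
    """Mean per-class recall: 0.5 * (TP/(TP+FN) + TN/(TN+FP)) for binary y.

    If a class is absent from ``y_true`` its recall is undefined; the score
    is then the mean recall over the classes actually present, with a
    warning. Empty input is an error.
    """
    y_true = np.asarray(y_true).ravel()
    y_pred = np.asarray(y_pred).ravel()
    if y_true.size == 0:
        raise ValueError("empty input")
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred differ in length")
    classes = np.unique(y_true)
    if classes.size < 2:
        warnings.warn(
            "only one class present in y_true; balanced accuracy computed on it alone",
            stacklevel=2,
        )
    recalls = [
        float(np.mean(y_pred[y_true == c] == c)) for c in classes
    ]
    return float(np.mean(recalls))


def make_kernel(kernel: str, seed: int = 0) -> BaseEstimator:
    """Instantiate a ranking kernel by id."""
    kernel = kernel.lower()
    if kernel == "lsvm":
        return LinearSVC(C=1.0, dual=True, max_iter=20000, random_state=seed)
    if kernel == "rf":
        return RandomForestClassifier(n_estimators=100, random_state=seed, n_jobs=1)
    if kernel == "lr1":
        return LogisticRegression(
            penalty="l1", solver="liblinear", C=1.0, max_iter=5000, random_state=seed
        )
    if kernel == "lr2":
        return LogisticRegression(
            penalty="l2", solver="lbfgs", C=1.0, max_iter=5000, random_state=seed
        )
    raise ValueError(f"unknown kernel {kernel!r}; choose from {KERNEL_IDS}")


def kernel_importances(fitted: BaseEstimator) -> tuple[np.ndarray, bool]:
    """(importance, signed) for a fitted kernel: absolute coefficients for
    linear models (signed values retrievable from coef_), impurity importance
    for forests (unsigned)."""
    if hasattr(fitted, "coef_"):
        return np.abs(np.asarray(fitted.coef_).ravel()), True
    if hasattr(fitted, "feature_importances_"):
        return np.asarray(fitted.feature_importances_, dtype=float), False
    raise ValueError(f"no importance rule for {type(fitted).__name__}")


def rank_features(kernel: BaseEstimator | str, X, y, seed: int = 0) -> np.ndarray:
    """Feature indices ordered most- to least-important.

    Ties break toward the smaller feature index, making the order a strict
    total order (and the elimination deterministic).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).ravel()
    if np.unique(y).size < 2:
        raise ValueError("need both classes to rank features")
    est = make_kernel(kernel, seed) if isinstance(kernel, str) else clone(kernel)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        est.fit(X, y)
    imp, _ = kernel_importances(est)
    # descending importance, ascending index among ties
    return np.lexsort((np.arange(imp.size), -imp))


def _visited_sizes(n_features: int, step: int) -> list[int]:
    """Subset sizes the elimination passes through: p, p-step, ..., 1."""
    sizes = [n_features]
    while sizes[-1] > 1:
        sizes.append(max(1, sizes[-1] - step))
    return sizes


def _eliminate(
    est: BaseEstimator,
    X: np.ndarray,
    y: np.ndarray,
    step: int,
    score_on: tuple[np.ndarray, np.ndarray] | None = None,
) -> tuple[dict[int, np.ndarray], dict[int, float]]:
    """One elimination run fit on (X, y).

    Returns ({size: active indices}, {size: held-out score}). Each visited
    size fits the kernel once; the same fit provides the held-out score (if
    ``score_on`` supplies test data) and the ranking used to drop the
    ``step`` weakest features. Ties in importance break toward the smaller
    feature index.
    """
    active = np.arange(X.shape[1])
    subsets: dict[int, np.ndarray] = {}
    scores: dict[int, float] = {}
    while True:
        model = clone(est)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model.fit(X[:, active], y)
        subsets[active.size] = active.copy()
        if score_on is not None:
            X_test, y_test = score_on
            scores[active.size] = balanced_accuracy(
                y_test, model.predict(X_test[:, active])
            )
        if active.size == 1:
            break
        imp, _ = kernel_importances(model)
        order = np.lexsort((np.arange(imp.size), -imp))
        keep = order[: max(1, active.size - step)]
        active = np.sort(active[keep])
    return subsets, scores


def rfe_path(
    kernel: str,
    X,
    y,
    step: int = 1,
    k: int = 10,
    seed: int = 0,
) -> list[dict]:
    """The elimination path: one record per visited subset size.

    Each record holds ``size``, the ``mean``/``sd`` over the k stratified
    folds of the held-out balanced accuracy at that size, and the active
    feature ``indices`` from the full-data elimination. Within each fold
    the elimination (ranking and dropping) sees only the training split, so
    the per-size scores carry no selection leakage; the full-data
    elimination only names the features at each size.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).ravel()
    if step < 1:
        raise ValueError("step must be >= 1")
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > X.shape[0]:
        raise ValueError(f"k={k} exceeds the {X.shape[0]} subjects")
    est = make_kernel(kernel, seed)
    sizes = _visited_sizes(X.shape[1], step)

    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    per_size: dict[int, list[float]] = {s: [] for s in sizes}
    for train, test in skf.split(X, y):
        _, fold_scores = _eliminate(
            est, X[train], y[train], step, score_on=(X[test], y[test])
        )
        for s in sizes:
            per_size[s].append(fold_scores[s])

    subsets, _ = _eliminate(est, X, y, step)
    path: list[dict] = []
    for s in sizes:
        arr = np.asarray(per_size[s])
        path.append(
            {
                "size": s,
                "mean": float(arr.mean()),
                "sd": float(arr.std(ddof=0)),
                "indices": subsets[s],
            }
        )
    return path


@dataclass
class SelectionResult:
    """Outcome of one RFE-CV run."""

    kernel: str
    step: int
    k: int
    seed: int
    sizes: np.ndarray
    means: np.ndarray
    sds: np.ndarray
    n_selected: int
    selected_indices: np.ndarray
    feature_names: list[str] = field(default_factory=list)
    coefficients: np.ndarray | None = None
    signed: bool = True

    def __post_init__(self) -> None:
        self.sizes = np.asarray(self.sizes, dtype=int)
        self.means = np.asarray(self.means, dtype=float)
        self.sds = np.asarray(self.sds, dtype=float)
        self.selected_indices = np.asarray(self.selected_indices, dtype=int)
        if self.selected_indices.size != self.n_selected:
            raise ValueError("n_selected does not match index count")
        if np.unique(self.selected_indices).size != self.n_selected:
            raise ValueError("selected indices must be unique")
        if not np.all(np.diff(self.selected_indices) > 0):
            raise ValueError("selected indices must be sorted ascending")

    @property
    def best_score(self) -> float:
        return float(self.means[self.sizes == self.n_selected][0])

    def to_json(self, path: str | Path) -> None:
        payload = {
            "kernel": self.kernel,
            "step": self.step,
            "k": self.k,
            "seed": self.seed,
            "path": [
                {"size": int(s), "mean": float(m), "sd": float(d)}
                for s, m, d in zip(self.sizes, self.means, self.sds)
            ],
            "n_selected": int(self.n_selected),
            "selected_indices": self.selected_indices.tolist(),
            "feature_names": self.feature_names,
            "coefficients": None if self.coefficients is None else self.coefficients.tolist(),
            "signed": self.signed,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    @classmethod
    def from_json(cls, path: str | Path) -> "SelectionResult":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            kernel=d["kernel"],
            step=d["step"],
            k=d["k"],
            seed=d["seed"],
            sizes=[p["size"] for p in d["path"]],
            means=[p["mean"] for p in d["path"]],
            sds=[p["sd"] for p in d["path"]],
            n_selected=d["n_selected"],
            selected_indices=d["selected_indices"],
            feature_names=d.get("feature_names", []),
            coefficients=None if d.get("coefficients") is None else np.asarray(d["coefficients"]),
            signed=d.get("signed", True),
        )


def select_best(
    path: list[dict],
    kernel: str = "lsvm",
    step: int = 1,
    k: int = 10,
    seed: int = 0,
    X=None,
    y=None,
    feature_names: list[str] | None = None,
) -> SelectionResult:
    """Pick the subset size with the best mean CV score (ties -> smallest n).

    If X and y are given, the kernel is refit on the winning subset over all
    data to provide final (signed, for linear kernels) importances.
    """
    if not path:
        raise ValueError("empty path")
    sizes = np.array([rec["size"] for rec in path])
    means = np.array([rec["mean"] for rec in path])
    best_mean = means.max()
    candidates = sizes[means >= best_mean - 1e-15]
    chosen_size = int(candidates.min())
    chosen = next(rec for rec in path if rec["size"] == chosen_size and rec["mean"] >= best_mean - 1e-15)
    selected = np.sort(np.asarray(chosen["indices"], dtype=int))

    coefficients = None
    signed = True
    if X is not None and y is not None:
        est = make_kernel(kernel, seed)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            est.fit(np.asarray(X, dtype=float)[:, selected], np.asarray(y).ravel())
        if hasattr(est, "coef_"):
            coefficients = np.asarray(est.coef_).ravel().copy()
            signed = True
        else:
            coefficients, signed = kernel_importances(est)
    names = (
        [feature_names[i] for i in selected] if feature_names is not None else []
    )
    return SelectionResult(
        kernel=kernel,
        step=step,
        k=k,
        seed=seed,
        sizes=sizes,
        means=np.array([rec["mean"] for rec in path]),
        sds=np.array([rec["sd"] for rec in path]),
        n_selected=selected.size,
        selected_indices=selected,
        feature_names=names,
        coefficients=coefficients,
        signed=signed,
    )


def run_rfecv(
    kernel: str,
    X,
    y,
    step: int = 1,
    k: int = 10,
    seed: int = 0,
    feature_names: list[str] | None = None,
) -> SelectionResult:
    """Convenience wrapper: rfe_path then select_best with a final refit."""
    path = rfe_path(kernel, X, y, step=step, k=k, seed=seed)
    return select_best(path, kernel=kernel, step=step, k=k, seed=seed,
                       X=X, y=y, feature_names=feature_names)


class RFECVSelector(BaseEstimator):
    """sklearn-style selector around the RFE-CV procedure.

    Parameters
    ----------
    kernel : {"lsvm", "rf", "lr1", "lr2"}
        Ranking kernel.
    step : int
        Features removed per elimination round.
    cv : int
        Stratified fold count for subset scoring.
    random_state : int
        Seed for folds and kernel randomness.

    Attributes
    ----------
    support_ : boolean mask of selected features.
    n_features_ : selected feature count.
    result_ : the full :class:`SelectionResult`.
    """

    def __init__(self, kernel: str = "lsvm", step: int = 1, cv: int = 10,
                 random_state: int = 0):
        self.kernel = kernel
        self.step = step
        self.cv = cv
        self.random_state = random_state

    def fit(self, X, y, feature_names: list[str] | None = None):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y).ravel()
        self.result_ = run_rfecv(
            self.kernel, X, y, step=self.step, k=self.cv,
            seed=self.random_state, feature_names=feature_names,
        )
        self.n_features_in_ = X.shape[1]
        self.support_ = np.zeros(X.shape[1], dtype=bool)
        self.support_[self.result_.selected_indices] = True
        self.n_features_ = int(self.support_.sum())
        return self

    def get_support(self, indices: bool = False):
        return np.flatnonzero(self.support_) if indices else self.support_

    def transform(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.support_.size:
            raise ValueError("X width does not match fitted feature count")
        return X[:, self.support_]

    def fit_transform(self, X, y, **fit_params):
        return self.fit(X, y, **fit_params).transform(X)
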