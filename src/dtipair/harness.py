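"""Grid-searched training and k-fold evaluation of the classifier battery.

Eight classifier families are evaluated on the selected features: linear SVM
(lsvm), logistic regression (lr), passive-aggressive (pagg), kernel SVM
(rbfsvm), Gaussian naive Bayes (gnb), random forest (rf), gradient boosting
(xgb) and a multilayer perceptron (nn). The classifiers themselves are
off-the-shelf scikit-learn / xgboost estimators behind a uniform adapter;
the folding, balanced-accuracy scoring, grid search and report layout are
this package's own.

Hyper-parameter search runs an exhaustive grid with stratified k-fold
(default k=5) mean balanced accuracy as the criterion; evaluation re-splits
with frozen parameters at k in {2, 4, 5, 10}, reporting mean +/- sd balanced
accuracy and a pooled AUC from continuous decision scores where the model
provides them (predicted labels otherwise, flagged).
"""

from __future__ import annotations

import itertools
import json
import warnings
from dataclasses import dataclass, field, asdict
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from sklearn.base import BaseEstimator, clone
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression, PassiveAggressiveClassifier
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC, LinearSVC

from .selection import SelectionResult, balanced_accuracy

__all__ = [
    "CLASSIFIER_IDS",
    "GridSearchReport",
    "build_classifier",
    "default_grids",
    "fixed_params",
    "grid_search",
    "cross_validate",
    "run_all",
]

CLASSIFIER_IDS = ("lsvm", "lr", "pagg", "rbfsvm", "gnb", "rf", "xgb", "nn")

DEFAULT_KS = (2, 4, 5, 10)

# MLP training-epoch cap; bounded desk runtime on small cohorts
NN_MAX_ITER = 400


def _load_packaged_yaml(name: str) -> dict:
    source = resources.files("dtipair.data").joinpath(name)
    with resources.as_file(source) as p, open(p) as fh:
        return yaml.safe_load(fh)


def default_grids(path: str | Path | None = None) -> dict:
    """The per-classifier hyper-parameter grids (packaged YAML by default)."""
    if path is not None:
        with open(path) as fh:
            return yaml.safe_load(fh)
    return _load_packaged_yaml("grids.yaml")


def fixed_params(path: str | Path | None = None) -> dict:
    """Frozen best-parameter sets for re-split evaluation runs."""
    if path is not None:
        with open(path) as fh:
            return yaml.safe_load(fh)
    return _load_packaged_yaml("fixed_params.yaml")


def build_classifier(classifier: str, params: dict | None = None, seed: int = 0) -> BaseEstimator:
    """Instantiate a classifier family with the given parameters.

    Raises ValueError for unknown families; invalid parameter combinations
    surface when sklearn validates them at fit time (the grid search treats
    those as skippable).
    """
    classifier = classifier.lower()
    p = dict(params or {})
    if classifier == "lsvm":
        penalty = p.pop("penalty", "l2")
        loss = p.pop("loss", "squared_hinge")
        # hinge loss needs the dual solver, l1 penalty the primal; the
        # impossible l1+hinge combination fails sklearn validation and is
        # skipped by the grid search
        return LinearSVC(penalty=penalty, loss=loss, dual=(loss == "hinge"),
                         max_iter=20000, random_state=seed, **p)
    if classifier == "lr":
        penalty = p.pop("penalty", "l2")
        if penalty == "elasticnet":
            p.setdefault("l1_ratio", 0.5)
        return LogisticRegression(penalty=penalty, max_iter=5000, random_state=seed, **p)
    if classifier == "pagg":
        return PassiveAggressiveClassifier(random_state=seed, **p)
    if classifier == "rbfsvm":
        return SVC(random_state=seed, **p)
    if classifier == "gnb":
        return GaussianNB(**p)
    if classifier == "rf":
        return RandomForestClassifier(random_state=seed, n_jobs=1, **p)
    if classifier == "xgb":
        from xgboost import XGBClassifier

        return XGBClassifier(random_state=seed, n_jobs=1, eval_metric="logloss", **p)
    if classifier == "nn":
        hls = p.pop("hidden_layer_sizes", (100,))
        if isinstance(hls, list):
            hls = tuple(hls)
        return MLPClassifier(hidden_layer_sizes=hls, max_iter=NN_MAX_ITER,
                             random_state=seed, **p)
    raise ValueError(f"unknown classifier {classifier!r}; choose from {CLASSIFIER_IDS}")


def _decision_scores(model: BaseEstimator, X: np.ndarray) -> tuple[np.ndarray, str]:
    """Continuous scores for AUC, with provenance flag."""
    if hasattr(model, "decision_function"):
        try:
            return np.asarray(model.decision_function(X), dtype=float).ravel(), "decision_function"
        except Exception:  # pragma: no cover - rare fit-state issues
            pass
    if hasattr(model, "predict_proba"):
        return np.asarray(model.predict_proba(X))[:, 1], "predict_proba"
    return np.asarray(model.predict(X), dtype=float), "labels"


@dataclass
class GridSearchReport:
    """One classifier's evaluation: best parameters and per-fold scores."""

    classifier: str
    k: int
    seed: int
    best_params: dict
    fold_scores: list[float]
    mean: float
    sd: float
    auc: float
    auc_source: str = "decision_function"
    n_configs: int = 1
    n_skipped: int = 0
    skipped_folds: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        scores = np.asarray(self.fold_scores, dtype=float)
        if abs(scores.mean() - self.mean) > 1e-12 or abs(scores.std(ddof=0) - self.sd) > 1e-12:
            raise ValueError("stored mean/sd do not match fold scores")

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, default=str)


def cross_validate(
    classifier: str,
    params: dict,
    X,
    y,
    k: int = 5,
    seed: int = 0,
    selector=None,
) -> GridSearchReport:
    """Stratified k-fold evaluation of one fixed-parameter classifier.

    Returns per-fold balanced accuracies and a pooled AUC over the
    concatenated test-fold scores. A fold whose training split lacks a class
    is skipped with a warning and recorded. If ``selector`` is given (an
    unfitted RFECVSelector), feature selection is redone inside each
    training fold — the fully nested, selection-bias-free protocol.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).ravel()
    if not 2 <= k <= X.shape[0]:
        raise ValueError(f"k={k} out of range for {X.shape[0]} subjects")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    fold_scores: list[float] = []
    skipped: list[int] = []
    all_scores: list[np.ndarray] = []
    all_true: list[np.ndarray] = []
    auc_source = "labels"
    for fold, (train, test) in enumerate(skf.split(X, y)):
        if np.unique(y[train]).size < 2:
            warnings.warn(f"fold {fold} lacks both classes; skipped", stacklevel=2)
            skipped.append(fold)
            continue
        Xtr, Xte = X[train], X[test]
        if selector is not None:
            sel = clone(selector).fit(Xtr, y[train])
            Xtr, Xte = sel.transform(Xtr), sel.transform(Xte)
        model = build_classifier(classifier, params, seed)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model.fit(Xtr, y[train])
        fold_scores.append(balanced_accuracy(y[test], model.predict(Xte)))
        scores, auc_source = _decision_scores(model, Xte)
        all_scores.append(scores)
        all_true.append(y[test])
    if not fold_scores:
        raise ValueError("no usable folds")
    pooled_true = np.concatenate(all_true)
    pooled_scores = np.concatenate(all_scores)
    auc = float(roc_auc_score(pooled_true, pooled_scores)) if np.unique(pooled_true).size == 2 else float("nan")
    arr = np.asarray(fold_scores)
    return GridSearchReport(
        classifier=classifier,
        k=k,
        seed=seed,
        best_params=dict(params),
        fold_scores=[float(s) for s in fold_scores],
        mean=float(arr.mean()),
        sd=float(arr.std(ddof=0)),
        auc=auc,
        auc_source=auc_source,
        skipped_folds=skipped,
    )


def _expand_grid(grid: dict) -> list[dict]:
    if not grid:
        return [{}]
    keys = sorted(grid)
    return [dict(zip(keys, combo)) for combo in itertools.product(*(grid[k] for k in keys))]


def grid_search(
    classifier: str,
    grid: dict,
    X,
    y,
    k: int = 5,
    seed: int = 0,
) -> GridSearchReport:
    """Exhaustive grid search scored by mean CV balanced accuracy.

    Configurations the underlying library rejects (incompatible
    solver/penalty/loss combinations) are skipped and counted. Ties between
    configurations break toward the earlier one in the deterministic
    (sorted-key, product-order) enumeration.
    """
    configs = _expand_grid(grid)
    if not configs:
        raise ValueError("empty grid")
    best: GridSearchReport | None = None
    n_skipped = 0
    for params in configs:
        try:
            report = cross_validate(classifier, params, X, y, k=k, seed=seed)
        except (ValueError, TypeError):
            n_skipped += 1
            continue
        if best is None or report.mean > best.mean + 1e-15:
            best = report
    if best is None:
        raise ValueError("every configuration in the grid was invalid")
    best.n_configs = len(configs)
    best.n_skipped = n_skipped
    return best


def run_all(
    X,
    y,
    classifiers: dict | None = None,
    ks: tuple[int, ...] = DEFAULT_KS,
    seed: int = 0,
    selection: SelectionResult | None = None,
) -> dict:
    """Evaluate every classifier family at every fold count.

    ``classifiers`` maps family id -> fixed parameter dict (defaults to the
    packaged frozen set). If ``selection`` is given, X is first restricted
    to its selected columns. Per-classifier failures are recorded, not
    fatal. Returns {"reports": {cid: {k: report}}, "errors": {...}}.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).ravel()
    if selection is not None:
        X = X[:, selection.selected_indices]
    params_by_id = classifiers if classifiers is not None else fixed_params()
    reports: dict[str, dict[int, GridSearchReport]] = {}
    errors: dict[str, str] = {}
    for cid in params_by_id:
        reports[cid] = {}
        for k in ks:
            try:
                reports[cid][k] = cross_validate(cid, params_by_id[cid] or {}, X, y, k=k, seed=seed)
            except Exception as exc:
                errors[f"{cid}@k={k}"] = str(exc)
    return {"reports": reports, "errors": errors}


def tables_from_reports(results: dict, ks: tuple[int, ...] = DEFAULT_KS) -> dict[str, pd.DataFrame]:
    """Render run_all output as the accuracy and AUC matrices
    (classifier rows, one column per k)."""
    reports = results["reports"]
    cols = [f"k={k}" for k in ks]
    acc = pd.DataFrame(index=list(reports), columns=cols, dtype=object)
    auc = pd.DataFrame(index=list(reports), columns=cols, dtype=float)
    for cid, by_k in reports.items():
        for k in ks:
            rep = by_k.get(k)
            if rep is None:
                continue
            acc.loc[cid, f"k={k}"] = f"{rep.mean:.3f} ± {rep.sd:.3f}"
            auc.loc[cid, f"k={k}"] = round(rep.auc, 3)
    return {"balanced_accuracy": acc, "auc": auc}
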