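"""Nine-classifier registry, performance correlation, and stacked ensembles.

The classifier zoo covers logistic regression (LR), k-nearest neighbours
(KNN), a support vector machine (SVM), Gaussian naive Bayes (NB), a decision
tree (DT), random forest (RF), XGBoost (XG), AdaBoost (AB) and extra trees
(ET).  Five canonical stacks combine them:

=======  =========================  =============================
stack    members                    character
=======  =========================  =============================
1        LR, KNN, SVM               hybrid linear/instance stack
2        NB, DT, RF                 tree + probabilistic stack
3        XG, AB, ET                 boosted stack
4        DT, RF, XG, AB, ET         advanced tree-based stack
5        all nine                   unified stack
=======  =========================  =============================

A stack trains every base model, encodes each object as the vector of base
models' hard 0/1 predictions, and fits a meta-classifier (logistic
regression by default) on those meta-features: the final prediction is
``H(h1(x), ..., hn(x))``.  Two meta-feature modes exist: the literal
in-sample mode (meta-features are the base models' training-set
predictions), and a cross-fitted mode where meta-features are out-of-fold
predictions so the meta-learner never sees a base model's fit of its own
row -- the default, since in-sample meta-features optimistically bias the
combiner.
"""

from __future__ import annotations

import time
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.ensemble import (AdaBoostClassifier, ExtraTreesClassifier,
                              RandomForestClassifier)
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold, cross_val_predict
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier
from xgboost import XGBClassifier

from .prep import METRIC_COLUMNS, compute_metrics

__all__ = [
    "CLASSIFIER_IDS",
    "make_classifier",
    "fit_base_models",
    "pearson_correlation",
    "StackDefinition",
    "FittedStack",
    "build_stacks",
    "fit_stack",
    "evaluate_stacks",
]

CLASSIFIER_IDS = ("LR", "KNN", "SVM", "NB", "DT", "RF", "XG", "AB", "ET")


def make_classifier(name: str, seed: int = 0, params: dict | None = None):
    """Instantiate a registry classifier with library-default settings and a
    fixed seed for every stochastic learner."""
    params = dict(params or {})
    factories = {
        "LR": lambda: LogisticRegression(max_iter=1000, random_state=seed,
                                         **params),
        "KNN": lambda: KNeighborsClassifier(**params),
        "SVM": lambda: SVC(random_state=seed, **params),
        "NB": lambda: GaussianNB(**params),
        "DT": lambda: DecisionTreeClassifier(random_state=seed, **params),
        "RF": lambda: RandomForestClassifier(random_state=seed, **params),
        "XG": lambda: XGBClassifier(random_state=seed, eval_metric="logloss",
                                    verbosity=0, **params),
        "AB": lambda: AdaBoostClassifier(random_state=seed, **params),
        "ET": lambda: ExtraTreesClassifier(random_state=seed, **params),
    }
    if name not in factories:
        raise ValueError(
            f"unknown classifier {name!r}; registry: {list(factories)}")
    return factories[name]()


def fit_base_models(X_train, y_train, X_test, y_test, seed: int = 42,
                    config: dict | None = None):
    """Fit all nine registry classifiers and evaluate them on the test split.

    ``config`` maps classifier id to a hyperparameter dict (library defaults
    otherwise).  Returns ``(models, performance)`` where ``performance`` is
    the 9 x 8 metric matrix (one row per model, columns Ac..Tt).
    """
    config = config or {}
    unknown = set(config) - set(CLASSIFIER_IDS)
    if unknown:
        raise ValueError(f"unknown classifier(s) in config: {sorted(unknown)}")
    models: dict = {}
    rows = []
    for name in CLASSIFIER_IDS:
        clf = make_classifier(name, seed=seed, params=config.get(name))
        t0 = time.perf_counter()
        clf.fit(X_train, y_train)
        elapsed = time.perf_counter() - t0
        models[name] = clf
        rec = compute_metrics(y_test, clf.predict(X_test), elapsed, name)
        rows.append(rec.to_row())
    perf = pd.DataFrame(rows).set_index("model")[METRIC_COLUMNS]
    return models, perf


def pearson_correlation(performance: pd.DataFrame,
                        axis: str = "metrics") -> pd.DataFrame:
    """Pearson correlation matrix of a performance table.

    ``axis="models"`` correlates the rows (models across metrics);
    ``axis="metrics"`` correlates the columns (metrics across models).
    Constant vectors get zero correlations (unit diagonal) with a warning.
    """
    if axis not in ("models", "metrics"):
        raise ValueError("axis must be 'models' or 'metrics'")
    M = performance if axis == "metrics" else performance.T
    if M.shape[1] < 2:
        raise ValueError("need at least 2 vectors to correlate")
    ids = list(M.columns)
    X = M.to_numpy(dtype=float)
    sds = X.std(axis=0, ddof=1)
    constant = np.flatnonzero(sds == 0)
    if constant.size:
        warnings.warn(
            f"constant vector(s) {[ids[j] for j in constant]}: "
            "correlations reported as 0", UserWarning, stacklevel=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        C = np.corrcoef(X, rowvar=False)
    C = np.atleast_2d(C)
    C[np.isnan(C)] = 0.0
    np.fill_diagonal(C, 1.0)
    C = np.clip((C + C.T) / 2, -1.0, 1.0)
    return pd.DataFrame(C, index=ids, columns=ids)


@dataclass
class StackDefinition:
    stack_id: int
    base_ids: tuple
    meta_id: str = "LR"
    cross_fit: bool = True

    def __post_init__(self) -> None:
        if not self.base_ids:
            raise ValueError("a stack needs at least one base classifier")
        unknown = set(self.base_ids) - set(CLASSIFIER_IDS)
        if unknown:
            raise ValueError(
                f"stack {self.stack_id}: unknown model(s) {sorted(unknown)}; "
                f"registry: {list(CLASSIFIER_IDS)}")
        self.base_ids = tuple(self.base_ids)


_CANONICAL_STACKS = {
    1: ("LR", "KNN", "SVM"),
    2: ("NB", "DT", "RF"),
    3: ("XG", "AB", "ET"),
    4: ("DT", "RF", "XG", "AB", "ET"),
    5: CLASSIFIER_IDS,
}


def build_stacks(config: dict | None = None,
                 correlation: pd.DataFrame | None = None):
    """The five canonical stack definitions, with optional membership
    overrides (``config = {stack_id: [model ids]}``) and an advisory report
    of mean within-stack correlation when a model-axis correlation matrix is
    supplied.  Correlations are advisory only; memberships are fixed lists.
    """
    config = config or {}
    stacks = []
    advisory: dict = {}
    for sid in range(1, 6):
        members = tuple(config.get(sid, _CANONICAL_STACKS[sid]))
        defn = StackDefinition(sid, members)
        stacks.append(defn)
        note = []
        if len(members) == 1:
            note.append("singleton stack: meta-learner adds nothing")
        if correlation is not None and len(members) > 1:
            present = [m for m in members if m in correlation.index]
            if len(present) > 1:
                sub = correlation.loc[present, present].to_numpy()
                off = sub[~np.eye(len(present), dtype=bool)]
                mean_r = float(off.mean())
                advisory[sid] = {"mean_within_correlation": mean_r}
                if mean_r > 0.9:
                    note.append("high within-stack correlation; "
                                "limited error diversity")
        if note:
            advisory.setdefault(sid, {})["notes"] = note
    return stacks, advisory


@dataclass
class FittedStack:
    """A trained stack: fitted base models plus the fitted meta-classifier."""

    definition: StackDefinition
    base_models: dict
    meta_model: object
    seed: int
    fit_time: float
    meta_feature_mode: str = "label"
    #: the matrix the meta-classifier was trained on (out-of-fold base
    #: predictions when cross-fitted, in-sample ones otherwise)
    meta_training_features: np.ndarray | None = None

    def _meta_features(self, X) -> np.ndarray:
        cols = [_base_output(self.base_models[m], X, self.meta_feature_mode)
                for m in self.definition.base_ids]
        return np.column_stack(cols)

    def predict(self, X) -> np.ndarray:
        return np.asarray(self.meta_model.predict(self._meta_features(X)),
                          dtype=int)


def _base_output(model, X, mode: str) -> np.ndarray:
    """A base model's meta-feature column: hard labels or a score."""
    if mode == "label":
        return np.asarray(model.predict(X), dtype=float)
    if hasattr(model, "predict_proba"):
        return np.asarray(model.predict_proba(X))[:, 1]
    return np.asarray(model.decision_function(X), dtype=float)


def _oof_output(clf, X, y, cv, mode: str) -> np.ndarray:
    if mode == "label":
        return np.asarray(cross_val_predict(clf, X, y, cv=cv,
                                            method="predict"), dtype=float)
    if hasattr(clf, "predict_proba"):
        return np.asarray(cross_val_predict(clf, X, y, cv=cv,
                                            method="predict_proba"))[:, 1]
    return np.asarray(cross_val_predict(clf, X, y, cv=cv,
                                        method="decision_function"),
                      dtype=float)


def fit_stack(defn: StackDefinition, X_train, y_train, seed: int = 42,
              config: dict | None = None, folds: int = 5,
              meta_features: str = "label") -> FittedStack:
    """Train a stack on ``(X_train, y_train)``.

    With ``defn.cross_fit`` the meta-features for each training row come
    from base models fitted with that row's fold held out (stratified
    ``folds``-fold); otherwise they are the base models' in-sample training
    predictions (the literal, leakage-prone procedure).  Base models are
    always refitted on the full training set for prediction time.
    ``meta_features`` selects hard 0/1 labels (default) or probability
    scores as the meta-encoding.
    """
    if meta_features not in ("label", "proba"):
        raise ValueError("meta_features must be 'label' or 'proba'")
    y = np.asarray(y_train)
    if len(np.unique(y)) < 2:
        raise ValueError("training labels contain a single class")
    config = config or {}
    t0 = time.perf_counter()
    base_models = {}
    meta_cols = []
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    for name in defn.base_ids:
        clf = make_classifier(name, seed=seed, params=config.get(name))
        if defn.cross_fit:
            meta_cols.append(_oof_output(clone(clf), X_train, y, cv,
                                         meta_features))
        clf.fit(X_train, y)
        base_models[name] = clf
        if not defn.cross_fit:
            meta_cols.append(_base_output(clf, X_train, meta_features))
    meta_X = np.column_stack(meta_cols)
    meta = make_classifier(defn.meta_id, seed=seed)
    meta.fit(meta_X, y)
    elapsed = time.perf_counter() - t0
    return FittedStack(defn, base_models, meta, seed, elapsed,
                       meta_feature_mode=meta_features,
                       meta_training_features=meta_X)


def evaluate_stacks(stacks, X_test, y_test) -> pd.DataFrame:
    """Metric matrix (one row per fitted stack, columns Ac..Tt) on a shared
    test split; the Tt column is each stack's recorded training time."""
    rows = []
    for fs in stacks:
        rec = compute_metrics(y_test, fs.predict(X_test), fs.fit_time,
                              f"Stack-{fs.definition.stack_id}")
        rows.append(rec.to_row())
    return pd.DataFrame(rows).set_index("model")[METRIC_COLUMNS]
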