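"""Grid-search refinement of a stack's members and best-classifier selection.

Each member of the winning stack is tuned by exhaustive grid search with
k-fold cross-validated accuracy; the member with the highest validation
score becomes the selected classifier.  Grids are small, conventional
ranges shipped as defaults and fully overridable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import GridSearchCV, StratifiedKFold

from .prep import METRIC_COLUMNS, PerformanceRecord, compute_metrics
from .stacking import StackDefinition, make_classifier

__all__ = ["GridSpec", "TunedResult", "DEFAULT_GRIDS", "grid_search",
           "select_best_classifier"]

#: conventional small grids per registry model (overridable)
DEFAULT_GRIDS: dict = {
    "LR": {"C": [0.1, 1.0, 10.0]},
    "KNN": {"n_neighbors": [3, 5, 11]},
    "SVM": {"C": [0.1, 1.0, 10.0]},
    "NB": {"var_smoothing": [1e-9, 1e-7]},
    "DT": {"max_depth": [3, 5, 10, None]},
    "RF": {"max_depth": [3, 5, 10, None], "n_estimators": [100, 300]},
    "ET": {"max_depth": [3, 5, 10, None], "n_estimators": [100, 300]},
    "XG": {"learning_rate": [0.01, 0.1, 0.3], "max_depth": [3, 6],
           "reg_lambda": [0.0, 1.0, 10.0]},
    "AB": {"n_estimators": [50, 200], "learning_rate": [0.1, 1.0]},
}


@dataclass
class GridSpec:
    model_id: str
    grid: dict

    def __post_init__(self) -> None:
        if not self.grid or any(len(v) == 0 for v in self.grid.values()):
            raise ValueError("every grid value list must be non-empty")

    @property
    def size(self) -> int:
        out = 1
        for v in self.grid.values():
            out *= len(v)
        return out


@dataclass
class TunedResult:
    model_id: str
    best_params: dict
    cv_score: float
    test_record: PerformanceRecord | None = None
    search_log: pd.DataFrame | None = field(default=None, repr=False)


def grid_search(model_id: str, grid: GridSpec | dict, X_train, y_train,
                folds: int = 5, seed: int = 42,
                X_test=None, y_test=None) -> TunedResult:
    """Exhaustive grid search by ``folds``-fold CV mean accuracy.

    Ties are broken by grid iteration order.  The winner is refitted on the
    full training set and, when a test split is supplied, evaluated into
    ``test_record``.  Unknown parameter names raise before any fitting.
    """
    if folds < 2:
        raise ValueError("folds must be >= 2")
    spec = grid if isinstance(grid, GridSpec) else GridSpec(model_id, grid)
    est = make_classifier(model_id, seed=seed)
    known = set(est.get_params())
    unknown = set(spec.grid) - known
    if unknown:
        raise ValueError(
            f"unknown hyperparameter(s) for {model_id}: {sorted(unknown)}")

    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    gs = GridSearchCV(est, spec.grid, scoring="accuracy", cv=cv, refit=True)
    gs.fit(X_train, y_train)
    rows = []
    for i, params in enumerate(gs.cv_results_["params"]):
        for k in range(folds):
            rows.append({
                "params": params, "fold": k,
                "accuracy": gs.cv_results_[f"split{k}_test_score"][i],
                "mean_cv_accuracy": gs.cv_results_["mean_test_score"][i],
            })
    log = pd.DataFrame(rows)
    record = None
    if X_test is not None and y_test is not None:
        import time
        t0 = time.perf_counter()
        refit = make_classifier(model_id, seed=seed,
                                params=gs.best_params_).fit(X_train, y_train)
        elapsed = time.perf_counter() - t0
        record = compute_metrics(y_test, refit.predict(X_test), elapsed,
                                 model_id)
    return TunedResult(model_id, dict(gs.best_params_),
                       float(gs.best_score_), record, log)


def select_best_classifier(stack: StackDefinition, grids: dict | None,
                           X_train, y_train, X_test, y_test,
                           folds: int = 5, seed: int = 42):
    """Tune every member of ``stack`` and pick the best.

    The member with the highest CV accuracy wins; exact ties fall back to
    the test metrics in lexicographic order (Ac, F1, MCC, -MAE, -Tt).
    Returns ``(winner, comparison)`` with ``comparison`` the per-member
    metric table (columns Ac..Tt).
    """
    if not stack.base_ids:
        raise ValueError("empty stack")
    grids = grids or {}
    results: list[TunedResult] = []
    for name in stack.base_ids:
        g = grids.get(name, DEFAULT_GRIDS[name])
        results.append(grid_search(name, GridSpec(name, g), X_train, y_train,
                                   folds=folds, seed=seed,
                                   X_test=X_test, y_test=y_test))

    def sort_key(r: TunedResult):
        rec = r.test_record
        return (-r.cv_score, -rec.Ac, -rec.F1, -rec.MCC, rec.MAE, rec.Tt)

    winner = min(results, key=sort_key)
    comparison = pd.DataFrame(
        [r.test_record.to_row() for r in results]).set_index("model")
    comparison = comparison[METRIC_COLUMNS]
    comparison["cv_score"] = [r.cv_score for r in results]
    comparison["best_params"] = [repr(r.best_params) for r in results]
    return winner, comparison
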