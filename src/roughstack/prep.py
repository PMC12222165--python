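"""Scaling, splitting, confusion-matrix metrics and paired model comparison.

Metrics follow the usual binary-classification definitions from the
confusion counts (TP, FP, TN, FN): accuracy, precision, sensitivity
(recall), specificity, F1, Matthews correlation coefficient, and the mean
absolute error of the hard labels (which equals 1 - accuracy for 0/1
predictions).  Training time is carried along as a criterion for the
downstream multi-criteria ranking but never enters exact checks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import train_test_split

__all__ = [
    "ScaledMatrix",
    "SplitIndices",
    "PerformanceRecord",
    "METRIC_COLUMNS",
    "standard_scale",
    "split",
    "compute_metrics",
    "paired_compare",
]

#: canonical metric column order used by every performance table
METRIC_COLUMNS = ["Ac", "Pr", "Sp", "Sn", "F1", "MCC", "MAE", "Tt"]


@dataclass
class ScaledMatrix:
    """A z-scored matrix together with the location/scale used."""

    values: np.ndarray
    means: np.ndarray
    sds: np.ndarray
    columns: list | None = None

    def inverse(self) -> np.ndarray:
        """Undo the scaling: x = z * s + mean."""
        return self.values * self.sds + self.means


@dataclass
class SplitIndices:
    train_idx: np.ndarray
    test_idx: np.ndarray
    seed: int
    test_fraction: float


def standard_scale(train, test=None):
    """Z-score ``train`` columns and apply the same transform to ``test``.

    The mean and standard deviation (population convention, divisor ``n``)
    are computed on the training matrix only.  A zero-variance training
    column raises, naming the column, so the caller can drop it.
    Returns one :class:`ScaledMatrix` (or a pair when ``test`` is given).
    """
    columns = list(train.columns) if isinstance(train, pd.DataFrame) else None
    X = np.asarray(train, dtype=float)
    if X.ndim != 2:
        raise ValueError("train must be a 2-D matrix")
    means = X.mean(axis=0)
    sds = X.std(axis=0, ddof=0)
    zero = np.flatnonzero(sds == 0)
    if zero.size:
        names = [columns[j] if columns else j for j in zero]
        raise ValueError(f"zero-variance column(s) in training data: {names}")
    scaled_train = ScaledMatrix((X - means) / sds, means, sds, columns)
    if test is None:
        return scaled_train
    T = np.asarray(test, dtype=float)
    if T.ndim == 1:
        T = T.reshape(1, -1)
    scaled_test = ScaledMatrix((T - means) / sds, means, sds, columns)
    return scaled_train, scaled_test


def split(n: int, test_fraction: float = 0.2, seed: int = 42,
          labels=None) -> SplitIndices:
    """Random train/test partition of ``range(n)``.

    ``|test| = round(test_fraction * n)``; reproducible from ``seed``.
    ``labels`` enables stratification (off by default).
    """
    if not 0 < test_fraction < 1:
        raise ValueError("test_fraction must be in (0, 1)")
    if n < 5:
        raise ValueError("need at least 5 rows to split")
    n_test = int(round(test_fraction * n))
    if n_test < 1 or n_test >= n:
        raise ValueError(
            f"test_fraction {test_fraction} leaves an empty part for n={n}")
    train_idx, test_idx = train_test_split(
        np.arange(n), test_size=n_test, random_state=seed, shuffle=True,
        stratify=None if labels is None else np.asarray(labels))
    return SplitIndices(np.sort(train_idx), np.sort(test_idx),
                        seed, test_fraction)


@dataclass
class PerformanceRecord:
    """One model's metric vector in the canonical (Ac..Tt) layout."""

    model_id: str
    Ac: float
    Pr: float
    Sp: float
    Sn: float
    F1: float
    MCC: float
    MAE: float
    Tt: float
    warnings: list = field(default_factory=list)

    def to_row(self) -> dict:
        row = {"model": self.model_id}
        row.update({m: getattr(self, m) for m in METRIC_COLUMNS})
        return row

    def values(self) -> list:
        return [getattr(self, m) for m in METRIC_COLUMNS]


def _safe_div(num: float, den: float, name: str, flags: list) -> float:
    if den == 0:
        flags.append(f"{name} undefined (zero denominator); reported as 0")
        return 0.0
    return num / den


def compute_metrics(y_true, y_pred, train_time: float = 0.0,
                    model_id: str = "") -> PerformanceRecord:
    """Confusion-matrix metrics for hard binary labels in {0, 1}.

    Undefined ratios (zero denominators) are reported as 0 with a warning
    flag on the record rather than NaN, so the multi-criteria ranking can
    always ingest the row.
    """
    yt = np.asarray(y_true).astype(int)
    yp = np.asarray(y_pred).astype(int)
    if yt.shape != yp.shape:
        raise ValueError("y_true and y_pred have different lengths")
    if not (np.isin(yt, (0, 1)).all() and np.isin(yp, (0, 1)).all()):
        raise ValueError("labels must be binary in {0, 1}")
    n = yt.size
    tp = int(((yt == 1) & (yp == 1)).sum())
    tn = int(((yt == 0) & (yp == 0)).sum())
    fp = int(((yt == 0) & (yp == 1)).sum())
    fn = int(((yt == 1) & (yp == 0)).sum())

    flags: list = []
    ac = (tp + tn) / n
    pr = _safe_div(tp, tp + fp, "Pr", flags)
    sn = _safe_div(tp, tp + fn, "Sn", flags)
    sp = _safe_div(tn, tn + fp, "Sp", flags)
    f1 = _safe_div(2 * pr * sn, pr + sn, "F1", flags)
    mcc_den = math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    mcc = _safe_div(tp * tn - fp * fn, mcc_den, "MCC", flags)
    mae = float(np.abs(yt - yp).mean())
    return PerformanceRecord(model_id, ac, pr, sp, sn, f1, mcc, mae,
                             float(train_time), flags)


def paired_compare(metric_a, metric_b, test: str = "t"):
    """Two-sided paired comparison of two equal-length metric vectors.

    ``test="t"`` runs the paired t-test, ``test="wilcoxon"`` the exact
    Wilcoxon signed-rank test.  All-zero (or zero-variance, for t)
    differences return ``(0.0, 1.0)`` by convention.
    """
    a = np.asarray(metric_a, dtype=float)
    b = np.asarray(metric_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired vectors must have equal length")
    if a.size < 3:
        raise ValueError("need at least 3 paired observations")
    diffs = a - b
    if test == "t":
        if np.std(diffs, ddof=0) == 0:
            return 0.0, 1.0
        res = stats.ttest_rel(a, b)
        return float(res.statistic), float(res.pvalue)
    if test == "wilcoxon":
        if np.all(diffs == 0):
            return 0.0, 1.0
        res = stats.wilcoxon(a, b, mode="exact" if a.size <= 25 else "auto")
        return float(res.statistic), float(res.pvalue)
    raise ValueError("test must be 't' or 'wilcoxon'")
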