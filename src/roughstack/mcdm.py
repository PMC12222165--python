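"""Objective criteria weighting (MEREC) and ranking (TOPSIS).

MEREC -- MEthod based on the Removal Effects of Criteria -- scores each
criterion by how much deleting it perturbs every alternative's
log-aggregated overall performance:

1. normalize the decision matrix so that smaller values mean better
   performance: ``n = min(x)/x`` for benefit criteria, ``n = x/max(x)`` for
   cost criteria;
2. overall performance ``P_t = ln(1 + mean_r |ln n_tr|)``;
3. recompute ``P'_tr`` with criterion ``r`` removed from the mean;
4. the weight of criterion ``r`` is its total absolute removal effect
   ``Ad_r = sum_t |P'_tr - P_t|``, normalized to sum to one.

TOPSIS then ranks the alternatives by relative closeness
``C_t = S_t^- / (S_t^- + S_t^+)`` to the ideal / anti-ideal points of the
weighted, vector-normalized matrix, where ``S^+``/``S^-`` are Euclidean
separations.  Both methods require a strictly positive matrix; zero cells
are epsilon-shifted on ingest and the shift recorded in provenance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "McdmMatrix",
    "WeightVector",
    "TopsisResult",
    "merec_weights",
    "topsis_rank",
    "rank_stability",
]

_DIRECTIONS = ("benefit", "cost")


@dataclass
class McdmMatrix:
    """Alternatives x criteria matrix with per-criterion directions.

    ``values`` has alternatives as the index and criteria as columns.
    ``directions`` maps every criterion to ``"benefit"`` (larger is better)
    or ``"cost"`` (smaller is better).  Non-positive cells are shifted up by
    ``eps = 1e-6 * column max`` (negative columns are first shifted to be
    non-negative); shifts are recorded in ``provenance``.
    """

    values: pd.DataFrame
    directions: dict
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = self.values.astype(float).copy()
        missing = set(self.values.columns) - set(self.directions)
        if missing:
            raise ValueError(f"criteria without a direction: {sorted(missing)}")
        bad = {c: d for c, d in self.directions.items()
               if c in self.values.columns and d not in _DIRECTIONS}
        if bad:
            raise ValueError(f"directions must be benefit/cost, got {bad}")
        shifts = {}
        for c in self.values.columns:
            col = self.values[c]
            if (col < 0).any():
                delta = -float(col.min())
                self.values[c] = col = col + delta
                shifts[c] = {"affine_shift": delta}
            if (col <= 0).any():
                eps = 1e-6 * float(col.max()) if col.max() > 0 else 1e-6
                self.values[c] = col + eps
                shifts.setdefault(c, {})["epsilon"] = eps
        if shifts:
            self.provenance = dict(self.provenance)
            self.provenance["positivity_shifts"] = shifts

    @property
    def alternative_ids(self) -> list:
        return list(self.values.index)

    @property
    def criterion_ids(self) -> list:
        return list(self.values.columns)

    def cost_mask(self) -> np.ndarray:
        return np.array([self.directions[c] == "cost"
                         for c in self.values.columns])

    @classmethod
    def from_csv(cls, matrix_path, directions_path) -> "McdmMatrix":
        """Read alternatives-as-rows CSV (first column = alternative id) and
        a YAML sidecar mapping criterion name -> benefit/cost."""
        values = pd.read_csv(matrix_path, index_col=0)
        with open(directions_path) as fh:
            directions = yaml.safe_load(fh)
        return cls(values, directions,
                   provenance={"source": str(matrix_path)})


@dataclass
class WeightVector:
    criterion_ids: list
    weights: np.ndarray

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if (self.weights < 0).any():
            raise ValueError("weights must be non-negative")
        if abs(self.weights.sum() - 1.0) > 1e-9:
            raise ValueError("weights must sum to 1")

    def as_series(self) -> pd.Series:
        return pd.Series(self.weights, index=self.criterion_ids)


@dataclass
class TopsisResult:
    closeness: pd.Series
    s_plus: pd.Series
    s_minus: pd.Series
    ranks: pd.Series          # 1 = best
    flags: list = field(default_factory=list)

    @property
    def best(self):
        return self.ranks.idxmin()


def _normalize_merec(X: np.ndarray, cost: np.ndarray) -> np.ndarray:
    # smaller normalized value = better performance, for both directions
    return np.where(cost, X / X.max(axis=0), X.min(axis=0) / X)


def merec_weights(dm: McdmMatrix) -> WeightVector:
    """MEREC criteria weights for a decision matrix.

    The log-mean inside the overall performance divides by the number of
    criteria.  A constant criterion column has no removal effect and weight
    0; if every column is constant the weights are uniform.
    """
    X = dm.values.to_numpy()
    m, n = X.shape
    if m < 2 or n < 2:
        raise ValueError("MEREC needs at least 2 alternatives and 2 criteria")
    N = _normalize_merec(X, dm.cost_mask())
    if (N <= 0).any():
        raise ValueError("normalized matrix must be strictly positive")
    L = np.abs(np.log(N))                       # removal-effect log terms
    P = np.log1p(L.sum(axis=1) / n)
    # P'_tr: overall performance with criterion r's term removed
    P_removed = np.log1p((L.sum(axis=1, keepdims=True) - L) / n)
    Ad = np.abs(P_removed - P[:, None]).sum(axis=0)
    total = Ad.sum()
    if total == 0:
        return WeightVector(dm.criterion_ids, np.full(n, 1.0 / n))
    return WeightVector(dm.criterion_ids, Ad / total)


def topsis_rank(dm: McdmMatrix, w: WeightVector) -> TopsisResult:
    """Rank alternatives by TOPSIS relative closeness under weights ``w``.

    Vector normalization, direction-aware ideal/anti-ideal points and
    Euclidean separations.  Higher closeness ranks earlier; exact ties are
    broken by alternative order and flagged.  If all alternatives are
    identical the closeness is 0/0; every alternative then gets 0.5 with a
    degeneracy flag.
    """
    if list(w.criterion_ids) != dm.criterion_ids:
        raise ValueError("weight criteria do not align with the matrix")
    X = dm.values.to_numpy()
    ids = dm.alternative_ids
    cost = dm.cost_mask()
    flags: list = []

    R = X / np.sqrt((X ** 2).sum(axis=0))
    U = R * w.weights
    ideal = np.where(cost, U.min(axis=0), U.max(axis=0))
    anti = np.where(cost, U.max(axis=0), U.min(axis=0))
    s_plus = np.sqrt(((U - ideal) ** 2).sum(axis=1))
    s_minus = np.sqrt(((U - anti) ** 2).sum(axis=1))
    denom = s_plus + s_minus
    if np.all(denom == 0):
        flags.append("degenerate matrix: all alternatives identical")
        closeness = np.full(len(ids), 0.5)
    else:
        closeness = np.where(denom == 0, 0.5, s_minus / np.where(denom == 0, 1, denom))

    order = sorted(range(len(ids)), key=lambda i: (-closeness[i], i))
    ranks = np.empty(len(ids), dtype=int)
    for pos, i in enumerate(order):
        ranks[i] = pos + 1
    rounded = np.round(closeness, 12)
    if len(np.unique(rounded)) < len(ids):
        flags.append("ties in closeness broken by alternative order")
    return TopsisResult(
        pd.Series(closeness, index=ids, name="closeness"),
        pd.Series(s_plus, index=ids, name="s_plus"),
        pd.Series(s_minus, index=ids, name="s_minus"),
        pd.Series(ranks, index=ids, name="rank"),
        flags)


def rank_stability(dm: McdmMatrix, w: WeightVector,
                   perturbation: float = 0.05, reps: int = 200,
                   seed: int = 0) -> pd.Series:
    """Fraction of jittered replicates in which each alternative ranks first.

    Weights and matrix entries are multiplied by independent uniform factors
    in ``1 +/- perturbation`` (weights renormalized) for each replicate.
    """
    if not 0 < perturbation < 0.5:
        raise ValueError("perturbation must be in (0, 0.5)")
    if reps < 10:
        raise ValueError("need at least 10 replicates")
    rng = np.random.default_rng(seed)
    wins = pd.Series(0.0, index=dm.alternative_ids)
    base = dm.values.to_numpy()
    for _ in range(reps):
        jw = w.weights * rng.uniform(1 - perturbation, 1 + perturbation,
                                     len(w.weights))
        jw = jw / jw.sum()
        jX = base * rng.uniform(1 - perturbation, 1 + perturbation, base.shape)
        jdm = McdmMatrix(pd.DataFrame(jX, index=dm.values.index,
                                      columns=dm.values.columns),
                         dm.directions)
        res = topsis_rank(jdm, WeightVector(dm.criterion_ids, jw))
        wins[res.best] += 1
    return wins / reps
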