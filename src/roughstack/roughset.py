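"""Decision tables, discernibility functions and Johnson's greedy reducer.

A decision table holds objects described by condition attributes plus a
categorical decision (class label).  Feature selection proceeds by building
the decision-relative discernibility function -- for every pair of objects
with different decisions, the set of condition attributes on which the pair
differs -- and then finding a small *hitting set* of that clause family.
Johnson's algorithm picks, at each step, the attribute with the largest total
clause weight, removes every clause it hits, and stops when no clause
remains.  An exhaustive enumerator of all inclusion-minimal reducts is
provided as a testing oracle.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DecisionTable",
    "DiscernibilityFunction",
    "Reduct",
    "discretize",
    "build_discernibility",
    "johnson_reduct",
    "enumerate_minimal_reducts",
    "select_features",
]


@dataclass
class DecisionTable:
    """Objects x condition attributes plus a categorical decision column.

    Parameters
    ----------
    data:
        One row per object; must contain ``decision`` as a column.  All other
        columns are condition attributes, in order.
    decision:
        Name of the decision column (default ``"target"``).
    nominal:
        Names of condition attributes to treat as nominal (never binned by
        :func:`discretize`).  Numeric dtypes not listed here are treated as
        continuous measurements.
    provenance:
        Free-form metadata recorded by transformations (bin edges, sources).
    """

    data: pd.DataFrame
    decision: str = "target"
    nominal: frozenset = frozenset()
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.decision not in self.data.columns:
            raise ValueError(f"decision column {self.decision!r} not in table")
        if self.data.columns.duplicated().any():
            dupes = self.data.columns[self.data.columns.duplicated()].tolist()
            raise ValueError(f"duplicate attribute names: {dupes}")
        if self.data.isna().any().any():
            raise ValueError("decision table contains missing values")
        if len(self.data) == 0:
            raise ValueError("decision table has no objects")
        self.nominal = frozenset(self.nominal)
        unknown = self.nominal - set(self.data.columns)
        if unknown:
            raise ValueError(f"nominal attributes not in table: {sorted(unknown)}")

    @property
    def attributes(self) -> list:
        """Condition attribute names, in column order."""
        return [c for c in self.data.columns if c != self.decision]

    @property
    def n_objects(self) -> int:
        return len(self.data)

    @property
    def decision_values(self) -> pd.Series:
        return self.data[self.decision]

    def conditions(self) -> pd.DataFrame:
        return self.data[self.attributes]

    @classmethod
    def from_csv(cls, path, decision: str = "target",
                 nominal: Iterable = ()) -> "DecisionTable":
        df = pd.read_csv(path)
        return cls(df, decision=decision, nominal=frozenset(nominal),
                   provenance={"source": str(path)})

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)


@dataclass
class DiscernibilityFunction:
    """Weighted family of attribute-name sets to be hit by a reduct.

    ``clauses`` maps each non-empty frozenset of attribute names to a
    positive weight (the number of discerning cross-class object pairs that
    produced it).  ``inconsistent_pairs`` counts pairs with different
    decisions but identical condition values; these cannot be discerned and
    are skipped.
    """

    clauses: dict
    attributes: tuple
    inconsistent_pairs: int = 0

    def __post_init__(self) -> None:
        universe = set(self.attributes)
        for clause, weight in self.clauses.items():
            if not clause:
                raise ValueError("empty clause in discernibility function")
            if not clause <= universe:
                raise ValueError(
                    f"clause {set(clause)} contains attributes outside the "
                    f"declared universe {sorted(universe)}")
            if weight <= 0:
                raise ValueError("clause weights must be positive")

    @property
    def total_weight(self) -> float:
        """Sum of clause weights = number of discerning cross-class pairs."""
        return float(sum(self.clauses.values()))

    def __len__(self) -> int:
        return len(self.clauses)


@dataclass
class Reduct:
    """Attribute subset returned by a reducer, with its greedy trace."""

    attributes: tuple
    selection_trace: list = field(default_factory=list)

    def __iter__(self):
        return iter(self.attributes)

    def __len__(self) -> int:
        return len(self.attributes)


_DISCRETIZE_METHODS = ("equal_frequency", "equal_width", "none")


def discretize(table: DecisionTable, method: str = "equal_frequency",
               bins: int = 3) -> DecisionTable:
    """Bin the numeric condition attributes of ``table``.

    Nominal attributes (per ``table.nominal`` or non-numeric dtype) pass
    through unchanged, as does the decision column.  ``method="none"`` is the
    identity.  Columns with no more distinct values than ``bins`` pass
    through with a warning.  Bin edges are recorded in the returned table's
    ``provenance["bin_edges"]``.
    """
    if method not in _DISCRETIZE_METHODS:
        raise ValueError(f"unknown method {method!r}; one of {_DISCRETIZE_METHODS}")
    if method == "none":
        return DecisionTable(table.data.copy(), table.decision, table.nominal,
                             dict(table.provenance))
    if bins < 2:
        raise ValueError("bins must be >= 2")

    out = table.data.copy()
    edges: dict = {}
    for col in table.attributes:
        if col in table.nominal:
            continue
        x = out[col]
        if not pd.api.types.is_numeric_dtype(x):
            continue
        if x.nunique() <= bins:
            warnings.warn(
                f"column {col!r} has <= {bins} distinct values; passed through",
                UserWarning, stacklevel=2)
            continue
        if method == "equal_frequency":
            codes, bin_edges = pd.qcut(x.to_numpy(), bins, labels=False,
                                       retbins=True, duplicates="drop")
        else:
            codes, bin_edges = pd.cut(x.to_numpy(), bins, labels=False,
                                      retbins=True, include_lowest=True)
        out[col] = codes.astype(int)
        edges[col] = [float(e) for e in bin_edges]
    prov = dict(table.provenance)
    prov["discretization"] = {"method": method, "bins": bins}
    prov["bin_edges"] = edges
    return DecisionTable(out, table.decision, table.nominal, prov)


def build_discernibility(table: DecisionTable) -> DiscernibilityFunction:
    """Decision-relative discernibility function of ``table``.

    Every object pair with different decision values contributes the clause
    of condition attributes on which the pair differs; identical clauses are
    merged with weight equal to their multiplicity.  Pairs that differ in
    decision but agree on every condition attribute are skipped and counted
    as ``inconsistent_pairs``.  A single-decision-class table yields an empty
    clause family.
    """
    attrs = table.attributes
    d = len(attrs)
    if d > 63:
        raise ValueError("more than 63 condition attributes not supported")
    # integer-code every column so comparison is exact
    codes = np.column_stack([
        pd.factorize(table.data[a].to_numpy())[0] for a in attrs
    ]) if d else np.empty((table.n_objects, 0), dtype=int)
    y = pd.factorize(table.decision_values.to_numpy())[0]

    powers = (np.int64(1) << np.arange(d, dtype=np.int64))
    clause_counts: dict = {}
    inconsistent = 0
    classes = np.unique(y)
    block = 256
    for ci in range(len(classes)):
        rows_i = codes[y == classes[ci]]
        for cj in range(ci + 1, len(classes)):
            rows_j = codes[y == classes[cj]]
            for start in range(0, len(rows_i), block):
                blk = rows_i[start:start + block]
                diff = blk[:, None, :] != rows_j[None, :, :]
                masks = (diff @ powers).ravel()
                inconsistent += int((masks == 0).sum())
                vals, cnts = np.unique(masks[masks != 0], return_counts=True)
                for v, c in zip(vals, cnts):
                    clause_counts[int(v)] = clause_counts.get(int(v), 0) + int(c)

    clauses = {
        frozenset(attrs[j] for j in range(d) if mask >> j & 1): float(w)
        for mask, w in clause_counts.items()
    }
    return DiscernibilityFunction(clauses, tuple(attrs), inconsistent)


def johnson_reduct(df: DiscernibilityFunction,
                   tie_break: Sequence | None = None) -> Reduct:
    """Greedy single reduct: repeatedly pick the attribute with the largest
    sum of weights over the clauses containing it, drop the clauses it hits,
    stop when none remain.  Ties are broken by position in ``tie_break``
    (default: the discernibility function's declared attribute order).
    """
    order = list(tie_break) if tie_break is not None else list(df.attributes)
    missing = set(df.attributes) - set(order)
    if missing:
        raise ValueError(f"tie_break omits attributes: {sorted(missing)}")
    rank = {a: i for i, a in enumerate(order)}

    remaining = dict(df.clauses)
    chosen: list = []
    trace: list = []
    while remaining:
        weight_sum: dict = {}
        for clause, w in remaining.items():
            for a in clause:
                weight_sum[a] = weight_sum.get(a, 0.0) + w
        best = min(weight_sum, key=lambda a: (-weight_sum[a], rank[a]))
        chosen.append(best)
        trace.append((best, weight_sum[best]))
        remaining = {c: w for c, w in remaining.items() if best not in c}
    return Reduct(tuple(chosen), trace)


def enumerate_minimal_reducts(df: DiscernibilityFunction,
                              max_attrs: int = 20) -> set:
    """All inclusion-minimal hitting sets of the clause family, by exhaustive
    search in increasing cardinality.  Exponential in the attribute count;
    guarded by ``max_attrs``.  Returns ``{frozenset()}`` for an empty family.
    """
    attrs = list(df.attributes)
    if len(attrs) > max_attrs:
        raise ValueError(
            f"{len(attrs)} attributes exceeds max_attrs={max_attrs}; "
            "exhaustive enumeration would be exponential")
    if not df.clauses:
        return {frozenset()}

    from itertools import combinations

    clauses = list(df.clauses)
    minimal: set = set()
    for k in range(1, len(attrs) + 1):
        for combo in combinations(attrs, k):
            s = frozenset(combo)
            if any(m <= s for m in minimal):
                continue
            if all(s & c for c in clauses):
                minimal.add(s)
    return minimal


def select_features(table: DecisionTable, reduct: Reduct) -> DecisionTable:
    """Restrict ``table`` to the reduct's attributes plus the decision column.

    Intended for the *original* (pre-discretization) table so downstream
    scaling sees raw values.
    """
    if len(reduct) == 0:
        raise ValueError("empty reduct: no informative attributes selected")
    missing = set(reduct.attributes) - set(table.attributes)
    if missing:
        raise ValueError(f"reduct attributes not in table: {sorted(missing)}")
    keep = [a for a in table.attributes if a in set(reduct.attributes)]
    data = table.data[keep + [table.decision]].copy()
    prov = dict(table.provenance)
    prov["selected_features"] = keep
    return DecisionTable(data, table.decision,
                         table.nominal & set(keep), prov)
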