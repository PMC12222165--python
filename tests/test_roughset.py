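"""Discretization, discernibility construction and the Johnson reducer,
checked against hand-traced examples and an exhaustive minimal-hitting-set
oracle."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from roughstack import (DecisionTable, DiscernibilityFunction, Reduct,
                        build_discernibility, discretize,
                        enumerate_minimal_reducts, johnson_reduct,
                        select_features)


def make_table(df, decision="target", nominal=()):
    return DecisionTable(pd.DataFrame(df), decision, frozenset(nominal))


class TestDecisionTable:
    def test_missing_values_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            make_table({"a": [1, None], "target": [0, 1]})

    def test_decision_column_required(self):
        with pytest.raises(ValueError, match="decision"):
            make_table({"a": [1, 2]}, decision="label")

    def test_attributes_exclude_decision(self, toy_table):
        assert toy_table.attributes == ["a", "b", "c"]


class TestDiscretize:
    def test_equal_frequency_median_split(self):
        t = make_table({"x": [1.0, 2.0, 3.0, 4.0], "target": [0, 0, 1, 1]})
        out = discretize(t, "equal_frequency", bins=2)
        assert out.data["x"].tolist() == [0, 0, 1, 1]

    def test_none_is_identity(self, toy_table):
        out = discretize(toy_table, "none")
        pd.testing.assert_frame_equal(out.data, toy_table.data)

    def test_equal_width_edges_match_direct_computation(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(0, 10, 100)
        t = make_table({"x": x, "target": rng.integers(0, 2, 100)})
        out = discretize(t, "equal_width", bins=4)
        assert out.data["x"].nunique() == 4
        edges = out.provenance["bin_edges"]["x"]
        width = (x.max() - x.min()) / 4
        expected_inner = [x.min() + k * width for k in (1, 2, 3)]
        assert np.allclose(edges[1:4], expected_inner, atol=1e-9)

    def test_nominal_passthrough(self):
        t = make_table({"x": [1.0, 2.0, 3.0, 4.0], "g": [0, 1, 0, 1],
                        "target": [0, 0, 1, 1]}, nominal=("g",))
        out = discretize(t, "equal_frequency", bins=2)
        assert out.data["g"].tolist() == [0, 1, 0, 1]

    def test_too_few_distinct_values_warns_and_passes_through(self):
        t = make_table({"x": [1.0, 1.0, 2.0, 2.0], "target": [0, 0, 1, 1]})
        with pytest.warns(UserWarning, match="distinct"):
            out = discretize(t, "equal_frequency", bins=3)
        assert out.data["x"].tolist() == [1.0, 1.0, 2.0, 2.0]

    def test_invalid_bins(self, toy_table):
        with pytest.raises(ValueError, match="bins"):
            discretize(toy_table, "equal_frequency", bins=1)


class TestBuildDiscernibility:
    def test_toy_table_clauses(self, toy_table):
        df = build_discernibility(toy_table)
        assert df.clauses == {frozenset("ac"): 2.0, frozenset("b"): 2.0}
        assert df.inconsistent_pairs == 0

    def test_single_class_gives_empty_function(self):
        t = make_table({"a": [0, 1, 2], "target": [1, 1, 1]})
        df = build_discernibility(t)
        assert len(df) == 0

    def test_two_objects_single_attribute(self):
        t = make_table({"a": [0, 1], "target": [0, 1]})
        df = build_discernibility(t)
        assert df.clauses == {frozenset("a"): 1.0}

    def test_inconsistent_pairs_counted_not_clause(self):
        t = make_table({"a": [0, 0, 1], "target": [0, 1, 1]})
        df = build_discernibility(t)
        assert df.inconsistent_pairs == 1
        assert df.clauses == {frozenset("a"): 1.0}

    def test_row_permutation_invariance(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            n, d = rng.integers(4, 10), rng.integers(2, 5)
            df = pd.DataFrame(rng.integers(0, 3, (n, d)),
                              columns=[f"a{j}" for j in range(d)])
            df["target"] = rng.integers(0, 2, n)
            if df["target"].nunique() < 2:
                continue
            t1 = DecisionTable(df, "target")
            t2 = DecisionTable(df.sample(frac=1, random_state=1)
                               .reset_index(drop=True), "target")
            f1, f2 = build_discernibility(t1), build_discernibility(t2)
            assert f1.clauses == f2.clauses
            assert f1.inconsistent_pairs == f2.inconsistent_pairs

    def test_weight_conservation(self):
        rng = np.random.default_rng(5)
        df = pd.DataFrame(rng.integers(0, 2, (12, 3)), columns=list("abc"))
        df["target"] = rng.integers(0, 2, 12)
        t = DecisionTable(df, "target")
        f = build_discernibility(t)
        y = df["target"].to_numpy()
        cross_pairs = int((y == 0).sum() * (y == 1).sum())
        assert f.total_weight + f.inconsistent_pairs == cross_pairs


class TestJohnsonReduct:
    def test_hand_traced_example(self):
        df = DiscernibilityFunction(
            {frozenset("ac"): 2.0, frozenset("b"): 2.0}, ("a", "b", "c"))
        red = johnson_reduct(df)
        assert red.attributes == ("a", "b")
        assert red.selection_trace == [("a", 2.0), ("b", 2.0)]

    def test_empty_family_empty_reduct(self):
        red = johnson_reduct(DiscernibilityFunction({}, ("a", "b")))
        assert red.attributes == ()

    def test_single_clause_forced_choice(self):
        df = DiscernibilityFunction({frozenset("x"): 1.0}, ("x", "y"))
        assert johnson_reduct(df).attributes == ("x",)

    def test_tie_break_follows_supplied_order(self):
        df = DiscernibilityFunction(
            {frozenset("ac"): 2.0, frozenset("b"): 2.0}, ("a", "b", "c"))
        red = johnson_reduct(df, tie_break=["c", "b", "a"])
        assert red.attributes[0] == "c"

    def test_incomplete_tie_break_rejected(self):
        df = DiscernibilityFunction({frozenset("a"): 1.0}, ("a", "b"))
        with pytest.raises(ValueError, match="omits"):
            johnson_reduct(df, tie_break=["a"])


class TestEnumerateMinimalReducts:
    def test_toy_family(self):
        df = DiscernibilityFunction(
            {frozenset("ac"): 1.0, frozenset("b"): 1.0}, ("a", "b", "c"))
        assert enumerate_minimal_reducts(df) == {frozenset("ab"),
                                                 frozenset("bc")}

    def test_empty_family(self):
        assert enumerate_minimal_reducts(
            DiscernibilityFunction({}, ("a",))) == {frozenset()}

    def test_singleton_clause(self):
        df = DiscernibilityFunction({frozenset("a"): 1.0}, ("a",))
        assert enumerate_minimal_reducts(df) == {frozenset("a")}

    def test_guard_against_blowup(self):
        attrs = tuple(f"a{i}" for i in range(25))
        df = DiscernibilityFunction({frozenset(attrs[:1]): 1.0}, attrs)
        with pytest.raises(ValueError, match="max_attrs"):
            enumerate_minimal_reducts(df)


@st.composite
def clause_families(draw):
    attrs = tuple("abcdefgh"[:draw(st.integers(2, 6))])
    n_clauses = draw(st.integers(1, 8))
    clauses = {}
    for _ in range(n_clauses):
        size = draw(st.integers(1, len(attrs)))
        clause = frozenset(draw(st.permutations(attrs))[:size])
        clauses[clause] = clauses.get(clause, 0) + draw(st.integers(1, 5))
    return DiscernibilityFunction({c: float(w) for c, w in clauses.items()},
                                  attrs)


class TestGreedyVsOracle:
    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(clause_families())
    def test_johnson_hits_every_clause_within_greedy_bound(self, df):
        red = johnson_reduct(df)
        chosen = set(red.attributes)
        assert all(chosen & c for c in df.clauses)
        minimal = enumerate_minimal_reducts(df, max_attrs=10)
        k_min = min(len(m) for m in minimal)
        # greedy set-cover guarantee with d = max clauses hit by one attribute
        max_degree = max(sum(1 for c in df.clauses if a in c)
                         for a in df.attributes)
        assert k_min <= len(red) <= math.ceil(
            (1 + math.log(max_degree)) * k_min)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(clause_families())
    def test_singleton_families_solved_exactly(self, df):
        singletons = {c: w for c, w in df.clauses.items() if len(c) == 1}
        if not singletons:
            return
        sub = DiscernibilityFunction(singletons, df.attributes)
        red = johnson_reduct(sub)
        assert {frozenset(red.attributes)} == enumerate_minimal_reducts(
            sub, max_attrs=10)


class TestSelectFeatures:
    def test_restriction_keeps_reduct_plus_decision(self, toy_table):
        out = select_features(toy_table, Reduct(("a", "b")))
        assert list(out.data.columns) == ["a", "b", "target"]
        pd.testing.assert_series_equal(out.decision_values,
                                       toy_table.decision_values)

    def test_full_reduct_is_identity(self, toy_table):
        out = select_features(toy_table, Reduct(("a", "b", "c")))
        pd.testing.assert_frame_equal(out.data, toy_table.data)

    def test_empty_reduct_rejected(self, toy_table):
        with pytest.raises(ValueError, match="empty reduct"):
            select_features(toy_table, Reduct(()))

    def test_unknown_attribute_rejected(self, toy_table):
        with pytest.raises(ValueError, match="not in table"):
            select_features(toy_table, Reduct(("z",)))
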