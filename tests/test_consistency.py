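"""Ratio-sign-consistency rule: worked examples, enumeration oracles and
algebraic properties (min/max equivalence, monotonicity, symmetry)."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from poolfrac.consistency import (
    ComparisonPlan,
    cross_group_de,
    de_sets,
    null_consistency_rate,
    null_paired_rate,
    paired_fraction_de,
    run_plan,
)
from poolfrac.model import AbundanceTable, ValidationError
from conftest import make_table, six_group_pools


def one_protein_table(a: list[float], b: list[float]) -> AbundanceTable:
    """Single-protein table whose pools split into groups A and B."""
    cols = {f"A{i}": [v] for i, v in enumerate(a)}
    cols |= {f"B{i}": [v] for i, v in enumerate(b)}
    return AbundanceTable(pd.DataFrame(cols, index=["X"], dtype=float))


def cross_verdict(a: list[float], b: list[float]) -> str:
    table = one_protein_table(a, b)
    [res] = cross_group_de(
        table, [f"A{i}" for i in range(len(a))], [f"B{i}" for i in range(len(b))]
    )
    return res.verdict


def minmax_oracle(a: list[float], b: list[float]) -> str:
    """Independent formulation of the all-cross-ratio rule."""
    if min(a) > max(b):
        return "up"
    if max(a) < min(b):
        return "down"
    return "not_DE"


# ---------------------------------------------------------------------------
# Worked examples
# ---------------------------------------------------------------------------

def test_cross_group_examples():
    assert cross_verdict([2, 3, 4], [1, 1, 1]) == "up"
    assert cross_verdict([1, 2, 3], [2, 2, 2]) == "not_DE"
    assert cross_verdict([1, 1, 1], [2, 3, 4]) == "down"


def test_cross_group_nine_ratios():
    table = one_protein_table([2, 3, 4], [1, 1, 1])
    [res] = cross_group_de(table, ["A0", "A1", "A2"], ["B0", "B1", "B2"])
    assert res.n_ratios == 9
    assert res.n_ratios_gt1 == 9 and res.n_ratios_lt1 == 0
    assert res.log2fc == pytest.approx(np.log2(2 * 3 * 4) / 3)


def test_tie_breaks_consistency():
    """A ratio of exactly 1 fails the strict >1 / <1 requirement."""
    assert cross_verdict([2, 3, 1], [1, 1, 1]) == "not_DE"


def test_missing_value_makes_not_evaluable():
    table = one_protein_table([2, np.nan, 4], [1, 1, 1])
    [res] = cross_group_de(table, ["A0", "A1", "A2"], ["B0", "B1", "B2"])
    assert res.verdict == "not_evaluable"
    assert np.isnan(res.log2fc)


def test_overlapping_groups_error():
    table = one_protein_table([1, 2], [3])
    with pytest.raises(ValidationError, match="overlap"):
        cross_group_de(table, ["A0", "A1"], ["A1"])


def test_paired_examples():
    pools = [f"P{i}" for i in range(18)]
    ev = AbundanceTable(pd.DataFrame({p: [2.0, 5.0] for p in pools},
                                     index=["up_p", "eq_p"]), fraction="EV")
    prot = AbundanceTable(pd.DataFrame({p: [1.0, 5.0] for p in pools},
                                       index=["up_p", "eq_p"]), fraction="PROT")
    results = {r.protein: r for r in paired_fraction_de(ev, prot)}
    assert results["up_p"].verdict == "up"
    assert results["up_p"].n_ratios == 18
    assert results["up_p"].log2fc == pytest.approx(1.0)
    assert results["eq_p"].verdict == "not_DE"    # all ratios exactly 1


def test_paired_matches_pools_by_suffix():
    ev = make_table({"X-1-EV": [4.0], "X-2-EV": [4.0]}, ["A"], "EV")
    prot = make_table({"X-1-PROT": [2.0], "X-2-PROT": [2.0]}, ["A"], "PROT")
    [res] = paired_fraction_de(ev, prot)
    assert res.verdict == "up" and res.n_ratios == 2


def test_paired_no_correspondence_errors():
    ev = make_table({"A-EV": [1.0]}, ["X"], "EV")
    prot = make_table({"B-PROT": [1.0]}, ["X"], "PROT")
    with pytest.raises(ValidationError):
        paired_fraction_de(ev, prot)


# ---------------------------------------------------------------------------
# Analytic null rates vs exhaustive enumeration
# ---------------------------------------------------------------------------

def enumeration_rate(m: int, n: int) -> float:
    """Fraction of rank assignments (values 1..m+n split into A and B)
    with a consistent cross-ratio direction — brute force over all
    C(m+n, m) assignments."""
    values = list(range(1, m + n + 1))
    consistent = 0
    total = 0
    for a_set in itertools.combinations(values, m):
        b_set = [v for v in values if v not in a_set]
        total += 1
        if minmax_oracle(list(a_set), b_set) in ("up", "down"):
            consistent += 1
    return consistent / total


@pytest.mark.parametrize("m, n", [(1, 1), (2, 1), (2, 2), (3, 3), (4, 2)])
def test_null_consistency_rate_matches_enumeration(m, n):
    assert null_consistency_rate(m, n) == pytest.approx(enumeration_rate(m, n))


def test_null_consistency_rate_known_values():
    assert null_consistency_rate(3, 3) == pytest.approx(0.1)    # 2 / C(6,3)
    assert null_consistency_rate(1, 1) == pytest.approx(1.0)
    assert null_consistency_rate(2, 1) == pytest.approx(2 / 3)
    with pytest.raises(ValidationError):
        null_consistency_rate(0, 3)


def test_null_paired_rate_known_values():
    assert null_paired_rate(1) == pytest.approx(1.0)
    assert null_paired_rate(2) == pytest.approx(0.5)            # 2 of 4 patterns
    assert null_paired_rate(18) == pytest.approx(2.0 ** -17)
    with pytest.raises(ValidationError):
        null_paired_rate(0)


# ---------------------------------------------------------------------------
# Property suites
# ---------------------------------------------------------------------------

positive_values = st.floats(min_value=1e-3, max_value=1e3,
                            allow_nan=False, allow_infinity=False)
group_lists = st.lists(positive_values, min_size=1, max_size=4)


@settings(max_examples=200, derandomize=True)
@given(a=group_lists, b=group_lists)
def test_minmax_equivalence(a, b):
    """The all-cross-ratios rule is exactly the min/max rule."""
    assert cross_verdict(a, b) == minmax_oracle(a, b)


@settings(max_examples=100, derandomize=True)
@given(a=st.lists(positive_values, min_size=2, max_size=4),
       b=st.lists(positive_values, min_size=2, max_size=4),
       data=st.data())
def test_subset_monotonicity(a, b, data):
    """A protein DE for (A, B) stays DE for any non-empty subsets;
    adding pools can only remove calls."""
    verdict = cross_verdict(a, b)
    if verdict not in ("up", "down"):
        return
    ka = data.draw(st.integers(min_value=1, max_value=len(a)))
    kb = data.draw(st.integers(min_value=1, max_value=len(b)))
    assert cross_verdict(a[:ka], b[:kb]) == verdict


@settings(max_examples=100, derandomize=True)
@given(a=group_lists, b=group_lists)
def test_symmetry_swapping_groups(a, b):
    """Swapping the groups flips up<->down and negates log2fc."""
    table = one_protein_table(a, b)
    ga = [f"A{i}" for i in range(len(a))]
    gb = [f"B{i}" for i in range(len(b))]
    [fwd] = cross_group_de(table, ga, gb)
    [rev] = cross_group_de(table, gb, ga)
    flip = {"up": "down", "down": "up", "not_DE": "not_DE"}
    assert rev.verdict == flip[fwd.verdict]
    assert rev.log2fc == pytest.approx(-fwd.log2fc, abs=1e-9)


@settings(max_examples=100, derandomize=True)
@given(a=group_lists, b=group_lists,
       c=st.floats(min_value=0.1, max_value=10,
                   allow_nan=False, allow_infinity=False))
def test_scale_invariance(a, b, c):
    """Scaling group A by c shifts log2fc by log2 c and moves verdicts
    exactly as the min/max oracle predicts."""
    [base] = cross_group_de(one_protein_table(a, b),
                            [f"A{i}" for i in range(len(a))],
                            [f"B{i}" for i in range(len(b))])
    scaled = [v * c for v in a]
    [res] = cross_group_de(one_protein_table(scaled, b),
                           [f"A{i}" for i in range(len(a))],
                           [f"B{i}" for i in range(len(b))])
    assert res.verdict == minmax_oracle(scaled, b)
    assert res.log2fc == pytest.approx(base.log2fc + math.log2(c), abs=1e-6)


def test_random_instances_match_oracle():
    """Bulk check of rule-vs-oracle agreement on random instances."""
    rng = np.random.default_rng(2024)
    for _ in range(1000):
        m, n = rng.integers(1, 5, size=2)
        a = list(rng.lognormal(0, 1, size=m))
        b = list(rng.lognormal(0, 1, size=n))
        assert cross_verdict(a, b) == minmax_oracle(a, b)


# ---------------------------------------------------------------------------
# Plan execution
# ---------------------------------------------------------------------------

def test_plan_shape():
    plan = ComparisonPlan()
    assert len(plan.age_comparisons) == 6
    assert len(plan.sex_comparisons) == 3


def test_run_plan_summary_bookkeeping(null_simulation, default_design):
    """Every summary row satisfies n_DE = n_up + n_down, and each
    comparison evaluates the full universe."""
    ev, prot, _ = null_simulation
    *_, meta = default_design
    results, summary = run_plan({"EV": ev, "PROT": prot}, meta)
    assert len(summary) == 18                    # 9 comparisons x 2 fractions
    assert (summary["n_DE"] == summary["n_up"] + summary["n_down"]).all()
    for res in results.values():
        assert {r.n_ratios for r in res} == {9}


def test_run_plan_warns_on_unexpected_group_size(null_simulation, default_design):
    ev, prot, _ = null_simulation
    *_, meta = default_design
    messages = []
    run_plan({"EV": ev}, meta, expected_pools_per_group=5,
             warn=messages.append)
    assert messages                              # warned, did not raise
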