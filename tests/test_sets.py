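"""Set-intersection logic: Venn regions, age dynamics, sex-shared sets."""

import pytest

from poolfrac.model import ValidationError
from poolfrac.sets import (
    age_dynamic_proteins,
    pct,
    sex_common_age_proteins,
    sex_consistent_across_ages,
    sex_overlap_age_de,
    venn,
)


def named_sets(n_a_only: int, n_both: int, n_b_only: int):
    a_only = {f"a{i}" for i in range(n_a_only)}
    both = {f"c{i}" for i in range(n_both)}
    b_only = {f"b{i}" for i in range(n_b_only)}
    return {"EV": a_only | both, "PROT": b_only | both}


def test_venn_counts_partition_union():
    v = venn(named_sets(717, 476, 40))
    assert v.union_size == 1233
    assert v.region_counts == {"EV&PROT": 476, "EV": 717, "PROT": 40}
    assert sum(v.region_counts.values()) == v.union_size
    assert v.region_percentages == {"EV&PROT": 38.6, "EV": 58.2, "PROT": 3.2}
    assert sum(v.region_percentages.values()) == pytest.approx(100.0, abs=0.15)


def test_venn_identical_sets():
    s = {"x", "y", "z"}
    v = venn({"A": s, "B": set(s)})
    assert v.region_counts["A&B"] == 3
    assert v.region_percentages["A&B"] == 100.0


def test_venn_disjoint_sets():
    v = venn({"A": {f"a{i}" for i in range(3)},
              "B": {f"b{i}" for i in range(7)}})
    assert v.region_counts == {"A&B": 0, "A": 3, "B": 7}
    assert v.union_size == 10


def test_venn_three_sets():
    v = venn({"A": {"x", "y"}, "B": {"y", "z"}, "C": {"y"}})
    assert v.region_counts["A&B&C"] == 1
    assert v.region_counts["A"] == 1 and v.region_counts["B"] == 1
    assert v.union_size == 3


def test_venn_set_count_limits():
    with pytest.raises(ValidationError):
        venn({"A": set()})
    with pytest.raises(ValidationError):
        venn({k: set() for k in "ABCDE"})


def test_pct_rounds_half_up():
    assert pct(476, 1233) == 38.6
    assert pct(1, 8) == 12.5
    assert pct(1, 400) == 0.3               # 0.25 -> 0.3, not banker's 0.2
    assert pct(122, 1193, decimals=2) == 10.23
    assert pct(36, 516, decimals=2) == 6.98


# ---------------------------------------------------------------------------
# Age dynamics
# ---------------------------------------------------------------------------

AGE_LABELS = ("young_vs_mid", "young_vs_old", "mid_vs_old")


def age_de(young_mid=(), young_old=(), mid_old=()):
    return dict(zip(AGE_LABELS, (set(young_mid), set(young_old), set(mid_old))))


def test_age_dynamic_thresholds():
    de = age_de(young_mid={"P1"}, young_old={"P1", "P2"}, mid_old={"P3"})
    assert age_dynamic_proteins(de, min_comparisons=2) == {"P1"}
    assert age_dynamic_proteins(de, min_comparisons=3) == set()
    assert age_dynamic_proteins(de, min_comparisons=1) == {"P1", "P2", "P3"}


def test_age_dynamic_monotone_in_min_comparisons():
    de = age_de(young_mid={"P1", "P2"}, young_old={"P2", "P3"},
                mid_old={"P2", "P3", "P4"})
    sets = [age_dynamic_proteins(de, k) for k in (1, 2, 3)]
    assert sets[2] <= sets[1] <= sets[0]


def test_age_dynamic_requires_three_comparisons():
    with pytest.raises(ValidationError):
        age_dynamic_proteins({"young_vs_mid": set()}, 2)


# ---------------------------------------------------------------------------
# Sex-shared age effects
# ---------------------------------------------------------------------------

def test_sex_overlap_same_comparison_and_direction():
    de_m = {"young_vs_old": {"P1": 1, "P2": 1}, "young_vs_mid": {"P3": -1},
            "mid_vs_old": {}}
    de_f = {"young_vs_old": {"P1": 1, "P2": -1}, "young_vs_mid": {},
            "mid_vs_old": {"P3": -1}}
    # P1 shares comparison and direction; P2 disagrees in direction;
    # P3 is DE in different comparisons per sex.
    assert sex_overlap_age_de(de_m, de_f, same_comparison=True) == {"P1"}
    assert sex_overlap_age_de(de_m, de_f, same_comparison=False) == {
        "P1", "P2", "P3"}


def test_sex_common_age_proteins_with_provenance():
    de_m = {"young_vs_old": {"P1": 1, "P4": 1}, "young_vs_mid": {"P1": 1},
            "mid_vs_old": {}}
    de_f = {"young_vs_old": {"P1": 1, "P4": 1}, "young_vs_mid": {},
            "mid_vs_old": {}}
    dynamic_m = {"P1"}          # P4 shared but not dynamic in either sex
    dynamic_f = set()
    result = sex_common_age_proteins(de_m, de_f, dynamic_m, dynamic_f)
    assert set(result) == {"P1"}
    assert result["P1"] == [("young_vs_old", 1)]


def test_sex_common_direction_conflict_excluded():
    de_m = {"young_vs_old": {"P1": 1}, "young_vs_mid": {}, "mid_vs_old": {}}
    de_f = {"young_vs_old": {"P1": -1}, "young_vs_mid": {}, "mid_vs_old": {}}
    assert sex_common_age_proteins(de_m, de_f, {"P1"}, {"P1"}) == {}


# ---------------------------------------------------------------------------
# Sex differences stable across ages
# ---------------------------------------------------------------------------

def test_sex_consistent_requires_all_three_same_direction():
    # ADIPOQ-like: higher in F (direction -1 for M-vs-F) in all groups.
    de = {"young": {"ADIPOQ": -1, "OXSR1": 1, "PZP": -1},
          "mid": {"ADIPOQ": -1, "OXSR1": 1},
          "old": {"ADIPOQ": -1, "OXSR1": -1, "PZP": -1}}
    assert sex_consistent_across_ages(de) == {"ADIPOQ"}


def test_sex_consistent_fixture_size_two():
    de = {"young": {"A": 1, "B": -1, "C": 1},
          "mid": {"A": 1, "B": -1},
          "old": {"A": 1, "B": -1, "D": 1}}
    assert sex_consistent_across_ages(de) == {"A", "B"}


def test_sex_consistent_requires_three_groups():
    with pytest.raises(ValidationError):
        sex_consistent_across_ages({"young": {}})
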