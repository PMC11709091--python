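"""Ratio-sign-consistency differential abundance.

The pipeline's core statistic is a non-parametric consistency rule on
abundance ratios rather than a p-value model:

* **Paired fraction contrast** (EV vs PROT): for every protein
  quantified in both fractions, the EV/PROT ratio is formed within each
  pool.  A protein is differentially abundant iff every ratio is
  strictly > 1 (EV-enriched, "up") or every ratio strictly < 1 ("down").
  With 18 matched pools this is 18 ratios per protein.
* **Cross-group contrast** (age or sex comparison): all |A| x |B| cross
  ratios a_i / b_j between the pools of the two groups are formed —
  nine ratios in the 3-vs-3 default design — and the same
  all-one-direction rule applies.  The rule is equivalent to
  min(A) > max(B) ("up") / max(A) < min(B) ("down"), which is how the
  implementation and its independent test oracle cross-check.

Under an exchangeable continuous null the false-call probability has a
closed form: 2 / C(m+n, m) for the cross-group rule (0.1 at 3 vs 3) and
2 * (1/2)^n for the paired rule (2^-17 at n = 18).  These analytic
companions are exposed so observed DE rates can be judged against
chance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .model import (
    AGE_GROUPS,
    SEXES,
    AbundanceTable,
    PoolMetadata,
    ValidationError,
)

VERDICTS = ("up", "down", "not_DE", "not_evaluable")


@dataclass(frozen=True)
class DeResult:
    """Per-protein record for one comparison."""

    protein: str
    comparison: str
    n_ratios: int
    n_ratios_gt1: int
    n_ratios_lt1: int
    verdict: str
    log2fc: float  # NaN when not evaluable

    def __post_init__(self) -> None:
        if self.verdict not in VERDICTS:
            raise ValidationError(f"unknown verdict {self.verdict!r}")


def de_results_to_frame(results: Sequence[DeResult]) -> pd.DataFrame:
    return pd.DataFrame([{
        "protein": r.protein,
        "comparison": r.comparison,
        "n_ratios": r.n_ratios,
        "n_ratios_gt1": r.n_ratios_gt1,
        "n_ratios_lt1": r.n_ratios_lt1,
        "verdict": r.verdict,
        "log2fc": r.log2fc,
    } for r in results])


def de_sets(results: Sequence[DeResult]) -> dict[str, set[str]]:
    """Split a result list into ``{"up": ..., "down": ..., "de": ...}``
    protein sets."""
    up = {r.protein for r in results if r.verdict == "up"}
    down = {r.protein for r in results if r.verdict == "down"}
    return {"up": up, "down": down, "de": up | down}


def de_directions(results: Sequence[DeResult]) -> dict[str, int]:
    """Protein -> +1 (up) / -1 (down) for DE proteins only."""
    out: dict[str, int] = {}
    for r in results:
        if r.verdict == "up":
            out[r.protein] = 1
        elif r.verdict == "down":
            out[r.protein] = -1
    return out


# ---------------------------------------------------------------------------
# Core verdict computation
# ---------------------------------------------------------------------------

def _verdicts_from_counts(
    evaluable: np.ndarray, n_gt: np.ndarray, n_lt: np.ndarray, n_total: int
) -> np.ndarray:
    verdict = np.where(
        ~evaluable, "not_evaluable",
        np.where(n_gt == n_total, "up",
                 np.where(n_lt == n_total, "down", "not_DE")),
    )
    return verdict.astype(object)


def paired_fraction_de(
    ev: AbundanceTable,
    prot: AbundanceTable,
    comparison: str = "EV_vs_PROT",
) -> list[DeResult]:
    """Paired EV-vs-PROT contrast over pools matched by plasma pool of
    origin.

    Pools are matched either by identical column names or by stripping a
    trailing ``-EV`` / ``-PROT`` suffix.  Proteins present in both
    tables' universes are evaluated; any missing value in either
    fraction makes the protein ``not_evaluable``.  "up" means
    EV-enriched.
    """
    def origin(pool: str, fraction: str) -> str:
        suffix = f"-{fraction}"
        return pool[: -len(suffix)] if pool.endswith(suffix) else pool

    ev_origin = {origin(p, "EV"): p for p in ev.pools}
    prot_origin = {origin(p, "PROT"): p for p in prot.pools}
    shared = [o for o in ev_origin if o in prot_origin]
    if not shared:
        raise ValidationError("no pools correspond between the EV and PROT tables")

    in_prot = set(prot.proteins)
    proteins = [p for p in ev.proteins if p in in_prot]
    a = ev.values.loc[proteins, [ev_origin[o] for o in shared]].to_numpy()
    b = prot.values.loc[proteins, [prot_origin[o] for o in shared]].to_numpy()
    n = len(shared)

    evaluable = ~np.isnan(a).any(axis=1) & ~np.isnan(b).any(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        ratios = a / b
        n_gt = (ratios > 1).sum(axis=1)
        n_lt = (ratios < 1).sum(axis=1)
        log2fc = np.log2(ratios).mean(axis=1)
    log2fc = np.where(evaluable, log2fc, np.nan)
    verdicts = _verdicts_from_counts(evaluable, n_gt, n_lt, n)

    return [
        DeResult(p, comparison, n, int(g), int(l), v, float(f))
        for p, g, l, v, f in zip(proteins, n_gt, n_lt, verdicts, log2fc)
    ]


def cross_group_de(
    table: AbundanceTable,
    group_a: Sequence[str],
    group_b: Sequence[str],
    comparison: str = "A_vs_B",
    require_detected_in: str = "groups",
) -> list[DeResult]:
    """All-cross-ratio contrast between two disjoint pool sets.

    For each protein all |A| x |B| ratios a_i / b_j are formed; "up"
    means consistently higher in ``group_a``.  ``log2fc`` is the mean of
    the log2 cross ratios (equivalently mean log2 A minus mean log2 B).

    ``require_detected_in``: ``"groups"`` (default) demands complete
    quantification in the pools of the two compared groups only;
    ``"all"`` additionally demands detection in every pool of the
    table.
    """
    group_a, group_b = list(group_a), list(group_b)
    if not group_a or not group_b:
        raise ValidationError("comparison groups must be non-empty")
    overlap = set(group_a) & set(group_b)
    if overlap:
        raise ValidationError(f"comparison groups overlap: {sorted(overlap)}")
    if require_detected_in not in ("groups", "all"):
        raise ValidationError("require_detected_in must be 'groups' or 'all'")

    a = table.values.loc[:, group_a].to_numpy()
    b = table.values.loc[:, group_b].to_numpy()
    m, n = a.shape[1], b.shape[1]
    evaluable = ~np.isnan(a).any(axis=1) & ~np.isnan(b).any(axis=1)
    if require_detected_in == "all":
        evaluable &= ~np.isnan(table.values.to_numpy()).any(axis=1)

    with np.errstate(invalid="ignore", divide="ignore"):
        ratios = a[:, :, None] / b[:, None, :]  # proteins x m x n
        n_gt = (ratios > 1).sum(axis=(1, 2))
        n_lt = (ratios < 1).sum(axis=(1, 2))
        log2fc = np.log2(a).mean(axis=1) - np.log2(b).mean(axis=1)
    log2fc = np.where(evaluable, log2fc, np.nan)
    verdicts = _verdicts_from_counts(evaluable, n_gt, n_lt, m * n)

    return [
        DeResult(p, comparison, m * n, int(g), int(l), v, float(f))
        for p, g, l, v, f in zip(table.proteins, n_gt, n_lt, verdicts, log2fc)
    ]


# ---------------------------------------------------------------------------
# Comparison plan
# ---------------------------------------------------------------------------

AGE_PAIRS = (("young", "mid"), ("young", "old"), ("mid", "old"))


@dataclass(frozen=True)
class ComparisonPlan:
    """The study's comparison grid: the three age contrasts within each
    sex plus the M-vs-F contrast within each age group."""

    age_comparisons: tuple[tuple[str, str, str], ...] = tuple(
        (sex, a, b) for sex in SEXES for a, b in AGE_PAIRS
    )
    sex_comparisons: tuple[str, ...] = AGE_GROUPS

    @staticmethod
    def age_label(sex: str, a: str, b: str) -> str:
        return f"{sex}:{a}_vs_{b}"

    @staticmethod
    def sex_label(age_group: str) -> str:
        return f"{age_group}:M_vs_F"

    @property
    def labels(self) -> list[str]:
        return (
            [self.age_label(*c) for c in self.age_comparisons]
            + [self.sex_label(g) for g in self.sex_comparisons]
        )


def pools_of_group(
    meta: Sequence[PoolMetadata], sex: str, age_group: str,
    fraction: Optional[str] = None,
) -> list[str]:
    return [
        p.pool_id for p in meta
        if p.sex == sex and p.age_group == age_group
        and (fraction is None or p.fraction == fraction)
    ]


def run_plan(
    tables: Mapping[str, AbundanceTable],
    meta: Sequence[PoolMetadata],
    plan: ComparisonPlan = ComparisonPlan(),
    expected_pools_per_group: Optional[int] = 3,
    warn=None,
) -> tuple[dict[tuple[str, str], list[DeResult]], pd.DataFrame]:
    """Apply every planned comparison to every fraction table.

    Returns ``(results, summary)`` where ``results`` maps
    ``(fraction, comparison_label)`` to a :class:`DeResult` list and
    ``summary`` is a table with one row per fraction x comparison and
    columns ``n_DE = n_up + n_down``, in the shape used to report DE
    protein counts between age groups.

    A group with a pool count different from ``expected_pools_per_group``
    triggers ``warn`` (default: ``warnings.warn``), not an error.
    """
    import warnings

    if warn is None:
        warn = warnings.warn

    results: dict[tuple[str, str], list[DeResult]] = {}
    rows = []
    for fraction, table in tables.items():
        in_table = set(table.pools)

        def group_pools(sex: str, age_group: str) -> list[str]:
            ids = [p for p in pools_of_group(meta, sex, age_group, fraction)
                   if p in in_table]
            if expected_pools_per_group and len(ids) != expected_pools_per_group:
                warn(
                    f"{fraction} {sex}/{age_group}: {len(ids)} pools, "
                    f"expected {expected_pools_per_group}"
                )
            return ids

        comparisons: list[tuple[str, list[str], list[str]]] = []
        for sex, a, b in plan.age_comparisons:
            comparisons.append(
                (plan.age_label(sex, a, b), group_pools(sex, a), group_pools(sex, b))
            )
        for age_group in plan.sex_comparisons:
            comparisons.append((
                plan.sex_label(age_group),
                group_pools("M", age_group),
                group_pools("F", age_group),
            ))

        for label, pools_a, pools_b in comparisons:
            res = cross_group_de(table, pools_a, pools_b, comparison=label)
            results[(fraction, label)] = res
            sets = de_sets(res)
            rows.append({
                "fraction": fraction,
                "comparison": label,
                "n_universe": len(res),
                "n_DE": len(sets["de"]),
                "n_up": len(sets["up"]),
                "n_down": len(sets["down"]),
            })
    summary = pd.DataFrame(rows)
    return results, summary


# ---------------------------------------------------------------------------
# Analytic null rates
# ---------------------------------------------------------------------------

def null_consistency_rate(m: int, n: int) -> float:
    """Probability that all m x n cross ratios share one direction when
    the m + n values are exchangeable with a continuous distribution.

    All ratios > 1 iff min(A) > max(B), i.e. the top m order statistics
    all land in A — one of the C(m+n, m) equally likely assignments —
    and symmetrically for all < 1, giving 2 / C(m+n, m).
    """
    if m < 1 or n < 1:
        raise ValidationError("group sizes must be >= 1")
    return 2.0 / math.comb(m + n, m)


def null_paired_rate(n: int) -> float:
    """Probability of a consistent direction across n independent
    symmetric-direction paired ratios: 2 * (1/2)^n."""
    if n < 1:
        raise ValidationError("n must be >= 1")
    return 2.0 * 0.5 ** n
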