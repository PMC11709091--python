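"""Set-intersection logic downstream of the DE calls.

Covers the Venn-style region bookkeeping of protein universes, the
"age-dynamic" proteins recurring across the three age contrasts of one
sex, proteins shared between the sexes with consistent direction, and
proteins separating the sexes in every age group.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from itertools import combinations
from typing import Mapping, Sequence, Set

from .model import ValidationError

Directions = Mapping[str, int]  # protein -> +1 (up) / -1 (down)


def round_half_up(x: Decimal | float, decimals: int = 1) -> float:
    """Round half away from zero (the convention used for reported
    percentages), avoiding banker's rounding."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(str(x)).quantize(q, rounding=ROUND_HALF_UP))


def pct(count: int, total: int, decimals: int = 1) -> float:
    """``100 * count / total`` rounded half-up to ``decimals``."""
    if total <= 0:
        raise ValidationError("total must be positive")
    return round_half_up(Decimal(count) * 100 / Decimal(total), decimals)


@dataclass
class VennSummary:
    """Exclusive-region counts and percentages of the union.

    Region labels join the names of the sets a region belongs to with
    ``&`` (e.g. for sets EV and PROT: ``"EV"``, ``"PROT"``,
    ``"EV&PROT"``); each count is the number of proteins in exactly
    those sets.
    """

    region_counts: dict[str, int]
    region_percentages: dict[str, float]
    union_size: int

    def __post_init__(self) -> None:
        if sum(self.region_counts.values()) != self.union_size:
            raise ValidationError("region counts must partition the union")


def venn(sets: Mapping[str, Set[str]]) -> VennSummary:
    """Exclusive-region decomposition of 2-4 named sets.

    Percentages are of the union, rounded half-up to one decimal.
    """
    names = list(sets)
    if not 2 <= len(names) <= 4:
        raise ValidationError("venn requires between 2 and 4 sets")
    union = set().union(*sets.values())
    counts: dict[str, int] = {}
    for r in range(len(names), 0, -1):
        for combo in combinations(names, r):
            inside = set.intersection(*(set(sets[n]) for n in combo))
            outside = set().union(
                *(set(sets[n]) for n in names if n not in combo), set()
            )
            counts["&".join(combo)] = len(inside - outside)
    percentages = {
        label: pct(c, len(union)) if union else 0.0
        for label, c in counts.items()
    }
    return VennSummary(
        region_counts=counts,
        region_percentages=percentages,
        union_size=len(union),
    )


# ---------------------------------------------------------------------------
# Age dynamics within one sex
# ---------------------------------------------------------------------------

def age_dynamic_proteins(
    de: Mapping[str, Set[str]], min_comparisons: int = 2
) -> set[str]:
    """Proteins DE (any direction) in at least ``min_comparisons`` of
    the three age contrasts of one sex and fraction.

    ``de`` must contain exactly the three age comparisons (keyed by
    their labels); the default ``min_comparisons=2`` selects the
    recurring "age-dynamic" proteins.
    """
    if len(de) != 3:
        raise ValidationError(
            f"expected exactly the three age comparisons, got {sorted(de)}"
        )
    counts: dict[str, int] = {}
    for proteins in de.values():
        for p in proteins:
            counts[p] = counts.get(p, 0) + 1
    return {p for p, c in counts.items() if c >= min_comparisons}


# ---------------------------------------------------------------------------
# Sex-shared age effects
# ---------------------------------------------------------------------------

def sex_overlap_age_de(
    de_m: Mapping[str, Directions],
    de_f: Mapping[str, Directions],
    same_comparison: bool = True,
) -> set[str]:
    """Proteins with an age difference in both sexes.

    With ``same_comparison=True`` (default) a protein qualifies only if
    some single age comparison calls it DE in **both** sexes with the
    same direction; with ``False`` any DE call per sex suffices.
    ``de_m`` / ``de_f`` map comparison label -> direction mapping.
    """
    if same_comparison:
        out: set[str] = set()
        for label, dirs_m in de_m.items():
            dirs_f = de_f.get(label, {})
            out |= {p for p, d in dirs_m.items() if dirs_f.get(p) == d}
        return out
    in_m = set().union(*(set(d) for d in de_m.values()), set())
    in_f = set().union(*(set(d) for d in de_f.values()), set())
    return in_m & in_f


def sex_common_age_proteins(
    de_m: Mapping[str, Directions],
    de_f: Mapping[str, Directions],
    dynamic_m: Set[str],
    dynamic_f: Set[str],
    same_comparison: bool = True,
) -> dict[str, list[tuple[str, int]]]:
    """Sex-common, age-dynamic proteins with provenance.

    Selects proteins DE in both sexes for at least one common age
    comparison with the same direction (see :func:`sex_overlap_age_de`),
    intersected with the union of the two sexes' age-dynamic sets.
    Returns ``protein -> [(comparison, direction), ...]`` recording which
    shared comparisons support each protein; the selected set is the
    mapping's keys.
    """
    shared = sex_overlap_age_de(de_m, de_f, same_comparison=same_comparison)
    selected = shared & (set(dynamic_m) | set(dynamic_f))
    provenance: dict[str, list[tuple[str, int]]] = {}
    for p in sorted(selected):
        support = []
        for label, dirs_m in de_m.items():
            d = dirs_m.get(p)
            if d is not None and de_f.get(label, {}).get(p) == d:
                support.append((label, d))
        provenance[p] = support
    return provenance


# ---------------------------------------------------------------------------
# Sex differences stable across age
# ---------------------------------------------------------------------------

def sex_consistent_across_ages(
    de_by_age: Mapping[str, Directions]
) -> set[str]:
    """Proteins DE between M and F in **all three** age groups with the
    same direction — the stable sex markers."""
    if len(de_by_age) != 3:
        raise ValidationError(
            f"expected the three age-group sex comparisons, got {sorted(de_by_age)}"
        )
    dirs = list(de_by_age.values())
    out = set()
    for p, d in dirs[0].items():
        if all(other.get(p) == d for other in dirs[1:]):
            out.add(p)
    return out
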