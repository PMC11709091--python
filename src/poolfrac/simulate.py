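"""Synthetic donor cohorts, pools and paired EV/PROT abundance matrices.

The generator emulates the pooled study design the pipeline was built
for: 120 healthy donors, 20 per sex x age group (young / middle-aged /
old, males and females), pooled four donors at a time into five pools
per group by mixing equal plasma volumes, with the first three pools of
each group analysed by proteomics in both an EV-enriched and a
protein-enriched SEC fraction.

Abundance model (all on the log2 scale unless noted):

* each protein has a lognormal baseline — ``Normal(baseline_mean_log2,
  baseline_sd_log2)`` across proteins;
* group structure enters as additive log2 offsets: per-age-group
  offsets (optionally sex-specific) for age-affected proteins, an
  M-minus-F offset per age group for sex-affected proteins, and a
  fraction offset of ``ev_enrichment_log2`` for fraction-enriched
  proteins;
* donors add ``Normal(0, donor_sd_log2)`` biological noise per protein;
* a pool is the **linear-scale mean** of its member donors (physical
  mixing of equal plasma volumes), then measured per fraction with
  ``Normal(0, tech_sd_log2)`` technical noise;
* values whose log2 falls below ``lod_log2`` are censored to missing,
  mimicking detection-limit dropout of data-independent acquisition.

Ground truth (which proteins carry which effects, with direction) is
returned alongside the matrices so recovery of the differential-
abundance rules can be measured exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .model import (
    AGE_GROUPS,
    SEXES,
    AbundanceTable,
    ParticleMeasurement,
    PoolMetadata,
    ValidationError,
    group_label,
)

#: Donor age ranges (years, inclusive) per (sex, age_group) — the ranges
#: of the recruited cohort the simulator emulates.
AGE_RANGES: Mapping[tuple[str, str], tuple[int, int]] = {
    ("M", "young"): (22, 34),
    ("F", "young"): (22, 35),
    ("M", "mid"): (43, 55),
    ("F", "mid"): (41, 54),
    ("M", "old"): (64, 79),
    ("F", "old"): (64, 76),
}

SEX_SCOPES = ("M-only", "F-only", "both")


@dataclass(frozen=True)
class Donor:
    donor_id: str
    sex: str
    age_group: str
    age_years: int

    @property
    def group(self) -> str:
        return group_label(self.sex, self.age_group)


@dataclass(frozen=True)
class CohortSpec:
    """Cohort and pooling design parameters.

    Defaults reproduce the emulated study: 20 donors per group, five
    plasma pools of four donors per group, the first three pools per
    group carried to proteomics.
    """

    donors_per_group: int = 20
    pools_per_group_plasma: int = 5
    pools_per_group_proteomics: int = 3
    donors_per_pool: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("donors_per_group", "pools_per_group_plasma",
                     "pools_per_group_proteomics", "donors_per_pool"):
            if getattr(self, name) < 1:
                raise ValidationError(f"{name} must be a positive integer")
        if self.donors_per_pool * self.pools_per_group_plasma > self.donors_per_group:
            raise ValidationError(
                "donors_per_pool x pools_per_group_plasma exceeds donors_per_group"
            )
        if self.pools_per_group_proteomics > self.pools_per_group_plasma:
            raise ValidationError(
                "pools_per_group_proteomics exceeds pools_per_group_plasma"
            )


@dataclass(frozen=True)
class AgeEffect:
    """Per-age-group mean log2 offsets for one age-affected protein.

    ``scope`` restricts the effect to one sex ("M-only" / "F-only") or
    applies it in both sexes ("both").
    """

    scope: str
    offsets: Mapping[str, float]  # age_group -> log2 offset

    def __post_init__(self) -> None:
        if self.scope not in SEX_SCOPES:
            raise ValidationError(f"scope must be one of {SEX_SCOPES}")
        unknown = set(self.offsets) - set(AGE_GROUPS)
        if unknown:
            raise ValidationError(f"unknown age groups in offsets: {unknown}")

    def applies_to(self, sex: str) -> bool:
        return self.scope == "both" or self.scope == f"{sex}-only"

    def offset(self, sex: str, age_group: str) -> float:
        return float(self.offsets.get(age_group, 0.0)) if self.applies_to(sex) else 0.0


@dataclass(frozen=True)
class SexEffect:
    """Per-age-group log2 M-minus-F offsets for one sex-affected protein."""

    offsets: Mapping[str, float]  # age_group -> log2 (M - F)

    def __post_init__(self) -> None:
        unknown = set(self.offsets) - set(AGE_GROUPS)
        if unknown:
            raise ValidationError(f"unknown age groups in offsets: {unknown}")

    def offset(self, sex: str, age_group: str) -> float:
        # Convention: males carry the full offset, females none, so the
        # M-minus-F difference equals the stated value.
        d = float(self.offsets.get(age_group, 0.0))
        return d if sex == "M" else 0.0


@dataclass(frozen=True)
class EffectSpec:
    """Protein-population effect structure for the simulator.

    The first ``round(frac_ev_enriched * n_proteins)`` proteins are
    EV-enriched and the next ``round(frac_prot_enriched * n_proteins)``
    PROT-enriched (deterministic assignment keeps ground truth legible);
    fraction enrichment adds ``ev_enrichment_log2`` to the enriched
    fraction.  Age and sex effects are sparse mappings keyed by protein
    id.  Noise terms and the detection limit are log2-scale.
    """

    n_proteins: int = 1500
    frac_ev_enriched: float = 0.45
    frac_prot_enriched: float = 0.15
    ev_enrichment_log2: float = 2.0
    age_affected: Mapping[str, AgeEffect] = field(default_factory=dict)
    sex_affected: Mapping[str, SexEffect] = field(default_factory=dict)
    donor_sd_log2: float = 0.5
    tech_sd_log2: float = 0.2
    lod_log2: float = 12.0
    baseline_mean_log2: float = 20.0
    baseline_sd_log2: float = 2.0

    def __post_init__(self) -> None:
        if self.n_proteins < 1:
            raise ValidationError("n_proteins must be positive")
        for name in ("frac_ev_enriched", "frac_prot_enriched"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must be in [0, 1]")
        if self.frac_ev_enriched + self.frac_prot_enriched > 1.0 + 1e-12:
            raise ValidationError("fraction-enriched proportions sum to more than 1")
        for name in ("donor_sd_log2", "tech_sd_log2", "baseline_sd_log2"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")

    # -- protein bookkeeping -------------------------------------------------
    @property
    def protein_ids(self) -> list[str]:
        width = max(4, len(str(self.n_proteins)))
        return [f"P{i:0{width}d}" for i in range(1, self.n_proteins + 1)]

    @property
    def n_ev_enriched(self) -> int:
        return round(self.frac_ev_enriched * self.n_proteins)

    @property
    def n_prot_enriched(self) -> int:
        return round(self.frac_prot_enriched * self.n_proteins)

    def fraction_class(self) -> pd.Series:
        """Per-protein label: "EV", "PROT" or "none"."""
        ids = self.protein_ids
        labels = np.array(["none"] * self.n_proteins, dtype=object)
        labels[: self.n_ev_enriched] = "EV"
        labels[self.n_ev_enriched: self.n_ev_enriched + self.n_prot_enriched] = "PROT"
        return pd.Series(labels, index=ids, name="fraction_class")

    @staticmethod
    def null(n_proteins: int = 1500, **kwargs) -> "EffectSpec":
        """No fraction, age or sex effects — the exchangeable null."""
        kwargs.setdefault("frac_ev_enriched", 0.0)
        kwargs.setdefault("frac_prot_enriched", 0.0)
        return EffectSpec(n_proteins=n_proteins, age_affected={},
                          sex_affected={}, **kwargs)


@dataclass
class SimulationTruth:
    """Ground-truth labels returned with simulated matrices."""

    effects: EffectSpec
    fraction_class: pd.Series  # protein -> "EV" | "PROT" | "none"

    def expected_age_direction(self, protein: str, sex: str,
                               group_a: str, group_b: str) -> Optional[str]:
        """Expected DE verdict of ``group_a`` vs ``group_b`` for one sex:
        "up" (higher in a), "down", or None (no mean difference)."""
        eff = self.effects.age_affected.get(protein)
        s = self.effects.sex_affected.get(protein)
        delta = 0.0
        if eff is not None:
            delta += eff.offset(sex, group_a) - eff.offset(sex, group_b)
        if s is not None:
            delta += s.offset(sex, group_a) - s.offset(sex, group_b)
        if delta > 0:
            return "up"
        if delta < 0:
            return "down"
        return None

    def expected_sex_direction(self, protein: str, age_group: str) -> Optional[str]:
        """Expected M-vs-F verdict within one age group."""
        delta = 0.0
        s = self.effects.sex_affected.get(protein)
        if s is not None:
            delta += float(s.offsets.get(age_group, 0.0))
        eff = self.effects.age_affected.get(protein)
        if eff is not None:
            delta += (eff.offset("M", age_group) - eff.offset("F", age_group))
        if delta > 0:
            return "up"
        if delta < 0:
            return "down"
        return None

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for p in self.effects.protein_ids:
            age = self.effects.age_affected.get(p)
            sex = self.effects.sex_affected.get(p)
            rows.append({
                "protein": p,
                "fraction_class": self.fraction_class[p],
                "age_scope": age.scope if age else "",
                "age_offsets": ";".join(
                    f"{g}={age.offsets.get(g, 0.0):g}" for g in AGE_GROUPS
                ) if age else "",
                "sex_offsets": ";".join(
                    f"{g}={sex.offsets.get(g, 0.0):g}" for g in AGE_GROUPS
                ) if sex else "",
            })
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Cohort and pools
# ---------------------------------------------------------------------------

def generate_cohort(spec: CohortSpec) -> list[Donor]:
    """Draw a donor cohort: ``donors_per_group`` donors in each of the
    six sex x age groups, ages uniform integers within each group's
    recruitment range.  Deterministic under ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    donors: list[Donor] = []
    i = 1
    for age_group in AGE_GROUPS:
        for sex in SEXES:
            lo, hi = AGE_RANGES[(sex, age_group)]
            ages = rng.integers(lo, hi + 1, size=spec.donors_per_group)
            for age in ages:
                donors.append(Donor(f"D{i:04d}", sex, age_group, int(age)))
                i += 1
    return donors


def make_pools(donors: Sequence[Donor], spec: CohortSpec) -> list[PoolMetadata]:
    """Partition each group's donors into plasma pools of
    ``donors_per_pool`` with balanced ages (donors sorted by age and
    dealt round-robin across pools).  The first
    ``pools_per_group_proteomics`` pools of each group are flagged for
    proteomics.  Unused donors (when the group is larger than the
    pooled total) are left out."""
    by_group: dict[tuple[str, str], list[Donor]] = {}
    for d in donors:
        by_group.setdefault((d.sex, d.age_group), []).append(d)

    pools: list[PoolMetadata] = []
    need = spec.donors_per_pool * spec.pools_per_group_plasma
    for age_group in AGE_GROUPS:
        for sex in SEXES:
            members = by_group.get((sex, age_group), [])
            if len(members) < need:
                raise ValidationError(
                    f"group {group_label(sex, age_group)}: need {need} donors, "
                    f"have {len(members)} (short by {need - len(members)})"
                )
            ordered = sorted(members, key=lambda d: (d.age_years, d.donor_id))[:need]
            assignment: list[list[Donor]] = [[] for _ in range(spec.pools_per_group_plasma)]
            for k, donor in enumerate(ordered):
                assignment[k % spec.pools_per_group_plasma].append(donor)
            for j, pool_members in enumerate(assignment, start=1):
                pools.append(PoolMetadata(
                    pool_id=f"{group_label(sex, age_group)}-{j}",
                    sex=sex,
                    age_group=age_group,
                    fraction=None,
                    donor_ids=tuple(d.donor_id for d in pool_members),
                    plasma_volume_mL=0.5 * spec.donors_per_pool,
                    proteomics=j <= spec.pools_per_group_proteomics,
                ))
    return pools


def fraction_pools(pools: Sequence[PoolMetadata]) -> list[PoolMetadata]:
    """Expand proteomics-flagged plasma pools into their EV and PROT
    fraction-level records (pool ids suffixed ``-EV`` / ``-PROT``)."""
    out = []
    for fraction in ("EV", "PROT"):
        for p in pools:
            if not p.proteomics:
                continue
            out.append(replace(
                p,
                pool_id=f"{p.pool_id}-{fraction}",
                fraction=fraction,
                source_pool=p.pool_id,
            ))
    return out


# ---------------------------------------------------------------------------
# Abundance simulation
# ---------------------------------------------------------------------------

def simulate_abundance(
    pools: Sequence[PoolMetadata],
    effects: EffectSpec,
    seed: int = 0,
) -> tuple[AbundanceTable, AbundanceTable, SimulationTruth]:
    """Simulate paired EV and PROT abundance matrices over the
    proteomics-flagged pools.  Returns ``(ev, prot, truth)``.

    See the module docstring for the generative model.
    """
    prot_pools = [p for p in pools if p.proteomics]
    if not prot_pools:
        raise ValidationError("no proteomics-flagged pools")
    rng = np.random.default_rng(seed)
    ids = effects.protein_ids
    n = effects.n_proteins

    baseline = rng.normal(effects.baseline_mean_log2, effects.baseline_sd_log2, size=n)

    # Per-(protein, group) systematic offsets, sparse.
    idx = {p: i for i, p in enumerate(ids)}
    group_offset = {}
    for sex in SEXES:
        for age_group in AGE_GROUPS:
            off = np.zeros(n)
            for p, eff in effects.age_affected.items():
                off[idx[p]] += eff.offset(sex, age_group)
            for p, eff in effects.sex_affected.items():
                off[idx[p]] += eff.offset(sex, age_group)
            group_offset[(sex, age_group)] = off

    frac_class = effects.fraction_class()
    ev_bonus = np.where(frac_class.to_numpy() == "EV", effects.ev_enrichment_log2, 0.0)
    prot_bonus = np.where(frac_class.to_numpy() == "PROT", effects.ev_enrichment_log2, 0.0)

    cols: dict[str, dict[str, np.ndarray]] = {"EV": {}, "PROT": {}}
    for pool in prot_pools:
        k = len(pool.donor_ids)
        donor_log2 = (
            baseline[:, None]
            + group_offset[(pool.sex, pool.age_group)][:, None]
            + rng.normal(0.0, effects.donor_sd_log2, size=(n, k))
        )
        pool_log2 = np.log2(np.mean(np.exp2(donor_log2), axis=1))
        for fraction, bonus in (("EV", ev_bonus), ("PROT", prot_bonus)):
            measured = pool_log2 + rng.normal(0.0, effects.tech_sd_log2, size=n) + bonus
            measured = np.where(measured < effects.lod_log2, np.nan, measured)
            cols[fraction][f"{pool.pool_id}-{fraction}"] = np.exp2(measured)

    ev = AbundanceTable(pd.DataFrame(cols["EV"], index=ids), fraction="EV")
    prot = AbundanceTable(pd.DataFrame(cols["PROT"], index=ids), fraction="PROT")
    truth = SimulationTruth(effects=effects, fraction_class=frac_class)
    return ev, prot, truth


def random_effects(
    base: EffectSpec,
    n_age_affected: int,
    n_sex_affected: int,
    effect_log2: float,
    seed: int = 0,
    scopes: Sequence[str] = SEX_SCOPES,
) -> EffectSpec:
    """Attach random sparse age and sex effects to ``base``.

    Affected proteins are sampled without replacement from the
    non-fraction-enriched pool when possible; age-affected proteins get
    a monotone-with-age offset (0, +/-effect, +/-2*effect for young /
    mid / old) with random sign and a random sex scope, so every
    pairwise age contrast differs by at least ``effect_log2``;
    sex-affected proteins get a constant M-minus-F offset of magnitude
    ``effect_log2`` with random sign across all age groups.
    """
    rng = np.random.default_rng(seed)
    ids = np.array(base.protein_ids)
    n_needed = n_age_affected + n_sex_affected
    neutral = ids[base.fraction_class().to_numpy() == "none"]
    candidates = neutral if len(neutral) >= n_needed else ids
    if len(candidates) < n_needed:
        raise ValidationError("not enough proteins for the requested effects")
    chosen = rng.choice(candidates, size=n_needed, replace=False)
    age_ids, sex_ids = chosen[:n_age_affected], chosen[n_age_affected:]

    age_affected: dict[str, AgeEffect] = {}
    for p in age_ids:
        sign = rng.choice([-1.0, 1.0])
        scope = str(rng.choice(list(scopes)))
        age_affected[str(p)] = AgeEffect(
            scope=scope,
            offsets={"young": 0.0, "mid": sign * effect_log2,
                     "old": sign * 2 * effect_log2},
        )
    sex_affected: dict[str, SexEffect] = {}
    for p in sex_ids:
        sign = rng.choice([-1.0, 1.0])
        sex_affected[str(p)] = SexEffect(
            offsets={g: sign * effect_log2 for g in AGE_GROUPS}
        )
    return replace(base, age_affected=age_affected, sex_affected=sex_affected)


# ---------------------------------------------------------------------------
# Particle counts
# ---------------------------------------------------------------------------

def simulate_particles(
    pools: Sequence[PoolMetadata],
    group_means: Mapping[str, float],
    cv: float = 0.2,
    seed: int = 0,
    instruments: Sequence[str] = ("NTA", "NFCM"),
    dilution_factor: float = 100.0,
    prep_volume_mL: float = 0.6,
    plasma_input_mL: float = 2.0,
) -> list[ParticleMeasurement]:
    """Lognormal particle concentrations per pool per instrument.

    ``group_means`` gives the true particles-per-mL-of-plasma mean per
    group; the simulated instrument reading is back-calculated through
    the prep concentration and dilution so that
    :func:`poolfrac.group_stats.normalize_particles` recovers values
    scattered around the group mean with coefficient of variation
    ``cv`` (``cv=0`` gives the mean exactly).
    """
    if any(m <= 0 for m in group_means.values()):
        raise ValidationError("group means must be positive")
    if cv < 0:
        raise ValidationError("cv must be >= 0")
    rng = np.random.default_rng(seed)
    sigma = math.sqrt(math.log1p(cv * cv))
    out = []
    for instrument in instruments:
        for pool in pools:
            mean = group_means[pool.group]
            noise = math.exp(rng.normal(-0.5 * sigma * sigma, sigma)) if sigma else 1.0
            plasma_conc = mean * noise
            measured = plasma_conc * plasma_input_mL / prep_volume_mL / dilution_factor
            out.append(ParticleMeasurement(
                pool_id=pool.pool_id,
                instrument=instrument,
                measured_concentration=measured,
                dilution_factor=dilution_factor,
                prep_volume_mL=prep_volume_mL,
                plasma_input_mL=plasma_input_mL,
            ))
    return out


# ---------------------------------------------------------------------------
# Analytes
# ---------------------------------------------------------------------------

#: Donor-level analyte means (and SDs) per group used by
#: :func:`simulate_analytes`; values emulate healthy-adult clinical
#: chemistry with the female-higher HDL pattern the pipeline's group
#: statistics are meant to detect.  Units: ALB g/L, others mg/dL.
ANALYTE_PROFILE: Mapping[str, Mapping[str, tuple[float, float]]] = {
    "ALB": {"Young-M": (45.1, 2.4), "Young-F": (43.6, 4.0), "Mid-M": (44.7, 2.1),
            "Mid-F": (43.8, 2.0), "Old-M": (43.6, 2.3), "Old-F": (42.5, 1.7)},
    "HDL": {"Young-M": (46.5, 7.3), "Young-F": (58.7, 12.4), "Mid-M": (43.8, 9.0),
            "Mid-F": (63.6, 12.1), "Old-M": (52.55, 12.9), "Old-F": (60.9, 13.6)},
    "LDL": {"Young-M": (110.7, 22.9), "Young-F": (95.0, 18.6), "Mid-M": (130.9, 22.8),
            "Mid-F": (126.6, 33.1), "Old-M": (117.1, 40.0), "Old-F": (126.9, 29.0)},
    "VLDL": {g: (20.0, 6.0) for g in
             ("Young-M", "Young-F", "Mid-M", "Mid-F", "Old-M", "Old-F")},
}

ANALYTE_UNITS = {"ALB": "g/L", "HDL": "mg/dL", "LDL": "mg/dL", "VLDL": "mg/dL"}


def simulate_analytes(donors: Sequence[Donor], seed: int = 0):
    """Per-donor clinical-chemistry values drawn from
    :data:`ANALYTE_PROFILE` (truncated at zero)."""
    from .model import AnalyteTable

    rng = np.random.default_rng(seed)
    data = {}
    for analyte, profile in ANALYTE_PROFILE.items():
        vals = []
        for d in donors:
            mean, sd = profile[d.group]
            vals.append(max(0.0, rng.normal(mean, sd)))
        data[analyte] = vals
    values = pd.DataFrame(data, index=[d.donor_id for d in donors])
    groups = {d.donor_id: d.group for d in donors}
    return AnalyteTable(values=values, units=dict(ANALYTE_UNITS), groups=groups)
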