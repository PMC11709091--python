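"""Core data types for the pooled-fraction proteomics pipeline.

The study design behind these types: healthy donors are grouped by sex
(M/F) and age (young / middle-aged / old), equal plasma volumes from
several donors are physically mixed into pools, and each pool analysed by
proteomics is separated by size-exclusion chromatography into an
EV-enriched fraction (``EV``) and a protein-enriched fraction (``PROT``).
Quantification matrices are therefore proteins x pools, one matrix per
fraction, with missing values meaning "not detected in this pool".
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

SEXES = ("M", "F")
AGE_GROUPS = ("young", "mid", "old")
FRACTIONS = ("EV", "PROT")

#: Display abbreviations for the six sex x age groups (Young-M ... Old-F).
_AGE_LABEL = {"young": "Young", "mid": "Mid", "old": "Old"}


def group_label(sex: str, age_group: str) -> str:
    """Return the canonical group abbreviation, e.g. ``"Young-M"``."""
    return f"{_AGE_LABEL[age_group]}-{sex}"


GROUP_LABELS = tuple(
    group_label(sex, age) for age in AGE_GROUPS for sex in SEXES
)


class ValidationError(ValueError):
    """Raised when a domain invariant is violated."""


@dataclass(frozen=True)
class PoolMetadata:
    """Design labels for one pool.

    ``fraction`` is ``None`` for a whole-plasma pool (before SEC
    fractionation) and ``"EV"`` / ``"PROT"`` for the fraction-level
    samples derived from it; ``source_pool`` then names the plasma pool
    of origin.  ``proteomics`` flags pools selected for MS analysis.
    """

    pool_id: str
    sex: str
    age_group: str
    fraction: Optional[str] = None
    donor_ids: tuple[str, ...] = ()
    plasma_volume_mL: float = 2.0
    proteomics: bool = False
    source_pool: Optional[str] = None

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise ValidationError(f"sex must be one of {SEXES}, got {self.sex!r}")
        if self.age_group not in AGE_GROUPS:
            raise ValidationError(
                f"age_group must be one of {AGE_GROUPS}, got {self.age_group!r}"
            )
        if self.fraction is not None and self.fraction not in FRACTIONS:
            raise ValidationError(
                f"fraction must be one of {FRACTIONS} or None, got {self.fraction!r}"
            )
        if not self.donor_ids:
            raise ValidationError(f"pool {self.pool_id}: donor list is empty")
        if len(set(self.donor_ids)) != len(self.donor_ids):
            raise ValidationError(f"pool {self.pool_id}: duplicate donor ids")
        if not self.plasma_volume_mL > 0:
            raise ValidationError(f"pool {self.pool_id}: plasma volume must be > 0")

    @property
    def group(self) -> str:
        """Group abbreviation, one of the six Young-M ... Old-F labels."""
        return group_label(self.sex, self.age_group)


def validate_pool_set(pools: Sequence[PoolMetadata]) -> None:
    """Check pool-id uniqueness across a collection of pools."""
    ids = [p.pool_id for p in pools]
    dupes = sorted({i for i in ids if ids.count(i) > 1})
    if dupes:
        raise ValidationError(f"duplicate pool ids: {', '.join(dupes)}")


class AbundanceTable:
    """A proteins x pools quantification matrix for one fraction.

    Values are linear-scale, non-negative normalized abundances; ``NaN``
    means not detected.  A value of exactly 0 is also treated as not
    detected (label-free pipelines commonly emit 0 for absent proteins),
    so "detected" means present and strictly positive.

    ``raw_tokens``, when set by the reader, holds the original text token
    of every cell so a table read from disk can be written back
    token-for-token.
    """

    def __init__(
        self,
        values: pd.DataFrame,
        fraction: Optional[str] = None,
        raw_tokens: Optional[pd.DataFrame] = None,
    ):
        if values.index.has_duplicates:
            dupes = sorted(values.index[values.index.duplicated()].unique())
            raise ValidationError(f"duplicate protein ids: {', '.join(map(str, dupes))}")
        if values.columns.has_duplicates:
            dupes = sorted(values.columns[values.columns.duplicated()].unique())
            raise ValidationError(f"duplicate pool ids: {', '.join(map(str, dupes))}")
        if fraction is not None and fraction not in FRACTIONS:
            raise ValidationError(f"fraction must be one of {FRACTIONS}, got {fraction!r}")
        vals = values.astype(float)
        with np.errstate(invalid="ignore"):
            if (vals.to_numpy() < 0).any():
                raise ValidationError("abundance values must be >= 0")
        # 0 == not detected; store as missing so downstream code has one
        # missingness representation.
        self.values = vals.mask(vals == 0.0)
        self.fraction = fraction
        self.raw_tokens = raw_tokens

    # -- basic introspection -------------------------------------------------
    @property
    def proteins(self) -> list[str]:
        return list(self.values.index)

    @property
    def pools(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def detected(self) -> pd.DataFrame:
        """Boolean mask: value present and > 0."""
        return self.values.notna() & (self.values > 0)

    def detection_rate(self) -> pd.Series:
        """Per-protein fraction of pools in which the protein is detected."""
        return self.detected().mean(axis=1)

    # -- subsetting ----------------------------------------------------------
    def select_proteins(self, proteins: Iterable[str]) -> "AbundanceTable":
        wanted = set(proteins)
        keep = [p for p in self.proteins if p in wanted]
        return AbundanceTable(self.values.loc[keep], fraction=self.fraction)

    def select_pools(self, pools: Sequence[str]) -> "AbundanceTable":
        missing = [p for p in pools if p not in self.values.columns]
        if missing:
            raise ValidationError(f"unknown pool ids: {', '.join(missing)}")
        return AbundanceTable(self.values.loc[:, list(pools)], fraction=self.fraction)

    def validate_against_metadata(self, pools: Sequence[PoolMetadata]) -> None:
        """Every column must resolve to a metadata record of this fraction."""
        by_id = {p.pool_id: p for p in pools}
        orphans = [c for c in self.pools if c not in by_id]
        if orphans:
            raise ValidationError(f"pools without metadata: {', '.join(orphans)}")
        if self.fraction is not None:
            wrong = [
                c for c in self.pools
                if by_id[c].fraction is not None and by_id[c].fraction != self.fraction
            ]
            if wrong:
                raise ValidationError(
                    f"pools with mismatched fraction: {', '.join(wrong)}"
                )

    def __repr__(self) -> str:  # pragma: no cover
        frac = self.fraction or "?"
        return f"AbundanceTable({self.shape[0]} proteins x {self.shape[1]} pools, {frac})"


@dataclass(frozen=True)
class ParticleMeasurement:
    """One particle-concentration reading for a pool's EV preparation.

    ``measured_concentration`` is particles per mL of the (possibly
    diluted) measured suspension; normalization to particles per mL of
    source plasma multiplies by the dilution factor and the ratio of
    concentrate volume to plasma input volume.
    """

    pool_id: str
    instrument: str  # "NTA" or "NFCM"
    measured_concentration: float
    dilution_factor: float = 1.0
    prep_volume_mL: float = 0.6
    plasma_input_mL: float = 2.0

    def __post_init__(self) -> None:
        if self.instrument not in ("NTA", "NFCM"):
            raise ValidationError(f"unknown instrument {self.instrument!r}")
        for name in ("measured_concentration", "dilution_factor",
                     "prep_volume_mL", "plasma_input_mL"):
            if not getattr(self, name) > 0:
                raise ValidationError(f"{name} must be strictly positive")


@dataclass
class AnalyteTable:
    """Clinical-chemistry analytes (ALB, HDL, LDL, VLDL ...) per sample.

    ``values`` is a samples x analytes frame; ``units`` maps analyte name
    to its unit string (e.g. ALB in g/L, lipoproteins in mg/dL) and is
    preserved on round-trip.  ``groups`` maps sample id to its sex-age
    group abbreviation.
    """

    values: pd.DataFrame
    units: Mapping[str, str] = field(default_factory=dict)
    groups: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        arr = self.values.to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            if (arr < 0).any():
                raise ValidationError("analyte values must be non-negative")
        for g in self.groups.values():
            if g not in GROUP_LABELS:
                raise ValidationError(f"unknown group {g!r}")

    def by_group(self, analyte: str) -> dict[str, list[float]]:
        """Values of one analyte split by group, ready for group statistics."""
        out: dict[str, list[float]] = {}
        for sample, value in self.values[analyte].items():
            if np.isnan(value):
                continue
            out.setdefault(self.groups[sample], []).append(float(value))
        return out
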