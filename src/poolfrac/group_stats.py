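"""Classical group statistics for analytes and particle counts.

Fisher's Least Significant Difference (LSD): pairwise t-tests that use
the pooled error variance of a one-way ANOVA, with df = N - k.  Applied
to plasma analytes (ALB / HDL / LDL / VLDL) and to normalized particle
concentrations across the six sex x age groups.  Tests are reported
unprotected (every pair regardless of the omnibus F), with the omnibus
F shown alongside; an optional Bonferroni adjustment is off by default
to match how per-pair significance bands are conventionally displayed
for these measurements.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .model import ParticleMeasurement, ValidationError


def significance_band(p: float) -> str:
    """Star band: ns (p >= 0.05), * (p < 0.05), ** (p <= 0.01),
    *** (p <= 0.001), **** (p <= 0.0001)."""
    if p >= 0.05:
        return "ns"
    if p <= 1e-4:
        return "****"
    if p <= 1e-3:
        return "***"
    if p <= 1e-2:
        return "**"
    return "*"


@dataclass(frozen=True)
class LsdResult:
    pair: tuple[str, str]
    mean_diff: float
    standard_error: float
    t_stat: float
    df: int
    p_value: float
    significance_band: str


@dataclass
class LsdTest:
    f_stat: float
    f_p_value: float
    mse: float
    df: int
    pairs: list[LsdResult]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "group_i": r.pair[0],
            "group_j": r.pair[1],
            "mean_diff": r.mean_diff,
            "se": r.standard_error,
            "t": r.t_stat,
            "df": r.df,
            "p": r.p_value,
            "band": r.significance_band,
        } for r in self.pairs])


def fisher_lsd(
    groups: Mapping[str, Sequence[float]],
    adjust: str = "none",
) -> LsdTest:
    """Fisher's LSD over two or more groups.

    t = (mean_i - mean_j) / sqrt(MSE * (1/n_i + 1/n_j)), two-sided p
    from Student's t with df = N - k, MSE the one-way-ANOVA pooled
    within-group mean square.  ``adjust="bonferroni"`` multiplies each
    pairwise p by the number of pairs (capped at 1).
    """
    if len(groups) < 2:
        raise ValidationError("need at least two groups")
    for name, vals in groups.items():
        if len(vals) < 2:
            raise ValidationError(f"group {name!r} has fewer than 2 values")
    if adjust not in ("none", "bonferroni"):
        raise ValidationError("adjust must be 'none' or 'bonferroni'")

    arrays = {name: np.asarray(vals, dtype=float) for name, vals in groups.items()}
    k = len(arrays)
    n_total = sum(a.size for a in arrays.values())
    df_within = n_total - k
    sse = sum(((a - a.mean()) ** 2).sum() for a in arrays.values())
    mse = sse / df_within

    grand = np.concatenate(list(arrays.values())).mean()
    ssb = sum(a.size * (a.mean() - grand) ** 2 for a in arrays.values())
    df_between = k - 1
    if mse > 0:
        f_stat = (ssb / df_between) / mse
        f_p = float(stats.f.sf(f_stat, df_between, df_within))
    else:
        f_stat = 0.0 if ssb == 0 else float("inf")
        f_p = 1.0 if ssb == 0 else 0.0

    n_pairs = k * (k - 1) // 2
    pairs = []
    for gi, gj in combinations(arrays, 2):
        a, b = arrays[gi], arrays[gj]
        diff = float(a.mean() - b.mean())
        se = float(np.sqrt(mse * (1 / a.size + 1 / b.size)))
        if se > 0:
            t = diff / se
            p = float(2 * stats.t.sf(abs(t), df_within))
        else:  # zero pooled variance: identical groups are a clean no-difference
            t = 0.0 if diff == 0 else float("inf") * np.sign(diff)
            p = 1.0 if diff == 0 else 0.0
        if adjust == "bonferroni":
            p = min(1.0, p * n_pairs)
        pairs.append(LsdResult(
            pair=(gi, gj), mean_diff=diff, standard_error=se,
            t_stat=t, df=df_within, p_value=p,
            significance_band=significance_band(p),
        ))
    return LsdTest(f_stat=float(f_stat), f_p_value=f_p, mse=float(mse),
                   df=df_within, pairs=pairs)


def normalize_particles(m: ParticleMeasurement) -> float:
    """Particles per mL of source plasma.

    The instrument sees the prep diluted ``dilution_factor``-fold; the
    prep of volume ``prep_volume_mL`` was concentrated from
    ``plasma_input_mL`` of plasma, so:

    measured * dilution_factor * prep_volume_mL / plasma_input_mL
    """
    return (
        m.measured_concentration * m.dilution_factor
        * m.prep_volume_mL / m.plasma_input_mL
    )


def particles_by_group(
    measurements: Sequence[ParticleMeasurement],
    pool_groups: Mapping[str, str],
    instrument: str,
) -> dict[str, list[float]]:
    """Normalized particles/mL-plasma per group for one instrument,
    ready for :func:`fisher_lsd`."""
    out: dict[str, list[float]] = {}
    for m in measurements:
        if m.instrument != instrument:
            continue
        out.setdefault(pool_groups[m.pool_id], []).append(normalize_particles(m))
    return out
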