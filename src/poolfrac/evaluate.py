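"""Calibration and recovery measurements for the consistency rules.

These routines judge the pipeline against its own generative model:
empirical false-call rates on exchangeable null data (to be compared
with the analytic 2/C(m+n, m) and 2*(1/2)^n rates) and
sensitivity/false-positive rates on simulated data with known ground
truth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .consistency import (
    ComparisonPlan,
    cross_group_de,
    de_directions,
    null_consistency_rate,
    paired_fraction_de,
    run_plan,
)
from .model import AbundanceTable
from .preprocess import detection_filter
from .simulate import (
    CohortSpec,
    EffectSpec,
    fraction_pools,
    generate_cohort,
    make_pools,
    random_effects,
    simulate_abundance,
)


def empirical_null_consistency_rate(
    n_proteins: int, m: int = 3, n: int = 3, seed: int = 0
) -> float:
    """DE rate of :func:`cross_group_de` on i.i.d. lognormal values —
    one Monte-Carlo replicate per protein."""
    rng = np.random.default_rng(seed)
    values = rng.lognormal(0.0, 1.0, size=(n_proteins, m + n))
    pools = [f"A{i}" for i in range(m)] + [f"B{i}" for i in range(n)]
    table = AbundanceTable(pd.DataFrame(
        values, index=[f"N{i}" for i in range(n_proteins)], columns=pools))
    res = cross_group_de(table, pools[:m], pools[m:])
    n_de = sum(r.verdict in ("up", "down") for r in res)
    return n_de / n_proteins


def empirical_null_paired_rate(
    n_proteins: int, n_pools: int = 18, seed: int = 0
) -> float:
    """DE rate of :func:`paired_fraction_de` on two independent
    i.i.d. lognormal tables (every per-pool ratio direction a fair
    coin)."""
    rng = np.random.default_rng(seed)
    ids = [f"N{i}" for i in range(n_proteins)]
    pools = [f"P{i}" for i in range(n_pools)]
    ev = AbundanceTable(pd.DataFrame(
        rng.lognormal(0, 1, size=(n_proteins, n_pools)), index=ids,
        columns=[f"{p}-EV" for p in pools]), fraction="EV")
    prot = AbundanceTable(pd.DataFrame(
        rng.lognormal(0, 1, size=(n_proteins, n_pools)), index=ids,
        columns=[f"{p}-PROT" for p in pools]), fraction="PROT")
    res = paired_fraction_de(ev, prot)
    n_de = sum(r.verdict in ("up", "down") for r in res)
    return n_de / n_proteins


@dataclass
class RecoveryMetrics:
    """Ground-truth recovery of the cross-group rule at a given design."""

    sensitivity: float          # truth-affected (protein, comparison) pairs
    false_positive_rate: float  # truth-null pairs called DE
    n_affected: int
    n_null: int
    analytic_null: float

    @property
    def fpr_se(self) -> float:
        """Binomial standard error of the null rate at this sample size
        (per-comparison; calls are independent across proteins)."""
        p = self.analytic_null
        return float(np.sqrt(p * (1 - p) / max(self.n_null, 1)))


def measure_recovery(
    seed: int,
    n_proteins: int = 2000,
    n_age_affected: int = 100,
    n_sex_affected: int = 50,
    effect_log2: float = 2.0,
    donor_sd_log2: float = 0.5,
    filter_threshold: float = 0.8,
) -> RecoveryMetrics:
    """Simulate the default pooled design, run the full filter + DE
    plan, and score every (protein, comparison, fraction) combination
    against ground truth.

    ``effect_log2 = 2.0`` with ``donor_sd_log2 = 0.5`` realises
    pairwise group effects at four biological standard deviations.
    """
    spec = CohortSpec(seed=seed)
    pools = make_pools(generate_cohort(spec), spec)
    meta = pools + fraction_pools(pools)
    base = EffectSpec(n_proteins=n_proteins, donor_sd_log2=donor_sd_log2,
                      frac_ev_enriched=0.3, frac_prot_enriched=0.1)
    effects = random_effects(base, n_age_affected, n_sex_affected,
                             effect_log2, seed=seed + 1)
    ev, prot, truth = simulate_abundance(pools, effects, seed=seed + 2)
    ev_f, _ = detection_filter(ev, filter_threshold)
    prot_f, _ = detection_filter(prot, filter_threshold)
    plan = ComparisonPlan()
    results, _ = run_plan({"EV": ev_f, "PROT": prot_f}, meta, plan)

    hits = misses = false_pos = n_null = 0
    for fraction, table in (("EV", ev_f), ("PROT", prot_f)):
        universe = set(table.proteins)
        for sex, a, b in plan.age_comparisons:
            dirs = de_directions(results[(fraction, plan.age_label(sex, a, b))])
            for p in truth.effects.protein_ids:
                expected = truth.expected_age_direction(p, sex, a, b)
                observed = dirs.get(p)
                if expected is None:
                    if p in universe:
                        n_null += 1
                        false_pos += observed is not None
                else:
                    want = 1 if expected == "up" else -1
                    hits += observed == want
                    misses += observed != want
        for age_group in plan.sex_comparisons:
            dirs = de_directions(results[(fraction, plan.sex_label(age_group))])
            for p in truth.effects.protein_ids:
                expected = truth.expected_sex_direction(p, age_group)
                observed = dirs.get(p)
                if expected is None:
                    if p in universe:
                        n_null += 1
                        false_pos += observed is not None
                else:
                    want = 1 if expected == "up" else -1
                    hits += observed == want
                    misses += observed != want

    m = spec.pools_per_group_proteomics
    return RecoveryMetrics(
        sensitivity=hits / max(hits + misses, 1),
        false_positive_rate=false_pos / max(n_null, 1),
        n_affected=hits + misses,
        n_null=n_null,
        analytic_null=null_consistency_rate(m, m),
    )
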