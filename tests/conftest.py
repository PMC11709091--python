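"""Shared fixtures: tiny hand-built tables and a default simulated run."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from poolfrac.model import AbundanceTable, PoolMetadata
from poolfrac.simulate import (
    CohortSpec,
    EffectSpec,
    fraction_pools,
    generate_cohort,
    make_pools,
    simulate_abundance,
)


def make_table(data: dict[str, list[float]], proteins: list[str],
               fraction: str | None = None) -> AbundanceTable:
    """Build an AbundanceTable from {pool_id: column values}."""
    return AbundanceTable(
        pd.DataFrame(data, index=proteins, dtype=float), fraction=fraction
    )


def six_group_pools(pools_per_group: int = 3, fraction: str | None = "EV"):
    """Fraction-level metadata: ``pools_per_group`` pools per sex x age
    group, pool ids like ``Young-M-1-EV``."""
    from poolfrac.model import AGE_GROUPS, SEXES, group_label

    pools = []
    donor = 0
    for age in AGE_GROUPS:
        for sex in SEXES:
            for j in range(1, pools_per_group + 1):
                donor += 4
                base = f"{group_label(sex, age)}-{j}"
                pid = f"{base}-{fraction}" if fraction else base
                pools.append(PoolMetadata(
                    pool_id=pid, sex=sex, age_group=age, fraction=fraction,
                    donor_ids=tuple(f"D{donor - k}" for k in range(4)),
                    proteomics=True,
                    source_pool=base if fraction else None,
                ))
    return pools


@pytest.fixture(scope="session")
def default_design():
    """Cohort, plasma pools and fraction-level metadata at the default
    design (120 donors, 30 plasma pools, 18 proteomics pools)."""
    spec = CohortSpec(seed=11)
    cohort = generate_cohort(spec)
    pools = make_pools(cohort, spec)
    return spec, cohort, pools, pools + fraction_pools(pools)


@pytest.fixture(scope="session")
def null_simulation(default_design):
    """Paired EV/PROT tables with no effects and default noise."""
    _, _, pools, _ = default_design
    effects = EffectSpec.null(n_proteins=800, lod_log2=float("-inf"))
    ev, prot, truth = simulate_abundance(pools, effects, seed=21)
    return ev, prot, truth
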