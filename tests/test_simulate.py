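"""Synthetic-data generator: design counts, determinism, noise model."""

import numpy as np
import pytest

from poolfrac.model import ValidationError
from poolfrac.simulate import (
    AgeEffect,
    CohortSpec,
    EffectSpec,
    SexEffect,
    fraction_pools,
    generate_cohort,
    make_pools,
    random_effects,
    simulate_abundance,
    simulate_particles,
)
from poolfrac.simulate import AGE_RANGES


def test_default_cohort_has_120_donors():
    donors = generate_cohort(CohortSpec(seed=1))
    assert len(donors) == 120
    groups = {(d.sex, d.age_group) for d in donors}
    assert len(groups) == 6
    for d in donors:
        lo, hi = AGE_RANGES[(d.sex, d.age_group)]
        assert lo <= d.age_years <= hi


def test_minimal_cohort_one_per_group():
    donors = generate_cohort(CohortSpec(
        donors_per_group=1, pools_per_group_plasma=1,
        pools_per_group_proteomics=1, donors_per_pool=1, seed=0))
    assert len(donors) == 6
    assert len({(d.sex, d.age_group) for d in donors}) == 6


def test_cohort_deterministic_under_seed():
    assert generate_cohort(CohortSpec(seed=7)) == generate_cohort(CohortSpec(seed=7))
    assert generate_cohort(CohortSpec(seed=7)) != generate_cohort(CohortSpec(seed=8))


def test_default_pooling_counts():
    spec = CohortSpec(seed=2)
    pools = make_pools(generate_cohort(spec), spec)
    assert len(pools) == 30                                # 6 groups x 5
    assert sum(p.proteomics for p in pools) == 18          # 6 groups x 3
    for p in pools:
        assert len(p.donor_ids) == 4
    all_donors = [d for p in pools for d in p.donor_ids]
    assert len(all_donors) == len(set(all_donors))         # disjoint pools


def test_singleton_pools():
    spec = CohortSpec(donors_per_group=3, pools_per_group_plasma=3,
                      pools_per_group_proteomics=1, donors_per_pool=1, seed=0)
    pools = make_pools(generate_cohort(spec), spec)
    assert all(len(p.donor_ids) == 1 for p in pools)


def test_pool_age_balance():
    """Round-robin dealing keeps pool mean ages within each group far
    tighter than the group's age range."""
    spec = CohortSpec(seed=3)
    donors = generate_cohort(spec)
    ages = {d.donor_id: d.age_years for d in donors}
    pools = make_pools(donors, spec)
    by_group: dict[str, list[float]] = {}
    for p in pools:
        mean_age = np.mean([ages[d] for d in p.donor_ids])
        by_group.setdefault(p.group, []).append(mean_age)
    for group, means in by_group.items():
        group_ages = [d.age_years for d in donors if d.group == group]
        assert max(means) - min(means) <= max(group_ages) - min(group_ages)


def test_insufficient_donors_names_group():
    spec = CohortSpec(donors_per_group=20, seed=0)
    donors = [d for d in generate_cohort(spec) if d.group != "Old-F"]
    with pytest.raises(ValidationError, match="Old-F"):
        make_pools(donors, spec)


def test_fraction_pools_expand_proteomics_only():
    spec = CohortSpec(seed=0)
    pools = make_pools(generate_cohort(spec), spec)
    fps = fraction_pools(pools)
    assert len(fps) == 36                                  # 18 x 2 fractions
    assert {p.fraction for p in fps} == {"EV", "PROT"}
    assert all(p.source_pool is not None for p in fps)


# ---------------------------------------------------------------------------
# Abundance model
# ---------------------------------------------------------------------------

def _pools():
    spec = CohortSpec(seed=5)
    return make_pools(generate_cohort(spec), spec)


def test_zero_noise_no_effects_gives_flat_identical_tables():
    effects = EffectSpec.null(
        n_proteins=50, donor_sd_log2=0.0, tech_sd_log2=0.0,
        baseline_sd_log2=0.0, lod_log2=float("-inf"))
    ev, prot, _ = simulate_abundance(_pools(), effects, seed=9)
    expected = 2.0 ** effects.baseline_mean_log2
    assert np.allclose(ev.values.to_numpy(), expected)
    assert np.allclose(ev.values.to_numpy(), prot.values.to_numpy())


def test_exact_fraction_ratio_without_noise():
    """ev_enrichment_log2 = 2 with zero noise forces EV/PROT = 4 for
    every EV-enriched protein in every pool."""
    effects = EffectSpec(
        n_proteins=40, frac_ev_enriched=0.5, frac_prot_enriched=0.0,
        ev_enrichment_log2=2.0, donor_sd_log2=0.0, tech_sd_log2=0.0,
        baseline_sd_log2=0.0, lod_log2=float("-inf"))
    ev, prot, truth = simulate_abundance(_pools(), effects, seed=9)
    enriched = truth.fraction_class[truth.fraction_class == "EV"].index
    ratio = ev.values.loc[enriched].to_numpy() / prot.values.loc[enriched].to_numpy()
    assert np.allclose(ratio, 4.0)
    neutral = truth.fraction_class[truth.fraction_class == "none"].index
    assert np.allclose(
        ev.values.loc[neutral].to_numpy() / prot.values.loc[neutral].to_numpy(), 1.0)


def test_simulation_deterministic():
    effects = EffectSpec(n_proteins=30)
    ev1, _, _ = simulate_abundance(_pools(), effects, seed=4)
    ev2, _, _ = simulate_abundance(_pools(), effects, seed=4)
    assert ev1.values.equals(ev2.values)


def test_pooling_attenuates_variance():
    """Across-pool variance of pool means is below across-donor variance
    (averaging four donors)."""
    effects = EffectSpec.null(n_proteins=200, tech_sd_log2=0.0,
                              donor_sd_log2=0.8, baseline_sd_log2=0.0,
                              lod_log2=float("-inf"))
    ev, _, _ = simulate_abundance(_pools(), effects, seed=12)
    pool_log2 = np.log2(ev.values.to_numpy())
    pool_var = pool_log2.var(axis=1).mean()
    donor_var = effects.donor_sd_log2 ** 2
    assert pool_var < donor_var


def test_lod_censoring_creates_missingness():
    effects = EffectSpec.null(n_proteins=400, lod_log2=20.0)  # at the mean
    ev, _, _ = simulate_abundance(_pools(), effects, seed=13)
    frac_missing = ev.values.isna().to_numpy().mean()
    assert 0.3 < frac_missing < 0.7


def test_effectspec_validation():
    with pytest.raises(ValidationError):
        EffectSpec(n_proteins=10, frac_ev_enriched=0.7, frac_prot_enriched=0.7)
    with pytest.raises(ValidationError):
        EffectSpec(n_proteins=10, donor_sd_log2=-1.0)
    with pytest.raises(ValidationError):
        AgeEffect(scope="all", offsets={})
    with pytest.raises(ValidationError):
        SexEffect(offsets={"ancient": 1.0})


def test_random_effects_counts_and_scopes():
    base = EffectSpec.null(n_proteins=300)
    spec = random_effects(base, n_age_affected=40, n_sex_affected=10,
                          effect_log2=2.0, seed=3)
    assert len(spec.age_affected) == 40
    assert len(spec.sex_affected) == 10
    assert not set(spec.age_affected) & set(spec.sex_affected)
    for eff in spec.age_affected.values():
        assert abs(eff.offsets["mid"]) == 2.0
        assert abs(eff.offsets["old"]) == 4.0


# ---------------------------------------------------------------------------
# Particles
# ---------------------------------------------------------------------------

def test_particles_cv_zero_hits_group_mean():
    pools = _pools()
    means = {p.group: 1e10 for p in pools}
    means["Mid-M"] = 2e10
    from poolfrac.group_stats import normalize_particles

    ms = simulate_particles(pools, means, cv=0.0, seed=1)
    groups = {p.pool_id: p.group for p in pools}
    for m in ms:
        assert normalize_particles(m) == pytest.approx(means[groups[m.pool_id]])


def test_particles_group_offset_recovered():
    pools = _pools()
    means = {p.group: 1e10 for p in pools}
    means["Mid-M"] = 2e10
    from poolfrac.group_stats import particles_by_group

    ms = simulate_particles(pools, means, cv=0.1, seed=2)
    groups = {p.pool_id: p.group for p in pools}
    rec = particles_by_group(ms, groups, "NTA")
    mid_m = np.mean(rec.pop("Mid-M"))
    assert all(mid_m > np.mean(v) for v in rec.values())


def test_particles_deterministic():
    pools = _pools()
    means = {p.group: 1e10 for p in pools}
    assert simulate_particles(pools, means, seed=5) == simulate_particles(
        pools, means, seed=5)
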