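"""End-to-end orchestration: simulate -> filter -> DE -> sets -> stats
-> cluster, as one reproducible, fully logged run.

A run is a pure function of its :class:`RunConfig`; a single top-level
seed deterministically derives one child seed per stage so individual
stages can be re-run in isolation without disturbing the others.
"""

from __future__ import annotations

import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import io as pio
from .cluster import cluster_heatmap, cluster_purity
from .consistency import (
    ComparisonPlan,
    de_directions,
    de_results_to_frame,
    de_sets,
    null_consistency_rate,
    null_paired_rate,
    paired_fraction_de,
    run_plan,
)
from .group_stats import fisher_lsd, particles_by_group
from .model import SEXES, ValidationError
from .preprocess import detection_filter
from .sets import (
    age_dynamic_proteins,
    sex_common_age_proteins,
    sex_consistent_across_ages,
    venn,
)
from .simulate import (
    CohortSpec,
    EffectSpec,
    fraction_pools,
    generate_cohort,
    make_pools,
    random_effects,
    simulate_abundance,
    simulate_analytes,
    simulate_particles,
)

_STAGES = ("cohort", "abundance", "particles", "analytes")


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage child seed (< 2**31) from the top seed."""
    import zlib

    key = zlib.crc32(stage.encode())  # stable across processes
    ss = np.random.SeedSequence(entropy=seed, spawn_key=(key,))
    return int(ss.generate_state(1)[0] % 2**31)


@dataclass
class RunConfig:
    """Everything a run needs; serializable to/from YAML and copied into
    the output directory for provenance."""

    seed: int = 0
    outdir: str = "poolfrac_run"
    # simulation
    donors_per_group: int = 20
    pools_per_group_plasma: int = 5
    pools_per_group_proteomics: int = 3
    donors_per_pool: int = 4
    n_proteins: int = 1500
    n_age_affected: int = 60
    n_sex_affected: int = 20
    effect_log2: float = 2.0
    donor_sd_log2: float = 0.5
    tech_sd_log2: float = 0.2
    lod_log2: float = 12.0
    particle_mean: float = 3e10
    particle_cv: float = 0.25
    # analysis thresholds
    filter_threshold: float = 0.8
    min_comparisons: int = 2
    # clustering
    cluster_distance: str = "correlation"
    cluster_linkage: str = "average"
    cluster_cut_k: int = 3

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @staticmethod
    def from_yaml(path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - set(RunConfig.__dataclass_fields__)
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return RunConfig(**data)

    def cohort_spec(self) -> CohortSpec:
        return CohortSpec(
            donors_per_group=self.donors_per_group,
            pools_per_group_plasma=self.pools_per_group_plasma,
            pools_per_group_proteomics=self.pools_per_group_proteomics,
            donors_per_pool=self.donors_per_pool,
            seed=stage_seed(self.seed, "cohort"),
        )

    def effect_spec(self) -> EffectSpec:
        base = EffectSpec(
            n_proteins=self.n_proteins,
            donor_sd_log2=self.donor_sd_log2,
            tech_sd_log2=self.tech_sd_log2,
            lod_log2=self.lod_log2,
        )
        return random_effects(
            base,
            n_age_affected=self.n_age_affected,
            n_sex_affected=self.n_sex_affected,
            effect_log2=self.effect_log2,
            seed=stage_seed(self.seed, "effects"),
        )


def run_all(config: RunConfig) -> dict:
    """Execute the full pipeline; returns the summary dict that is also
    written to ``summary.txt`` (plus all intermediate tables)."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = []
    t0 = time.time()

    def log(stage: str, message: str) -> None:
        log_lines.append(
            f"[{time.time() - t0:8.2f}s] seed={config.seed} {stage}: {message}"
        )

    config.to_yaml(out / "config.yaml")
    summary: dict = {"seed": config.seed}

    try:
        # -- simulate ------------------------------------------------------
        stage = "simulate"
        cohort = generate_cohort(config.cohort_spec())
        pools = make_pools(cohort, config.cohort_spec())
        effects = config.effect_spec()
        ev, prot, truth = simulate_abundance(
            pools, effects, seed=stage_seed(config.seed, "abundance")
        )
        meta = pools + fraction_pools(pools)
        pio.write_pool_metadata(meta, out / "pools.tsv")
        pio.write_abundance(ev, out / "ev.tsv")
        pio.write_abundance(prot, out / "prot.tsv")
        pio.write_table(truth.to_frame(), out / "truth.tsv")
        log(stage, f"{len(cohort)} donors, {len(pools)} plasma pools, "
                   f"{ev.shape[0]} proteins x {ev.shape[1]} pools per fraction")

        # -- filter --------------------------------------------------------
        stage = "filter"
        ev_f, ev_report = detection_filter(ev, config.filter_threshold)
        prot_f, prot_report = detection_filter(prot, config.filter_threshold)
        pio.write_table(ev_report.to_frame(), out / "filter_ev.tsv")
        pio.write_table(prot_report.to_frame(), out / "filter_prot.tsv")
        summary["universe_ev"] = ev_report.n_retained
        summary["universe_prot"] = prot_report.n_retained
        log(stage, f"EV {ev_report.n_retained}/{ev_report.n_input} retained; "
                   f"PROT {prot_report.n_retained}/{prot_report.n_input} retained")

        # -- fraction contrast + venn -------------------------------------
        stage = "fraction_de"
        paired = paired_fraction_de(ev_f, prot_f)
        pio.write_table(de_results_to_frame(paired), out / "de_EV_vs_PROT.tsv")
        v = venn({"EV": set(ev_f.proteins), "PROT": set(prot_f.proteins)})
        pio.write_table(pd.DataFrame([
            {"region": k, "count": v.region_counts[k],
             "pct_of_union": v.region_percentages[k]}
            for k in v.region_counts
        ]), out / "venn_universes.tsv")
        summary["venn"] = {
            "union": v.union_size,
            "counts": v.region_counts,
            "percentages": v.region_percentages,
        }
        n_paired_de = len(de_sets(paired)["de"])
        summary["paired_de"] = n_paired_de
        log(stage, f"{n_paired_de} fraction-DE proteins; venn {v.region_counts}")

        # -- age / sex comparisons ----------------------------------------
        stage = "cross_group_de"
        plan = ComparisonPlan()
        results, plan_summary = run_plan(
            {"EV": ev_f, "PROT": prot_f}, meta, plan,
            expected_pools_per_group=config.pools_per_group_proteomics,
        )
        for (fraction, label), res in results.items():
            safe = label.replace(":", "_")
            pio.write_table(de_results_to_frame(res), out / f"de_{fraction}_{safe}.tsv")
        m = config.pools_per_group_proteomics
        plan_summary["null_rate"] = null_consistency_rate(m, m)
        plan_summary["observed_rate"] = plan_summary["n_DE"] / plan_summary["n_universe"]
        pio.write_table(plan_summary, out / "de_summary.tsv")
        summary["de_summary"] = plan_summary.to_dict(orient="records")
        log(stage, f"{len(results)} comparisons; "
                   f"analytic null rate {null_consistency_rate(m, m):.4g}")

        # -- set analysis --------------------------------------------------
        stage = "sets"
        sets_out: dict = {}
        for fraction in ("EV", "PROT"):
            per_sex_dirs = {}
            per_sex_dynamic = {}
            for sex in SEXES:
                # Key by the age pair (not the sex-prefixed label) so the
                # two sexes' results align comparison-by-comparison.
                de_dir = {
                    f"{a}_vs_{b}": de_directions(
                        results[(fraction, plan.age_label(sex, a, b))]
                    )
                    for s2, a, b in plan.age_comparisons if s2 == sex
                }
                dynamic = age_dynamic_proteins(
                    {lab: set(d) for lab, d in de_dir.items()},
                    min_comparisons=config.min_comparisons,
                )
                per_sex_dirs[sex] = de_dir
                per_sex_dynamic[sex] = dynamic
                pio.write_gene_list(dynamic, out / f"dynamic_{fraction}_{sex}.txt")
            common = sex_common_age_proteins(
                per_sex_dirs["M"], per_sex_dirs["F"],
                per_sex_dynamic["M"], per_sex_dynamic["F"],
            )
            pio.write_gene_list(common, out / f"sex_common_age_{fraction}.txt")
            sex_de = {
                g: de_directions(results[(fraction, plan.sex_label(g))])
                for g in plan.sex_comparisons
            }
            stable = sex_consistent_across_ages(sex_de)
            pio.write_gene_list(stable, out / f"sex_consistent_{fraction}.txt")
            sets_out[fraction] = {
                "dynamic_M": len(per_sex_dynamic["M"]),
                "dynamic_F": len(per_sex_dynamic["F"]),
                "sex_common_age": len(common),
                "sex_consistent": len(stable),
            }
        summary["sets"] = sets_out
        log(stage, str(sets_out))

        # -- group statistics ---------------------------------------------
        stage = "group_stats"
        group_means = {p.group: config.particle_mean for p in pools}
        particles = simulate_particles(
            pools, group_means, cv=config.particle_cv,
            seed=stage_seed(config.seed, "particles"),
        )
        pio.write_particles(particles, out / "particles.tsv")
        pool_groups = {p.pool_id: p.group for p in pools}
        lsd = fisher_lsd(particles_by_group(particles, pool_groups, "NTA"))
        pio.write_table(lsd.to_frame(), out / "lsd_particles_NTA.tsv")
        analytes = simulate_analytes(cohort, seed=stage_seed(config.seed, "analytes"))
        pio.write_analytes(analytes, out / "analytes.tsv")
        for analyte in analytes.values.columns:
            res = fisher_lsd(analytes.by_group(analyte))
            pio.write_table(res.to_frame(), out / f"lsd_{analyte}.tsv")
        summary["particles_F"] = lsd.f_stat
        log(stage, f"particle LSD omnibus F={lsd.f_stat:.3f} (p={lsd.f_p_value:.3g})")

        # -- clustering ----------------------------------------------------
        stage = "cluster"
        cluster_out = {}
        for sex in SEXES:
            labels = [plan.age_label(sex, a, b)
                      for s2, a, b in plan.age_comparisons if s2 == sex]
            dynamic = age_dynamic_proteins(
                {lab: de_sets(results[("EV", lab)])["de"] for lab in labels},
                min_comparisons=config.min_comparisons,
            )
            pool_ids = [p.pool_id for p in meta
                        if p.fraction == "EV" and p.sex == sex]
            if len(dynamic) < 2:
                log(stage, f"EV-{sex}: fewer than 2 dynamic proteins; skipped")
                continue
            sub = ev_f.select_proteins(dynamic).select_pools(pool_ids)
            result = cluster_heatmap(
                sub,
                distance=config.cluster_distance,
                linkage=config.cluster_linkage,
                cut_k=config.cluster_cut_k,
            )
            (out / f"cluster_EV_{sex}_cols.nwk").write_text(result.col_newick() + "\n")
            (out / f"cluster_EV_{sex}_rows.nwk").write_text(result.row_newick() + "\n")
            pio.write_table(
                pd.DataFrame({
                    "pool": list(result.col_clusters),
                    "cluster": list(result.col_clusters.values()),
                }),
                out / f"cluster_EV_{sex}_labels.tsv",
            )
            age_of = {p.pool_id: p.age_group for p in meta}
            purity = cluster_purity(result.col_clusters, age_of)
            cluster_out[f"EV_{sex}_purity"] = purity
            log(stage, f"EV-{sex}: {len(dynamic)} proteins, "
                       f"column purity at k={config.cluster_cut_k}: {purity:.3f}")
        summary["clustering"] = cluster_out

    except Exception as exc:
        log(stage, f"FAILED: {exc}")
        (out / "run.log").write_text("\n".join(log_lines) + "\n")
        raise RuntimeError(
            f"stage {stage!r} failed; last good outputs under {out}"
        ) from exc

    # -- report ------------------------------------------------------------
    report = _render_summary(summary, config)
    (out / "summary.txt").write_text(report)
    log("report", "summary written")
    (out / "run.log").write_text("\n".join(log_lines) + "\n")
    return summary


def _render_summary(summary: dict, config: RunConfig) -> str:
    m = config.pools_per_group_proteomics
    lines = [
        "poolfrac run summary",
        "====================",
        f"seed: {summary['seed']}",
        "",
        f"protein universes after >{config.filter_threshold:.0%} detection filter: "
        f"EV {summary['universe_ev']}, PROT {summary['universe_prot']}",
        "",
        "universe overlap (percent of union):",
    ]
    for region, count in summary["venn"]["counts"].items():
        pctg = summary["venn"]["percentages"][region]
        lines.append(f"  {region}: {count} ({pctg}%)")
    lines += [
        "",
        f"paired EV-vs-PROT DE proteins (all matched-pool ratios "
        f"one-directional): {summary['paired_de']}",
        "",
        "age / sex comparisons (all-cross-ratio rule; "
        f"analytic null rate {null_consistency_rate(m, m):.4g} per comparison):",
        f"{'fraction':<9}{'comparison':<18}{'n_DE':>6}{'up':>5}{'down':>6}{'rate':>8}",
    ]
    for row in summary["de_summary"]:
        lines.append(
            f"{row['fraction']:<9}{row['comparison']:<18}{row['n_DE']:>6}"
            f"{row['n_up']:>5}{row['n_down']:>6}{row['observed_rate']:>8.3f}"
        )
    lines += ["", "protein-set sizes:"]
    for fraction, d in summary["sets"].items():
        lines.append(f"  {fraction}: {d}")
    lines += ["", "clustering (column purity vs age groups):"]
    for key, val in summary.get("clustering", {}).items():
        lines.append(f"  {key}: {val:.3f}")
    lines += [
        "",
        f"paired-rule analytic null at n=18: {null_paired_rate(18):.3g}",
        "",
    ]
    return "\n".join(lines)
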