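#!/usr/bin/env python
"""Hierarchical clustering of the age-dynamic EV proteins per sex:
z-scored log2 abundance, correlation distance, average linkage.
Reports whether the young / mid / old pools separate into pure column
clusters at k = 3.

Reads results/filter/, results/sets/, results/data/pools.tsv; writes
results/cluster/.
"""

from pathlib import Path

import pandas as pd

from poolfrac import io as pio
from poolfrac.cluster import cluster_heatmap, cluster_purity

ROOT = Path(__file__).resolve().parent.parent / "results"
OUT = ROOT / "cluster"

if __name__ == "__main__":
    OUT.mkdir(parents=True, exist_ok=True)
    ev = pio.read_abundance(ROOT / "filter" / "ev_filtered.tsv", "EV")
    meta = pio.read_pool_metadata(ROOT / "data" / "pools.tsv")
    ages = {p.pool_id: p.age_group for p in meta}

    for sex in ("M", "F"):
        dynamic = set((ROOT / "sets" / f"dynamic_EV_{sex}.txt").read_text().split())
        pool_ids = [p.pool_id for p in meta
                    if p.fraction == "EV" and p.sex == sex]
        if len(dynamic) < 2:
            print(f"EV-{sex}: fewer than 2 age-dynamic proteins; skipping")
            continue
        sub = ev.select_proteins(dynamic).select_pools(pool_ids)
        result = cluster_heatmap(sub, cut_k=3)
        (OUT / f"EV_{sex}_cols.nwk").write_text(result.col_newick() + "\n")
        (OUT / f"EV_{sex}_rows.nwk").write_text(result.row_newick() + "\n")
        pio.write_table(result.zscores.reset_index(names="protein"),
                        OUT / f"EV_{sex}_zscores.tsv")
        pio.write_table(pd.DataFrame({
            "pool": list(result.col_clusters),
            "cluster": list(result.col_clusters.values()),
        }), OUT / f"EV_{sex}_col_clusters.tsv")
        purity = cluster_purity(result.col_clusters, ages)
        print(f"EV-{sex}: {len(dynamic)} age-dynamic proteins over "
              f"{len(pool_ids)} pools; column purity at k=3: {purity:.3f}")
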