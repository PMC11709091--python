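#!/usr/bin/env python
"""Detection-rate filtering and universe overlap.

Keeps proteins detected in more than 80% of each fraction's pools,
then reports the overlap of the two retained universes as exclusive /
common Venn regions with percentages of the union.

Reads results/data/, writes results/filter/.
"""

from pathlib import Path

import pandas as pd

from poolfrac import io as pio
from poolfrac.preprocess import detection_filter
from poolfrac.sets import venn

DATA = Path(__file__).resolve().parent.parent / "results" / "data"
OUT = Path(__file__).resolve().parent.parent / "results" / "filter"
THRESHOLD = 0.8

if __name__ == "__main__":
    OUT.mkdir(parents=True, exist_ok=True)
    ev = pio.read_abundance(DATA / "ev.tsv", "EV")
    prot = pio.read_abundance(DATA / "prot.tsv", "PROT")
    ev_f, ev_rep = detection_filter(ev, THRESHOLD)
    prot_f, prot_rep = detection_filter(prot, THRESHOLD)
    pio.write_abundance(ev_f, OUT / "ev_filtered.tsv")
    pio.write_abundance(prot_f, OUT / "prot_filtered.tsv")
    pio.write_table(ev_rep.to_frame(), OUT / "filter_report_ev.tsv")
    pio.write_table(prot_rep.to_frame(), OUT / "filter_report_prot.tsv")

    v = venn({"EV": set(ev_f.proteins), "PROT": set(prot_f.proteins)})
    pio.write_table(pd.DataFrame(
        [{"region": k, "count": v.region_counts[k],
          "pct_of_union": v.region_percentages[k]} for k in v.region_counts]),
        OUT / "venn_universes.tsv")

    print(f"EV: {ev_rep.n_retained}/{ev_rep.n_input} proteins detected in "
          f">{THRESHOLD:.0%} of {ev.shape[1]} pools")
    print(f"PROT: {prot_rep.n_retained}/{prot_rep.n_input}")
    for region, count in v.region_counts.items():
        print(f"  {region}: {count} ({v.region_percentages[region]}% of "
              f"{v.union_size})")
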