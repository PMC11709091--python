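#!/usr/bin/env python
"""Classical group statistics: particle concentrations normalized to
particles per mL of source plasma, and plasma analytes (ALB / HDL /
LDL / VLDL), compared across the six groups by Fisher's LSD.

Reads results/data/, writes results/stats/.
"""

from pathlib import Path

from poolfrac import io as pio
from poolfrac.group_stats import fisher_lsd, particles_by_group

ROOT = Path(__file__).resolve().parent.parent / "results"
OUT = ROOT / "stats"

if __name__ == "__main__":
    OUT.mkdir(parents=True, exist_ok=True)
    meta = pio.read_pool_metadata(ROOT / "data" / "pools.tsv")
    pool_groups = {p.pool_id: p.group for p in meta}

    measurements = pio.read_particles(ROOT / "data" / "particles.tsv")
    for instrument in ("NTA", "NFCM"):
        groups = particles_by_group(measurements, pool_groups, instrument)
        res = fisher_lsd(groups)
        pio.write_table(res.to_frame(), OUT / f"lsd_particles_{instrument}.tsv")
        n_sig = sum(r.significance_band != "ns" for r in res.pairs)
        print(f"{instrument}: omnibus F={res.f_stat:.2f} (p={res.f_p_value:.3f}); "
              f"{n_sig}/{len(res.pairs)} significant pairs")

    analytes = pio.read_analytes(ROOT / "data" / "analytes.tsv")
    for analyte in analytes.values.columns:
        res = fisher_lsd(analytes.by_group(analyte))
        pio.write_table(res.to_frame(), OUT / f"lsd_{analyte}.tsv")
        mf = [r for r in res.pairs
              if r.pair[0].split("-")[0] == r.pair[1].split("-")[0]]
        sig = [f"{r.pair[0]} vs {r.pair[1]}: {r.significance_band}" for r in mf]
        print(f"{analyte} ({analytes.units[analyte]}): within-age M-vs-F "
              + "; ".join(sig))
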