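#!/usr/bin/env python
"""Set-intersection triage of the DE calls: proteins recurring across
age comparisons within a sex ("age-dynamic"), age effects shared by
both sexes with consistent direction, and sex differences stable
across all three age groups.

Reads results/de/ per-comparison tables, writes results/sets/.
"""

from pathlib import Path

import pandas as pd

from poolfrac import io as pio
from poolfrac.sets import (
    age_dynamic_proteins,
    sex_common_age_proteins,
    sex_consistent_across_ages,
)

ROOT = Path(__file__).resolve().parent.parent / "results"
OUT = ROOT / "sets"
AGE_PAIRS = ("young_vs_mid", "young_vs_old", "mid_vs_old")
MIN_COMPARISONS = 2


def directions(fraction: str, label: str) -> dict[str, int]:
    df = pio.read_table(ROOT / "de" / f"de_{fraction}_{label}.tsv")
    de = df[df["verdict"].isin(["up", "down"])]
    return {r.protein: (1 if r.verdict == "up" else -1)
            for r in de.itertuples()}


if __name__ == "__main__":
    OUT.mkdir(parents=True, exist_ok=True)
    rows = []
    for fraction in ("EV", "PROT"):
        per_sex = {sex: {pair: directions(fraction, f"{sex}_{pair}")
                         for pair in AGE_PAIRS} for sex in ("M", "F")}
        dynamic = {sex: age_dynamic_proteins(
            {k: set(v) for k, v in per_sex[sex].items()}, MIN_COMPARISONS)
            for sex in ("M", "F")}
        common = sex_common_age_proteins(per_sex["M"], per_sex["F"],
                                         dynamic["M"], dynamic["F"])
        sex_de = {g: directions(fraction, f"{g}_M_vs_F")
                  for g in ("young", "mid", "old")}
        stable = sex_consistent_across_ages(sex_de)

        for sex in ("M", "F"):
            pio.write_gene_list(dynamic[sex], OUT / f"dynamic_{fraction}_{sex}.txt")
        pio.write_gene_list(common, OUT / f"sex_common_age_{fraction}.txt")
        pio.write_gene_list(stable, OUT / f"sex_consistent_{fraction}.txt")
        rows.append({
            "fraction": fraction,
            f"dynamic_M (DE in >= {MIN_COMPARISONS} age comparisons)": len(dynamic["M"]),
            "dynamic_F": len(dynamic["F"]),
            "sex_common_age": len(common),
            "sex_consistent": len(stable),
        })
        print(f"{fraction}: dynamic M={len(dynamic['M'])} F={len(dynamic['F'])}; "
              f"sex-common age-dynamic={len(common)}; "
              f"stable sex markers={len(stable)}")
    pd.DataFrame(rows).to_csv(OUT / "set_sizes.tsv", sep="\t", index=False)
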