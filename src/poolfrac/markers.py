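"""Marker-panel characterization of the EV and PROT fractions.

Panels are shipped as editable plain-text data files (one identifier
per line, ``#`` comments): canonical EV markers, the top-100
Exocarta/Vesiclepedia match list, apolipoproteins, abundant
blood-component proteins and complement components.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .consistency import paired_fraction_de
from .model import AbundanceTable, ValidationError


@dataclass(frozen=True)
class MarkerPanel:
    name: str
    members: tuple[str, ...]
    source_note: str = ""

    def __post_init__(self) -> None:
        if not self.members:
            raise ValidationError(f"panel {self.name!r} is empty")
        if len(set(self.members)) != len(self.members):
            dupes = sorted({m for m in self.members if self.members.count(m) > 1})
            raise ValidationError(
                f"panel {self.name!r} has duplicate members: {', '.join(dupes)}"
            )


def parse_panel_text(text: str, name: str) -> MarkerPanel:
    members: list[str] = []
    notes: list[str] = []
    for line in text.splitlines():
        if line.startswith("#"):
            notes.append(line.lstrip("# "))
            continue
        symbol = line.split("#", 1)[0].strip()
        if symbol:
            members.append(symbol)
    return MarkerPanel(name=name, members=tuple(members),
                       source_note=" ".join(notes).strip())


def load_panel(path: Union[str, Path]) -> MarkerPanel:
    path = Path(path)
    return parse_panel_text(path.read_text(), name=path.stem)


def builtin_panels() -> list[MarkerPanel]:
    """The shipped panels, read from the package's data files."""
    root = resources.files("poolfrac").joinpath("data/panels")
    panels = []
    for entry in sorted(root.iterdir(), key=lambda e: e.name):
        if entry.name.endswith(".txt"):
            panels.append(parse_panel_text(entry.read_text(), name=entry.name[:-4]))
    return panels


def get_panel(name: str) -> MarkerPanel:
    for panel in builtin_panels():
        if panel.name == name:
            return panel
    known = ", ".join(p.name for p in builtin_panels())
    raise ValidationError(f"unknown panel {name!r}; shipped panels: {known}")


# ---------------------------------------------------------------------------
# Panel summaries
# ---------------------------------------------------------------------------

def rank_markers(
    table: AbundanceTable, panel: MarkerPanel, log_base: int = 10
) -> pd.DataFrame:
    """Mean abundance, whole-table rank and detection rate per marker.

    Rank 1 is the highest mean abundance over detected pools; ranks are
    computed over all detected proteins of the table, with ties broken
    by identifier so they form a permutation of 1..n.  Markers absent
    from the table (or never detected) get an undefined rank (NaN) and
    detection rate 0.  ``log_base`` (10 or 2) selects the scale of the
    reported log mean.
    """
    if log_base not in (10, 2):
        raise ValidationError("log_base must be 10 or 2")
    means = table.values.mean(axis=1, skipna=True)
    rate = table.detection_rate()
    detected = means.dropna()
    order = sorted(detected.index, key=lambda p: (-detected[p], p))
    ranks = {p: i + 1 for i, p in enumerate(order)}
    log = np.log10 if log_base == 10 else np.log2

    rows = []
    for m in panel.members:
        present = m in table.values.index
        mean = float(means[m]) if present and not np.isnan(means.get(m, np.nan)) else np.nan
        rows.append({
            "marker": m,
            "mean_abundance": mean,
            f"log{log_base}_mean": float(log(mean)) if mean > 0 else np.nan,
            "rank": float(ranks[m]) if m in ranks else np.nan,
            "detection_rate": float(rate[m]) if present else 0.0,
        })
    return pd.DataFrame(rows)


def panel_contrast(
    ev: AbundanceTable, prot: AbundanceTable, panel: MarkerPanel
) -> pd.DataFrame:
    """Per-marker log2 mean +/- SD in each fraction and the enrichment
    direction from the paired per-pool ratio rule ("EV", "PROT", or ""
    when not consistently directional / not evaluable)."""
    shared = [m for m in panel.members if m in ev.values.index and m in prot.values.index]
    direction: dict[str, str] = {}
    if shared:
        results = paired_fraction_de(ev.select_proteins(shared),
                                     prot.select_proteins(shared))
        for r in results:
            direction[r.protein] = {"up": "EV", "down": "PROT"}.get(r.verdict, "")

    def stats_of(table: AbundanceTable, m: str) -> tuple[float, float]:
        if m not in table.values.index:
            return np.nan, np.nan
        vals = table.values.loc[m].dropna()
        if vals.empty:
            return np.nan, np.nan
        logged = np.log2(vals.to_numpy())
        return float(logged.mean()), float(logged.std(ddof=1)) if logged.size > 1 else 0.0

    rows = []
    for m in panel.members:
        ev_mean, ev_sd = stats_of(ev, m)
        prot_mean, prot_sd = stats_of(prot, m)
        rows.append({
            "marker": m,
            "ev_mean_log2": ev_mean,
            "ev_sd_log2": ev_sd,
            "prot_mean_log2": prot_mean,
            "prot_sd_log2": prot_sd,
            "direction": direction.get(m, ""),
        })
    return pd.DataFrame(rows)
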