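"""Tab-delimited readers and writers.

All pipeline artifacts are plain TSV: abundance matrices (proteins x
pools), pool metadata, particle counts, analyte tables and result
tables.  Abundance files map empty cells, ``NA`` and ``0`` to "not
detected"; the original token of every cell is kept so that a file can
be rewritten byte-for-byte.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .model import (
    AbundanceTable,
    AnalyteTable,
    ParticleMeasurement,
    PoolMetadata,
    ValidationError,
)

PathLike = Union[str, Path]

#: Tokens meaning "not detected" in an abundance matrix.
MISSING_TOKENS = ("", "NA", "NaN", "nan")

#: Fixed float precision for result tables (stated in each file header).
FLOAT_FORMAT = "%.6g"


def _fmt(x: object) -> str:
    if isinstance(x, float):
        if np.isnan(x):
            return "NA"
        return FLOAT_FORMAT % x
    return str(x)


# ---------------------------------------------------------------------------
# Abundance matrices
# ---------------------------------------------------------------------------

def read_abundance(path: PathLike, fraction: Optional[str] = None) -> AbundanceTable:
    """Read a proteins x pools abundance matrix.

    First column: protein identifier (case-sensitive gene symbol).
    Header row: pool ids.  Empty cells, ``NA`` and ``0`` all mean "not
    detected" and become missing values; the original token is recorded
    for lossless round-trip.

    Raises :class:`ValidationError` on duplicate protein or pool ids and
    on non-numeric cells (reporting row and column).
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines:
        raise ValidationError(f"{path}: empty file")
    from collections import Counter

    header = lines[0].split("\t")
    pool_ids = header[1:]
    dupes = sorted(p for p, c in Counter(pool_ids).items() if c > 1)
    if dupes:
        raise ValidationError(f"{path}: duplicate pool ids in header: {', '.join(dupes)}")

    proteins: list[str] = []
    rows: list[list[float]] = []
    tokens: list[list[str]] = []
    for i, line in enumerate(lines[1:], start=2):
        cells = line.split("\t")
        if len(cells) != len(header):
            raise ValidationError(
                f"{path}: line {i} has {len(cells)} fields, expected {len(header)}"
            )
        proteins.append(cells[0])
        tokens.append(cells[1:])
        row: list[float] = []
        for j, tok in enumerate(cells[1:]):
            if tok in MISSING_TOKENS:
                row.append(np.nan)
                continue
            try:
                val = float(tok)
            except ValueError:
                raise ValidationError(
                    f"{path}: non-numeric value {tok!r} at row {i} "
                    f"(protein {cells[0]!r}), column {pool_ids[j]!r}"
                ) from None
            row.append(np.nan if val == 0.0 else val)
        rows.append(row)

    dupes = sorted(p for p, c in Counter(proteins).items() if c > 1)
    if dupes:
        raise ValidationError(
            f"{path}: duplicate protein ids: {', '.join(dupes)}"
        )
    values = pd.DataFrame(rows, index=proteins, columns=pool_ids, dtype=float)
    raw = pd.DataFrame(tokens, index=proteins, columns=pool_ids, dtype=object)
    return AbundanceTable(values, fraction=fraction, raw_tokens=raw)


def write_abundance(table: AbundanceTable, path: PathLike) -> None:
    """Write an abundance matrix as TSV.

    If the table was read from disk (``raw_tokens`` present), the
    original tokens are re-emitted so read -> write is the identity.
    Otherwise missing values are written as empty cells and numbers at
    ``%.6g``.
    """
    path = Path(path)
    out: list[str] = ["\t".join(["protein", *table.pools])]
    if table.raw_tokens is not None:
        for protein in table.proteins:
            out.append("\t".join([protein, *table.raw_tokens.loc[protein]]))
    else:
        for protein in table.proteins:
            cells = [
                "" if np.isnan(v) else FLOAT_FORMAT % v
                for v in table.values.loc[protein]
            ]
            out.append("\t".join([protein, *cells]))
    path.write_text("\n".join(out) + "\n")


# ---------------------------------------------------------------------------
# Pool metadata
# ---------------------------------------------------------------------------

_META_COLUMNS = [
    "pool_id", "sex", "age_group", "fraction", "donor_ids",
    "plasma_volume_mL", "proteomics", "source_pool",
]


def write_pool_metadata(pools: Sequence[PoolMetadata], path: PathLike) -> None:
    rows = []
    for p in pools:
        rows.append({
            "pool_id": p.pool_id,
            "sex": p.sex,
            "age_group": p.age_group,
            "fraction": p.fraction or "",
            "donor_ids": ";".join(p.donor_ids),
            "plasma_volume_mL": FLOAT_FORMAT % p.plasma_volume_mL,
            "proteomics": int(p.proteomics),
            "source_pool": p.source_pool or "",
        })
    pd.DataFrame(rows, columns=_META_COLUMNS).to_csv(path, sep="\t", index=False)


def read_pool_metadata(path: PathLike) -> list[PoolMetadata]:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    pools = []
    for _, r in df.iterrows():
        pools.append(PoolMetadata(
            pool_id=r["pool_id"],
            sex=r["sex"],
            age_group=r["age_group"],
            fraction=r["fraction"] or None,
            donor_ids=tuple(r["donor_ids"].split(";")) if r["donor_ids"] else (),
            plasma_volume_mL=float(r["plasma_volume_mL"]),
            proteomics=bool(int(r.get("proteomics", "0") or 0)),
            source_pool=r.get("source_pool", "") or None,
        ))
    ids = [p.pool_id for p in pools]
    dupes = sorted({i for i in ids if ids.count(i) > 1})
    if dupes:
        raise ValidationError(f"{path}: duplicate pool ids: {', '.join(dupes)}")
    return pools


# ---------------------------------------------------------------------------
# Particle measurements
# ---------------------------------------------------------------------------

def write_particles(measurements: Sequence[ParticleMeasurement], path: PathLike) -> None:
    rows = [{
        "pool_id": m.pool_id,
        "instrument": m.instrument,
        "measured_concentration": FLOAT_FORMAT % m.measured_concentration,
        "dilution_factor": FLOAT_FORMAT % m.dilution_factor,
        "prep_volume_mL": FLOAT_FORMAT % m.prep_volume_mL,
        "plasma_input_mL": FLOAT_FORMAT % m.plasma_input_mL,
    } for m in measurements]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_particles(path: PathLike) -> list[ParticleMeasurement]:
    df = pd.read_csv(path, sep="\t")
    return [
        ParticleMeasurement(
            pool_id=str(r["pool_id"]),
            instrument=str(r["instrument"]),
            measured_concentration=float(r["measured_concentration"]),
            dilution_factor=float(r["dilution_factor"]),
            prep_volume_mL=float(r["prep_volume_mL"]),
            plasma_input_mL=float(r["plasma_input_mL"]),
        )
        for _, r in df.iterrows()
    ]


# ---------------------------------------------------------------------------
# Analyte tables
# ---------------------------------------------------------------------------

_UNIT_RE = re.compile(r"^(?P<name>.+?) \((?P<unit>[^)]+)\)$")


def write_analytes(table: AnalyteTable, path: PathLike) -> None:
    """Columns: sample_id, group, then one ``NAME (unit)`` column per analyte."""
    cols = {"sample_id": list(table.values.index),
            "group": [table.groups[s] for s in table.values.index]}
    for analyte in table.values.columns:
        unit = table.units.get(analyte, "")
        label = f"{analyte} ({unit})" if unit else analyte
        cols[label] = [_fmt(float(v)) for v in table.values[analyte]]
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False)


def read_analytes(path: PathLike) -> AnalyteTable:
    df = pd.read_csv(path, sep="\t")
    groups = dict(zip(df["sample_id"].astype(str), df["group"].astype(str)))
    units: dict[str, str] = {}
    data: dict[str, list[float]] = {}
    for col in df.columns:
        if col in ("sample_id", "group"):
            continue
        m = _UNIT_RE.match(col)
        name, unit = (m.group("name"), m.group("unit")) if m else (col, "")
        units[name] = unit
        data[name] = df[col].astype(float).tolist()
    values = pd.DataFrame(data, index=df["sample_id"].astype(str).tolist())
    return AnalyteTable(values=values, units=units, groups=groups)


# ---------------------------------------------------------------------------
# Generic result tables and gene lists
# ---------------------------------------------------------------------------

def write_table(result: pd.DataFrame, path: PathLike) -> None:
    """Write a result table deterministically.

    Rows are sorted by a ``rank`` column if present, else by ``protein``
    ascending if present, else left in input order; columns keep their
    given order.  Floats are written at the fixed precision stated in
    the header comment.  An empty result yields a header-only file.
    """
    path = Path(path)
    df = result.copy()
    if "rank" in df.columns:
        df = df.sort_values("rank", kind="mergesort")
    elif "protein" in df.columns:
        df = df.sort_values("protein", kind="mergesort")
    lines = [f"# poolfrac result table; floats formatted {FLOAT_FORMAT}"]
    lines.append("\t".join(map(str, df.columns)))
    for _, row in df.iterrows():
        lines.append("\t".join(_fmt(v) for v in row))
    path.write_text("\n".join(lines) + "\n")


def read_table(path: PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def write_gene_list(symbols: Sequence[str], path: PathLike) -> None:
    """One gene symbol per line, sorted — the export format used for
    external enrichment tools."""
    Path(path).write_text("\n".join(sorted(set(symbols))) + "\n")
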