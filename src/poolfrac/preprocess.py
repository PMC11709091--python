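"""Detection-rate filtering prior to differential-abundance analysis.

Proteins quantified in more than a threshold fraction of a fraction's
pools (default: strictly more than 80%) are retained; with the default
design of 18 proteomics pools per fraction this keeps proteins detected
in at least 15 pools.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .model import AbundanceTable, ValidationError


@dataclass
class FilterReport:
    fraction: str | None
    n_input: int
    n_retained: int
    threshold: float
    detection_rate: pd.Series  # per input protein

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "protein": self.detection_rate.index,
            "detection_rate": self.detection_rate.to_numpy(),
            "retained": (self.detection_rate > self.threshold).astype(int),
        })


def detection_filter(
    table: AbundanceTable, threshold: float = 0.8
) -> tuple[AbundanceTable, FilterReport]:
    """Keep proteins detected in strictly more than ``threshold`` of the
    table's pools; protein order is preserved.

    The strict inequality matters at the design's natural breakpoints:
    with 18 pools, 15/18 (83.3%) passes and 14/18 (77.8%) does not.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValidationError(f"threshold must be in [0, 1], got {threshold}")
    if table.shape[0] == 0 or table.shape[1] == 0:
        raise ValidationError("cannot filter an empty table")
    rate = table.detection_rate()
    keep = rate[rate > threshold].index
    filtered = AbundanceTable(table.values.loc[keep], fraction=table.fraction)
    report = FilterReport(
        fraction=table.fraction,
        n_input=table.shape[0],
        n_retained=len(keep),
        threshold=threshold,
        detection_rate=rate,
    )
    return filtered, report
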