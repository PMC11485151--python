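"""Length statistics per shape class and cross-group normalized comparison.

Bundle length is a strong correlate of shape class (flat I/L bundles are
the longest, closed C bundles the shortest). Comparing lengths across
species of different brain size requires a scale normalization: lengths of
the source group are multiplied by the square root of the ratio of pial
surface areas, ``sqrt(S_target / S_source)``, before the per-class percent
difference is computed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from tractoshape.geometry import PointCloud, arc_length


@dataclass(frozen=True)
class LengthReport:
    """Per-class mean and population standard deviation of centroid lengths.

    ``table`` has one row per class with columns ``n``, ``mean_mm``,
    ``sd_mm``. ``sd_convention`` records the divisor used (population, N).
    ``normalization_factor`` is 1.0 for raw reports.
    """

    table: pd.DataFrame
    group: str = ""
    normalization_factor: float = 1.0
    sd_convention: str = "population"

    def __post_init__(self) -> None:
        if self.normalization_factor <= 0:
            raise ValueError("normalization factor must be > 0")
        if (self.table["sd_mm"] < 0).any() or (self.table["n"] < 1).any():
            raise ValueError("invalid length table")

    @property
    def classes(self) -> list[str]:
        return list(self.table.index)


def length_stats(
    clouds: Sequence[PointCloud],
    class_of: Mapping[str, str],
    group: str = "",
) -> LengthReport:
    """Mean +/- population sd of arc lengths per shape class."""
    records: dict[str, list[float]] = {}
    for i, c in enumerate(clouds):
        cid = c.source_id or f"cloud{i}"
        if cid not in class_of:
            raise ValueError(f"cloud {cid!r} has no class label")
        records.setdefault(class_of[cid], []).append(arc_length(c))
    rows = {
        cls: {
            "n": len(vals),
            "mean_mm": float(np.mean(vals)),
            "sd_mm": float(np.std(vals)),  # population (N) divisor
        }
        for cls, vals in sorted(records.items())
    }
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index.name = "class"
    return LengthReport(table=table, group=group)


def surface_normalization_factor(surface_source: float, surface_target: float) -> float:
    """Multiplicative length factor ``sqrt(S_target / S_source)``.

    Scales lengths measured in the source group onto the spatial scale of
    the target group, assuming lengths grow with the linear size of the
    cortex (square root of its area).
    """
    if surface_source <= 0 or surface_target <= 0:
        raise ValueError("pial surface areas must be > 0")
    return math.sqrt(surface_target / surface_source)


def normalize_lengths(report: LengthReport, factor: float) -> LengthReport:
    """Apply a multiplicative factor to every mean and sd of a report."""
    if factor <= 0:
        raise ValueError("factor must be > 0")
    table = report.table.copy()
    table["mean_mm"] *= factor
    table["sd_mm"] *= factor
    return replace(
        report, table=table, normalization_factor=report.normalization_factor * factor
    )


def compare_groups(
    report_a_normalized: LengthReport, report_b: LengthReport
) -> pd.DataFrame:
    """Per-class percent length difference of group A (normalized) vs B.

    ``percent_diff = 100 * (mean_A_normalized - mean_B) / mean_B``: positive
    values mean group A bundles are longer than group B at common scale.
    """
    a = report_a_normalized.table
    b = report_b.table
    if set(a.index) != set(b.index):
        missing = sorted(set(a.index).symmetric_difference(b.index))
        raise ValueError(f"class labels differ between reports: {missing}")
    b = b.loc[a.index]
    out = pd.DataFrame(
        {
            "mean_a_mm": a["mean_mm"],
            "mean_b_mm": b["mean_mm"],
            "percent_diff": 100.0 * (a["mean_mm"] - b["mean_mm"]) / b["mean_mm"],
        }
    )
    out.index.name = "class"
    return out
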