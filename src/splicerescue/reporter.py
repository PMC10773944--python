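"""Two-channel splicing-reporter quantification.

A bichromatic splicing reporter expresses GFP from the exon-including
minigene and mCherry from the exon-skipping one, so the per-cell channel
balance reads out the splicing choice.  Relative mCherry intensity is the
two-channel fraction mCherry / (mCherry + GFP) on background-subtracted
intensities; background subtraction itself is the caller's responsibility
(small negative post-subtraction values are clipped to zero only behind an
explicit flag).  Group-comparison statistics are left to standard routines;
this module provides the quantification and the per-group mean / SEM / n
summaries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

INTENSITY_COLUMNS = ["i_mcherry", "i_gfp"]


@dataclass(frozen=True)
class ReporterCell:
    """One measured cell: identity labels plus background-subtracted
    channel intensities (arbitrary units)."""

    cell_id: str
    tissue: str
    stage: str
    genotype: str
    i_mcherry: float
    i_gfp: float

    @property
    def rel_mcherry(self) -> float:
        return rel_intensity(self.i_mcherry, self.i_gfp)


def rel_intensity(i_mcherry: float, i_gfp: float, clip_negative: bool = False) -> float:
    """Relative mCherry fraction of the two-channel total.

    Returns NaN (missing) when both channels are zero; negative inputs are
    an error unless ``clip_negative`` clips them to zero first.
    """
    if clip_negative:
        i_mcherry = max(float(i_mcherry), 0.0)
        i_gfp = max(float(i_gfp), 0.0)
    if i_mcherry < 0 or i_gfp < 0:
        raise ValueError("intensities must be non-negative (background-subtracted)")
    total = i_mcherry + i_gfp
    if total == 0:
        return math.nan
    return i_mcherry / total


def summarize_reporter(
    cells: pd.DataFrame, group_by: list[str], clip_negative: bool = False
) -> pd.DataFrame:
    """Per-group mean, SEM and n of relative mCherry intensity.

    ``cells`` needs the grouping columns plus ``i_mcherry``/``i_gfp``.
    Cells with missing ratios (0/0) are excluded; singleton groups report a
    missing SEM.
    """
    missing = [c for c in list(group_by) + INTENSITY_COLUMNS if c not in cells.columns]
    if missing:
        raise ValueError(f"missing column(s): {', '.join(missing)}")
    if not group_by:
        raise ValueError("group_by must name at least one column")
    ratios = np.array(
        [
            rel_intensity(mc, gf, clip_negative=clip_negative)
            for mc, gf in zip(cells["i_mcherry"], cells["i_gfp"])
        ]
    )
    work = cells[list(group_by)].copy()
    work["rel_mcherry"] = ratios
    work = work.dropna(subset=["rel_mcherry"])

    def _sem(x: pd.Series) -> float:
        return float(x.std(ddof=1) / math.sqrt(len(x))) if len(x) > 1 else math.nan

    out = (
        work.groupby(list(group_by), sort=True)["rel_mcherry"]
        .agg(mean_rel_mcherry="mean", sem=_sem, n="count")
        .reset_index()
    )
    return out
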