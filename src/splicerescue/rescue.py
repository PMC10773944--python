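"""Splicing Rescue Index (SRI) per event and per isoform strain.

For a splicing event dysregulated in the null mutant, the rescue achieved
by an isoform-only strain is::

    SRI = 1 - dPSI_iso / dPSI_mut

where both ΔPSIs are group-mean PSI of the strain minus wild type.  SRI = 1
means the strain fully restores wild-type splicing of the event, SRI = 0
means the mutant defect is untouched, and values above 1 (overshoot) or
below 0 (defect worsened) are kept without clamping; a flag column marks
overshoot and opposite-sign ΔPSIs.

Rescue strength classes use half-open intervals so every finite SRI maps to
exactly one class: weak (SRI < 0.33), intermediate (0.33 <= SRI < 0.66),
high (SRI >= 0.66).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .diffsplice import PsiTable

log = logging.getLogger(__name__)

#: class boundaries for rescue strength
WEAK_BOUND = 0.33
HIGH_BOUND = 0.66

SRI_COLUMNS = ["event_id", "strain", "dpsi_mut", "dpsi_iso", "sri", "rescue_class", "overshoot", "sign_flip"]


def compute_sri(dpsi_iso: float, dpsi_mut: float) -> float:
    """SRI of one event: ``1 - dpsi_iso / dpsi_mut`` with no clamping.

    Raises ``ValueError`` when ``dpsi_mut`` is zero (callers enforce a
    |ΔPSI_mut| floor before dividing).
    """
    if dpsi_mut == 0:
        raise ValueError("dpsi_mut is zero: SRI undefined")
    return 1.0 - dpsi_iso / dpsi_mut


def classify_rescue(sri: float) -> str:
    """Classify rescue strength as weak / intermediate / high."""
    if not math.isfinite(sri):
        raise ValueError(f"non-finite SRI: {sri!r}")
    if sri < WEAK_BOUND:
        return "weak"
    if sri < HIGH_BOUND:
        return "intermediate"
    return "high"


def sri_table(
    mut_records: pd.DataFrame,
    psi: PsiTable,
    strain: str,
    dpsi_floor: float = 0.05,
) -> pd.DataFrame:
    """Per-event SRI of ``strain`` over the mutant-dysregulated event set.

    ``mut_records`` is the differential-splicing table of the null mutant;
    only rows flagged dysregulated contribute.  Events whose |ΔPSI_mut|
    falls below ``dpsi_floor`` or whose group PSI is missing in wild type
    or the isoform strain are skipped (counted in the log).
    """
    if psi.groups is None:
        raise ValueError("PsiTable lacks group means; build it with a design")
    genotypes = set(psi.groups["genotype"])
    if strain not in genotypes:
        raise ValueError(f"strain {strain!r} missing from PSI table")
    if "wt" not in genotypes:
        raise ValueError("PSI table lacks the wt genotype")

    gmeans = psi.groups.set_index(["event_id", "genotype"])["mean_psi"]
    dys = mut_records[mut_records["dysregulated"]]
    rows = []
    below_floor = missing = 0
    for rec in dys.itertuples():
        dpsi_mut = float(rec.dpsi)
        if abs(dpsi_mut) < dpsi_floor or dpsi_mut == 0:
            below_floor += 1
            continue
        psi_iso = gmeans.get((rec.event_id, strain), np.nan)
        psi_wt = gmeans.get((rec.event_id, "wt"), np.nan)
        if not (np.isfinite(psi_iso) and np.isfinite(psi_wt)):
            missing += 1
            continue
        dpsi_iso = float(psi_iso) - float(psi_wt)
        sri = compute_sri(dpsi_iso, dpsi_mut)
        rows.append(
            {
                "event_id": rec.event_id,
                "strain": strain,
                "dpsi_mut": dpsi_mut,
                "dpsi_iso": dpsi_iso,
                "sri": sri,
                "rescue_class": classify_rescue(sri),
                "overshoot": sri > 1.0,
                "sign_flip": dpsi_iso * dpsi_mut < 0,
            }
        )
    if below_floor or missing:
        log.info(
            "sri_table(%s): skipped %d events below |dPSI| floor %.3g, %d with missing PSI",
            strain,
            below_floor,
            dpsi_floor,
            missing,
        )
    return pd.DataFrame(rows, columns=SRI_COLUMNS)


def sri_from_dpsi_columns(
    table: pd.DataFrame,
    iso_col: str,
    mut_col: str,
    dpsi_floor: float = 0.05,
    strain: str = "iso",
) -> pd.DataFrame:
    """SRI recomputed from precomputed ΔPSI columns.

    Accepts any table carrying per-event ΔPSI of the isoform strain and the
    null mutant (e.g. inclusion-level differences passed through from an
    rMATS result), so published result tables can be consumed directly
    without re-deriving PSI from counts.
    """
    rows = []
    for rec in table.itertuples(index=False):
        dpsi_mut = float(getattr(rec, mut_col))
        dpsi_iso = float(getattr(rec, iso_col))
        if not (np.isfinite(dpsi_mut) and np.isfinite(dpsi_iso)) or abs(dpsi_mut) < dpsi_floor:
            continue
        sri = compute_sri(dpsi_iso, dpsi_mut)
        rows.append(
            {
                "event_id": getattr(rec, "event_id", None),
                "strain": strain,
                "dpsi_mut": dpsi_mut,
                "dpsi_iso": dpsi_iso,
                "sri": sri,
                "rescue_class": classify_rescue(sri),
                "overshoot": sri > 1.0,
                "sign_flip": dpsi_iso * dpsi_mut < 0,
            }
        )
    return pd.DataFrame(rows, columns=SRI_COLUMNS)


@dataclass(frozen=True)
class SriSummary:
    """Per-strain SRI summary with the between-strain test (shared pair-wise)."""

    strain: str
    n_events: int
    mean_sri: float
    sd_sri: float
    t_stat: float
    p_value: float


def compare_strains(
    sri_short, sri_long, welch: bool = False
) -> tuple[SriSummary, SriSummary]:
    """Two-sample t-test of mean SRI between the two isoform strains.

    Pooled-variance (Student's) by default; ``welch=True`` drops the
    equal-variance assumption.  Degenerate case of zero variance in both
    groups with equal means yields t = 0, p = 1.
    """
    a = np.asarray(sri_short, float)
    b = np.asarray(sri_long, float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each strain needs >= 2 SRI values")
    if np.std(a) == 0 and np.std(b) == 0 and a.mean() == b.mean():
        t, p = 0.0, 1.0
    else:
        t, p = stats.ttest_ind(a, b, equal_var=not welch)
    return (
        SriSummary("iso_short", len(a), float(a.mean()), float(a.std(ddof=1)), float(t), float(p)),
        SriSummary("iso_long", len(b), float(b.mean()), float(b.std(ddof=1)), float(t), float(p)),
    )


def summary_frame(pair: tuple[SriSummary, SriSummary]) -> pd.DataFrame:
    """Flatten a pair of strain summaries into a two-row table."""
    return pd.DataFrame(
        [
            {
                "strain": s.strain,
                "n_events": s.n_events,
                "mean_sri": s.mean_sri,
                "sd_sri": s.sd_sri,
                "t_stat": s.t_stat,
                "p_value": s.p_value,
            }
            for s in pair
        ]
    )
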