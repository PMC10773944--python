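"""Gene-list thresholding and set-overlap enrichment.

Differential-expression result tables are reduced to up/down gene lists by
a fold-change and FDR filter (both strict inequalities), and overlap
between two lists drawn from an explicit tested universe is scored with a
one-sided (enrichment) Fisher's exact test.  The universe is never
defaulted to the union of the sets: an overlap p-value is meaningless
without the population of genes that could have appeared in either list.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.stats import hypergeom


@dataclass(frozen=True)
class OverlapTest:
    universe_size: int
    set_a_size: int
    set_b_size: int
    overlap: int
    odds_ratio: float
    p_value: float
    direction: str = "greater"


def filter_by_thresholds(
    records: pd.DataFrame,
    fc_threshold: float = 1.5,
    fdr_threshold: float = 0.05,
    fc_scale: str = "log2",
    gene_col: str = "gene",
    fc_col: str = "log2fc",
    fdr_col: str = "fdr",
) -> tuple[list[str], list[str]]:
    """Split a DE table into (up, down) gene lists.

    Keeps records with |log2 FC| > log2(fc_threshold) and FDR strictly
    below ``fdr_threshold``; a record at exactly the fold-change threshold
    is excluded.  ``fc_scale`` declares whether the fold-change column is
    ``"log2"`` or ``"linear"``.
    """
    missing = [c for c in (gene_col, fc_col, fdr_col) if c not in records.columns]
    if missing:
        raise ValueError(f"missing column(s): {', '.join(missing)}")
    if fc_scale not in ("log2", "linear"):
        raise ValueError("fc_scale must be 'log2' or 'linear'")
    fc = records[fc_col].astype(float)
    if fc_scale == "linear":
        if (fc <= 0).any():
            raise ValueError("linear fold changes must be positive")
        fc = np.log2(fc)
    cut = math.log2(fc_threshold)
    keep = (fc.abs() > cut) & (records[fdr_col].astype(float) < fdr_threshold)
    up = records.loc[keep & (fc > 0), gene_col].astype(str).tolist()
    down = records.loc[keep & (fc < 0), gene_col].astype(str).tolist()
    return up, down


def overlap_pvalue(universe_size, set_a_size, set_b_size, overlap) -> np.ndarray | float:
    """Hypergeometric upper-tail P(X >= overlap); equals the one-sided
    (greater) Fisher's exact p for the implied 2x2 table.  Vectorised."""
    return hypergeom.sf(np.asarray(overlap) - 1, universe_size, set_a_size, set_b_size)


def fisher_overlap(universe, set_a, set_b, alternative: str = "greater") -> OverlapTest:
    """Fisher's exact test of overlap enrichment between two gene sets.

    ``set_a`` and ``set_b`` must be subsets of ``universe``; the odds ratio
    is the sample odds ratio of the 2x2 table, reported as ``inf`` when a
    zero off-diagonal cell forces it and ``nan`` for the empty 0/0 case.
    """
    universe = {str(g).strip() for g in universe}
    set_a = {str(g).strip() for g in set_a}
    set_b = {str(g).strip() for g in set_b}
    for name, s in (("set_a", set_a), ("set_b", set_b)):
        stray = sorted(s - universe)
        if stray:
            raise ValueError(f"{name} has elements outside the universe: {stray[:10]}")
    n = len(universe)
    a, b = len(set_a), len(set_b)
    k = len(set_a & set_b)
    if alternative == "greater":
        p = float(overlap_pvalue(n, a, b, k))
    elif alternative == "two-sided":
        from scipy.stats import fisher_exact

        table = [[k, a - k], [b - k, n - a - b + k]]
        p = float(fisher_exact(table, alternative="two-sided")[1])
    else:
        raise ValueError("alternative must be 'greater' or 'two-sided'")
    num = k * (n - a - b + k)
    den = (a - k) * (b - k)
    if den > 0:
        odds = num / den
    elif num > 0:
        odds = math.inf
    else:
        odds = math.nan
    return OverlapTest(n, a, b, k, odds, min(p, 1.0), alternative)


def venn_counts(sets: dict[str, set | list]) -> dict[tuple[str, ...], int]:
    """Disjoint-region counts of 2 or 3 named sets.

    Keys are sorted tuples of the set names whose exclusive intersection
    the region represents; values sum to the union size.
    """
    if not 2 <= len(sets) <= 3:
        raise ValueError("venn_counts takes 2 or 3 named sets")
    named = {name: set(map(str, members)) for name, members in sets.items()}
    names = sorted(named)
    regions: dict[tuple[str, ...], int] = {}
    for r in range(1, len(names) + 1):
        for inside in combinations(names, r):
            region = set.intersection(*(named[n] for n in inside))
            for outside in names:
                if outside not in inside:
                    region -= named[outside]
            regions[inside] = len(region)
    return regions
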