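"""PSI estimation and replicate-aware differential splicing.

The per-replicate inclusion level of an event is the effective-length
normalised fraction of junction evidence supporting the inclusion form::

    psi = (I / lI) / (I / lI + S / lS)

with I inclusion reads, S skipping reads and (lI, lS) the effective lengths
of the two forms.  Cells with I + S below a coverage floor are missing.

Differential splicing between a strain and wild type is tested per event
with a beta-binomial likelihood-ratio test on the read-level inclusion
probability: the null model shares one mean inclusion probability across
both groups, the alternative fits one per group, with the intra-class
correlation rho held fixed at a per-event moment estimate shrunk across
events.  The statistic is referred to chi-square with one degree of
freedom.  At rho = 0 the test reduces exactly to the binomial LRT.  ΔPSI is
reported on the psi scale as the difference of group-mean replicate PSIs,
decoupled from library size.  P-values are Benjamini–Hochberg adjusted over
all testable events of the contrast.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.special import betaln
from scipy.stats import chi2
from statsmodels.stats.multitest import multipletests

log = logging.getLogger(__name__)

_P_EPS = 1e-9


@dataclass
class PsiTable:
    """Per-sample PSI values plus per-genotype group means.

    ``samples`` has columns event_id, sample_id, total, psi (NaN below the
    coverage floor); ``groups`` has event_id, genotype, mean_psi, n_reps and
    is None when no design was supplied.
    """

    samples: pd.DataFrame
    groups: pd.DataFrame | None = None

    def group_mean(self, event_id: str, genotype: str) -> float:
        if self.groups is None:
            raise ValueError("PsiTable was built without a design; no group means")
        sel = self.groups[
            (self.groups["event_id"] == event_id) & (self.groups["genotype"] == genotype)
        ]
        return float(sel["mean_psi"].iloc[0]) if len(sel) else float("nan")


def estimate_psi(
    counts: pd.DataFrame,
    events: pd.DataFrame,
    design: pd.DataFrame | None = None,
    min_total: int = 10,
) -> PsiTable:
    """Estimate per-replicate PSI and, given a design, per-genotype means.

    Group means are arithmetic means over replicates whose total junction
    coverage reaches ``min_total``; groups with no covered replicate have a
    missing mean.
    """
    if len(events) and not (
        (events["inc_eff_len"] > 0) & (events["skip_eff_len"] > 0)
    ).all():
        raise ValueError("event with non-positive effective length")
    merged = counts.merge(
        events[["event_id", "inc_eff_len", "skip_eff_len"]], on="event_id", how="left"
    )
    if merged["inc_eff_len"].isna().any():
        missing = merged.loc[merged["inc_eff_len"].isna(), "event_id"].iloc[0]
        raise ValueError(f"counts reference undeclared event: {missing!r}")
    total = merged["inc_count"] + merged["skip_count"]
    inc_norm = merged["inc_count"] / merged["inc_eff_len"]
    skip_norm = merged["skip_count"] / merged["skip_eff_len"]
    denom = inc_norm + skip_norm
    psi = np.where((total >= min_total) & (denom > 0), inc_norm / denom.replace(0, np.nan), np.nan)
    samples = pd.DataFrame(
        {
            "event_id": merged["event_id"],
            "sample_id": merged["sample_id"],
            "total": total.astype(int),
            "psi": psi,
        }
    )
    groups = None
    if design is not None:
        joined = samples.merge(design[["sample_id", "genotype"]], on="sample_id", how="left")
        groups = (
            joined.groupby(["event_id", "genotype"], sort=True)["psi"]
            .agg(mean_psi="mean", n_reps="count")
            .reset_index()
        )
    return PsiTable(samples=samples, groups=groups)


# --------------------------------------------------------------------------
# Beta-binomial likelihood-ratio test


def _loglik(p: float, inc: np.ndarray, tot: np.ndarray, rho: float) -> float:
    """Log-likelihood (up to the count-only constant) at mean inclusion p."""
    p = min(max(p, _P_EPS), 1.0 - _P_EPS)
    if rho == 0.0:
        return float(np.sum(inc * np.log(p) + (tot - inc) * np.log1p(-p)))
    a = p * (1.0 - rho) / rho
    b = (1.0 - p) * (1.0 - rho) / rho
    return float(np.sum(betaln(inc + a, tot - inc + b) - betaln(a, b)))


def _mle(inc: np.ndarray, tot: np.ndarray, rho: float) -> float:
    if rho == 0.0:
        return float(np.sum(inc) / np.sum(tot))
    res = minimize_scalar(
        lambda q: -_loglik(q, inc, tot, rho),
        bounds=(_P_EPS, 1.0 - _P_EPS),
        method="bounded",
        options={"xatol": 1e-10},
    )
    return float(res.x)


def betabin_lrt(
    inc_a: np.ndarray,
    tot_a: np.ndarray,
    inc_b: np.ndarray,
    tot_b: np.ndarray,
    rho: float,
    permutation: bool = False,
) -> tuple[float, float]:
    """Likelihood-ratio test of equal mean inclusion probability.

    Fits beta-binomial models with a shared versus group-specific mean,
    dispersion held at ``rho``, and refers ``2·Δloglik`` to chi-square(1).
    Returns ``(lrt_stat, p_value)``; groups whose totals are all zero give
    ``(nan, nan)``.

    ``permutation=True`` replaces the asymptotic reference with the exact
    label-permutation distribution of the statistic (all distinct group
    reassignments of the replicates), which is preferable for very small
    designs where chi-square is optimistic.
    """
    inc_a, tot_a = np.asarray(inc_a, float), np.asarray(tot_a, float)
    inc_b, tot_b = np.asarray(inc_b, float), np.asarray(tot_b, float)
    if len(inc_a) != len(tot_a) or len(inc_b) != len(tot_b):
        raise ValueError("inc/tot lists must have equal length per group")
    if (inc_a < 0).any() or (inc_b < 0).any() or (inc_a > tot_a).any() or (inc_b > tot_b).any():
        raise ValueError("counts must satisfy 0 <= inc <= tot")
    if not 0 <= rho < 1:
        raise ValueError("rho must be in [0, 1)")
    if tot_a.sum() == 0 or tot_b.sum() == 0:
        return float("nan"), float("nan")
    inc_0 = np.concatenate([inc_a, inc_b])
    tot_0 = np.concatenate([tot_a, tot_b])
    ll_alt = _loglik(_mle(inc_a, tot_a, rho), inc_a, tot_a, rho) + _loglik(
        _mle(inc_b, tot_b, rho), inc_b, tot_b, rho
    )
    ll_null = _loglik(_mle(inc_0, tot_0, rho), inc_0, tot_0, rho)
    stat = 2.0 * (ll_alt - ll_null)
    if stat < 1e-7:  # numerical floor; the alternative nests the null
        stat = 0.0
    if permutation:
        return stat, _permutation_pvalue(inc_0, tot_0, len(inc_a), ll_null, stat, rho)
    p = float(chi2.sf(stat, df=1)) if stat > 0 else 1.0
    return stat, p


def _permutation_pvalue(
    inc_0: np.ndarray, tot_0: np.ndarray, n_a: int, ll_null: float, observed: float, rho: float
) -> float:
    """Exact label-permutation p: enumerate every split of the pooled
    replicates into groups of the original sizes (chi-square-free)."""
    from itertools import combinations

    idx = np.arange(len(inc_0))
    as_extreme = total = 0
    for pick in combinations(idx, n_a):
        mask = np.zeros(len(idx), bool)
        mask[list(pick)] = True
        ll_alt = _loglik(_mle(inc_0[mask], tot_0[mask], rho), inc_0[mask], tot_0[mask], rho)
        ll_alt += _loglik(_mle(inc_0[~mask], tot_0[~mask], rho), inc_0[~mask], tot_0[~mask], rho)
        stat = max(2.0 * (ll_alt - ll_null), 0.0)
        as_extreme += stat >= observed - 1e-9
        total += 1
    return as_extreme / total


# --------------------------------------------------------------------------
# Dispersion estimation


def estimate_dispersion(
    counts: pd.DataFrame, design: pd.DataFrame, min_total: int = 1
) -> pd.Series:
    """Per-event intra-class correlation with shrinkage across events.

    A one-way ANOVA moment estimator of the beta-binomial rho is pooled over
    genotype groups with >= 2 covered replicates, floored at 0, then shrunk
    toward the across-event median with weight n_reps / (n_reps + 4).
    Events without an estimable rho receive the median.
    """
    joined = counts.merge(design[["sample_id", "genotype"]], on="sample_id")
    joined["total"] = joined["inc_count"] + joined["skip_count"]
    joined = joined[joined["total"] >= max(min_total, 1)]

    raw: dict[str, float] = {}
    nrep: dict[str, int] = {}
    for event_id, ev in joined.groupby("event_id", sort=True):
        msb_num = msw_num = 0.0
        msb_df = 0
        msw_df = 0.0
        nc_num = nc_den = 0.0
        used = 0
        for _, grp in ev.groupby("genotype"):
            n_j = grp["total"].to_numpy(float)
            y_j = grp["inc_count"].to_numpy(float)
            m = len(n_j)
            if m < 2:
                continue
            big_n = n_j.sum()
            p_bar = y_j.sum() / big_n
            p_j = y_j / n_j
            msb_num += float(np.sum(n_j * (p_j - p_bar) ** 2))
            msb_df += m - 1
            msw_num += float(np.sum(n_j * p_j * (1.0 - p_j)))
            msw_df += big_n - m
            nc = (big_n - np.sum(n_j**2) / big_n) / (m - 1)
            nc_num += nc * (m - 1)
            nc_den += m - 1
            used += m
        if msb_df == 0 or msw_df <= 0:
            continue
        msb = msb_num / msb_df
        msw = msw_num / msw_df
        nc = nc_num / nc_den
        denom = msb + (nc - 1.0) * msw
        if denom <= 0:
            rho_hat = 0.0
        else:
            rho_hat = max(0.0, (msb - msw) / denom)
        raw[event_id] = min(rho_hat, 0.999)
        nrep[event_id] = used

    event_ids = sorted(counts["event_id"].unique())
    median = float(np.median(list(raw.values()))) if raw else 0.0
    out = {}
    for ev in event_ids:
        if ev in raw:
            w = nrep[ev] / (nrep[ev] + 4.0)
            out[ev] = w * raw[ev] + (1.0 - w) * median
        else:
            out[ev] = median
    return pd.Series(out, name="rho")


# --------------------------------------------------------------------------
# Multiple testing


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, order-preserving."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# --------------------------------------------------------------------------
# Differential splicing contrast


def diff_splice(
    counts: pd.DataFrame,
    events: pd.DataFrame,
    design: pd.DataFrame,
    strain: str,
    alpha: float = 0.01,
    dpsi_floor: float = 0.05,
    min_total: int = 10,
    rho: pd.Series | float | None = None,
    permutation: bool = False,
) -> pd.DataFrame:
    """Test every event for differential splicing between ``strain`` and wt.

    Returns one record per testable event (>= 2 covered replicates in both
    groups) with columns event_id, strain, dpsi, lrt_stat, p_value,
    p_adjusted and the dysregulated flag (p_adjusted < alpha and
    |dpsi| >= dpsi_floor), sorted by p_adjusted then event_id.
    """
    genotypes = set(design["genotype"])
    if strain not in genotypes:
        raise ValueError(f"strain {strain!r} not present in design")
    if "wt" not in genotypes:
        raise ValueError("design must contain a 'wt' genotype")

    psi = estimate_psi(counts, events, design, min_total=min_total)
    if rho is None:
        sub_design = design[design["genotype"].isin(["wt", strain])]
        rho = estimate_dispersion(counts[counts["sample_id"].isin(sub_design["sample_id"])], sub_design)
    if np.isscalar(rho):
        rho = pd.Series(float(rho), index=sorted(counts["event_id"].unique()))

    joined = counts.merge(design[["sample_id", "genotype"]], on="sample_id")
    joined["total"] = joined["inc_count"] + joined["skip_count"]
    joined = joined[(joined["genotype"].isin(["wt", strain])) & (joined["total"] >= min_total)]
    gmeans = psi.groups.set_index(["event_id", "genotype"])["mean_psi"]

    rows = []
    skipped = 0
    for event_id, ev in joined.groupby("event_id", sort=True):
        grp_w = ev[ev["genotype"] == "wt"]
        grp_s = ev[ev["genotype"] == strain]
        if len(grp_w) < 2 or len(grp_s) < 2:
            skipped += 1
            continue
        stat, p = betabin_lrt(
            grp_s["inc_count"].to_numpy(),
            grp_s["total"].to_numpy(),
            grp_w["inc_count"].to_numpy(),
            grp_w["total"].to_numpy(),
            float(rho.get(event_id, 0.0)),
            permutation=permutation,
        )
        if not np.isfinite(p):
            skipped += 1
            continue
        dpsi = float(gmeans.get((event_id, strain), np.nan)) - float(
            gmeans.get((event_id, "wt"), np.nan)
        )
        rows.append(
            {"event_id": event_id, "strain": strain, "dpsi": dpsi, "lrt_stat": stat, "p_value": p}
        )
    if skipped:
        log.info("diff_splice(%s): %d events untestable (coverage)", strain, skipped)

    records = pd.DataFrame(rows, columns=["event_id", "strain", "dpsi", "lrt_stat", "p_value"])
    if len(records):
        records["p_adjusted"] = bh_adjust(records["p_value"].to_numpy())
        records["dysregulated"] = (records["p_adjusted"] < alpha) & (
            records["dpsi"].abs() >= dpsi_floor
        )
        records = records.sort_values(["p_adjusted", "event_id"], kind="mergesort").reset_index(
            drop=True
        )
    else:
        records["p_adjusted"] = pd.Series(dtype=float)
        records["dysregulated"] = pd.Series(dtype=bool)
    return records
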