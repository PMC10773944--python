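"""PSI arithmetic, the beta-binomial LRT, dispersion recovery, and BH."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from splicerescue.diffsplice import (
    bh_adjust,
    betabin_lrt,
    diff_splice,
    estimate_dispersion,
    estimate_psi,
)
from splicerescue.simdata import SimConfig, simulate_dataset


def _one_event(inc, skip, inc_len=100.0, skip_len=100.0):
    events = pd.DataFrame(
        {
            "event_id": ["e1"],
            "gene_id": ["g1"],
            "event_type": ["SE"],
            "inc_eff_len": [inc_len],
            "skip_eff_len": [skip_len],
        }
    )
    counts = pd.DataFrame(
        {"event_id": ["e1"], "sample_id": ["s1"], "inc_count": [inc], "skip_count": [skip]}
    )
    return counts, events


@pytest.mark.parametrize(
    "inc,skip,inc_len,skip_len,expected",
    [
        (30, 10, 100.0, 100.0, 0.75),
        (20, 20, 2.0, 1.0, 1 / 3),
    ],
)
def test_psi_formula(inc, skip, inc_len, skip_len, expected):
    counts, events = _one_event(inc, skip, inc_len, skip_len)
    psi = estimate_psi(counts, events, min_total=10)
    assert psi.samples["psi"].iloc[0] == pytest.approx(expected)


def test_psi_below_coverage_floor_is_missing():
    counts, events = _one_event(3, 2)
    assert math.isnan(estimate_psi(counts, events, min_total=10).samples["psi"].iloc[0])


def test_psi_rejects_nonpositive_effective_length():
    counts, events = _one_event(3, 2)
    events.loc[0, "inc_eff_len"] = 0.0
    with pytest.raises(ValueError, match="effective length"):
        estimate_psi(counts, events)


@settings(derandomize=True, deadline=None, max_examples=50)
@given(
    inc=st.integers(10, 500),
    skip=st.integers(10, 500),
    bump=st.integers(1, 50),
    inc_len=st.floats(10, 300),
    skip_len=st.floats(10, 300),
)
def test_psi_monotone_in_inclusion_reads(inc, skip, bump, inc_len, skip_len):
    def psi(i):
        counts, events = _one_event(i, skip, inc_len, skip_len)
        return estimate_psi(counts, events, min_total=1).samples["psi"].iloc[0]

    assert psi(inc + bump) > psi(inc)


# --------------------------------------------------------------------------
# beta-binomial LRT


def test_lrt_null_identity_on_identical_groups():
    for rho in (0.0, 0.05):
        stat, p = betabin_lrt([10, 12], [40, 44], [10, 12], [40, 44], rho)
        assert stat == 0.0 and p == 1.0


def _binomial_lrt_oracle(inc_a, tot_a, inc_b, tot_b):
    """Closed-form binomial log-likelihood ratio (independent of the module)."""

    def ll(inc, tot, p):
        out = 0.0
        for x, n in zip(inc, tot):
            out += (x * math.log(p) if x else 0.0) + ((n - x) * math.log(1 - p) if n > x else 0.0)
        return out

    pa = sum(inc_a) / sum(tot_a)
    pb = sum(inc_b) / sum(tot_b)
    p0 = (sum(inc_a) + sum(inc_b)) / (sum(tot_a) + sum(tot_b))
    return 2 * (ll(inc_a, tot_a, pa) + ll(inc_b, tot_b, pb) - ll(inc_a, tot_a, p0) - ll(inc_b, tot_b, p0))


@pytest.mark.parametrize(
    "inc_a,tot_a,inc_b,tot_b",
    [
        ([50], [100], [90], [100]),
        ([10, 20, 15], [40, 50, 45], [30, 28], [40, 41]),
        ([0, 1], [30, 30], [29, 30], [30, 30]),
    ],
)
def test_lrt_at_zero_rho_equals_binomial_oracle(inc_a, tot_a, inc_b, tot_b):
    stat, _ = betabin_lrt(inc_a, tot_a, inc_b, tot_b, 0.0)
    assert stat == pytest.approx(_binomial_lrt_oracle(inc_a, tot_a, inc_b, tot_b), abs=1e-9)


def test_lrt_symmetric_under_group_swap():
    stat_ab, p_ab = betabin_lrt([12, 18], [40, 40], [30, 31], [40, 40], 0.03)
    stat_ba, p_ba = betabin_lrt([30, 31], [40, 40], [12, 18], [40, 40], 0.03)
    assert stat_ab == pytest.approx(stat_ba, rel=1e-6) and p_ab == pytest.approx(p_ba, rel=1e-6)


def test_lrt_all_zero_totals_gives_missing_p():
    stat, p = betabin_lrt([0], [0], [5], [10], 0.02)
    assert math.isnan(stat) and math.isnan(p)


def test_lrt_input_validation():
    with pytest.raises(ValueError, match="rho"):
        betabin_lrt([1], [2], [1], [2], 1.0)
    with pytest.raises(ValueError, match="inc <= tot"):
        betabin_lrt([3], [2], [1], [2], 0.0)


def test_permutation_reference_for_small_designs():
    """The exact label-permutation p is granular in 1/C(6,3), equals 1 for
    identical groups, and hits the floor for a clean separation."""
    _, p_null = betabin_lrt([10, 11], [40, 40], [10, 11], [40, 40], 0.02, permutation=True)
    assert p_null == 1.0
    _, p_sep = betabin_lrt([2, 3, 1], [40, 40, 40], [38, 37, 39], [40, 40, 40], 0.02, permutation=True)
    assert p_sep == pytest.approx(2 / 20)  # observed split and its mirror


def test_lrt_type_one_error_calibrated_at_known_rho():
    """Under a shared beta-binomial null with rho known, the raw rejection
    rate at nominal 0.05 stays within +/- 0.01 over 2000 events."""
    rng = np.random.default_rng(42)
    rho, n_events, reps, cov = 0.02, 2000, 3, 100
    a, b = 0.5 * (1 - rho) / rho, 0.5 * (1 - rho) / rho
    rejections = 0
    for _ in range(n_events):
        tot = rng.negative_binomial(10, 10 / 110, size=2 * reps) + 1
        p_cell = rng.beta(a, b, size=2 * reps)
        inc = rng.binomial(tot, p_cell)
        _, p = betabin_lrt(inc[:reps], tot[:reps], inc[reps:], tot[reps:], rho)
        rejections += p < 0.05
    assert rejections / n_events == pytest.approx(0.05, abs=0.01)


# --------------------------------------------------------------------------
# dispersion


def test_identical_fractions_give_zero_dispersion():
    counts = pd.DataFrame(
        {
            "event_id": ["e1"] * 4,
            "sample_id": ["a1", "a2", "b1", "b2"],
            "inc_count": [20, 40, 10, 30],
            "skip_count": [20, 40, 30, 90],
        }
    )
    design = pd.DataFrame(
        {"sample_id": ["a1", "a2", "b1", "b2"], "genotype": ["wt", "wt", "m", "m"], "replicate": [1, 2, 1, 2]}
    )
    rho = estimate_dispersion(counts, design)
    assert rho["e1"] == pytest.approx(0.0, abs=1e-12)


def test_single_replicate_groups_fall_back_to_median():
    counts = pd.DataFrame(
        {
            "event_id": ["e1", "e1"],
            "sample_id": ["a1", "b1"],
            "inc_count": [20, 10],
            "skip_count": [20, 30],
        }
    )
    design = pd.DataFrame(
        {"sample_id": ["a1", "b1"], "genotype": ["wt", "m"], "replicate": [1, 1]}
    )
    rho = estimate_dispersion(counts, design)
    assert rho["e1"] == 0.0  # global median of an empty raw set


def test_dispersion_recovery_from_simulation():
    """Median estimate within +/- 0.02 of a true rho = 0.05 (500 events, 5 reps)."""
    bundle = simulate_dataset(
        SimConfig(n_events=500, frac_affected=0.0, dispersion=0.05, replicates=5, seed=4)
    )
    rho = estimate_dispersion(bundle.counts, bundle.design)
    assert float(np.median(rho)) == pytest.approx(0.05, abs=0.02)


# --------------------------------------------------------------------------
# BH adjustment


def _bh_oracle(p):
    """Hand-rolled step-up procedure, independent of statsmodels."""
    p = list(p)
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adj = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adj[i] = running
    return adj


def test_bh_hand_examples():
    assert bh_adjust([0.03]) == pytest.approx([0.03])
    assert bh_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04, 0.04, 0.04, 0.04])


def test_bh_matches_oracle_and_is_permutation_equivariant():
    rng = np.random.default_rng(0)
    p = rng.random(200)
    adj = bh_adjust(p)
    assert adj == pytest.approx(_bh_oracle(p))
    perm = rng.permutation(len(p))
    assert bh_adjust(p[perm]) == pytest.approx(adj[perm])
    assert (adj >= p).all() and (adj <= 1).all()


def test_bh_rejects_out_of_range():
    with pytest.raises(ValueError):
        bh_adjust([0.5, 1.2])


# --------------------------------------------------------------------------
# full contrast


def test_diff_splice_requires_known_strain(small_bundle):
    with pytest.raises(ValueError, match="ghost"):
        diff_splice(small_bundle.counts, small_bundle.events, small_bundle.design, "ghost")


def test_diff_splice_drops_zero_coverage_events(small_bundle):
    counts = small_bundle.counts.copy()
    target = small_bundle.events["event_id"].iloc[0]
    counts.loc[counts["event_id"] == target, ["inc_count", "skip_count"]] = 0
    records = diff_splice(counts, small_bundle.events, small_bundle.design, "null")
    assert target not in set(records["event_id"])


def test_diff_splice_records_are_sorted_and_flag_consistent(small_bundle):
    records = diff_splice(
        small_bundle.counts, small_bundle.events, small_bundle.design, "null"
    )
    assert records["p_adjusted"].is_monotonic_increasing
    assert (records["p_adjusted"] >= records["p_value"] - 1e-12).all()
    expected_flag = (records["p_adjusted"] < 0.01) & (records["dpsi"].abs() >= 0.05)
    assert (records["dysregulated"] == expected_flag).all()
    assert records["dpsi"].between(-1, 1).all()
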