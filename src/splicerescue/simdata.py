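"""Synthetic junction-count datasets for a wild-type / null / isoform-only design.

The simulator emulates the splicing structure of a replicated bulk RNA-seq
experiment over four genotypes: wild type (``wt``), a null mutant of a
splicing regulator (``null``), and two engineered strains that express only
the exon-skipping (``iso_short``) or exon-including (``iso_long``) isoform
of the regulator.

Generative model, per event *e* and sample *s*:

1. baseline inclusion level  psi_wt ~ Uniform(0.1, 0.9);
2. a fraction ``frac_affected`` of events receives a mutant effect:
   psi_null = clip(psi_wt ± Uniform(0.1, 0.4), 0.02, 0.98); the realised
   ΔPSI_mut = psi_null − psi_wt is recorded as truth;
3. each affected event draws a rescue fraction r per isoform strain from
   Normal(rescue_mean, rescue_sd) truncated to [−0.2, 1.2]; its true
   inclusion level is psi_iso = clip(psi_wt + (1 − r)·ΔPSI_mut, 0, 1), so
   r = 1 recovers wild-type splicing exactly and r = 0 leaves the mutant
   defect untouched — the rescue-index estimator targets r by construction;
4. total junction coverage n_es ~ NegativeBinomial(mean, size), emulating
   library-size variation;
5. inclusion reads ~ BetaBinomial(n_es, p_e, rho) where
   p = psi·lI / (psi·lI + (1 − psi)·lS) is the read-level inclusion
   probability under effective lengths (lI, lS) and rho is the
   between-replicate intra-class correlation; skipping reads = n − inclusion.

One seed drives a fixed draw order (baselines → affected flags → effects →
rescues → coverage → counts), so identical configurations reproduce
bit-identical tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd

from .io_formats import (
    read_counts_tsv,
    read_design_tsv,
    read_events_tsv,
    write_counts_tsv,
    write_design_tsv,
    write_events_tsv,
)

GENOTYPES = ("wt", "null", "iso_short", "iso_long")

#: truncation bounds for per-event rescue fractions; rescue may overshoot
#: past complete rescue (r > 1) or go the wrong way (r < 0)
RESCUE_BOUNDS = (-0.2, 1.2)


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic dataset generator.

    All fractions are validated to their stated bounds on construction;
    invalid values raise ``ValueError`` naming the field.
    """

    n_events: int = 500
    frac_affected: float = 0.3
    psi_baseline: tuple[float, float] = (0.1, 0.9)
    effect: tuple[float, float] = (0.1, 0.4)
    rescue_mean_short: float = 0.57
    rescue_mean_long: float = 0.89
    rescue_sd: float = 0.10
    dispersion: float = 0.02
    coverage_mean: float = 100.0
    coverage_size: float = 10.0
    replicates: int = 3
    inc_eff_len: float = 150.0
    skip_eff_len: float = 100.0
    seed: int = 0

    def __post_init__(self) -> None:
        checks = {
            "n_events": self.n_events >= 1,
            "frac_affected": math.isfinite(self.frac_affected) and 0 <= self.frac_affected <= 1,
            "psi_baseline": 0 < self.psi_baseline[0] <= self.psi_baseline[1] < 1,
            "effect": 0 <= self.effect[0] <= self.effect[1] <= 1,
            "rescue_sd": math.isfinite(self.rescue_sd) and self.rescue_sd >= 0,
            "rescue_mean_short": math.isfinite(self.rescue_mean_short),
            "rescue_mean_long": math.isfinite(self.rescue_mean_long),
            "dispersion": math.isfinite(self.dispersion) and 0 <= self.dispersion < 1,
            "coverage_mean": math.isfinite(self.coverage_mean) and self.coverage_mean >= 1,
            "coverage_size": math.isfinite(self.coverage_size) and self.coverage_size > 0,
            "replicates": self.replicates >= 2,
            "inc_eff_len": self.inc_eff_len > 0,
            "skip_eff_len": self.skip_eff_len > 0,
        }
        for name, ok in checks.items():
            if not ok:
                raise ValueError(f"invalid SimConfig field: {name}")

    @classmethod
    def from_mapping(cls, cfg: dict[str, object]) -> "SimConfig":
        """Build a SimConfig from a flat run-configuration mapping."""
        kwargs: dict[str, object] = {}
        flat = dict(cfg)
        if "psi_baseline_low" in flat or "psi_baseline_high" in flat:
            kwargs["psi_baseline"] = (
                float(flat.get("psi_baseline_low", 0.1)),
                float(flat.get("psi_baseline_high", 0.9)),
            )
        if "effect_low" in flat or "effect_high" in flat:
            kwargs["effect"] = (float(flat.get("effect_low", 0.1)), float(flat.get("effect_high", 0.4)))
        names = {f.name for f in fields(cls)}
        for key, value in flat.items():
            if key in names:
                kwargs[key] = value
        return cls(**kwargs)


@dataclass
class SimBundle:
    """A simulated dataset plus its generating truth."""

    events: pd.DataFrame
    design: pd.DataFrame
    counts: pd.DataFrame
    truth: pd.DataFrame
    config: SimConfig = field(repr=False, default=None)  # type: ignore[assignment]


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float, size: int) -> np.ndarray:
    """Normal draws truncated to RESCUE_BOUNDS by redrawing."""
    lo, hi = RESCUE_BOUNDS
    if sd == 0:
        return np.full(size, float(np.clip(mean, lo, hi)))
    out = rng.normal(mean, sd, size)
    bad = (out < lo) | (out > hi)
    while bad.any():
        out[bad] = rng.normal(mean, sd, int(bad.sum()))
        bad = (out < lo) | (out > hi)
    return out


def read_level_probability(psi: np.ndarray, inc_len: float, skip_len: float) -> np.ndarray:
    """Probability that a junction read supports inclusion, given PSI.

    Inverts the effective-length-normalised PSI formula, so downstream PSI
    estimation is unbiased under unequal form lengths.
    """
    return psi * inc_len / (psi * inc_len + (1.0 - psi) * skip_len)


def simulate_dataset(config: SimConfig) -> SimBundle:
    """Simulate a replicated four-genotype junction-count dataset."""
    rng = np.random.default_rng(config.seed)
    n = config.n_events
    event_ids = np.array([f"ev{i:05d}" for i in range(n)])

    # 1. baselines
    psi_wt = rng.uniform(*config.psi_baseline, n)
    # 2. affected flags and mutant effects
    affected = rng.random(n) < config.frac_affected
    magnitude = rng.uniform(*config.effect, n)
    sign = np.where(rng.random(n) < 0.5, -1.0, 1.0)
    psi_null = np.where(
        affected, np.clip(psi_wt + sign * magnitude, 0.02, 0.98), psi_wt
    )
    dpsi_mut = psi_null - psi_wt
    # 3. per-event rescue fractions (drawn for all events; meaningful where affected)
    rescue_short = _truncated_normal(rng, config.rescue_mean_short, config.rescue_sd, n)
    rescue_long = _truncated_normal(rng, config.rescue_mean_long, config.rescue_sd, n)
    psi_iso_short = np.where(
        affected, np.clip(psi_wt + (1.0 - rescue_short) * dpsi_mut, 0.0, 1.0), psi_wt
    )
    psi_iso_long = np.where(
        affected, np.clip(psi_wt + (1.0 - rescue_long) * dpsi_mut, 0.0, 1.0), psi_wt
    )

    truth = pd.DataFrame(
        {
            "event_id": event_ids,
            "affected": affected,
            "psi_wt": psi_wt,
            "psi_null": psi_null,
            "psi_iso_short": psi_iso_short,
            "psi_iso_long": psi_iso_long,
            "dpsi_mut": dpsi_mut,
            "rescue_short": np.where(affected, rescue_short, np.nan),
            "rescue_long": np.where(affected, rescue_long, np.nan),
        }
    )

    events = pd.DataFrame(
        {
            "event_id": event_ids,
            "gene_id": [f"gene{i:05d}" for i in range(n)],
            "event_type": "SE",
            "inc_eff_len": config.inc_eff_len,
            "skip_eff_len": config.skip_eff_len,
        }
    )

    design = pd.DataFrame(
        [
            {"sample_id": f"{g}_r{k}", "genotype": g, "replicate": k}
            for g in GENOTYPES
            for k in range(1, config.replicates + 1)
        ]
    )

    psi_by_genotype = {
        "wt": psi_wt,
        "null": psi_null,
        "iso_short": psi_iso_short,
        "iso_long": psi_iso_long,
    }

    # 4. coverage, 5. counts — one (event × sample) grid in design order
    n_samples = len(design)
    p_nb = config.coverage_size / (config.coverage_size + config.coverage_mean)
    totals = rng.negative_binomial(config.coverage_size, p_nb, size=(n, n_samples))

    p_read = np.empty((n, n_samples))
    for j, genotype in enumerate(design["genotype"]):
        p_read[:, j] = read_level_probability(
            psi_by_genotype[genotype], config.inc_eff_len, config.skip_eff_len
        )
    rho = config.dispersion
    if rho > 0:
        a = p_read * (1.0 - rho) / rho
        b = (1.0 - p_read) * (1.0 - rho) / rho
        p_cell = rng.beta(np.maximum(a, 1e-12), np.maximum(b, 1e-12))
        p_cell = np.where(p_read <= 0, 0.0, np.where(p_read >= 1, 1.0, p_cell))
    else:
        p_cell = p_read
    inc = rng.binomial(totals, p_cell)

    counts = pd.DataFrame(
        {
            "event_id": np.repeat(event_ids, n_samples),
            "sample_id": np.tile(design["sample_id"].to_numpy(), n),
            "inc_count": inc.ravel(),
            "skip_count": (totals - inc).ravel(),
        }
    )
    return SimBundle(events=events, design=design, counts=counts, truth=truth, config=config)


def write_fixture(bundle: SimBundle, directory: str | Path) -> dict[str, Path]:
    """Write a bundle as events/design/counts/truth TSVs; lossless round-trip."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "events": write_events_tsv(bundle.events, directory / "events.tsv"),
        "design": write_design_tsv(bundle.design, directory / "design.tsv"),
        "counts": write_counts_tsv(bundle.counts, directory / "counts.tsv"),
    }
    truth_path = directory / "truth.tsv"
    bundle.truth.to_csv(truth_path, sep="\t", index=False)
    paths["truth"] = truth_path
    return paths


def read_fixture(directory: str | Path) -> SimBundle:
    """Read a bundle previously written by :func:`write_fixture`."""
    directory = Path(directory)
    events = read_events_tsv(directory / "events.tsv")
    design = read_design_tsv(directory / "design.tsv")
    counts = read_counts_tsv(directory / "counts.tsv", events)
    truth_path = directory / "truth.tsv"
    truth = (
        pd.read_csv(truth_path, sep="\t", dtype={"event_id": str})
        if truth_path.exists()
        else pd.DataFrame()
    )
    return SimBundle(events=events, design=design, counts=counts, truth=truth, config=None)
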