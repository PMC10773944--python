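"""Readers and writers for the pipeline's tab-separated table dialects.

Tables are exchanged as UTF-8 TSV files with a single header row:

``events.tsv``
    ``event_id  gene_id  event_type  inc_eff_len  skip_eff_len``
``design.tsv``
    ``sample_id  genotype  replicate``
``counts.tsv``
    ``event_id  sample_id  inc_count  skip_count``

The rMATS reader accepts the junction-count (JC) flavour of an SE result
table.  Genomic coordinate columns are carried through untouched as opaque
metadata; no coordinate arithmetic is performed, so no 0/1-based or strand
conventions are assumed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml

log = logging.getLogger(__name__)

EVENT_TYPES = frozenset({"SE", "MXE", "A5SS", "A3SS"})

EVENT_COLUMNS = ["event_id", "gene_id", "event_type", "inc_eff_len", "skip_eff_len"]
DESIGN_COLUMNS = ["sample_id", "genotype", "replicate"]
COUNT_COLUMNS = ["event_id", "sample_id", "inc_count", "skip_count"]


@dataclass(frozen=True)
class SpliceEvent:
    """One alternative-splicing event.

    Attributes
    ----------
    event_id : str
        Unique token within a dataset.
    gene_id : str
        Gene the event belongs to.
    event_type : str
        One of ``SE``, ``MXE``, ``A5SS``, ``A3SS``.
    inc_eff_len, skip_eff_len : float
        Effective lengths (number of read positions that can produce a
        junction read) of the inclusion and skipping forms; must be > 0.
    """

    event_id: str
    gene_id: str
    event_type: str
    inc_eff_len: float
    skip_eff_len: float

    def __post_init__(self) -> None:
        if self.event_type not in EVENT_TYPES:
            raise ValueError(f"unknown event_type {self.event_type!r} for event {self.event_id}")
        if not (self.inc_eff_len > 0 and self.skip_eff_len > 0):
            raise ValueError(f"non-positive effective length for event {self.event_id}")


def validate_events(events: pd.DataFrame) -> pd.DataFrame:
    """Validate an events table (unique ids, known types, positive lengths)."""
    missing = [c for c in EVENT_COLUMNS if c not in events.columns]
    if missing:
        raise ValueError(f"events table missing columns: {', '.join(missing)}")
    dup = events["event_id"][events["event_id"].duplicated()]
    if len(dup):
        raise ValueError(f"duplicate event_id: {dup.iloc[0]!r}")
    bad_type = set(events["event_type"]) - EVENT_TYPES
    if bad_type:
        raise ValueError(f"unknown event_type token(s): {sorted(bad_type)}")
    if len(events) and not ((events["inc_eff_len"] > 0) & (events["skip_eff_len"] > 0)).all():
        offender = events.loc[
            ~((events["inc_eff_len"] > 0) & (events["skip_eff_len"] > 0)), "event_id"
        ].iloc[0]
        raise ValueError(f"non-positive effective length for event {offender!r}")
    return events


def validate_counts(counts: pd.DataFrame, events: pd.DataFrame | None = None) -> pd.DataFrame:
    """Validate a junction-count table; optionally check referential integrity."""
    missing = [c for c in COUNT_COLUMNS if c not in counts.columns]
    if missing:
        raise ValueError(f"counts table missing columns: {', '.join(missing)}")
    for col in ("inc_count", "skip_count"):
        vals = counts[col]
        if len(vals) and ((vals < 0).any() or (vals != vals.astype(int)).any()):
            raise ValueError(f"{col} must be non-negative integers")
    if events is not None:
        unknown = set(counts["event_id"]) - set(events["event_id"])
        if unknown:
            raise ValueError(f"counts reference undeclared event(s): {sorted(unknown)[:10]}")
    return counts


def _read_tsv(path: str | Path) -> pd.DataFrame:
    # only empty fields are missing: genotype tokens such as "null" are data
    return pd.read_csv(
        path,
        sep="\t",
        keep_default_na=False,
        na_values=[""],
        dtype={"event_id": str, "sample_id": str, "gene_id": str},
        float_precision="round_trip",
    )


def read_events_tsv(path: str | Path) -> pd.DataFrame:
    return validate_events(_read_tsv(path))


def write_events_tsv(events: pd.DataFrame, path: str | Path) -> Path:
    validate_events(events)
    path = Path(path)
    events.to_csv(path, sep="\t", index=False)
    return path


def read_design_tsv(path: str | Path) -> pd.DataFrame:
    design = _read_tsv(path)
    missing = [c for c in DESIGN_COLUMNS if c not in design.columns]
    if missing:
        raise ValueError(f"design table missing columns: {', '.join(missing)}")
    return design


def write_design_tsv(design: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    design.to_csv(path, sep="\t", index=False)
    return path


def read_counts_tsv(path: str | Path, events: pd.DataFrame | None = None) -> pd.DataFrame:
    counts = _read_tsv(path)
    counts["inc_count"] = counts["inc_count"].astype(int)
    counts["skip_count"] = counts["skip_count"].astype(int)
    return validate_counts(counts, events)


def write_counts_tsv(counts: pd.DataFrame, path: str | Path) -> Path:
    validate_counts(counts)
    path = Path(path)
    counts.to_csv(path, sep="\t", index=False)
    return path


def read_gene_list(path: str | Path) -> list[str]:
    """Read one gene token per line, '#' comments ignored.

    Duplicates are removed, preserving first occurrence; surrounding
    whitespace is trimmed and comparison is case-sensitive.
    """
    seen: dict[str, None] = {}
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        token = line.strip()
        if not token or token.startswith("#"):
            continue
        seen.setdefault(token, None)
    return list(seen)


def write_gene_list(genes: list[str], path: str | Path) -> Path:
    path = Path(path)
    path.write_text("".join(f"{g}\n" for g in genes), encoding="utf-8")
    return path


# --------------------------------------------------------------------------
# rMATS SE (junction-count flavour) reader

_RMATS_MANDATORY = [
    "IJC_SAMPLE_1",
    "SJC_SAMPLE_1",
    "IJC_SAMPLE_2",
    "SJC_SAMPLE_2",
    "IncFormLen",
    "SkipFormLen",
]
_RMATS_PASSTHROUGH = ["IncLevel1", "IncLevel2", "IncLevelDifference", "PValue", "FDR"]


def _split_int_list(cell: object, row_id: str, column: str) -> list[int]:
    parts = str(cell).split(",")
    out = []
    for part in parts:
        part = part.strip()
        try:
            out.append(int(part))
        except ValueError:
            raise ValueError(
                f"non-integer count {part!r} in column {column} of row {row_id}"
            ) from None
    return out


def read_rmats_se(
    path: str | Path, group_a_label: str = "group1", group_b_label: str = "group2"
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame | None]:
    """Read an rMATS SE.MATS.JC-style table.

    Returns ``(events, counts, precomputed)`` where replicate counts are
    expanded into the long count table with synthesized sample ids
    ``<group>_r<k>`` and ``precomputed`` carries any IncLevel / FDR columns
    untouched (``None`` when the file has none of them).
    """
    raw = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if "ID" in raw.columns:
        id_col = "ID"
    elif "GeneID" in raw.columns:
        id_col = "GeneID"
    else:
        raise ValueError("missing mandatory column: ID (or GeneID)")
    for col in _RMATS_MANDATORY:
        if col not in raw.columns:
            raise ValueError(f"missing mandatory column: {col}")
    gene_col = "GeneID" if "GeneID" in raw.columns else id_col

    event_rows, count_rows = [], []
    for _, row in raw.iterrows():
        event_id = str(row[id_col])
        inc_a = _split_int_list(row["IJC_SAMPLE_1"], event_id, "IJC_SAMPLE_1")
        skip_a = _split_int_list(row["SJC_SAMPLE_1"], event_id, "SJC_SAMPLE_1")
        inc_b = _split_int_list(row["IJC_SAMPLE_2"], event_id, "IJC_SAMPLE_2")
        skip_b = _split_int_list(row["SJC_SAMPLE_2"], event_id, "SJC_SAMPLE_2")
        if len(inc_a) != len(skip_a) or len(inc_b) != len(skip_b):
            raise ValueError(f"ragged replicate count lists in row {event_id}")
        event_rows.append(
            {
                "event_id": event_id,
                "gene_id": str(row[gene_col]).strip('"'),
                "event_type": "SE",
                "inc_eff_len": float(row["IncFormLen"]),
                "skip_eff_len": float(row["SkipFormLen"]),
            }
        )
        for label, incs, skips in ((group_a_label, inc_a, skip_a), (group_b_label, inc_b, skip_b)):
            for k, (i, s) in enumerate(zip(incs, skips), start=1):
                count_rows.append(
                    {
                        "event_id": event_id,
                        "sample_id": f"{label}_r{k}",
                        "inc_count": i,
                        "skip_count": s,
                    }
                )

    events = pd.DataFrame(event_rows, columns=EVENT_COLUMNS)
    counts = pd.DataFrame(count_rows, columns=COUNT_COLUMNS)
    validate_events(events)

    passthrough = [c for c in _RMATS_PASSTHROUGH if c in raw.columns]
    precomputed = None
    if passthrough:
        precomputed = raw[[id_col] + passthrough].rename(columns={id_col: "event_id"}).copy()
        # "NA" replicate inclusion levels mean missing PSI, not zero
        for col in ("IncLevelDifference", "PValue", "FDR"):
            if col in precomputed.columns:
                precomputed[col] = pd.to_numeric(precomputed[col], errors="coerce")
    return events, counts, precomputed


# --------------------------------------------------------------------------
# Run configuration

#: default run configuration; simulation keys mirror ``simdata.SimConfig``
CONFIG_DEFAULTS: dict[str, object] = {
    "n_events": 500,
    "frac_affected": 0.3,
    "psi_baseline_low": 0.1,
    "psi_baseline_high": 0.9,
    "effect_low": 0.1,
    "effect_high": 0.4,
    "rescue_mean_short": 0.57,
    "rescue_mean_long": 0.89,
    "rescue_sd": 0.10,
    "dispersion": 0.02,
    "coverage_mean": 100.0,
    "coverage_size": 10.0,
    "replicates": 3,
    "inc_eff_len": 150.0,
    "skip_eff_len": 100.0,
    "seed": 0,
    # analysis-stage parameters
    "alpha": 0.01,
    "dpsi_floor": 0.05,
    "min_total": 10,
}

_CONFIG_TYPES: dict[str, type] = {
    "n_events": int,
    "replicates": int,
    "min_total": int,
    "seed": int,
}

_CONFIG_BOUNDS: dict[str, tuple[float, float]] = {
    "frac_affected": (0.0, 1.0),
    "dispersion": (0.0, 0.999999),
    "alpha": (0.0, 1.0),
    "dpsi_floor": (0.0, 1.0),
    "rescue_sd": (0.0, 10.0),
}


def load_config(path: str | Path | None) -> dict[str, object]:
    """Load a flat key-value (YAML-syntax) run configuration.

    Unknown keys are rejected, defaults are filled in, and the resolved
    configuration is echoed to the log.
    """
    resolved = dict(CONFIG_DEFAULTS)
    if path is not None:
        loaded = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ValueError("config must be a flat key-value document")
        unknown = set(loaded) - set(CONFIG_DEFAULTS)
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        for key, value in loaded.items():
            want = _CONFIG_TYPES.get(key)
            if want is int:
                if isinstance(value, bool) or not isinstance(value, int):
                    raise ValueError(f"config key {key!r} must be an integer, got {value!r}")
            elif not isinstance(value, (int, float)) or isinstance(value, bool):
                raise ValueError(f"config key {key!r} must be numeric, got {value!r}")
            lo, hi = _CONFIG_BOUNDS.get(key, (float("-inf"), float("inf")))
            if not (lo <= float(value) <= hi):
                raise ValueError(f"config key {key!r} out of bounds [{lo}, {hi}]: {value!r}")
            resolved[key] = value
    for key, value in sorted(resolved.items()):
        log.info("config %s = %r", key, value)
    return resolved
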