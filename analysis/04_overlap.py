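#!/usr/bin/env python
"""Gene-set overlap between strains' dysregulated splicing events.

Builds per-strain gene lists from the differential-splicing tables of
02_diffsplice.py, counts the Venn regions, and scores pairwise overlap
against the universe of all tested events with a one-sided Fisher's
exact test. Strains sharing a regulator are expected to share targets,
so the null-vs-isoform overlaps should be strongly enriched.
"""

from pathlib import Path

import pandas as pd

from splicerescue.setoverlap import fisher_overlap, venn_counts

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    events = pd.read_csv(ROOT / "sim" / "events.tsv", sep="\t", dtype=str)
    gene_of = events.set_index("event_id")["gene_id"]

    lists: dict[str, set] = {}
    universe: set = set()
    for strain in ("null", "iso_short", "iso_long"):
        rec = pd.read_csv(ROOT / f"diffsplice_{strain}.tsv", sep="\t", dtype={"event_id": str})
        universe |= set(gene_of.loc[rec["event_id"]])
        lists[strain] = set(gene_of.loc[rec.loc[rec["dysregulated"], "event_id"]])

    regions = venn_counts(lists)
    venn = pd.DataFrame(
        [{"region": "&".join(k), "count": v} for k, v in sorted(regions.items())]
    )
    venn.to_csv(ROOT / "venn.tsv", sep="\t", index=False)
    print("Venn regions over dysregulated genes:")
    print(venn.to_string(index=False))

    rows = []
    for a, b in (("null", "iso_short"), ("null", "iso_long"), ("iso_short", "iso_long")):
        test = fisher_overlap(universe, lists[a], lists[b])
        rows.append({"set_a": a, "set_b": b, **test.__dict__})
        print(f"{a} vs {b}: overlap {test.overlap} "
              f"(|A|={test.set_a_size}, |B|={test.set_b_size}, N={test.universe_size}), "
              f"p = {test.p_value:.3g}")
    pd.DataFrame(rows).to_csv(ROOT / "overlap.tsv", sep="\t", index=False)


if __name__ == "__main__":
    main()
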