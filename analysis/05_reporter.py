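#!/usr/bin/env python
"""Quantify a simulated bichromatic splicing-reporter experiment.

Emulates per-cell two-channel measurements of a splicing reporter in
which exon inclusion drives GFP and skipping drives mCherry: 30 cells
per stage across L1-L4 with the true mCherry fraction drifting upward
as development shifts splicing toward the skipped form. Summarises
relative mCherry intensity per stage (mean, SEM, n) the way imaging
quantifications are reported.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from splicerescue.reporter import summarize_reporter

ROOT = Path(__file__).resolve().parent.parent / "results"

STAGE_MEANS = {"L1": 0.40, "L2": 0.45, "L3": 0.51, "L4": 0.56}


def main() -> None:
    rng = np.random.default_rng(2026)
    rows = []
    for stage, mu in STAGE_MEANS.items():
        for i in range(30):
            frac = float(np.clip(rng.normal(mu, 0.07), 0.02, 0.98))
            total = rng.uniform(400, 2500)  # arbitrary-unit intensity scale
            rows.append(
                {
                    "cell_id": f"{stage}_c{i:02d}",
                    "tissue": "VNC",
                    "stage": stage,
                    "genotype": "wt",
                    "i_mcherry": frac * total,
                    "i_gfp": (1 - frac) * total,
                }
            )
    cells = pd.DataFrame(rows)
    cells.to_csv(ROOT / "reporter_cells.tsv", sep="\t", index=False)

    summary = summarize_reporter(cells, ["tissue", "stage"])
    summary.to_csv(ROOT / "reporter_summary.tsv", sep="\t", index=False)
    print("relative mCherry intensity per stage (mean +/- SEM, n):")
    for row in summary.itertuples(index=False):
        print(f"  {row.stage}: {row.mean_rel_mcherry:.3f} +/- {row.sem:.3f} (n={row.n})")
    l1 = summary.loc[summary["stage"] == "L1", "mean_rel_mcherry"].iloc[0]
    l4 = summary.loc[summary["stage"] == "L4", "mean_rel_mcherry"].iloc[0]
    print(f"L1 -> L4 shift toward the skipped form: +{l4 - l1:.3f}")


if __name__ == "__main__":
    main()
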