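# splicerescue

Tools for asking a precise question about alternative splicing: when a
splicing regulator is knocked out and then one of its protein isoforms is
restored, *how much of the regulator's splicing program does that isoform
rescue?* The package grew out of isoform-rescue experiments in
*C. elegans*, where a muscleblind-family regulator exists as exon-including
(long) and exon-skipping (short) isoforms and engineered strains express
exactly one of them, but the machinery applies to any wild-type / null /
isoform-only strain design with replicated junction-count data.

## The statistic

For one splicing event, the inclusion level is the effective-length
normalised percent spliced in,

```
psi = (I / lI) / (I / lI + S / lS)
```

with `I` inclusion and `S` skipping junction reads and `lI`, `lS` the
effective lengths of the two forms. ΔPSI of a strain is its group-mean psi
minus wild type's. Over events dysregulated in the null mutant, each
isoform strain gets a per-event **splicing rescue index**

```
SRI = 1 − ΔPSI_iso / ΔPSI_mut
```

SRI = 1 is complete rescue (the strain restores wild-type splicing),
SRI = 0 is no rescue, values above 1 (overshoot) or below 0 are kept
unclamped and flagged. Events are classed weak (SRI < 0.33), intermediate
(0.33 ≤ SRI < 0.66) or high (SRI ≥ 0.66), and strains are compared by a
pooled-variance two-sample t-test on their per-event SRI distributions.

Dysregulated events are detected with a replicate-aware beta-binomial
likelihood-ratio test on junction counts (dispersion estimated per event
by moments with shrinkage across events, chi-square(1) reference,
Benjamini–Hochberg adjustment). Supporting modules cover rMATS-style SE
result tables as a real-data entry point, DE-list thresholding with
Fisher's-exact set-overlap testing, and two-channel (GFP/mCherry)
splicing-reporter quantification.

## Worked example

The numbered scripts under `analysis/` run the whole study on synthetic
data from the built-in simulator (500 events, four genotypes, three
replicates each, rescue fractions centred at 0.57 / 0.89 for the
short / long isoform):

```
python analysis/01_simulate.py
python analysis/02_diffsplice.py
python analysis/03_rescue_index.py
```

which prints

```
null: 402 of 500 testable events dysregulated -> results/diffsplice_null.tsv
...
SRI over 402 mutant-dysregulated events per strain
  mean SRI short = 0.581 (sd 0.262)
  mean SRI long  = 0.896 (sd 0.287)
  Student's t = -16.22, p = 2.15e-51
```

The estimated mean SRIs recover the simulator's configured rescue
fractions (0.57 and 0.89), and the long-isoform strain rescues
significantly better than the short one — the pipeline reads the planted
biology back out of raw junction counts. `analysis/04_overlap.py` and
`analysis/05_reporter.py` run the set-overlap and reporter-quantification
stages the same way.

The same stages are available as a CLI (`splicerescue simulate | psi |
diffsplice | sri | overlap | report | pipeline`), each writing flat TSVs
plus a JSON run manifest so stages are resumable and byte-reproducible
for a fixed seed.

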