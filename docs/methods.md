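# Methods

## Model and quantities

An alternative-splicing event is observed through junction reads
supporting its inclusion form (count `I`, effective length `lI`) and
skipping form (`S`, `lS`). The per-replicate inclusion level is

    psi = (I/lI) / (I/lI + S/lS),

the standard effective-length de-biased percent spliced in; effective
length counts the read positions that can yield a junction read for each
form, so unequal form lengths do not bias psi. Group inclusion is the
arithmetic mean of per-replicate psi values (not pooled counts), which
decouples ΔPSI from library size. ΔPSI for a strain is group-mean psi of
the strain minus wild type; both signs are kept.

For an event dysregulated in the null mutant, the splicing rescue index of
an isoform-only strain is

    SRI = 1 − ΔPSI_iso / ΔPSI_mut.

SRI is a ratio of two differences sharing the wild-type reference: 1 means
the strain restores wild-type splicing of the event, 0 means the mutant
defect persists unchanged. SRI is never clamped — overshoot (SRI > 1,
the strain pushes splicing past wild type) and sign flips (ΔPSI_iso
opposite in sign to ΔPSI_mut) occur in real data and are flagged in the
output instead. Rescue classes partition the line with half-open
intervals, weak < 0.33 ≤ intermediate < 0.66 ≤ high; strict-inequality
class definitions leave the boundaries unassigned, so the left-closed
convention is a deliberate choice recorded here and in run logs.

Strain comparison uses the pooled-variance (Student's) two-sample t-test
on the per-event SRI values, two-sided; Welch's correction is available
behind a flag. Events are weighted equally in per-strain means. SRI is
computed over the mutant-dysregulated event set for both strains, so the
two strains are scored on a common universe of events.

## Differential splicing test

Counts are modelled beta-binomially on the read-level inclusion
probability p = psi·lI / (psi·lI + (1−psi)·lS) with intra-class
correlation ρ capturing extra-binomial variation between biological
replicates. The test is a likelihood ratio between a shared-p and a
per-group-p model with ρ held fixed, referred to chi-square with one
degree of freedom; at ρ = 0 it reduces exactly to the binomial LRT
(verified against the closed form). The likelihood lives on counts; the
reported effect (ΔPSI) stays on the interpretable psi scale.

ρ is estimated per event by a one-way ANOVA moment estimator pooled over
genotype groups with ≥ 2 covered replicates, floored at 0 and shrunk
toward the across-event median with weight n/(n+4) (n = replicates used);
events without an estimable ρ receive the median. On data simulated at
ρ = 0.05 (500 events, 5 replicates) the median estimate lands within
±0.02 of truth, and with ρ known the raw test rejects at 5.5% for nominal
5% over 2000 null events.

Replicates below the coverage floor (default `min_total` = 10 junction
reads) are dropped from an event's test; an event is testable when ≥ 2
replicates per group remain. Benjamini–Hochberg adjustment runs over all
testable events of a contrast (delegated to statsmodels; an independent
step-up oracle backs the tests). An event is dysregulated when adjusted
p < α (default 0.01) **and** |ΔPSI| ≥ `dpsi_floor` (default 0.05). The
floor is not part of the original dysregulation criterion this design
mirrors; it exists to guard the SRI denominator against near-zero
ΔPSI_mut and can be set to 0.

## Synthetic data

The simulator generates the study conditions the analysis assumes: four
genotypes (wt, null, iso_short, iso_long) × 3 biological replicates;
baseline PSI ~ Uniform(0.1, 0.9); a configurable fraction of events
(default 0.3; recovery experiments use 1.0) receives a mutant effect of
magnitude Uniform(0.1, 0.4) with random sign, truncated so the mutant PSI
stays in [0.02, 0.98]; per-event rescue fractions ~ Normal(0.57, 0.10)
for the short strain and Normal(0.89, 0.10) for the long one, truncated
to [−0.2, 1.2] because real rescue overshoots 1; true isoform PSI is
psi_wt + (1−r)·ΔPSI_mut clipped to [0, 1], so the SRI estimator targets r
by construction. Coverage is NegativeBinomial(mean 100, size 10) per
event-sample, emulating library-size variation; inclusion counts are
beta-binomial with ρ = 0.02 via the length-aware read-level probability,
keeping PSI estimation unbiased under the default unequal effective
lengths (150 inclusion / 100 skipping, typical SE junction geometry at
150 bp reads). One seed drives a fixed draw order (baselines → flags →
effects → rescues → coverage → counts), so equal configs are
bit-identical.

What the simulator does not emulate: read-level alignment artefacts,
event-type-specific junction geometry (all events are two-form; the
SE/MXE/A5SS/A3SS label is metadata), correlated events within genes, and
batch structure. Passing recovery tests therefore demonstrates estimator
correctness under the assumed count model, not robustness to mapping or
annotation error.

## Problem sizes and numerical choices

Recovery runs use 500 fully affected events (≈400 survive the
dysregulation filter); calibration uses 2000 null events; sensitivity
uses 1000 events with |ΔPSI| ≥ 0.2. At these sizes a full pipeline run
takes seconds on one core. The beta-binomial MLE is a bounded scalar
optimisation on [1e−9, 1−1e−9] (xatol 1e−10); LRT statistics below 1e−7
are treated as exactly 0 (the alternative nests the null, so tiny
negative or positive residuals are optimisation noise). Zero-total groups
yield a missing test. Fisher overlap uses the one-sided (greater)
hypergeometric tail — enrichment is the question — with the universe
supplied explicitly, never defaulted to the union; the sample odds ratio
reports `inf` when a zero cell forces it. Gene identifiers compare
case-sensitively after whitespace trimming. Reporter ratios define
relative mCherry as mCherry/(mCherry+GFP), the two-channel normalisation
consistent with percentages that sum across channels; 0/0 cells are
missing, not zero, and background subtraction is the caller's
responsibility (negative clipping only behind an explicit flag).

## Known limitations

- The chi-square reference is asymptotic; at very low coverage or
  replicate counts the permutation alternative (available for small
  designs) is safer.
- Per-event SRI is a ratio estimator; events with |ΔPSI_mut| just above
  the floor carry noisy SRIs, which inflates the spread (not materially
  the mean) of per-strain summaries.
- The rMATS reader accepts the JC (junction-count) SE table only; other
  event-type tables are consumed as generic two-form count TSVs.
- Only two-group, unpaired contrasts are supported.
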