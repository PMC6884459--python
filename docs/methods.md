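# Methods

## The question and the model

Bulk RNA-seq of a mutant embryo collected in a fixed window (here 6–12 h
after egg laying) is compared with a stage-matched control and interpreted
against a wild-type developmental reference: per-gene expression across
contiguous half-open 2-hour bins covering [0, 24) h. The analysis treats a
developmental delay as a *rigid shift of the sampling window along the
wild-type trajectory*: a mutant delayed by Δ hours and collected at
[6, 12) expresses each gene approximately as wild type does over
[6−Δ, 12−Δ). Two observable consequences follow and both are implemented
as checks:

* a significant change in a gene is *compatible* with delay only if the
  wild-type trajectory moves in the right direction — up-regulation
  requires higher early (0–6 h) than late (6–12 h) reference expression,
  down-regulation the reverse; equality is counted as incompatible,
  because an unchanged trajectory cannot produce a change in either
  direction under any shift;
* a gene silent in every reference bin can never be activated by a delay,
  so any up-regulated reference-silent gene (derepression) indicates
  direct action.

The window comparison aggregates bin values by the arithmetic mean
(configurable to max); windows must tile exactly onto bin boundaries.
Genes without a reference row cannot be judged and are excluded from
classification but reported in a side channel, so counts always partition.

## Differential expression stand-in

The per-gene test is Welch's *t* on log2(x+1)-transformed replicate
values, two-sided, with Benjamini–Hochberg adjustment across all tested
genes and direction assigned at q < α (default 0.05) by comparing raw
condition means. A gene is *detected* if any replicate of either
condition is nonzero, and *testable* if detected, both condition means
reach `min_tested_mean` (default 1.0 FPKM) and at least one group has
nonzero variance on the log scale. This is intentionally the simplest
calibrated test whose outputs (status, direction, means, q) feed the
downstream stages; no isoform deconvolution, dispersion shrinkage or
multi-factor design is attempted. Fold change is log2 of the
pseudocounted mean ratio, (mean_mutant+1)/(mean_control+1), consistent
with the test transform.

Calibration: on label-exchangeable (null) data the tested p-values are
close to uniform (Kolmogorov–Smirnov distance ≈ 0.03 at 2000 genes with
biological CV 0.2 and three replicates per group). At very low biological
CV (≤ 0.1) the skewness of shot noise on the log scale makes the
small-sample *t* slightly miscalibrated in the body of the distribution
(KS ≈ 0.06); the far tail that drives BH rejections remains conservative —
the simulated false-discovery proportion over 200 global-null replicates
is ≈ 0.015 at α = 0.05.

## Exact rank tests

`wilcoxon_rank_sum_exact` and `wilcoxon_signed_rank_exact` enumerate the
full permutation null (all C(n1+n2, n1) group labelings, or all 2^n sign
assignments) whenever the pooled size is at most 20, using mid-ranks so
ties are handled exactly. The two-sided p-value is the total probability
of outcomes whose statistic deviates from its null mean by at least the
observed deviation — the symmetric-deviation definition. With ties the
null distribution need not be symmetric, and this definition can differ
from the "double the smaller tail" convention some software uses; the
symmetric definition is used consistently and reproduces the minimal
complete-separation p of 2/252 ≈ 0.0079 at n = 5 vs 5. Above the
enumeration limit both tests fall back to the tie-corrected normal
approximation. Kruskal–Wallis is computed with mid-ranks and the standard
tie correction against the χ² approximation; when every pooled value is
identical it returns H = 0, p = 1 rather than an error. Welch's *t* uses
the Welch–Satterthwaite degrees of freedom, with degenerate-variance
conventions (p = 1 for equal means, p → 0 flagged for unequal means).

## Overrepresentation

For each term carried by at least one study gene, the p-value is the
hypergeometric upper tail P(X ≥ k) for k of n study genes carrying a term
that K of N background genes carry (one-sided Fisher's exact test;
computed in log space via the scipy survival function for stability at
large N). The background defaults to the full annotation universe. The
BH adjustment is shared with the DE stage. The most-specific-term filter
keeps significant terms with no significant descendant in the transitive
closure of a supplied parent→child edge table (cycles are rejected); it
is a documented approximation of bottom-of-the-hierarchy term selection,
whose exact upstream rule is not public. With no edge table the filter
passes all significant terms through and sets a warning flag.

## Synthetic data generator

The generator emulates gene-level summaries of a staged embryo
experiment, not reads. Each non-silent background gene follows a smooth
trajectory from one of three shape classes — early-declining exponential
(decay constant τ ~ U(2, 6) h), late-rising logistic (midpoint
U(8, 18) h, steepness U(1, 3) h), or a Gaussian bump with peak time
U(0, 24) h and width U(1.5, 4) h — scaled by a log-normal amplitude
(median 20 FPKM, log-sd 1). The class mix is 0.4/0.4/0.2: the reference
profiles this emulates are dominated by monotone early-high or late-high
genes, with peaked genes a minority. Reference bin values are trajectory
averages over each bin (33-point trapezoid quadrature), so a window mean
over aligned bins equals the trajectory's window mean.

Gene roles are drawn first, by exact fraction of the gene count: silent
genes (all-zero rows; default 19% to match the roughly one-fifth of
annotated genes with no embryonic expression in the emulated reference),
then direct-effect sets. Direct-effect genes ride *flat* trajectories and
are multiplied by 2^(±`direct_effect_log2fc`) in the mutant only — a flat
gene's change can never be produced by a shift, which makes the injected
truth identifiable by the window rule and is the intended test bed for
the classifier's specificity. The delay is a rigid shift: the mutant's
expected expression is the trajectory mean over the collection window
moved earlier by `delay_hours` (shifting past time 0 is an error).

Replicates multiply the expected value by log-normal noise with CV
`biological_cv` (default 0.1 — synchronized-embryo pools average out much
organism-level variation), convert to counts with a negative-binomial
sampler (variance μ + φμ², φ = `nb_dispersion`, default 0.01 for
technical overdispersion; biological variation is carried by the
log-normal term, so the two are not double-counted), at `library_size`
fragments (default 2×10⁷, typical bulk depth). FPKM output rescales
counts with a uniform 1 kb gene length — length effects cancel in every
downstream statistic used here. Defaults of 2000 genes and 3 replicates
per condition keep simulation-based tests fast while matching the
replicate structure of the emulated experiment. One seed drives every
draw (reference and sampling use decorrelated child streams), so equal
configurations give bitwise-identical outputs.

What the generator does *not* emulate: gene-length variation, GC or
mappability bias, isoform structure, correlated co-regulation between
genes, partially penetrant or per-gene-variable delays, and compositional
effects of very highly expressed genes. Passing recovery tests therefore
demonstrates the pipeline's logic under the stated noise model, not
robustness to these real-data features.

## Numerical and design choices

* Percentages are rounded to one decimal (class tallies) or two decimals
  (low-expression fraction), matching conventional reporting; coding-loss
  percent is an integer.
* BH q-values come from statsmodels' step-up implementation behind
  `bh_adjust`; tests cross-check it against a hand step-up oracle.
* Stage assignment uses Spearman correlation (scale-free across FPKM
  magnitudes); the best bin is the argmax with the earliest bin on ties;
  constant sample or all-constant reference columns are degenerate
  errors. It exists to quantify "resembles younger embryos" on synthetic
  data, where an injected 2 h delay moves the best bin one bin earlier.
* Exact-test enumeration guards float comparisons with a 10⁻¹² tolerance
  when comparing rank-sum deviations.
* TSV round-trips are exact: floats are written with `repr` so
  read(write(x)) is an identity.
* The tally operates on record streams but is also constructible from
  bare counts (`ClassTally.from_counts`) for arithmetic on published
  count tables.

## Problem sizes in the test suite

Simulation-based properties run at 500–2000 genes with 3 replicates per
condition: 200 global-null replicates for FDR control, 50 seeded runs for
the staging shift, 5–10 runs for classifier fidelity and derepression.
These sizes give stable Monte-Carlo estimates (binomial standard errors
below 2 percentage points for the 90%-level fractions) with a suite that
completes in well under a minute.

## Known limitations

* The DE stand-in tests gene-level means only; genes whose regulation is
  isoform-specific would be invisible.
* The delay model is global and rigid; a mutant that delays only part of
  the program would be under-called by the window rule.
* The window rule compares two fixed windows (0–6 vs 6–12 h by default);
  genes peaking inside 6–12 h can change under a small shift while
  passing the rule in either direction.
* The most-specific-term filter depends entirely on the supplied edge
  table; with a partial hierarchy, parents of unlisted children are
  reported as specific.
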