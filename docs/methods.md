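# Methods

## Model and procedure

The segmentation model is a hidden Markov chain over fixed-width genome bins
with multivariate Bernoulli ("product-Bernoulli") emissions: given hidden
state k, each of M binarized occupancy tracks emits 1 independently with
probability e_km. This is the emission family standard for binarized ChIP
inputs (as in chromHMM); it keeps every EM update in closed form. The number
of states K is a parameter with default 4, matching the four-state
band/interband vocabulary (Aquamarine, Lazurite, Malachite, Ruby).

Training is Baum–Welch EM with scaled (per-step normalised) forward/backward
recursions, so likelihood computation cannot underflow regardless of sequence
length. Parameter estimates are floored at ε = 1e-6 (and capped at 1 − ε),
then renormalised, which prevents zero-probability lock-in. Initialisation
per restart: uniform initial distribution, transitions 0.9 on the diagonal
with the remainder spread uniformly, emissions drawn uniformly from
[0.1, 0.9] from a restart-specific seeded stream. Five restarts by default;
the highest converged log-likelihood wins, ties going to the lowest restart
index. Convergence is declared when the log-likelihood improves by less than
1e-6 in relative terms, with a 500-iteration cap; a non-converged best
restart is returned flagged (`converged_ = False`), not raised.

Decoding is Viterbi in log space, with exact ties broken toward the lowest
state index, making decoding bit-for-bit deterministic. Posterior-marginal
decoding is deliberately not the default output.

Masked bins — assembly gaps, or bins unobserved in any track — split the
chain into independent segments: each segment restarts from the initial
distribution, and no imputation is performed. Chromosome boundaries break the
chain the same way.

State labels are assigned from emissions only: the state with the highest
emission on the promoter/interband marker (CHRIZ) is Aquamarine; among the
rest the highest elongation-marker (RNA-polII) emission is Lazurite; of the
remaining two, the one with the lower mean emission across all tracks is Ruby
(condensed, protein-depleted) and the other Malachite. On exact marker ties
the lower state index wins the earlier rule and the displaced state competes
on the remaining rules; the rule order itself is fixed and documented.

## Binarization and track input

Continuous signal (bedGraph) is aggregated per bin (bp-weighted mean, or max)
and thresholded at an empirical quantile (default 0.9) of the observed bins,
with strict `>` so a constant track binarizes to all zeros. Peak-call input
(BED) is treated as already binary: a bin is occupied if any peak overlaps
it. Both paths exist because occupancy data circulates in both forms;
which one a given analysis used is a configuration choice, not a guess the
code makes.

Coordinates are 0-based half-open internally and in BED; region partition
files and human-readable reports use 1-based inclusive positions (the
FlyBase convention). The default bin size of 200 bp follows common practice
for chromatin-state segmentation and is configurable. Terminal bins keep
their true (short) width so bp totals are conserved exactly.

## Statistics

Compartment comparisons use the two-sided Mann–Whitney rank-sum test with
midrank tie handling: exact enumeration when the pooled sample is ≤ 16 with
no ties, otherwise a tie-corrected normal approximation with continuity
correction (delegated to scipy behind the package's own surface, which also
defines the degenerate all-tied case as p = 1). "Pairwise Wilcoxon"
comparisons between states are rank-sum tests as well, because bins of
different states cannot be paired; no pairing structure is invented.

Significance is a fixed p < 0.001 rule with no multiple-testing correction by
default (a Bonferroni flag exists). The effect size is log2 of the ratio of
mean bin signal in-state versus background; rows with an empty bin set or a
zero mean are emitted flagged with missing statistics rather than dropped.

Known limitation, recorded in every enrichment table's metadata: the sampling
unit is the genome bin, and neighbouring bins are strongly autocorrelated, so
nominal p-values are anti-conservative. The fixed 0.001 threshold partially
compensates but does not fix this; treat calls near the threshold with
caution.

## Region features and expression binning

Feature densities are `count / length_mb` with the counting rule explicit:
`start_in` (default — every feature counted exactly once across a partition),
`midpoint_in`, or `any_overlap`. Stored densities keep full precision;
display rounding mimics report style (one decimal below 15 per Mb, nearest
integer above, matching printed values like 7.5 and 95). Worked-example
reports accept (count, length) pairs directly so literature figures can be
recomputed without annotation files.

The expression classifier bins RPKM into eight ordered categories with
integer edges (>1000; 101–1000; 51–100; 26–50; 11–25; 4–10; 1–3; 0). The
nominal bins leave fractional values (e.g. 3.5) undefined; the implementation
assigns each fractional gap to the adjacent category whose upper bound it
sits above ((3,4) → VeryLow, (100,101) → High, [0,1) → ExtremelyLow/None),
which keeps the classifier total and monotone while agreeing with every
integer edge.

The shipped partition of the chromosome-3 heterochromatic interval names six
zones; only the eu/heterochromatin variability zone on 3L has determined
border coordinates (22,267,604–23,151,844). The other borders are stored as
explicit unknowns, never invented. Note an arithmetic wrinkle: these borders
are sometimes quoted as spanning "approximately 0.844 Mb", but the
coordinates themselves differ by 884,240 bp ≈ 0.884 Mb; the package computes
the arithmetic truth from the coordinates and reports 0.88424 Mb.

## Synthetic data: what it emulates and what it does not

The generator produces binarized multi-track occupancy by sampling a known
4-state chain and its Bernoulli emissions, optionally corrupted by
independent bit-flip noise (< 0.5); gene/ORC-like annotations per region with
Poisson(density × length) counts and uniform placement; and per-tissue RPKM
vectors drawn uniformly inside requested category ranges. Every generator is
a pure function of (spec, seed).

Default truth model: 4 states, 6 tracks, self-transition 0.95, emission
profiles following the qualitative state descriptions — Aquamarine CHRIZ 0.9,
Lazurite RNA-polII 0.8, Malachite flat 0.3, Ruby flat 0.05. Under these
defaults the Malachite–Ruby profiles differ by at most 0.25, and measured
Viterbi accuracy at 50k bins sits at ≈ 0.948–0.952. The parameter-recovery
guarantees (emissions within ±0.05, accuracy ≥ 0.95) are therefore stated —
and tested — under the `strong_separation` variant, in which Malachite
carries a moderate H3K9me2/HP1/SuVar signature so every state pair differs by
≥ 0.4 in some track; this is also the biologically cleaner description, since
the condensed band states are the ones enriched for those marks.

The het/eu preset constructs two compartments sharing emission profiles but
differing in state mix, with transition matrices of the form
sI + (1 − s)·1πᵀ (s = 0.9), whose stationary distribution is exactly π:
Ruby 0.70 / active (Aquamarine+Lazurite) 0.10 in the heterochromatic
compartment versus Ruby 0.519 / active 0.30 in the euchromatic one — a
three-fold active-chromatin contrast by construction. At the default 500,000
bins per compartment the Markov-chain sampling error of a state fraction is
≈ 0.004, so the realised fractions land within ±0.01 of the targets. This is
a construction check of the bookkeeping, not a reproduction of any empirical
compartment comparison: reproducing the real heterochromatin analysis
requires the original occupancy datasets and their (unpublished)
binarization.

What the synthetic data does **not** emulate: peak-calling artefacts, ChIP
efficiency differences between antibodies, spatially correlated noise,
copy-number and underreplication gradients, repeat-driven mappability
structure, and realistic gene-length distributions. Passing tests on
synthetic data therefore demonstrate correctness of the estimators and
bookkeeping under the stated generative assumptions — not robustness to the
full messiness of real chromatin profiling data.

## Problem sizes and numerics

The test suite and acceptance script run at sizes chosen to make sampling
error small relative to the tolerances being checked while staying
single-CPU-friendly: 50,000 bins for parameter recovery (binomial error on an
emission estimate ≈ 0.004), 500,000 bins per compartment for the state-mix
construction, 1,000 replicates for null calibration of the rank-sum test, and
exhaustive enumeration oracles confined to K ≤ 3, T ≤ 8. Dynamic-programming
kernels are numba-compiled; the first call in a fresh process pays a one-off
JIT compilation cost of a few seconds.
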