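# Methods

## The measurement problem

CCAN occupancy on α-satellite is inferred from nuclease-protected DNA
fragments sequenced as read pairs. On a homogeneous tandem repeat the
two mates of a pair map ambiguously (any placement is equivalent up to
the repeat period), so two standard shortcuts fail: fragment length
cannot be inferred from mate distance, and per-base coverage near the
ends of a short repeat reference is biased because boundary-spanning
fragments cannot be placed end-to-end. The package works around both:
lengths come from overlap-merging the pairs themselves, and coverage
comes from mapping to a triplicated repeat consensus followed by
folding modulo the period.

## Read-pair merging

A pair is merged by (1) trimming 3′ bases below Phred `min_quality`
(default 25), (2) reverse-complementing R2, (3) accepting the longest
suffix(R1)/prefix(revcomp R2) overlap of length ≥ `min_overlap`
(default 15) with at most one mismatch per 10 overlap nt, and
(4) resolving overlap disagreements to the higher-quality base. Merged
products shorter than `min_length` (default 25) are discarded; pairs
with no acceptable overlap are retained as unmerged (in 25 × 25
short-read mode no merging is attempted and only end counts are used).
The mismatch tolerance inside the overlap is implementation-defined
here: published overlap mergers do not document a single canonical
rule, and on error-free input every reasonable rule agrees, which is
the regime the exactness tests pin down (every error-free pair from a
fragment ≤ 2·read_length − min_overlap merges to its true length).

A subtlety of tandem repeats: an overlap longer than the true one would
imply a self-alignment of the repeat shifted by less than the read
length; for 250-nt reads and a 340-nt period such shifts are
geometrically impossible, so period-shifted false merges cannot occur.

## Mapping and folding

Alignment is exhaustive, ungapped, end-to-end: every start position on
both strands is scanned and the placement with the fewest mismatches
wins, ties broken leftmost-then-plus-strand (arbitrary but
deterministic). A hit is rejected when its best mismatch count exceeds
`max_mismatch_frac` × length (default 0.1). At reference sizes of tens
of kilobases the O(n·m) scan is fast in vectorised form and avoids an
aligner dependency; ungapped matching is the correct model because the
simulator's mutation process is substitution-only (below).

Occupancy over a repeat unit is computed against three tandem copies of
the unit consensus; covered position *p* contributes to folded position
*p* mod period. Folding conserves total coverage mass exactly and makes
the profile invariant to which copy the aligner picked — the property
tests permute the copy choice explicitly. Whether "occupancy" should be
per-base coverage or fragment counts is ambiguous in the field's usage;
per-base coverage is implemented as the primary statistic, with
fragment counts available from the hit tables.

## CENP-B box score and scan

The ancestral 15-bp core of the 17-bp CENP-B box, `TTCGTTGGAAACGGG`, is
scored by identity: 15/15 → 1.0, each mismatch −0.25, ≥4 mismatches →
0. The scanner reports every window on either strand with ≤3
mismatches — exactly the nonzero-score set, so scan and score are
mutually consistent. This replaces a motif-search-tool significance
criterion with an explicit mismatch cutoff; the two could differ only
for >3-mismatch sites with favourable positional statistics, which
carry zero score anyway. Overlapping same-strand windows collapse to
the fewest-mismatch (leftmost on tie) occurrence. Density is collapsed
hits per kilobase of scanned sequence.

## Calibration, enrichment, recovery, correlation

Calibrated count = raw × C / spike, with C = 10,000 (arbitrary; cancels
in every ratio). Fold enrichment = (target + ψ)/(IgG + ψ) on calibrated
counts, pseudocount ψ = 1 calibrated unit (set ψ = 0 for exact ratios).
Percent recovery normalises an antibody's per-fraction calibrated
counts to 100. The motif–enrichment association is the Pearson
product-moment correlation on untransformed values (a log10 option
exists and is reported separately); per-fraction correlations are
computed across contigs, and the pooled variant averages enrichment per
contig across fractions before correlating.

## The simulator and what it does (not) emulate

The simulator is the package's ground truth and defines the study
conditions:

* **Arrays** — an ancestral 340- or 342-nt dimer (AT-rich synthetic
  backbone, fixed seed, one perfect box at offset 60; the backbone is a
  synthetic stand-in for a real subfamily consensus, adequate because
  every downstream statistic depends on repeat geometry, box content
  and divergence, not the particular backbone) expanded into n copies,
  each mutated per base at the divergence rate, substitutions only,
  uniform over the three alternatives. Expected pairwise identity is
  (1−r)² + r²/3 ≈ 1 − 2r(1−r); r = 0.06 lands in the high-80s/low-90s
  percent identity regime characteristic of homogeneous arrays. No
  indels: this keeps the period exact so folding stays well defined
  (indel divergence is out of scope). Divergence *panels* mutate a
  founder dimer per array (array age) and expand it with ~2%
  within-array divergence (young expansion).
* **Occupancy link** — per-unit truth occupancy is `50**score` times
  lognormal noise: a log-linear link spanning the ~50-fold per-dimer
  enrichment range observed on real arrays. The quantitative form of
  the box-score→occupancy relationship is not an inference target —
  only correlations constrain it — so the link is a simulation choice.
  The lognormal σ defaults to 0.7, calibrated once so that the
  recovered score–enrichment Pearson r falls in the 0.66–0.83 regime
  reported for real arrays (σ = 0 pushes r toward its noiseless
  ceiling; the acceptance band used in tests is 0.6–0.85).
* **Salt partitioning** — fraction weights are a per-unit categorical
  over {no-salt, low-salt, high-salt, pellet}, interpolating linearly
  in box score between (0.10, 0.40, 0.35, 0.15) at score 0 and
  (0.02, 0.15, 0.68, 0.15) at score 1. The perfect-box preset was
  chosen so a homogeneous array recovers >80% of its signal in
  high-salt + pellet, the hallmark of intact CCAN particles. Solubility
  is drawn per unit, not per fragment, because particle stability is a
  property of the bound complex.
* **Fragments** — a three-component Gaussian mixture: subnucleosomal
  (100 ± 10 nt, weight 0.2), nucleosomal (172 ± 8 nt, weight 0.6),
  dimeric (340 ± 15 nt, weight 0.2), truncated to [25, 500] nt
  (below 25 the merge filter drops them; 500 brackets the observed
  ~100–450 bp range). Fragments centre on the unit's CENP-B box with
  Gaussian jitter (default sd 40 nt) and are allocated to units
  proportionally to truth occupancy. IgG background fragments are
  uniform in position and fraction.
* **Reads** — R1/R2 are the fragment's ends (truncated at the fragment
  boundary), Phred 37 throughout, with optional uniform sequencing
  errors marked by Phred 11 at the error position. Spike-in reads from
  an exogenous random genome are appended with `spike_` names; per-
  sample spike depth varies around its mean so calibration is
  exercised, not a no-op.

Not emulated: PCR duplicates, quality-score structure, indels,
higher-order repeat units beyond the dimer, nuclease sequence bias, and
chromatin features not reducible to the box-score link. Passing tests
therefore demonstrate that the *methods* recover known truth under
these conditions, not that real arrays obey the link function.

## Numerical and design choices

* Coordinates are 0-based half-open everywhere; bedGraph output follows
  the standard.
* All stochastic operations take explicit integer seeds; the pipeline
  derives every stage seed from the single config seed, and identical
  configs produce byte-identical tables.
* Degenerate inputs fail loudly: all-zero occupancy arrays, empty
  histograms after restriction, zero spike counts, zero-variance
  correlations, sub-2-unit fold-ranges.
* Dimer classification thresholds — centroid within 25 nt of the box
  start counts as "centered" (about half a nucleosome's DNA reach);
  monomer ratio ≥ 1.5 counts as asymmetric (above flat-noise
  fluctuation at ~50× coverage) — formalise phenomena that were
  described qualitatively; both are configurable knobs, and the
  parameter-recovery test shows ≥95% classification accuracy at 50×
  coverage.
* Zero-occupancy units receive the enrichment pseudocount before
  fold-range so the statistic stays finite.
* Default problem sizes (6–40 arrays of 4–12 units, 10³–10⁵ fragments)
  keep every simulation at interactive speed while leaving Monte-Carlo
  bands comfortably tighter than the assertions they feed.

## Known limitations

The exhaustive aligner is quadratic and intended for repeat consensi
and desk-scale contigs, not genomes. Fraction-resolved fold enrichment
compares against IgG *within* the same fraction, so an antibody that
redistributes material across fractions can show sub-unity enrichment
in depleted fractions even on its true targets — the cross-contig
correlation is unaffected, but absolute per-fraction enrichments should
be read with that in mind. Density-based correlations are weaker than
score-based ones on small synthetic panels because density is nearly
binary for short arrays.
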