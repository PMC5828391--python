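# satfrag

Fragment-level occupancy analysis of centromeric tandem repeats.

Human centromeres are megabase arrays of ~171-bp α-satellite monomers;
the functional, CENP-A-rich cores are built from 340-bp (SF1) or 342-bp
(SF2) head-to-tail **dimeric units** carrying one CENP-B box per dimer.
Profiling the CENP-A/B/C (CCAN) complex on such arrays from paired-end
nuclease-protection data (CUT&RUN or native ChIP combined with salt
fractionation) poses three repeat-specific problems that `satfrag`
addresses for desk-scale references:

1. **Fragment lengths cannot be taken from end-mapping** — both ends of
   a fragment map ambiguously on a homogeneous repeat. `satfrag` merges
   overlapping 250 × 250 read pairs (quality-trim q25, minimum length
   25, minimum overlap 15) so each insert's length is known directly.
2. **Occupancy profiles suffer reference edge effects** — fragments
   spanning a unit boundary cannot map end-to-end onto a single-unit
   consensus. `satfrag` maps to a *tandemly triplicated* dimer consensus
   and folds coverage back onto one period (position *p* contributes to
   *p* mod period), conserving mass exactly.
3. **Samples are not comparable without calibration** — enrichment is
   computed from spike-in-calibrated counts (`raw × C / spike`) as the
   ratio of a specific antibody to a nonspecific IgG control, and salt
   fractions (no-salt / low-salt / high-salt / pellet) are summarised as
   percent recovery.

Around these sit a CENP-B box scanner (ancestral 15-bp core
`TTCGTTGGAAACGGG`, score `max(0, 1 − 0.25·m)` for `m` mismatches,
density in hits/kb), per-dimer structural classification (occupancy
fold-range across units, footprint orientation relative to the box,
symmetric vs one-monomer asymmetric binding), and a ground-truth
simulator that generates α-satellite arrays, box-score-linked occupancy,
salt-fraction partitioning, CCAN-protected fragment-length regimes
(~100 bp subnucleosomal, ~160–185 bp nucleosomal, ~340 bp dimeric), and
paired-end reads with spike-in — so the whole pipeline is testable
without any external data.

## Worked example

Run the full simulated workflow (6 arrays across a divergence gradient,
CENP-A + CENP-B + IgG across four salt fractions):

```python
from satfrag import RunConfig, run_pipeline

out = run_pipeline(RunConfig(out_dir="demo", seed=1, n_arrays=6,
                             units_per_array=8, n_fragments=4000,
                             n_igg_fragments=4000))
```

`demo/` then contains FASTA/FASTQ inputs, the merged fragment-length
table, hit tables, folded bedGraph profiles, and summary TSVs. With the
config above, `recovery.tsv` reports for CENP-A:

```
antibody  fraction   percent
CENP-A    no_salt        3.9
CENP-A    low_salt      18.0
CENP-A    high_salt     57.3
CENP-A    pellet        20.9
```

— the simulated CCAN particles are largely insoluble below 500 mM NaCl,
so ~78% of the calibrated CENP-A signal sits in high-salt + pellet
(IgG, by contrast, spreads evenly). `correlations.tsv` gives the
per-fraction Pearson correlation between each contig's CENP-B box score
and its CENP-A/IgG fold enrichment:

```
antibody  x           fraction   pearson_r  n
CENP-A    best_score  high_salt      0.841  6
CENP-A    best_score  pooled         0.865  6
```

reflecting the simulated link between box strength and particle
stability. `motifs.tsv` shows box density of ~2.94/kb on homogeneous
arrays (one box per 340-bp dimer) decaying with divergence, and
`dimer_profiles.tsv` classifies every unit's footprint
(orientation/symmetry) and reports the per-array occupancy fold-range.

The same stages are available as subcommands of the `satfrag` CLI
(`simulate`, `merge`, `map`, `motifs`, `enrich`, `dimers`, `run`,
`fixtures`); see `satfrag --help`.

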