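# Methods

## Coordinates, TSS selection, promoter windows

All intervals are 0-based half-open internally; GTF and RepeatMasker `.out`
(1-based closed) are converted at the I/O boundary, BED is native. Overlap
means any shared base (>= 1 bp).

Each gene gets one TSS: the transcript isoform with the highest mean
expression across all samples (ties to the lexicographically smallest
transcript id). When transcript-level expression is unavailable — the
synthetic generator emits gene-level values only — the fallback is the
outermost (5'-most in gene orientation) TSS, which is deterministic and
strand-symmetric.

A promoter window `(upstream, downstream)` on the plus strand is
`[tss - upstream, tss + downstream)`; on the minus strand
`[tss - downstream + 1, tss + upstream + 1)`, which mirrors the plus strand
exactly: the TSS base itself is inside the window iff `downstream >= 1`.
Windows are clipped to the contig and dropped (with a warning) if empty.
Defaults per analysis: enrichment/dosage/regression use `(2000, 0)` (2 kb
upstream), distance curves extend the window to the largest bin edge,
motif scanning uses the proximal `(300, 50)`, coverage summaries
`(5000, 1000)`. All are configurable flags.

Repeat orientation is relative to the host gene (`same`/`opposite`).
Fragments are the counting unit (partial copies count; RepeatMasker
fragments sharing an ID can optionally be joined via
`io_formats.join_fragments`). A repeat overlapping two genes' promoters
counts for both. Unstranded intervals (CpG islands, TFBS) are never
orientation-split. TSS distance is signed (upstream positive), measured to
the nearest base of the repeat, 0 if the repeat covers the TSS;
`nearest_distance` features store the minimum absolute distance.

## Statistics

* Gene filtering: drop genes whose maximum never reaches 5 expression
  units; keep the 12 000 most variable (sample SD) of the survivors.
* Fold-change: `log2((mean_to + pc) / (mean_from + pc))`, arithmetic stage
  means of raw values, pseudocount default 1 unit.
* Hierarchical clustering: 1 − Pearson distance, average linkage, on
  row-standardized profiles; the tree is cut into exactly k clusters; rows
  are sorted by id first so the result is order-invariant. Blastocyst
  subtypes use the same machinery on sample columns, labels ordered by
  cluster size.
* Rank bins: genes sorted by fold-change (ties by id), consecutive bins of
  fixed size; a trailing remainder of at least half a bin is kept and
  flagged, smaller remainders dropped with a warning. Per-bin fold-change
  is the mean of per-gene log2 values (the variance-stabilized choice;
  log2-of-mean-ratio weights high expressors and was not adopted).
* Enrichment: 2x2 in-cluster vs all-other-clusters-combined tables, Pearson
  chi-square without continuity correction; Fisher's exact test substitutes
  whenever any expected cell is below 5.
* t-tests are Welch's, two-sided. Equal zero-variance groups give p = 1;
  unequal ones are flagged degenerate rather than assigned a p-value.
* Multiple testing is Benjamini-Hochberg everywhere, applied jointly within
  each battery. Features present in fewer than 20 genes are skipped in
  per-type presence tests (configurable).
* Regression is OLS with intercept; zero-variance columns are dropped with a
  note, perfectly collinear groups keep their lexicographically first
  member (greedy rank test), so the dropped set is deterministic.
* PWM scores: `score(i, b) = log2((p(i,b) + pc*bg_b) / ((1+pc)*bg_b))`,
  pseudocount 0.01 per cell, uniform background by default. Site counting
  at similarity tau counts windows scoring at least tau times the maximal
  achievable log-odds (the alternative reading — positional identity to the
  consensus — is behind a flag); windows containing N are unscorable. Both
  strands are scanned via the reverse complement.
* Genome distribution: each base is painted with one region label,
  precedence promoter > exon > intron > downstream > intergenic
  ("downstream" = 2 kb 3' of the gene end); a repeat is assigned by
  midpoint, expected counts are proportional to region lengths, which makes
  length-weighted mean fold exactly 1 per repeat name. Copy-number fits are
  lognormal MLE (mu = mean, sigma = population SD of log counts) with an
  approximate KS goodness-of-fit (parameters estimated from the same data).
  Strand preference is chi-square against 50:50, repeats near genes on both
  strands excluded. Inter-repeat distance spectra get a descriptive log-log
  slope, not a formal power-law fit.

## The synthetic generator

`synthetic_data.default_config()` emulates the statistical structure of
staged early-embryo expression on one 10 Mb chromosome with 2000 genes
(uniform TSS placement, >= 4 kb spacing, 1 kb single-exon genes), six
stages (oocyte ... blastocyst) x 4 samples, and three repeat families:

| family  | role       | copy rate /bp | effect (log2/copy) | orientation | decay scale |
|---------|------------|---------------|--------------------|-------------|-------------|
| B1sim   | SINE/Alu   | 1e-3          | +0.3               | both        | 50 kb (weak) |
| MT2sim  | LTR/ERVL   | 1e-4          | +1.2               | same only   | 1 kb (sharp) |
| L1sim   | LINE/L1    | 3e-4          | 0                  | —           | kept >= 1.2 kb from TSSs |

MT2sim copies take the nearest gene's strand with probability 0.8.
Expression is `baseline x archetype profile x 2^effect x 2^N(0, 0.8)` per
sample: lognormal baselines (median 30 units), four stage archetypes
(maternal decay 35%, transient 2C 15%, late activation 25%, flat 25%), and
the planted effect `sum_f beta_f * sum_copies exp(-d/scale)` over admissible
copies inside the 2 kb effect window, applied multiplicatively from the
late-2C stage on. Effects additive in log2 match the ~20–40%-per-copy
scale of reported SINE dosage effects; the exponential decay is a
single-parameter stand-in for an observed but unparameterized decay shape.
Motif consensus strings are planted into host-family consensus sequences;
genome FASTA emission (repeat copies spliced into random background) is
optional and off by default.

What the generator does **not** emulate: read-level noise and mapping
ambiguity, transcript isoform diversity (TSS selection on expression is
exercised by hand fixtures instead), genomic GC/CpG structure, correlated
repeat nesting, or allele-specific expression. Passing tests therefore
demonstrate correctness of the statistical machinery under the planted
model, not biological validity on real data.

## Recovery checks and problem sizes

Parameter recovery regresses the pseudocount-free fold-change on the
generator's true exposures (decay-weighted, orientation-split sums recorded
in `SimTruth`) plus archetype indicators — the correctly specified model,
under which each planted beta is the true coefficient. A count-based
regression is deliberately misspecified under sharp decay (counts ignore
the within-window decay), which is why the worked example's LTR count
coefficient is attenuated; the count regression is checked qualitatively
(sign, significance pattern) instead. The noise-free exactness check uses a
no-decay, flat-archetype, zero-noise config where `fold_change ->
build_feature_table -> multiple_regression` returns the planted 0.3 to
machine precision. Recovery with a pseudocount of 0 is exact in log-ratio
space because simulated values are strictly positive; the pipeline default
pseudocount stays 1.

The test suite uses 100 simulation seeds for coefficient recovery (2000
genes each), a 2400-gene/24-bin configuration for the rank-bin correlation
(a moderately prevalent strong-effect family, copy rate 5e-4 and beta 0.5,
so the presence fraction responds linearly instead of saturating), 10^4
random features for empirical type-I rates, and 10^4 random interval
queries for the brute-force overlap oracle. `scripts/acceptance.py` uses 30
recovery seeds to stay fast while estimating coverage percentages.

## Known limitations

* The KS p-value for the lognormal copy-number fit is anti-conservative
  (estimated parameters); it is reported as descriptive.
* Region painting holds one byte per genome base; fine for desk-scale
  genomes, memory-heavy for mammalian-scale ones (a sorted-interval
  implementation would replace it there).
* `group_motif_anova` assumes homoskedastic groups (classical one-way
  ANOVA); a rank-transform flag is available for heavy-tailed scores.
* The enrichment background is always "all other clusters combined";
  genome-wide backgrounds are not implemented.
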