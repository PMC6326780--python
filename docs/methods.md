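# Methods

## Coordinates and distances

All internal coordinates are 0-based half-open (BED convention); GFF3 is
converted at the reader boundary. Distances between features are
edge-to-edge gaps: overlapping or abutting intervals are at distance 0.
"Within X bp" is inclusive (gap ≤ X); "< 150 bp" is strict. Phrased this
way, the tier boundaries (overlap / < 150 / ≤ 500 / > 500) partition any
peak set. Distances ignore strand — an inverted repeat is the same
binding substrate in either orientation. Peak distance is measured from
the peak boundary by default; a summit mode (1 bp midpoint proxy)
is available through `PipelineConfig.peak_distance_mode` because peak
callers differ in which reference they report.

## Decayed-ITR detection

The scanner looks for local alignments of a consensus ITR (28 bp by
default) on both strands, scoring +1 match, −1 mismatch, −2 gap open,
−1 gap extend (an approximation of the megablast regime; all four are
configurable). A hit is retained when two separate criteria hold on the
best-scoring local alignment at its locus:

- identity ≥ 0.80 — matching columns over all aligned columns
  (gap columns included);
- length ≥ 0.80 — consensus positions inside the alignment over
  consensus length.

This dual-filter reading is the strictest consistent interpretation of
an "80% of length and identity" retention rule. Consequences worth
knowing: substitutions clustered at one end can make a *trimmed* local
alignment optimal, so a copy is judged by its best alignment, not by its
full-length overlap with the consensus; and near-threshold divergence
levels leave individual copies above the filter with binomial-tail
probability, so "recall at divergence d" is a distribution, not a step
function.

Hit finding is two-stage: an ungapped seed pass computes full-length and
7-mer-chunk Hamming distances at every offset with numpy shifts
(pigeonhole: a copy with few edit operations contains a near-intact
ungapped chunk), and each merged candidate window is re-scored with an
affine local alignment (Biopython's `PairwiseAligner`). An exhaustive
per-window scan (`scan_consensus_bruteforce`) provides the reference
implementation; the two are tested for exact agreement on random
genomes. IUPAC ambiguity codes in the consensus match any listed base;
`N` in the genome matches nothing and scores as a mismatch when aligned.
Overlapping same-strand hits keep the single best-scoring window (ties:
leftmost, then plus strand); no chaining, since each ITR is a ≤ 28 bp
unit.

Remnant classification is greedy left-to-right over sorted hits: two
consecutive hits on one chromosome in inverted orientation with a gap of
6 ± 2 bp form a Made1-like miniature element (the tolerance absorbs
spacer indels); inverted pairs with gaps up to `pair_max_gap` (default
1500 bp, roughly the interior of a full-length element) form a paired
remnant; everything else is a solo ITR. Each hit belongs to exactly one
annotation.

## Gene context

A gene is its TSS-to-poly(A) span plus the union of its exons
(overlapping recorded exons are merged; exon union length is the FPKM
denominator). "Intragenic ITR" means the ITR overlaps the gene *span* —
the TSS-to-poly(A) reading — with an intron-only mode available as a
config switch, since reasonable studies differ on whether exonic copies
count. Gene UTRs are part of the span. Overlapping genes each receive a
peak that falls in both, which is why peak-bearing genes can outnumber
intragenic peaks.

Per-gene binding classes are assigned in priority order: `bound_itr`
(some peak within 500 bp of an intragenic ITR) > `distal_peak_with_itr`
> `peak_no_itr`; genes without an overlapping peak are `no_peak`. The
priority order resolves genes with several peaks deterministically.
Summary percentages are integer-rounded over peak-bearing genes.

## Expression integration

DE tables arrive fitted (gene, mean expression, log2 fold-change,
adjusted P); the package applies the call thresholds only: |FC| strictly
greater than 2, padj ≤ 0.05 inclusive, missing padj → not significant
(matching the NA behaviour of independent filtering in standard DE
fitters). Genes absent from a table are `ns`, not errors. FPKM is
`fragments × 10⁹ / (total_fragments × union_exon_bp)`; expression bins
are half-open `[e_i, e_{i+1})` with an implicit `[0, e_1)` first bin.
Direction concordance between two conditions counts genes called in
both, how many flipped sign, and per direction in A how many moved the
same way in B. `near_itr_10kb` (ITR-less gene within 10 kb of an ITR) is
measured gene-span edge to ITR edge and is mutually exclusive with ITR
containment.

## Enrichment statistics

The hypergeometric tail is computed as a log-sum-exp over log-gamma pmf
terms: `P(X ≥ k)` for over-representation (inclusive of k), `P(X ≤ k)`
under. The log10 tail is accurate to better than 1e−9 relative error at
transcriptome-scale inputs (N ≈ 16,776), verified against exact
big-integer rational enumeration, so tails around 1e−78 are meaningful
on the log scale even where the linear probability is degenerate. Tests
are one-sided and uncorrected, matching how such screens report raw
hypergeometric P-values; the population defaults to the genes in the
analyzed table. Mann–Whitney U delegates to scipy (exact enumeration for
small untied samples, tie-corrected normal approximation otherwise).

## Metaprofiles

Coverage comes from bedGraph text tracks (bit-exact tests, no binary
dependencies; bigWig is deliberately out of scope). Profiles average
per-base coverage in consecutive `bin_size` (default 10 bp) bins across
`[mid − halfwidth, mid + halfwidth)` windows centred on reference-point
midpoints (`floor((start+end)/2)`); minus-strand rows are reversed so
bins read 5′→3′; edge-clipped points are dropped and counted rather than
zero-padded. The summary profile is the mean over rows (median
available). RPGC normalization scales by
`genome_size / (total_reads × read_length)` so mean depth is 1×; RPKM
scales per-bin values by `10⁹ / (total_reads × bin_size)`. Input
subtraction is cell-wise and requires identical geometry and
normalization. The default half-width (2 kb) covers the ~1 kb phased
nucleosome arrays flanking ITR centres with margin.

## Synthetic data: what it emulates, and what it does not

The generator plants, on an i.i.d. uniform A/C/G/T background:

- decayed ITR copies — per-site substitution probability `d`, indels at
  `d/10` with geometric lengths (p = 0.5), so decay is primarily
  substitutional, the scanner's main regime;
- Made1-like elements (inverted pair, 6 bp spacer) for ~45% of
  remnants; about two-thirds of remnants inside introns;
- peak sets with `round(frac_at_itr × n_peaks)` peaks centred within
  ±150 bp of randomly chosen ITRs (the ground-truth bound set) and the
  rest uniform — uniform peaks occasionally land near ITRs by chance,
  so recovered near-ITR fractions sit slightly above the planted
  fraction;
- IP tracks as triangular-kernel peak signal over Poisson background,
  input as Poisson background, and nucleosome-style tracks with a
  Gaussian trough at each ITR centre flanked by an exponentially damped
  200 bp cosine;
- paired DE tables over a 16,776-gene universe: 960 up / 517 down in
  condition A (ITR genes up-weighted by a configurable odds ratio,
  default 3), 103 genes shared with condition B of which each flips
  direction with probability 0.74, plus B-exclusive calls biased 3:1
  toward down-regulation. padj values are assigned consistently with
  the calls, never fitted — DE model fitting is consumed, not
  implemented.

These defaults are the study design the package is exercised at; the
`paper-scale` preset keeps the printed peak and DE-table counts on a
10 Mb genome with 160 remnants, and the `small` preset (200 kb, tracks
included) runs every stage in seconds. What the generator does *not*
emulate: real repeat-family landscapes, GC/isochore structure, read-level
noise, correlated expression, or peak-width/shape realism. Passing
closure tests therefore demonstrates correctness of the bookkeeping and
statistics on planted signal, not detection power on real chromatin.

All generators draw from one `numpy` `default_rng` per call and are
byte-identical for a fixed seed.

## Numerical and degenerate-input choices

- Gap scoring: the first gap position costs open + extend (−3), later
  positions −1.
- Tail guards: log tail sums are clipped at 0 (p ≤ 1) against rounding.
- `intersect_features` ties break by leftmost target start, then name;
  queries on chromosomes without targets stay unpaired rather than
  erroring.
- Empty peak or annotation sets yield zero-count tables, not errors;
  an empty gene set in expression binning yields a zero row.
- Scanner windows shorter than 80% of the consensus are skipped — they
  cannot host a retainable hit.

## Problem sizes used in the checks

Oracle-equivalence scans run on 20 kb genomes; closure runs use the
10 Mb paper-scale layout for peak/DE bookkeeping (planted coordinates,
no re-scan) and the 200 kb preset where the genome is re-scanned.
Calibration of the test size uses 1000 null draws at N=2000, K=200,
n=300. These sizes are the package's own validation design: large enough
for the binomial bands to be informative, small enough to run anywhere.

## Known limitations

- The scanner targets short (≤ ~40 bp) consensus units; it does not
  chain hits into full-length element alignments.
- Exact reproduction of a published remnant count from a real genome
  depends on the original search parameters (word size, e-value) that
  such studies rarely print; the alignment scores here are explicit and
  configurable instead.
- bedGraph tracks are expanded to dense per-chromosome arrays for
  profiling — fine up to tens of megabases, not for whole mammalian
  genomes in one pass.
- The Mann–Whitney exact path requires untied samples; tied small
  samples fall back to the asymptotic approximation.
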