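# Methods

`stat5targets` implements the desk-scale statistical core of an integrative
ChIP/nascent-RNA/CAGE analysis for finding the direct target genes of an
activated transcription factor (the motivating system is pSTAT5 in
EPO-stimulated murine erythroid cells).  Every stage is exercised end-to-end
on a seeded synthetic-data generator that plants known structure, so the
pipeline's claims are validated by recovery rather than by re-processing
archived sequencing runs.

## Coordinate conventions

All coordinates are 0-based half-open internally.  GTF input (1-based
inclusive) is converted at the reader boundary; narrowPeak/BED/bedGraph are
used as-is.  A narrowPeak summit offset of -1 ("no estimate") falls back to
the interval midpoint.  Chromosome names are compared exactly; no "chr"
aliasing is performed, so mismatched naming surfaces as an explicit
no-gene-on-chromosome warning instead of silently empty joins.

## Peak annotation

Each peak is represented by its summit, the single-base maximum-evidence
binding estimate.  Classification precedence:

1. **promoter** — the gene-oriented distance from *any* TSS lies in
   `[-1000, +100]` nt (both boundaries inclusive).  The window is a property
   of TSSs, not of the nearest gene, so a summit inside one gene's intron
   but within another gene's TSS window is a promoter hit.
2. **UTR / CDS / intron** — the summit falls in a gene body: exonic hits are
   CDS when inside the CDS span, UTR otherwise (genes without an annotated
   CDS treat all exonic hits as UTR); non-exonic body hits are intronic.
3. **distal** — within 50 kb of a gene-body edge (inclusive).
4. **intergenic** — everything else.

Nearest-TSS distances are signed in gene orientation (negative = upstream).
Ties on |distance| resolve to the lexicographically smallest gene id and are
logged.  The promoter window and distal limit are parameters (`annotate
--promoter-up/--promoter-down/--distal`), because reasonable window choices
move the promoter fraction by several points and published figures differ on
which value they quote.

## Motif analysis

Degenerate IUPAC consensus matching and log-odds PWM scanning both operate
on both strands (the reverse strand via the reverse-complement of the
motif), with sequence `N` matching only a pattern `N`.  PWMs are estimated
as `(count + pseudocount) / (n + 4*pseudocount)` per column against a
configurable background (default uniform 0.25); positions containing `N`
score -inf.  Shipping presets: GAS `TTCYMRGAA`, GATA `WGATAR` (variant
`WGATAA` also provided), KLF `CCMCRCCCN`.  The GAS consensus is *not*
exactly self-reverse-complementary (its reverse complement is `TTCYKRGAA`);
`is_palindromic` reports this honestly rather than symmetrising the motif.

### Central enrichment

The test asks whether best motif sites concentrate at the centres of
summit-aligned sequences (default summit +/- 500 bp).  Per sequence the
single best site is kept — ties resolve to the site closest to the centre,
then the lowest offset, then the forward strand; consensus motifs count
only exact matches and sequences without one are excluded from `n`.  For
each odd window width `W` in `1, 3, ..., max_window` (default `L // 2`) the
central count `k` is compared against Binomial(`n`, `p0`) where `p0` is the
fraction of candidate site-centre positions inside the window; the reported
window minimises the tail probability and `adjusted_p = p * n_windows`
(Bonferroni over windows, deliberately left uncapped as a plain product).

With 10 sequences of length 101 and a 9-mer planted dead-centre this gives
the closed form `p = (1/93)^10` at `W = 1`, which the tests assert.  Under a
uniform-position null the adjusted p is below 0.05 in well under 7% of 500
replicates.

**Known bias**: for low-information patterns that match several times per
sequence, the closest-to-centre tie-break concentrates "best" sites
centrally even under a compositionally uniform null, so wide-window
marginal enrichments of degenerate motifs (e.g. the GATA preset against
GAS-planted sequences) should be read as neighbourhood descriptions, not
calibrated p-values.  High-information, truly central motifs (the GAS
element at `W = 1`) are unaffected.

## Co-occupancy and signal heatmaps

Two factors co-occupy a site when their summits lie within 500 bp
(inclusive; configurable) on the same chromosome; each reference peak pairs
with its nearest qualifying partner.  Venn regions are derived from the
boolean binding matrix and partition the reference set.

Heatmap quantification follows the clustered-heatmap recipe: signal is
averaged per-base into 50 bins around each summit, scaled to reads per
million (`1e6 / total_reads`), log2(x+1)-transformed, and divided by the
track's maximum over the *clustered area* (not per-row), so the display
window shares the clustering window's scale.  The clustering window
defaults to 500 bp around the summit with the alternative 200 bp span one
config knob away (both spans are quoted in the motivating study's methods
and figure caption); the display window defaults to 10 kb.

Rows are clustered by the nearest-neighbour chain algorithm on Euclidean
distances over the concatenated per-track bins.  The chain implementation
collects reciprocal-nearest-neighbour merges under a Lance–Williams update
and then sorts/relabels merges by height, which yields a merge tree
identical (same merges, same heights) to naive O(n^3) agglomerative
clustering for every *reducible* linkage — average (default), complete,
single, Ward.  Centroid/median linkage is refused with an explanation,
because the chain algorithm can invert merges under non-reducible updates.
Leaf order is a recursive traversal visiting the lower-height (tighter)
child first, ties to the smaller node id.  Correctness is checked two
independent ways: a brute-force agglomerative oracle written in the test
suite, and `scipy.cluster.hierarchy.linkage`.

## Differential expression of nascent RNA

Counts are normalised by median-of-ratios size factors (ratio of each
library to the per-gene geometric mean, median over genes with all-positive
counts; total-count scaling as a logged fallback).  Per gene:

* `fold_change = (mean_plus + 1) / (mean_minus + 1)` on normalised
  condition means (pseudocount 1 bounds folds at low counts);
* `mean_fpkm` is the mean of the two condition-mean FPKMs, with
  `FPKM = count * 1e9 / (length * library_size)`;
* significance comes from an exact conditional binomial test on the pooled
  normalised counts: `k` = stimulated pool out of `n` = total pool, null
  proportion = the stimulated libraries' share (1/2 for balanced designs).
  The two-sided p is the doubled smaller tail, capped at 1 — exact and
  fully vectorisable;
* Benjamini–Hochberg FDR over the tested genes; genes below a mean
  normalised count of 10 (configurable) are reported untested.

A gene is *induced* at FDR < 0.05 and fold >= 1.5, *repressed* at fold <=
1/1.5.  The thresholds parameterise the effect-size floor of the motivating
study's printed DEG table.  Because the binomial test conditions on the
pooled total it ignores biological overdispersion; at the generator's
dispersion (0.01) the fold-change floor dominates the error rate and the
planted-truth criteria (sensitivity >= 0.9, empirical FDR <= 0.1, null
false-call rate <= 0.07) hold with a wide margin, but on strongly
overdispersed data a count-model test (e.g. a negative-binomial GLM) would
be the appropriate upgrade.

Replicate QC is the per-condition Spearman correlation of log-scale FPKM
over genes expressed in either replicate of a pair (all pairs averaged when
there are more than two replicates).

## CAGE dynamics

Tag-count libraries across the time course are normalised as relative log
expression: per-library scale factor = median over all-positive regions of
(count / per-region geometric mean), upper-quartile scaling as a logged
fallback; `rle = log2(count/scale + 1)`.  Replicates are averaged on the
normalised linear scale per time point.  A region whose maximal
pseudocounted fold over t=0 stays below 2 is *unresponsive*; otherwise it
is *immediate* when the maximum occurs at or before 60 min and *delayed*
after.  Both thresholds are parameters; they encode the qualitative
fast-vs-slow induction language of the motivating study (30–60 min primary
transcription versus ~2 h maxima).

## Target classification

Peaks link to every gene whose TSS lies within the linkage window of the
summit (default 100 kb, inclusive; the study quotes both 50 kb and 100 kb
in different places, so the window is a flag and reports state the value
used).  Links are deliberately not nearest-gene-exclusive: a regulated gene
need not be the closest gene to its enhancer.  Scenarios:

* **direct** — a differential gene with at least one linked peak;
  `promoter_bound` when any linked peak sits in that gene's own promoter
  window, else `enhancer_bound`;
* **independent** — a differential gene with no linked peak (a candidate
  target of a parallel signalling arm);
* **background** — non-differential genes;
* separately, every peak whose linked genes are all non-differential
  (including peaks with no link at all) is flagged **bound_unresponsive**.

Direct + independent partition the DEG set by construction, and enlarging
the window can only move genes from independent to direct.

## The synthetic study

The generator is a pure function of its config (seed included): same seed,
byte-identical outputs.  Defaults mirror the motivating study's scale and
are fixed once:

* **Genome** — 4 chromosomes x 3 Mb of i.i.d. uniform ACGT sequence.
  Chromosomes carry roles: two *mixed* chromosomes host the feature-class
  peaks and all planted direct-target genes; a *quiet* chromosome carries
  the planted independent DEGs and filler genes and contains no reference
  peak; the last chromosome hosts only non-DEG genes plus a >50 kb gene
  desert for intergenic peaks, so everything on it is bound-unresponsive by
  construction.  Genes have 2–6 exons with a >=600 nt first/last exon, a
  CDS inset 400/300 nt from the oriented ends and >=700 nt introns, giving
  guaranteed plantable promoter/UTR/CDS/intron/distal positions; bodies are
  pairwise disjoint and infeasible packing raises.
* **Peaks** — 302 reference peaks with class quota 70 promoter / 12 UTR /
  10 CDS / 90 intron / 75 distal / 45 intergenic (~23% promoter, majority
  intronic/distal), fold enrichments log-uniform 5–40, one peak per host
  gene, summits >= ~2 kb apart.  A GAS 9-mer is written at the summit for
  80% of peaks.  Co-occupied KLF1/GATA1 partners (fractions 67/302 and
  147/302) sit within +/-500 bp of their reference summit; decoy factor
  peaks are placed >= 2 kb from every reference summit, which makes the
  planted co-occupancy counts exact under the 500 bp rule.
* **Signal** — triangular peaks (half-width 300 nt) over a 0.2 floor, with
  a planted tall/short (30 vs 8) two-cluster structure on the reference
  track for heatmap validation.
* **Counts** — baseline means log-uniform on [500, 5000] (every gene at or
  above the 500-read recovery depth), 2+2 replicates with library factors
  (1.0, 1.08, 0.94, 1.02), negative-binomial noise at dispersion 0.01 — a
  typical well-behaved cell-line replicate dispersion, consistent with the
  high replicate correlations the pipeline's QC reports (~0.98).  63 genes
  are induced and 24 repressed with fold changes log-uniform on [1.5, 8.4],
  the printed range of the motivating study's DEG table; 40+15 of them are
  direct (hosted on mixed chromosomes), the rest independent (quiet
  chromosome).
* **CAGE** — time grid {0, 30, 60, 120, 240, 480, 1440} min, two
  replicates, base ~200 tags.  Responsive regions follow a log-time bump
  peaking at 30/60 min (immediate) or 120/240 min (delayed) with amplitude
  3–8x; 10 regions per class plus 170 stable background promoters.  The
  background is essential, not cosmetic: median-of-ratios normalisation
  assumes most regions are unchanged, and a table where two-thirds respond
  coherently would (correctly) absorb the common induction into the scale
  factors and flatten real responses.  Per-library depth factors
  (log-normal, sd 0.2) and 15% multiplicative noise are removed/tolerated
  by RLE.

What the generator does **not** emulate — GC structure and repeats, read-
level noise and mappability, fragment-size effects on peak shape, isoform
complexity, correlated gene-gene expression, chromatin-contact geometry.
Passing recovery tests therefore demonstrates the correctness of the
statistics and of the integration logic under the stated noise model, not
robustness to every artefact of real sequencing data.

## Problem sizes and determinism

The validation suite runs the full default study (302 peaks / 330 genes /
4x2 count libraries / 200 CAGE regions), a 200-replicate x 2000-gene null
DEG study, a 500-replicate central-enrichment null at n=200, and 50 random
20x50 clustering matrices per linkage — sizes chosen so the whole suite
completes in well under a minute on a single core while keeping every
binomial/recovery margin wide.  All randomness flows through
`numpy.random.default_rng` seeded from the config or the test, so every
number in the README and `results/` is exactly reproducible.

## Known limitations

* The binomial DEG test understates variance under strong overdispersion
  (see above); the dispersion knob makes this explorable.
* Central enrichment of highly degenerate motifs is biased by the central
  tie-break (see above).
* Feature classification is summit-based; interval-overlap annotation would
  classify broad peaks differently.
* `bound_unresponsive` is a per-peak statement about linked genes within
  the window; distant regulation beyond the window is invisible without
  chromatin-conformation data and is explicitly out of scope.
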