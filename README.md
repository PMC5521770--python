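# stat5targets

Identifying the **direct target genes of an activated transcription factor**
by integrating three assays: ChIP-seq peaks for the factor, differential
expression of newly transcribed (4sU-labelled) RNA, and CAGE promoter
activity over a stimulation time course.  The motivating system is pSTAT5 in
EPO-stimulated murine erythroid cells, where a few hundred occupied sites
must be reconciled with tens of rapidly induced genes.

The package provides, as a tested library with a CLI on top:

* **Peak annotation** — nearest-TSS distances and a six-way feature
  classification (promoter = 1 kb upstream / 100 nt downstream of any TSS;
  UTR/CDS/intron inside gene bodies; distal within 50 kb of a body;
  intergenic otherwise).
* **Motif analysis** — degenerate-consensus (GAS `TTCYMRGAA`, GATA
  `WGATAR`, KLF `CCMCRCCCN`) and PWM scanning on both strands, plus a
  central-enrichment test: per summit-centred sequence the best site is
  kept and its centrality tested against a Binomial(n, p0) null over
  candidate positions, minimised over odd window widths with a Bonferroni
  window correction.
* **Co-occupancy and heatmaps** — summits within 500 bp define
  co-occupancy; signal is binned (50 bins), reads-per-million normalised,
  log-transformed, max-normalised over the clustered area, and row-ordered
  by a from-scratch **nearest-neighbour chain** agglomerative clustering
  (average/complete/single/Ward), proven equal to naive O(n³) clustering.
* **Differential expression** — median-of-ratios normalisation,
  pseudocounted fold changes, an exact pooled binomial test with BH-FDR
  (induced: fold ≥ 1.5, FDR < 0.05), and Spearman replicate QC.
* **CAGE dynamics** — relative-log-expression normalisation and an
  immediate (peak ≤ 60 min) / delayed / unresponsive (< 2-fold) caller.
* **Target scenarios** — each DEG with a peak within 100 kb of its TSS is a
  likely *direct* target (promoter- or enhancer-bound); DEGs without one
  are likely *independent* of the factor; peaks whose linked genes are all
  unresponsive are flagged *bound-unresponsive*.
* **A seeded synthetic-data generator** (first-class, tested code) that
  plants all of the above structure — feature classes, central GAS words,
  co-occupancy fractions, fold changes in the printed 1.5–8.4 range, CAGE
  dynamics classes — and records the truth for recovery testing.

See `docs/methods.md` for the full model description, parameter rationale
and known limitations.

## Worked example

The numbered drivers under `analysis/` run the whole study on the default
synthetic dataset (seed 0) and write their tables under `results/`:

```bash
python analysis/01_simulate.py
python analysis/02_annotate_peaks.py
...
python analysis/07_classify_targets.py
```

`02_annotate_peaks.py` prints:

```
annotated 302 peaks
  intron       29.8 %
  distal       24.8 %
  promoter     23.2 %
  intergenic   14.9 %
  UTR           4.0 %
  CDS           3.3 %
planted classes recovered: 302/302
```

— about a quarter of binding sites sit in promoters and the majority in
intronic/distal (enhancer-like) space, and every planted class label is
recovered.  `03_motif_enrichment.py`:

```
GAS   (TTCYMRGAA): 242/245 best sites in a 1 nt central window, adjusted p = 0
GATA  (WGATAR): 132/251 best sites in a 335 nt central window, adjusted p = 1.05e-07
KLF   (CCMCRCCCN): 4/36 best sites in a 173 nt central window, adjusted p = 224
```

— the GAS element is overwhelmingly summit-centred (direct binding), while
the degenerate neighbourhood motifs show at most weak, wide-window signal
(an adjusted p above 1 just means "nothing after correction").
`04_cooccupancy_heatmap.py` recovers the planted co-occupancy exactly and
separates the planted signal clusters:

```
co-occupancy (summits within 500 bp):
  KLF1_total   67
  GATA1_total  147
  GATA1+KLF1   36
  none         124
planted tall/short clusters recovered (reference track): 100.0 %
```

`05_differential_expression.py` and `07_classify_targets.py` close the
loop from counts to scenarios:

```
60 genes induced, 24 repressed (of 330)
planted DEGs recovered: 84/87
replicate Spearman r: EPO+ 0.986, EPO- 0.975
...
scenario summary: {"background": 246, "bound_unresponsive_peaks": 70,
                   "direct": 54, "direct_enhancer_bound": 40,
                   "direct_promoter_bound": 14, "independent": 30, "n_deg": 84}
recovery vs planted truth:
  scenario_gene_recovery        96.55 %
  bound_unresponsive_recovery  100.00 %
  scenario_recovery             99.23 %
  deg_sensitivity               96.55 %
  dynamics_recovery            100.00 %
```

The three DEGs missed are planted close to the 1.5-fold calling floor —
exactly the genes an FDR-controlled caller is expected to drop.

The same stages are available as a CLI for file-based inputs
(narrowPeak/GTF/FASTA/bedGraph/TSV):

```bash
stat5targets simulate --seed 0 --outdir simdata
stat5targets annotate --peaks simdata/pSTAT5.narrowPeak --gtf simdata/genes.gtf --out ann.tsv
stat5targets deg --counts simdata/counts.tsv --design simdata/design.tsv --out degs.tsv
stat5targets run --config pipeline.yaml --outdir out   # full pipeline + manifest
```

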