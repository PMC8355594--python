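# thymoflux

Metabolic profiling of T-cell development couples two very different
measurements: extracellular-flux assays (Seahorse mito stress tests) that
quantify glycolytic and mitochondrial activity of sorted thymocyte
populations, and bulk RNA-seq of metabolic gene programs across the same
ordered developmental stages (DN → ISP → DP early → DP late → SP).
`thymoflux` implements the full analysis chain for this kind of study —
for immunologists and computational biologists who have well-level kinetic
flux exports and a normalized expression matrix and want reproducible,
testable numbers connecting the two.

## What it computes

**Bioenergetic metrics per well.** A mito stress test records oxygen
consumption rate (OCR, pmol O₂/min) and extracellular acidification rate
(ECAR, mpH/min) through four injection phases: baseline, oligomycin, FCCP
(two injections, one phase), and rotenone/antimycin A (Rot/AA). After
normalizing rates to cell number per well,

```
basal ECAR   = baseline ECAR
basal OCR    = baseline OCR − Rot/AA OCR
maximal OCR  = max post-FCCP OCR − Rot/AA OCR
SRC          = maximal OCR − basal OCR        (spare respiratory capacity)
OCR/ECAR     = basal OCR / basal ECAR
```

with group summaries (mean ± sd over technical-replicate wells) and
two-tailed unpaired t tests (Welch by default) under Benjamini–Hochberg
adjustment.

**Gene-panel trajectories.** Curated metabolic pathways (glycolysis, TCA,
ETC, nucleotide synthesis, FAO, PPP, ribosomal programs, regulators) are
summarized as the mean z-score of member genes per population. The
double-negative subsets (DN1–3 in mouse, Thy1–3 in human) are composited
into one DN value as a convex combination weighted by each subset's
measured proportion (mouse thymus: 4% / 3% / 93%). A variable-gene filter
selects differentially expressed genes from a precomputed DE table
(|fold change| > 2 with adjusted Wald p < 0.01 in ≥ 1 contrast, ≥ 5 FPKM
in ≥ 1 sample, plus CPM / mappability / count-outlier exclusions), and
standardized PCA summarizes population structure.

**Transcriptome–flux integration.** Per-population flux means are
asinh-transformed (x ↦ asinh(x/5)) and correlated gene-by-gene with
z-scored expression over the shared populations. Each gene gets a Pearson
R, a two-sided p (t reference, n−2 df; undefined when only 3 populations
are available), a BH-adjusted p over the pathway family, and a sign class:
positive (R > 0.5), negative (R < −0.5), or weak.

**Synthetic data.** `thymoflux.simulate` generates all three input kinds
with known ground truth — piecewise-constant stress-test kinetics with
Gaussian noise and optional mixing transients, stage-structured expression
with programmed peak-at-ISP / nadir-at-DP-early trajectories, flux-linked
genes and anticorrelated isoform pairs, and DE tables with known filter
outcomes — so every stage of the pipeline is testable against truth.

## Worked example

Simulate a plate (5 populations × 4 wells, 5% measurement noise), extract
metrics, and integrate with simulated expression:

```bash
thymoflux simulate-flux --seed 42 --noise-sd 0.05 --out sim
thymoflux flux-metrics --traces sim/traces.csv --counts sim/cell_counts.csv \
    --out flux --compare "DN:DP early" --compare "ISP8:DP early"
head -4 flux/group_summary.tsv
```

```
group   metric      mean                sd                  n
DN      basal_ecar  29.60611560687124   0.8300899204797553  4
DN      basal_ocr   59.59072819105359   1.1871783232611934  4
DN      maximal_ocr 121.73069534226921  4.163500066258418   4
```

The DN estimates sit on the simulator's truth (basal ECAR 30, basal OCR
60, maximal OCR 120 per 1000 cells) within the 5% measurement noise. The
comparison table shows basal OCR collapsing at DP early
(t = 75.2, adjusted p ≈ 2×10⁻⁶ vs DN). Then:

```bash
thymoflux simulate-expression --seed 42 --out expr
thymoflux integrate --flux-summary flux/group_summary.tsv \
    --expr expr/expression.tsv --panel expr/panel.yaml \
    --scheme scheme.yaml --metric basal_ocr --out integrated
```

`integrated/correlation_glycolysis.tsv`:

```
        gene_id       r  raw_p  adj_p sign_class
  GLYCOLYSIS001  0.9555 0.0112 0.0227   positive
  GLYCOLYSIS002  0.9550 0.0114 0.0227   positive
  ...
GLYCOLYSISISOA1  0.8929 0.0414 0.0414   positive
GLYCOLYSISISOB1 -0.9040 0.0352 0.0391   negative
```

All eight glycolysis genes simulated with a slope-1 link to basal OCR are
recovered as positively correlated (R > 0.9, adjusted p < 0.05); the
mirrored isoform pair splits into one positive and one negative gene —
the isoenzyme-switching signature the classification is designed to
surface. `scheme.yaml` holds the stage ordering and DN weights (see
`tests/test_cli.py` for a complete copy).

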