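# Methods

## Bioenergetic metrics from stress-test kinetics

A mito stress test partitions the measurement axis into four phases by an
injection schedule: baseline; oligomycin (ATP-synthase inhibition, leaving
proton-leak respiration); FCCP (uncoupling, driving maximal respiration —
the two FCCP injections are treated as a single phase); and
rotenone/antimycin A, which silences the electron transport chain and
leaves only non-mitochondrial oxygen consumption. The schedule is a list
of (phase, first measurement index) pairs; every measurement maps to
exactly one phase, and the default layout is three measurements per phase.

Derived metrics per well:

* basal ECAR = baseline ECAR,
* basal OCR = baseline OCR − Rot/AA OCR,
* maximal OCR = maximum single post-FCCP OCR − Rot/AA OCR,
* spare respiratory capacity (SRC) = maximal − basal OCR (held as an
  identity of the two computed values, never recomputed independently),
* OCR/ECAR ratio = basal OCR / basal ECAR (NaN with a `zero_basal_ecar`
  flag when basal ECAR is 0).

Aggregation choices the instrument literature does not fix are exposed as
options with documented defaults:

* **Baseline aggregation** (`baseline_mode`): mean of all baseline
  measurements (default) or the last pre-injection measurement. Both are
  common instrument conventions; neither is asserted as canonical.
* **Rot/AA floor**: mean of the Rot/AA-phase measurements. The phase
  minimum would be an alternative; the mean is less noise-sensitive at
  3 measurements per phase.
* **Maximum OCR**: the single largest FCCP-phase measurement (not the
  phase mean) — "maximal respiration" is a peak response.
* **Mixing transients** (`exclude_first_post_injection`, default off):
  optionally drop the first measurement of each post-injection phase,
  where compound mixing can bias the level.

Rates are normalized to cell number per well before metric extraction
(per 1000 cells by default; a pure rescaling recorded in the output).
Normalization is refused on an already-normalized trace set rather than
silently applied twice. Negative derived metrics are reported with a
quality flag, never clipped: silently clipping at zero would bias group
means upward precisely in the low-signal populations where the question
is whether activity collapsed.

Group summaries use the sample (n−1) standard deviation; a single-well
group reports sd as NaN, not 0. Group comparisons are two-tailed unpaired
t tests — Welch by default, since technical-replicate counts of 2–4 wells
make the equal-variance assumption untestable; the pooled-variance Student
variant is selectable. The BH family is exactly the set of comparisons
submitted in one call, so the caller controls family scope (per figure,
per metric, per experiment).

## Gene panels over ordered stages

Expression enters as a gene × population matrix of count-normalized,
variance-stabilized values computed upstream; this package performs no
count normalization itself. Populations follow an ordered scheme (mouse:
DN1, DN2, DN3, ISP8, DP early, DP late, SP8, SP4; human: Thy1–3, ISP4,
…, with SP4 absent from the human organoid scheme). Panel gene symbols
are matched case-insensitively so mouse title-case and human upper-case
symbols resolve identically.

**DN compositing.** The DN compartment is measured as one population in
flux assays but sequenced as three subsets. The composite DN expression
value is the convex combination Σ wᵢ·xᵢ with the measured subset
proportions (mouse thymus 4/3/93%, mouse organoid 1/1/98%, human thymus
0.1/59.9/40%, human organoid 0.1/79.9/20%). Compositing happens on the
expression scale *before* z-scoring of the correlation input: a convex
combination of z-scores from the full stage set would not correspond to
any population's expression on any scale.

**z-scoring** is per gene row over the populations in view, with the n−1
denominator. Constant rows map to all zeros and are flagged (rather than
NaN) so pathway means stay defined; they are excluded from correlation
families downstream.

**Pathway trajectories** are unweighted means of member-gene z-scores per
population, with per-pathway coverage reported; a pathway matching zero
genes is an error, and absent genes are listed, never silently dropped.

**Variable-gene filter.** A gene passes iff (a) some pairwise contrast has
fold change > 2 in either direction (the two-sided reading: the selected
set should contain both up- and down-regulated genes) with BH-adjusted
Wald p < 0.01, (b) its maximum expression reaches 5 FPKM, (c) maximum CPM
≥ 0.5, (d) mappable length ≥ 50 bp, and (e) it is not a count outlier.
The outlier flag is consumed as annotated by the upstream DE tool
(Cook's-style detection belongs there), not recomputed. All five
thresholds are parameters; the filter is monotone in each, so relaxing
any threshold can only grow the set.

**PCA** standardizes each gene to mean 0, sd 1 across populations before
the decomposition (constant genes are dropped with a warning), reports
variance fractions that are nonincreasing and sum to 1, and fixes
component signs deterministically by making each component's
largest-magnitude loading positive.

## Transcriptome–flux integration

The per-population flux value is the mean of well-level metrics across
replicates, computed before any transform. Flux values are then
asinh-transformed, x ↦ asinh(x/c) with cofactor c = 5 — log-like
compression for large values but linear and odd near zero, so zero or
slightly negative derived fluxes remain well-defined. Gene z-scores are
never transformed.

Per gene, Pearson R is computed between the z-scored trajectory and the
transformed flux vector over the shared populations; the two-sided p
comes from t = R·√((n−2)/(1−R²)) with n−2 degrees of freedom. With n = 3
populations (the organoid configuration) that p would rest on one degree
of freedom and is reported as undefined; such genes are excluded from the
BH family. Constant expression rows get an undefined R with a reason and
are likewise excluded. Sign classes: positive (R > 0.5), negative
(R < −0.5), weak otherwise; `significant` additionally requires adjusted
p < 0.05. The default BH family is one pathway per call (matching
per-panel volcano-style plots); `family="all-pathways"` pools every gene
into one family.

Thymus-style runs default to all five shared populations (DN, ISP,
DP early, SP8, SP4); because it is ambiguous whether DP early belongs in
the thymus correlation set, the `populations` argument accepts any
explicit subset (≥ 3) and the run manifest records exactly which
populations, parameters and input digests produced each table.

## The synthetic-data generator

The flux simulator draws, per group, a four-level piecewise-constant OCR
profile — baseline = basal + non-mitochondrial floor, oligomycin =
floor + residual fraction × basal, FCCP = floor + fold × basal (fold ≥ 1,
so true SRC ≥ 0), Rot/AA = floor — and a two-level ECAR profile, adds
i.i.d. Gaussian noise per measurement (absolute, or relative to the
group's baseline level), optionally a decaying post-injection mixing
transient, and scales each well by its drawn cell count so that
normalization is genuinely exercised. Ground truth is returned on the
normalized per-1000-cell scale. Default group levels encode the
qualitative developmental profile (per 1000 cells): DN basal OCR 60 with
FCCP fold 2.0, ISP8 55/1.4, DP early 15/1.05, SP8 35/1.5, SP4 28/1.45 —
highest activity and reserve in DN/ISP, a collapse at DP early, partial
SP recovery with SP8 > SP4. Under relative noise the analytic standard
error of the group-mean basal OCR is sd·√(2/m)/√W (m measurements per
phase, W wells), which the recovery tests use for coverage.

The expression simulator evaluates, per pathway, a piecewise-linear stage
template: a pre-peak plateau at half amplitude, a distinct peak
(+amplitude, ISP by default), a nadir (−amplitude, DP early by default),
and partial recovery to 0 at the final stage. Each gene adds a constant
baseline offset (irrelevant after z-scoring) and Gaussian noise
(sd 0.25 by default). Genes in a *linked* pathway instead follow
slope × (standardized true flux metric per population, with DN subsets
sharing the composite DN value), so a linked gene is exactly affine in
the raw flux vector at zero noise; the developmental shape of linked
genes comes from the flux profile itself. Isoform pairs add two genes
with mirrored (±template) trajectories, anticorrelated at R = −1 in the
noise-free limit. The DE-table simulator constructs genes that satisfy
all filter predicates or violate a random nonempty subset, and recomputes
the expected pass set by brute-force predicate evaluation on the emitted
table.

What the generators do *not* emulate: read-level counts, library-size or
batch effects, within-plate spatial structure, correlated noise between
genes or wells, biological replicate variance distinct from technical
noise, and edge effects of real plates. Passing tests therefore
demonstrate that the pipeline's arithmetic, alignment, calibration and
classification behave correctly under the assumed noise model — not that
the model captures every failure mode of real instruments or libraries.

## Numerical choices

* Sample sd uses n−1 everywhere; z-scores and Pearson R follow.
* BH adjustment is the step-up suffix-minimum; ties in raw p receive
  equal adjusted values by construction.
* Pearson R is clamped to [−1, 1] against floating-point drift before
  the t transform; 1−R² ≤ 0 maps to p = 0.
* Degenerate t tests: two constant equal groups give t = 0, p = 1;
  constant unequal groups give ±∞ with p = 0.
* Zero-variance flux vectors abort integration with an error rather than
  emitting NaN correlations.
* Tolerances: exact identities are tested at 1e-9 to 1e-12; p-value
  comparisons against reference implementations at 1e-9.

## Problem sizes in the test and acceptance runs

Monte-Carlo checks use 500 plates (stochastic flux recovery), 500 linked
and 2,000–20,000 null correlation draws, 200 full pipeline runs, 100 DE
tables, 10,000 BH vectors and 2,000 null t tests — sizes at which each
asserted rate's binomial/Monte-Carlo error is small against its margin
(the one deliberately tight case, the null weak rate whose true value is
60.9% against a 60% bound, uses 20,000 draws so the check resolves the
margin rather than the draw). The whole suite runs in a few minutes on
one core.

## Known limitations

* Only the delimited trace dialect defined here is parsed; proprietary
  binary instrument files are out of scope.
* No ATP-production-rate or proton-efflux modeling; the only background
  correction is the Rot/AA subtraction.
* DE statistics, count normalization and variance stabilization are
  consumed, not computed; no clustering or GO enrichment.
* With three populations, correlation significance is undefined by
  design; sign classes remain available but are descriptive only.
* No partial correlations or regression of flux on expression; R values
  quantify marginal monotone association only.
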