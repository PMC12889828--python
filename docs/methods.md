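# Methods

This note documents the models implemented in `methylotype`, the
choices made where the design was genuinely open, what the synthetic
cohort does and does not emulate, and the numerical conventions.  It
states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Signal aggregation

Per-CpG 6-base calls (depth, 5mC count, 5hmC count per site) are
filtered to sites with depth ≥ 3 and pooled per region as a
pooled-count fraction, Σ modified counts / Σ depth.  Pooling counts
rather than averaging per-site fractions weights deep sites more,
matching how the counts were compiled; the two conventions agree as
depth becomes uniform.  A region is reported missing when fewer than 10
qualifying CpG sites fall inside it.  The site-depth and site-count
thresholds are distinct filters and both are exposed as parameters.

Gene-body 5hmC uses the full `[start, end)` gene span; promoter 5mC
uses the strand-aware window from 1 kb upstream to 5 kb downstream of
the TSS, clipped at the chromosome start.  On the minus strand the
window is the exact mirror image of the plus-strand window across the
TSS.  Note that the promoter window inherently overlaps the first 5 kb
of the gene body; aggregation is purely positional, so CpG sites in the
overlap contribute to both regions.

RNA counts for the buffy-coat validation are normalized to CPM after
removing erythroid/platelet marker transcripts (anucleated cells
contribute RNA but no DNA), log10-transformed with a +1 pseudocount
(the transform needs a zero-handling convention; +1 keeps zero counts
at zero), and converted to within-sample Z-scores.  The validation
statistic is the Pearson correlation of per-bin medians over 50
quantile bins of the epigenetic score; when the gene count is not
divisible by 50, the first `n mod 50` bins receive one extra gene.

## Tumor/normal deconvolution

Bulk plasma fractions are modeled as a two-component mixture of a
tumor and a normal (hematopoietic) methylome.  For gene g in sample s
with ctDNA purity p_s:

* 5hmC: `m_T = (m_bulk − (1 − p)·m_N) / p`
* 5mC:  `m_T = (m_bulk·(CN_T + CN_N) − m_N·CN_N) / CN_T` with
  `CN_T = p·cn_tumor`, `CN_N = (1 − p)·cn_normal` (2 on autosomes, 1 on
  X/Y for the all-male setting; configurable).

The background `m_N` is the gene-wise mean over buffy-coat controls of
the sample's timepoint class (baseline vs treated); a class with no
controls falls back, flagged, to the mean over all controls.  Controls
are identified by their source flag, never by purity.

Conventions where the equations leave room:

* **Purity gate.**  Samples with purity < 0.1 are ctDNA-negative and
  are refused: the inversion amplifies noise as 1/p, and at p < 0.1 the
  tumor signal is not reliably separable from background.
* **Clipping.**  Solutions outside [0, 1] are clipped and flagged;
  flags are returned alongside the values so clipped cells remain
  auditable.  All order/monotonicity properties hold before clipping.
* **Homozygous deletion.**  `cn_tumor = 0` yields a missing value, not
  zero — with no tumor template there is no tumor methylation state to
  estimate.
* **Gene-level copy number** is taken from the segment with the
  largest base-pair overlap with the gene body (ties to the
  lower-coordinate segment).  Largest overlap is robust to breakpoints
  inside genes; the TSS-containing segment is a reasonable alternative
  the data model also supports via a trivial re-assignment.

With `cn_tumor = 2` on an autosome the 5mC equation reduces
algebraically to the 5hmC equation; this identity is enforced to
1e−12 in the tests.

## Expression inference

Tumor promoter 5mC is re-oriented as the depleted fraction
`d_T = 1 − m_T`.  Per gene, the baseline plasma cohort provides anchors
(mean and sd, n−1 denominator) for `d_T` and for tumor gene-body 5hmC;
genes with fewer than two baseline observations or zero baseline
variance are dropped with a report.  The per-mark Z-scores and their
equally weighted composite are computed for every plasma sample against
those same baseline anchors, so baseline columns have exactly zero mean
and unit sd per gene and later timepoints read as change in baseline
standard deviations.  A missing value in either mark makes the
composite missing — no single-mark fallback, so the composite always
means the same thing.  Anchors are cohort-wide; per-subset re-anchoring
is not implemented.

## Outcome association

* **Cox screen**: one proportional-hazards fit per gene (single
  covariate, the composite baseline Z), natural-log coefficients
  reported on the log2 scale.  P-values are left unadjusted by design:
  the screen selects a P < 0.05 gene list for downstream pathway
  projection, not single-gene discoveries.  Genes with inestimable
  coefficients are reported missing with the failure reason.
* **Preranked GSEA** runs on genes ranked by the Spearman correlation
  of composite Z with PFS (average ranks for ties; constant genes get
  statistic 0).  The weighted running-sum enrichment with a seeded
  gene-permutation null is delegated to gseapy; nominal p-values are
  floored at 1/permutations and BH-adjusted across sets.
* **Fisher exact** p-values use the probability-mass two-sided rule
  (sum over tables with point probability ≤ observed), the convention
  that reproduces the printed worked examples to two significant
  figures.
* **Diversity** is the Shannon-Weiner index with natural logarithm
  (the base is a convention; natural log is the package default and the
  closed forms in the tests are stated in nats).  Subclone diversity
  normalizes CCFs to proportions first.

## Longitudinal dynamics

The exposure model is a gene-wise linear mixed model
`z ~ Exposed + (1 | Case)`, with "Exposed" pooling restaging and
progression samples (a flag restricts to progression only).  Fits use
REML via statsmodels.  Satterthwaite degrees of freedom are not
available in that machinery, so Wald t-tests use the between-within
approximation `df = n_obs − n_cases − 1` throughout — for the balanced
paired designs this package targets, the two approximations are close,
and on perfectly paired data the fixed effect equals the mean paired
difference (verified to 1e−8 in the tests).

ΔgeneZ is the per-gene difference of baseline-anchored composite
scores, progression minus baseline, for cases with exactly one scored
sample at each of the two timepoints; genes missing in either sample
are omitted.  ΔRMS is the root of the mean squared ΔgeneZ over retained
genes (the figure-legend phrase "gene-wise mean root square" is read as
this same statistic).

Cumulative CCF shift sums |ΔCCF| over subclones matched by clone id;
clones absent at one timepoint count their full CCF, which makes the
statistic symmetric in the two timepoints.  The two resistance axes
are strict thresholds: clonal remodeling iff shift > 0.1, intrinsic
(rapid) resistance iff rPFS < 2 months; a case may carry both labels.

The group test on ΔgeneZ matrices is an ordinary two-group linear model
with limma-style empirical-Bayes variance moderation: residual
variances are shrunk toward a scaled-F prior fitted by moments on
log-variances (trigamma inversion by Newton iteration), giving
moderated t statistics with `d0 + d_resid` degrees of freedom.  As the
observed variance dispersion grows the fitted prior weight d0 → 0 and
the moderated t converges to the ordinary t (checked numerically).  The
top 500 genes per direction are selected by moderated t, truncating
gracefully on small panels.

## Trajectory integration

Upstream-regulator sets (filtered to |activation Z| > 1.5 and overlap
p < 0.05 when attributes are present) are projected onto the
baseline-anchored composite matrix as the mean over target genes
present, requiring ≥ 5 present targets.  The regulator-score block and
a per-sample genomic feature block (SV counts after the strict
TAF > 0.1 filter, percent genome altered, whole-genome duplication,
cumulative CCF shift to date) enter a multiblock sparse PLS with the
ordinal timepoint (0/1/2) as response and 2 components.

The extraction is an iterative covariance-maximizing scheme (horst
scheme): per component, each block's weight vector is iterated to a
fixed point maximizing the sum of covariances of its score with the
response and with every other block's score.  The design is fully
connected, with block-block edges down-weighted to 0.1 relative to
response edges — the response-focused design weighting recommended for
DIABLO-style integrations, which keeps the components response-driven
while still letting shared cross-block structure break ties.  Features
are centered and unit-scaled per block; missing cells are mean-imputed
and counted; consensus sample coordinates are the unweighted mean of
block scores; blocks deflate on their own scores and the response on
the consensus score.  Sparsity (keep-top-k per block) is available and
off by default, since no per-block selection counts are prescribed.
The algorithm is deterministic given the inputs; the seed argument
exists for API symmetry with stochastic variants.

Arm geometry: the baseline centroid is the mean of baseline sample
coordinates; each arm's direction is the unit vector from that centroid
to the centroid of progression samples of the arm's cases (cases with
both labels contribute to both arms); sample arm scores are projections
of centered coordinates onto arm directions, and case arm deltas are
progression minus baseline scores.  Scores are invariant to global
translation and equivariant under rotation.

## The synthetic cohort

The generator emulates the data shapes of a three-timepoint mCRPC-like
plasma study.  Defaults are the study conditions: 20 cases with
baseline/restaging/progression plasma samples, purity uniform on
[0.10, 0.85], nine buffy-coat controls (5 baseline-class, 4
treated-class), four gene programs of 40 genes in a 400-gene panel, a
+0.8σ exposure shift on the exposure program at treated timepoints, and
two disjoint planted resistance arms (8 clonal-remodeling cases with
cumulative CCF shift drawn above 0.1, 8 rapid cases with rPFS drawn
below 2 months).

**Latent model and link.**  Gene-level latent expression is a
program-activity factor model (case-level activity, loading 0.8) plus
gene noise, standardized per gene over baseline samples, clipped at
±3, and shifted by the planted effects.  Tumor fractions are affine in
the latent Z: gene-body 5hmC `= α_g + β_g·Z` and depleted promoter 5mC
likewise, with α ∈ [0.45, 0.55] and β ∈ [0.05, 0.09] so fractions stay
inside (0, 1) under the largest planted shifts.  The affine link is
deliberate: it makes the noiseless pipeline an exact inverse (forward
mixing → deconvolution → baseline standardization returns the stored
truth to ~1e−10), so correctness is testable to numerical precision.  A
saturating (logistic) link would be more realistic at extreme
expression but would forfeit exactness; the affine link is its
first-order form over the operating range.

**Noise.**  The matrix-level emitter adds Gaussian noise (sd 0.003) to
bulk and buffy fractions, the scale of pooled binomial error over
multi-kb regions at ~20–30× coverage.  The file-level emitter instead
draws binomial per-CpG counts (40–120 body sites, 12–40 promoter sites,
depths 2–60, so the depth-3 and 10-site filters are exercised); in
noiseless mode counts are laid out deterministically and the recorded
truth is the realized (count-quantized) value, inverted by the
generator's own algebra.  Because the promoter window overlaps the gene
body, realized region fractions pool all emitted sites inside each
region with the same positional rule the aggregator uses.

**Arm asymmetry.**  The two planted arms are displaced along different
gene programs and are additionally distinguishable in time and in the
genomic block: intrinsic resistance builds gradually (half shift at
restaging), clonal remodeling appears at progression together with
extra structural variants and a faster-rising percent genome altered.
This asymmetry is what makes two response-driven latent components able
to separate the arms; with a fully symmetric design the arm contrast is
orthogonal to the response and unidentifiable in two components.  Even
so, the 2-D geometry of an individual 20-case cohort occasionally
degenerates (the two arm directions become nearly colinear), which is
why the acceptance script reports the median arm recovery over
replicate cohorts.

**Everything else.**  Survival is exponential proportional hazards on
the survival-program activity (rapid cases progress before 2 months by
construction; 20% uniform censoring).  Clone CCFs are Dirichlet at
baseline with a planted transfer between clones.  Clonotype repertoires
are geometric-abundance draws whose evenness increases with rPFS.  RNA
counts are negative binomial with means monotone in the same blood
latent factor that shapes the buffy-coat background methylome, so the
buffy-coat RNA validation is closed-loop.  One `numpy` generator seeded
from the config drives all draws in a fixed order; emission is
byte-reproducible.

**What passing does not show.**  The generator draws genes
independently given programs, uses a single well-behaved background per
class, knows the true purity exactly, and has no mappability, GC,
fragment-size or batch structure.  Passing the suite demonstrates the
estimators are correct and calibrated under the stated model — not that
real cfDNA data satisfies that model.  The buffy noise is small enough
that single-mark and composite RNA correlations are all high in the
validation; on real data the composite's advantage over single marks is
larger because per-mark noise is larger.

## Problem sizes

The default test and acceptance runs use 400-gene panels, 20-case
cohorts, 100 replicate cohorts for the recovery rates, 2000 null genes
for Cox calibration and 500 for mixed-model calibration — sizes chosen
so the full suite and the acceptance script each complete in a few
minutes on one CPU while keeping Monte-Carlo error well inside the
asserted bands.

## Known limitations

* Purity is consumed from the sample sheet, never estimated.
* Two-component mixture only; no immune-subtype decomposition.
* Satterthwaite df are approximated by the between-within rule (see
  above).
* The multiblock embedding's component count is fixed at 2; with three
  or more strong temporal programs plus nuisance case-level variance,
  arm directions can collapse in unlucky cohorts.
* Cohort-wide baseline anchors only.
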