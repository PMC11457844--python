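# Methods

## Percentile-rank harmonization

Each sample's expression vector is replaced by its ranks (ascending, so
higher expression → higher rank) divided by the number of measured genes,
yielding values in (0, 1] that are invariant to any per-sample monotone
rescaling. Ties are broken uniformly at random; because that makes the
transform stochastic, the tie-breaking seed is a required argument and is
recorded on the output (`PercentileMatrix.rank_seed`). Genes missing for a
sample (possible after a union merge) stay missing and are excluded from
that sample's rank denominator — they are never imputed as zero.

RNA-seq studies are merged on the **intersection** of gene sets (all
studies measure the same transcriptome); microarray studies, whose panels
differ, are merged on the **union**, with absent genes missing. For
microarrays a second, missingness-robust score is provided: the fraction
of measured housekeeping genes each gene exceeds in its sample
(`hk_fraction_score`). Probe-level microarray data are collapsed to genes
by keeping the probe with the highest mean across samples; equal means are
broken by the lexicographically smallest probe identifier so the collapse
is deterministic.

## Housekeeping reference thresholds

Housekeeping genes are ubiquitously expressed reference genes; a compact
default list of 70 canonical symbols (actin/tubulin, glycolytic enzymes,
ribosomal proteins, translation factors) ships with the package and can be
replaced by any one-symbol-per-line file. Within each study, all
housekeeping percentile values — pooled across genes and samples into one
distribution — give that study's 1st, 50th and 90th percentiles; the
medians of these across studies are the pooled low/medium/high thresholds.
Thresholds are computed on percentile-transformed values (they are
plotted on the percentile scale downstream), and quantiles use linear
interpolation between order statistics throughout the package. The
high-expression call is strict: a score must *exceed* the p90 threshold,
reading "greater than 90% of housekeeping genes" literally.

Pooling across genes and samples (rather than per-gene first) treats the
study's housekeeping expression as a single reference distribution; with
tens of housekeeping genes at high, low-variance expression the two
readings differ negligibly, and the single-pool reading matches the
threshold lines drawn at the 1st/50th/90th percentiles in landscape plots.

## RNA → protein concordance

Accuracy for a target is the fraction of samples where the RNA and protein
high indicators agree — both agreement cells (high/high and low/low) count,
so the inaccuracy rate is 1 − accuracy. Each platform is thresholded
against its own housekeeping p90, using the same housekeeping list on both
by default. Targets with fewer than 10 usable samples are reported with
missing accuracy. Sensitivity and specificity (protein-high as condition)
are supplementary columns, not the headline metric; no continuous
RNA–protein correlation is modeled.

## Primary vs. metastatic screen

Effect size is the rank-biserial correlation r = 2·U/(n₁n₂) − 1, with U
counting (primary > metastatic) pairs and ties worth ½ — the
Wilcoxon-consistent definition, equal to the difference between favorable
and unfavorable pair proportions. Positive r means primary-enriched.
The test is the two-sided Wilcoxon rank-sum: exact null when the smaller
group has ≤ 25 samples and the data are tie-free, otherwise the normal
approximation with continuity correction (recorded in run provenance).
FDR is Benjamini–Hochberg over all emitted (target × cancer type)
comparisons as one family — the simplest, most conservative family
definition. Comparisons need ≥ 10 samples (configurable) in each group.

## Cell-line matching

Criterion (i): the line's target percentile must reach the pct-quantile
(default 0.95) of the target's percentile distribution across the tumor
samples of the queried (cancer type, primary/metastatic) group. The
reference distribution is deliberately the *within-group* tumor
distribution: the alternative (a pan-cancer distribution) is obtainable by
passing a pooled annotation. Criterion (ii): the line's median Spearman
correlation — computed over all shared genes against tumors with purity
≥ 0.6 — must reach the pct-quantile across candidate lines; with fewer
than 5 candidate lines the quantile is too unstable and the criterion is
reported as undefined. Purity is consumed from the annotation (estimated
upstream, e.g. by ESTIMATE); no purity inference is performed here.
Raising pct can only shrink the passing set.

## Single-cell detection fractions

Counts are binarized — any positive value is "detected" — because dropout
makes quantitative per-cell values unreliable; the binarization is
idempotent and invariant to rescaling of non-zero counts. Tumor
heterogeneity is the fraction of malignant cells per sample detecting each
target (malignancy taken from the input annotation, never inferred);
samples with fewer than 20 malignant cells (configurable) are flagged
low-confidence rather than dropped. Normal-tissue fractions are reported
per cell type, per replicate sample and pooled; the pooled fraction equals
the cell-count-weighted mean of replicate fractions exactly.

## Two-target combination screen

For each ordered-free pair of targets and each (cancer type, normal
tissue) comparison with ≥ 10 samples per class, a logistic regression of
class (cancer = 1, primary + metastatic samples of the type; normal = 0)
on the two percentile values. A comparison passes when: F1 of the cancer
class at the 0.5-probability rule exceeds 0.95; both gene coefficients are
strictly positive (the model-based reading of "higher in cancer" — a
median-based alternative is a flag away); and both per-gene Wald p values
are below 0.05 after Benjamini–Hochberg correction across *all* per-gene
tests in the screen. A pair is highlighted when strictly more than 90% of
its comparisons pass. No class rebalancing is applied — F1 is
prevalence-sensitive by design.

**Separation.** Perfectly separable comparisons make maximum-likelihood
estimates diverge. Divergent fits (non-convergence, non-finite standard
errors, or |β| > 200 — percentile-scale predictors make legitimate
coefficients of a few tens) are refitted with a lightly ridge-penalized
IRLS (λ = 1e−4); F1 comes from its 0.5 rule, Wald statistics from the
penalized information matrix, and `separation_flag` is set (also whenever
the fitted rule classifies the training data perfectly). A caveat worth
stating plainly: under complete separation the data cannot attribute the
split to either gene individually, so flagged fits essentially never
satisfy the dual-Wald criterion — separation is a property to report, not
a pass.

## Synthetic cohorts

The generator emulates the statistical structure the analysis assumes,
not the biology of any real compendium:

- **Bulk.** Per-gene log-normal background (background genes
  log-mean ~ N(1, 1), targets ~ N(0.5, 0.5)); housekeeping genes at high
  expression with log-means spread linearly over [3, 5] so the three
  thresholds are well separated; per-sample log-noise SD 0.7. Each study
  multiplies all its samples by a scale factor — raw values incomparable,
  within-sample ranks untouched. Each cancer type and normal tissue gets a
  background-gene signature (log-SD 0.8, targets and housekeeping genes
  excluded so planted effects stay clean); tumors carry their type's
  signature attenuated by purity (~ U(0.5, 1)), cell lines carry it fully —
  this is what makes high-purity tumors correlate with same-type lines.
  Targets are elevated in their assigned types; metastatic samples add the
  signed `met_shift` (positive = metastatic-enriched, hence negative
  rank-biserial r). Each type's designated best line is a low-noise
  (SD 0.15 vs 0.9) draw from the type centroid with +3 log-units on the
  type's targets.
- **Paired omics.** Only the high/low indicator matters downstream, so the
  protein matrix is built by indicator coupling: per target and sample the
  protein high call equals the RNA call with the planted probability,
  flipped otherwise. Housekeeping proteins occupy a fixed high band,
  "high" targets are placed above the band, "low" targets far below, and
  rank-neutral filler genes keep the number of genes above the band
  constant in every sample — so the percentile threshold sits at the same
  value everywhere and the planted agreement survives thresholding
  *exactly* (a concordance of 1.0 yields accuracy exactly 1.0).
- **Single cell.** A cell of type c detects target t with the planted
  Bernoulli probability; detected cells draw 1 + Poisson(1.3) counts,
  undetected cells are exactly zero. Background genes get gene-specific
  detection ~ U(0.02, 0.3), housekeeping genes 0.8.
- **Separable pairs.** Both genes of a planted pair are elevated
  (+1.3 log-units) in the named cancer type and suppressed (−0.65) in the
  named normal tissue. These margins are sized so the two-gene clouds
  separate strongly (F1 ≈ 0.97) while still overlapping enough that the
  logistic ML fit is identified and each gene's Wald test carries
  information — a perfectly separated design would make the dual-Wald
  criterion unattainable (see above).

All randomness flows from one root seed through named SHA-256-keyed
substreams, so identical (spec, seed) reproduce byte-identical datasets
and changing one dataset's parameters never perturbs another's draws.

What passing tests on these cohorts show — and what they do not: the
generator reproduces rank structure, study scale, planted effect
directions and rates, but not library-size artifacts, batch effects
beyond a scalar, gene–gene correlation networks, isoform complexity, or
realistic dropout–depth coupling. Recovery here demonstrates the
*machinery* is correct, not that any particular real-data estimate is.

## Problem sizes and defaults

The reference cohort (`default_spec`) is 2,000 genes × 800 samples
(two studies at 5× relative scale, five tumor types, three normal
tissues, 20 cell lines, ~2,850 single cells), chosen to exercise every
code path while keeping a full pipeline run and the test suite fast on a
single CPU. Key defaults: `min_group` 10 (group-size floor), `purity_min`
0.6, `pct` 0.95, `alpha` 0.05, `f1_min` 0.95, highlight proportion 0.90,
`min_cells` 20 — the first six mirror the analysis definitions above; the
cell floor guards against unstable small-denominator fractions.

## Known limitations

- The hk-fraction score and the percentile/p90 call agree in rank logic
  but are not numerically identical; microarray and RNA-seq calls should
  not be mixed within one comparison.
- Wald p-values from the ridge fallback are approximate and intentionally
  conservative; likelihood-ratio or exact tests are not implemented.
- The union merge assumes one shared gene namespace; identifier mapping
  across annotation systems is out of scope and must happen upstream.
- Landscape "levels" classify group medians only; outlier-driven
  single-sample positivity is visible in the five-number summaries but not
  flagged separately.
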