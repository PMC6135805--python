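# Methods

This note records the models, conventions and numerical choices behind
`secrenet`, and what the synthetic study does and does not establish
about real data.

## Scope and shape

The package chains six stages — secretome set algebra, PPI expansion,
differential expression, DEG-overlap ranking, pre-ranked enrichment, and
Elispot survival statistics — plus a generator that produces every input
with planted ground truth. The stages that are genuinely fitted models
are exposed statsmodels-style (`DifferentialExpression.fit()` →
`DEGResults`, `PrerankedGSEA.fit()` → `GseaResults`,
`MediaComparison.fit()` → `MediaComparisonResults`, each with a
`summary()`); set algebra, network expansion and simulation are plain
functions, orchestrated by `run_pipeline` and the `secrenet` CLI.

## Target-decoy PSM filtering

Peptides shorter than 7 residues are removed first. Peptide q-values are
the running minimum over score thresholds of (#decoys ≥ s)/(#targets ≥
s); at tied scores decoys sort ahead of targets (conservative). Target
PSMs with q ≤ 0.01 are aggregated to proteins by best peptide score and
the same q-value procedure is repeated at the protein level with the
same threshold. The more conservative (#decoys+1)/#targets estimator is
available as `plus_one=True`. Protein inference is best-peptide only —
no parsimony grouping and no rescoring; the package consumes pre-scored
PSM tables.

The estimator assumes an incorrect identification is equally likely to
hit the target or the decoy database (concatenated search with equal
database sizes). The synthetic PSM generator therefore defaults to equal
numbers of null targets and decoys; with that premise satisfied, the
q-value at the acceptance boundary tracks the realized false-discovery
proportion to well under ±0.02 with 1000 decoys.

## Fraction set algebra

Each secretome fraction is one set of upper-case gene symbols (replicates
pre-merged by union). The funnel is: union of the bioactive fractions;
subtraction of the serum background; subtraction of the inactive control
proteome; intersection of the per-fraction cleaned sets. Identifier
normalization upper-cases, applies an optional raw→symbol mapping, and
strips numeric isoform suffixes after a configurable delimiter
(`YWHAZ-2` → `YWHAZ`; `HLA-DRB1` is untouched because the suffix is not
numeric). Everything operates at gene-symbol level, not protein-group
level.

## PPI expansion

Networks are undirected simple graphs with per-edge confidence in
[0, 1]; duplicate edges keep the maximum confidence, self-loops are
dropped, and filtering at a confidence threshold is composable
(filtering at c then c′ > c equals filtering once at c′). Expansion is
first neighbors only — no diffusion, no multi-hop. Seeds absent from the
network are reported, never silently dropped. By default partner sets may
include other seeds (`include_seed_partners=False` removes them). No
confidence threshold is applied by default; it is a reproducibility knob.

## Differential expression

* **TMM.** Reference sample: 75th CPM percentile closest to the mean
  75th percentile. Per sample, log2 ratios (M) and average abundances (A)
  over genes positive in both; 30% two-sided M-trim and 5% A-trim by
  rank; weights are the asymptotic inverse variances
  (N−y)/(Ny) + (N_r−y_r)/(N_r y_r); factors scaled to geometric mean 1.
  This matches edgeR's `calcNormFactors` to 1e-6 on matrices with zeros
  (cross-checked in the test suite via Rscript when available).
* **log2 CPM.** log2((count + 0.5) / (effective library in millions)),
  effective library = raw total × TMM factor.
* **Abundance filter.** Keep genes with mean log2 CPM ≥ 3, inclusive at
  the boundary; the (mean, CV) diagnostic table for the threshold plot is
  returned alongside.
* **Batch adjustment.** Per gene, an additive two-factor least-squares
  fit (population + batch); the estimated batch effects, centered so the
  grand mean is preserved, are subtracted. Exactly aliased designs raise.
  This is a fixed-effect stand-in with the same intent as supervised
  normalization: remove batch while protecting the biological variable.
* **Testing.** One-way fixed-effects ANOVA across populations with exact
  F p-values. When the data were batch-adjusted, the residual degrees of
  freedom are reduced by (batches − 1) — the adjusted matrix lives in a
  lower-dimensional space, and ignoring that makes the test
  anti-conservative (empirical FDR 0.068 instead of 0.043 at nominal
  0.05 in the calibration study). The ranking statistic is the
  pooled-variance two-sample t between the two focal populations
  (Welch by flag); with two groups F = t². BH q-values; DEG ⇔ q ≤ 0.05.
* **PCVA.** Genes are z-scored across samples, PCA is taken over
  samples, and each of the first three PCs' score variance is attributed
  to each annotation factor by the R² of a one-way fit of the scores on
  that factor, averaged with variance-explained weights. Factors with a
  single level, or with one level per sample (no replication — e.g. a
  subject id in a design without repeated measures), contribute 0 with a
  warning; when one-way R² values of a PC sum above 1 they are rescaled
  so factor shares plus residual total 100%.

## Pre-ranked GSEA

Genes sort by score descending, ties broken by symbol. Hits add
|score|^p normalized over the set (p = 1 by default; p = 0 gives the
unweighted KS form), misses subtract 1/(N−|S|). ES is the signed
extremum; when the positive and negative excursions tie exactly — a
structurally common event, e.g. when every miss lies outside the hit run
— the positive side wins unless the negative deviation is larger by more
than a 1e-9 relative margin. This tie rule is part of the statistic's
definition here.

Null distributions come from gene-label permutation (random same-size
subsets of the ranked universe; with pre-ranked input, phenotype
permutation is impossible). NES divides ES by the mean magnitude of
same-sign null ES; nominal p is the smoothed same-sign tail fraction
(1+k)/(1+n). FDR q follows the pooled-NES procedure — the tail fraction
of all normalized null NES beyond the observed NES over the matching
tail fraction of observed NES — with BH-style step-up monotonicity
within each sign. Both ES signs are tested and the direction (high/low)
is reported. Fixed seed ⇒ bit-identical output.

Set summarization: least-square group means per gene, z-scored across
groups with the sample SD (ddof = 1, so two groups map to ±1/√2);
per-set PC1 via SVD of the row-centered submatrix, sign oriented to
correlate positively with the set's mean profile; Ward clustering
(Euclidean, scipy linkage) of the set×group PC1 profiles, serializable
to Newick.

## Elispot survival statistics

Wells are averaged per day; the reference is the largest of the day-1,
-2, -3 means (ties to the earliest day); percents are 100 × day mean /
reference, making the normalization scale-invariant. A zero reference
(no surviving cells in the window) raises. Condition comparisons fit
OLS of percent ~ day + media-indicator on the pooled per-day values
(day continuous; `log_scale=True` applies log1p; `normalize=False`
accepts pre-normalized series). The ANOVA view fits day and condition
as fixed effects (no interaction) or one-way on condition alone, with
BH adjustment across pairwise contrasts on request.

**Known limitation.** Normalizing each series to its own noisy day-1–3
maximum injects a series-level random effect that the OLS standard error
cannot see. When reference-day counts carry noise comparable to the
pooled per-day information, the media test is anti-conservative; when
the mean curve is far from linear on the modeling scale, it is
conservative. The test is approximately calibrated when the modeling
scale is right (log of an exponential decay is linear in day) and the
late-day counting noise dominates the reference noise. The calibration
study uses such a regime — equal decay 0.45/day, days {1, 2, 7, 10},
3 wells of up to 300 spots, log scale — and observes uniform null
p-values (KS p between 0.10 and 0.74 across disjoint 200-seed blocks,
type-I error ≈ 0.02 at nominal 0.05). Densely sampled early time
courses analyzed on the raw percent scale should not be trusted for
inference without replicate series.

## The synthetic study

Defaults define one fixed set of study conditions:

| quantity | default | rationale |
| --- | --- | --- |
| network | 500 nodes, 2000 edges, attachment bias 1 | sparse, right-skewed degree distribution with genuine hubs |
| factors | 5 hubs with degree ≥ 15 | survival-factor analogues; hub status is what the ranking exploits |
| genes | 2000 (network nodes + filler tokens) | desk-scale stand-in for a ~17k-gene transcriptome |
| samples | 8 blood ASC vs 4 BM LLPC, 2 batches | the study's unbalanced two-population design at reduced n |
| counts | NB, variance μ + 0.1 μ², baselines log-uniform | bulk RNA-seq overdispersion; ~25–30% of genes fall below the 3-log2 filter |
| DE | neighbors of factors at 0.5, background 0.05, |lfc| = 1.5 | planted signal the integration step must find |
| batch | gene-wise N(0, 1) offset per batch | drives the leading PCs pre-adjustment (~75% PCVA share), removable by regression. A scalar per-batch shift would be a pure library-size effect and vanish under CPM — hence gene-wise |
| libraries | log-uniform 0.5–2 million | exercises TMM |
| fractions | 3 bioactive + 2 inactive + FBS background; dropout 0, contaminants 5% | the clean funnel recovers exactly the planted factors; dropout is exercised separately in tests |
| PSMs | 500 true + 1000 null targets + 1000 decoys, score shift 3 SD | concatenated-search premise (null targets = decoys) |
| gene sets | 30 sets of 20–80 genes, 5 enriched at factor 5, direction-coherent | enriched sets prefer planted DE genes of one fold-change direction, as real dysregulated pathways move together; mixed signs would cancel in a running-sum statistic |
| Elispot | secretome decay 0.08/day vs media 1.2/day, Poisson wells | the qualitative contrast of supportive vs plain media |

All randomness flows from one integer seed through named
`SeedSequence` substreams, so regenerating any single input reproduces
what a full pipeline run with the same master seed produced.

**Recovery evaluation.** With zero dropout the proteomic funnel returns
exactly the planted factors, so ranking only the funnel output would
make top-10 recovery vacuous. The recovery experiments therefore rank a
50-seed candidate list — the 5 planted factors plus 45 sampled
non-factor nodes — emulating a realistic candidate list in which most
entries are not survival factors. All factors reach the top 10 in ≥ 95%
of runs under the default conditions.

**What passing tests do not show.** The generator plants clean additive
effects: no outlier samples, no correlated gene modules outside the
planted sets, no isoform ambiguity, no missingness structure in the
proteomics beyond uniform dropout, and NB counts with a single shared
dispersion. Real data violate all of these; the synthetic results
establish correctness of the implementation and calibration under the
stated model, not performance on any particular real study.

## Problem sizes

The test suite and the acceptance script run the calibration studies at
2000 genes × 12 samples (50 simulations), 200-gene-set permutation
nulls at 200–1000 permutations, and 20 end-to-end recovery studies —
sizes chosen so a full verification pass completes in about half a
minute on one CPU while keeping Monte-Carlo error well inside the
asserted margins.
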