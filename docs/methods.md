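# Methods

This note documents the models behind each pipeline stage, the defaults and
why they were chosen, what the synthetic cohorts do and do not emulate, and
the numerical conventions that make results reproducible.

## Bulk preprocessing

Expression enters as TPM (transcripts per million), is transformed to
log2(TPM + 1), and duplicate gene rows are averaged *after* the transform,
so a twice-measured gene contributes the mean of its log profiles.  "Not
expressed" means TPM exactly 0: TPM has no natural nonzero floor, and a
detection threshold would add a parameter without changing the planted-truth
analyses.  The zero filter is inclusive (a gene with zeros in ≥ 80% of
samples is removed); the variance filter then drops the
floor(0.2 × remaining) lowest-variance genes, with ties at the cutoff broken
by gene id so the output is deterministic.  Filtering runs on the *merged*
matrix after cohort harmonization, because the divergence signature is
defined on the merged sample space and a per-cohort filter could remove a
gene from one cohort only.  Harmonization intersects gene sets (sorted) and
restricts to disease codes present in both cohorts.  Samples absent from a
mutation table are wild-type — variant tables list variants, not reference
calls — and "mutant" means at least one record whose variant classification
is not "Silent".

## Stability selection

The classifier is an L2-regularized linear hinge-loss (maximum-margin) SVM
with C = 1.0 and balanced class weights.  Tumor and cell-line cohorts are
typically an order of magnitude apart in size, and balancing prevents the
margin from being dominated by the larger class; C is left at its
conventional default because the signature is defined by weight *ranks*,
which are insensitive to moderate rescaling of the loss.  Each of the 50
splits is stratified by cohort label (guaranteeing both classes in every
80/20 split) and per-gene standardization is fit on the training portion
only: |w| comparisons across genes are meaningful only on a common scale,
and fitting the scaler on the full matrix would leak the held-out samples.

Per split, the top k = ceil(top_frac × G) genes by |w| are kept (dense
ranking, ties by gene id, no tie expansion — determinism over etiquette).
The default merge across splits is the intersection — the signature a gene
must earn in *every* resample — with union exposed as `merge_rule="union"`
for a more permissive screen.  Split seeds are drawn sequentially from a
generator seeded by the master seed, so an n-split run's first m seeds equal
an m-split run's seeds: intersections are monotone along nested seed
sequences, which makes the resampling depth an honest knob.

The two-pass protocol removes immune programs between passes.  The
first-pass stable set is tested for pathway over-representation; among the
top 100 pathways by p-value, those significant at q < 0.05 and labeled
"immune" contribute all of their member genes to a blocklist, and the
selection reruns on the remaining genes.  Immune signal in a
tumor-versus-culture comparison largely reflects the absent microenvironment
rather than drift of the malignant cells themselves, which is why it is
removed rather than reported.

## Over-representation analysis

Enrichment is the hypergeometric upper tail P(X ≥ k) for an overlap of k
between a query of n genes and a pathway of K members in a universe of N.
The tail is accumulated from log-space PMF terms (cached log-factorials plus
a max-shifted log-sum-exp), keeping full relative precision for p-values far
below the double-precision underflow of a naive product; the test suite
pins the implementation to an exact rational enumeration oracle over the
full parameter grid with N ≤ 60 at relative error 1e-12.  The universe
defaults to the genes that survived preprocessing — the set the query was
actually drawn from — and is configurable.  BH-FDR is applied across all
tested pathways with significance at q < 0.05.  A ranked
(Kolmogorov–Smirnov-style) enrichment mode is deliberately out of scope:
every downstream consumer here needs overlap p-values, not running-sum
scores.

## ceRNA bridging

miRNA identifiers are lowercased, stripped of the three-letter species
prefix, and resolved through an alias map; arm suffixes (-5p/-3p) are
preserved because the two arms are distinct mature miRNAs.  A miRNA bridges
a lncRNA set to a pathway gene set when it has at least one interaction into
each; the operation takes the pathway gene set as an explicit parameter so
the caller decides whether "pathway genes" means the selected divergent
genes or the full pathway membership.  Interaction tables are consumed as
TSV exports, not live database queries — reproducibility requires frozen
inputs.  The bridged network is exported as a SIF edge file plus a node
attribute table (id, type, log fold change), written in sorted order so
export → import → export is byte-identical.

## miRNA batch correction and fold changes

Cross-platform miRNA comparison merges the harmonized feature intersection,
applies log2(x + 1), and corrects batch structure with the parametric
empirical-Bayes location-scale model: per feature the data are standardized
against the batch-design fit; per-batch additive (γ) and multiplicative (δ)
effects are estimated and shrunk toward batch-level priors (normal on γ,
inverse-gamma on δ, hyperparameters by method of moments, iterative joint
solution to relative tolerance 1e-4); the adjusted data are rescaled to the
pooled variance and grand mean.  Correction operates on the log scale,
where the additive-plus-multiplicative model is a reasonable description of
sequencing and probe data; a raw-scale path would mix the model's location
term with library-size effects.

By default a final **exact alignment** step pins each feature's per-batch
mean to its grand mean and per-batch variance to the pooled within-batch
variance.  Shrinkage alone leaves O(1/√n) residual batch means (the shrunk
estimate deliberately under-corrects), which both leaves detectable batch
signal in small studies and makes the operation non-idempotent — a second
run would chase the residuals.  With alignment the correction preserves
every feature's grand mean to machine precision and is an exact fixed
point: correcting corrected data returns it unchanged.  The EB estimates
remain the reported model (γ̂, δ̂, γ*, δ*, hyperpriors per batch), and
`exact_align=False` gives the vanilla EB behavior, which the test suite
cross-checks against an independent implementation (agreement ~5e-3; the
residual gap is a hyperprior convention — that implementation estimates the
γ-prior variance with the population formula where this package uses the
sample variance, as in the canonical description of the model).

Log fold change is mean(cell line) − mean(tumor) per feature on the log
scale; positive means higher expression in culture.

## Concordance statistics

Group comparisons use the two-sided Mann–Whitney U test: the exact null
distribution when n₁·n₂ ≤ 400 and the pooled data are tie-free (enumeration
is cheap there), otherwise the normal approximation with tie correction.
Pathway concordance computes, per disease, the Spearman correlation of the
pathway-gene expression vectors for *every* (tumor sample, cell-line
sample) pair — ranks are computed once per sample and all pairs evaluated
as a matrix product — and diseases are sorted by mean ρ descending with
ties broken by disease code.  Fewer than three shared pathway genes is an
error: rank correlation on two points is ±1 by construction.  The
protein-level comparison treats the quantification matrix as generic
features; which antibodies represent which pathway is a configuration
table, not logic.  Mutation burden is the fraction of a disease's samples
carrying a non-silent variant in the queried gene, correlated against mean
concordance with Spearman's ρ.

## Single-cell stage

QC removes a cell when its detected-gene count exceeds the ceiling OR its
mitochondrial metric does.  The default mitochondrial metric is the count
of distinct mitochondrial genes detected (`mito_metric="n_genes"`), an
unusual but literal reading of a gene-count threshold; the conventional
percent-of-counts metric is available as `percent_counts`.  Counts are
normalized to the median library size and log1p-transformed; cells are
embedded with the top 40 principal components (reduced with a warning when
fewer cells are available), connected in a 15-nearest-neighbor graph, and
partitioned with Leiden community detection (delegated to the established
graph library, seed exposed).  Each cluster is labeled with the marker
signature of highest mean z-scaled expression, ties broken by signature
name.

The default Leiden resolution is 1.0, the standard setting for real tissue
with many cell types.  The toy-scale validation simulations (one or two
homogeneous populations of a few hundred cells) are clustered at resolution
0.1: at that scale modularity at resolution 1.0 over-partitions isotropic
sampling noise into many small communities, so checks asking "is this one
population or two?" must run at a coarse-structure resolution.  This is a
property of small homogeneous simulations, not of the clustering on
realistically heterogeneous data.

Tumor-up marker genes come from a one-sided (group A greater) Wilcoxon
rank-sum scan on the normalized log counts — exact for groups of ≤ 5 cells,
asymptotic with tie correction otherwise — ranked by p, ties by effect size
then gene name, with BH q-values over all genes.  Per-sample
subtype-signature scores are hypergeometric upper-tail p-values of the
sample's top-100 list against each signature, reported as −log10 p.

## Synthetic cohorts

The generators emit the exact file dialects the pipeline reads, plus a
ground-truth object, and identical (config, seed) pairs reproduce identical
outputs.

**Bulk.** Baseline log2 expression is Normal(μ_g, σ) with μ_g ~ U(2, 8)
and σ = 1; matrices are emitted on the TPM scale (2^x − 1) so preprocessing
is exercised end to end.  Defaults: 2000 coding genes + 20 lncRNAs, 200
tumor and 60 cell-line samples over 6 diseases — an ~3:1 cohort imbalance
and desk-scale sizes that keep a full two-pass selection under ~5 s.  Four
25-gene "cancer driver" pathways and all lncRNAs are shifted down by
Δ = 1.5 log2 units in cell lines (a strong but realistic pathway-level
effect, ~2.8× linear); a 50-gene immune program is expressed in tumors only
(cell-line TPM exactly 0); a 25-gene control pathway and 10 decoy pathways
are non-differential; 50 "silent" genes are zero in ~90% of samples to
exercise the zero filter.  A MAF-like table plants per-disease non-silent
KRAS/TP53 carrier rates of 10–60% plus silent decoy records.

**Sponge system.** 60 miRNAs (40 bridging with edges into both the lncRNA
set and the driver genes, 20 decoys with only one edge kind).  In cell
lines, 90% of bridging miRNAs shift up by Δ and the rest down
(direction-consistency 0.9); decoys carry no cohort effect.  Batch
structure follows the location-scale generative model (additive shift 5,
multiplicative scale 2 on batch B) with both cohorts split across both
batches.  This **crossed design is an intentional idealization**: real
cross-platform studies often confound platform with cohort, in which case
no correction can separate the batch effect from the biology — with the
crossed design the planted cohort effect is identifiable and the
correction's recovery can be scored.  The two emitted matrices use
divergent naming conventions ("hsa-mir-…" versus "MIR…") with an alias map,
and 8 features are absent from the second platform to exercise the
intersection step.

**Single cell.** Negative-binomial counts (dispersion r = 2) over 900 genes
including 20 mitochondrial; per-gene base rate lognormal around 0.2;
program genes elevated 10× in their population.  Two tumor samples mix
malignant populations expressing subtype programs S2/S3 with T-cell and
macrophage infiltrate (infiltrate fraction 0.3); the cell-line sample draws
only an S1-like malignant population; a 50-gene tumor-up program (8×) is
active in every tumor cell.  Ten over-detected outliers (25× rates) and ten
mitochondria-rich outliers (mitochondrial rate 10) are injected; the QC
ceilings for this geometry (600 detected genes, 15 mitochondrial genes)
separate them from normal cells by many binomial standard deviations, so
QC removal is exact with overwhelming probability.

What the generators do **not** emulate: gene–gene correlation structure
(genes are independent given their program), disease-specific expression
differences (disease labels are exchangeable), copy-number or mutational
signatures, platform-specific mean-variance relationships, and dropout
beyond what the negative binomial implies.  Passing recovery tests
therefore demonstrates that the pipeline's inference is correct under its
own model assumptions at realistic effect and sample sizes — not that those
assumptions capture every property of real tumors.

## Numerical conventions

Variance uses the sample convention (ddof = 1) except the pooled residual
variance in batch standardization, which is the maximum-likelihood pooled
estimate over all samples (ddof = 0), matching the standard formulation.
All orderings that feed downstream decisions (rank ties, variance-filter
ties, pathway sorting, cluster-label ties, network export) break ties
lexicographically.  All randomness flows through seeded NumPy generators;
split seeds derive sequentially from the master seed and stay below 2^31.
Degenerate hyperpriors in the batch model (zero between-feature spread)
fall back to the unshrunk estimates rather than dividing by zero.

## Known limitations

The stable-set size depends on the top fraction and the resampling depth,
not on a significance calibration, so it is a screening tool rather than an
error-controlled discovery procedure.  The bridging step inherits whatever
ascertainment bias the interaction tables carry.  The exact-alignment batch
default assumes batch is not confounded with the contrast of interest; with
full confounding it will remove biology, silently.  The single-cell typing
assigns exactly one label per cluster and has no "unknown" category.
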