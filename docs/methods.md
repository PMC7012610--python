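# Methods

This note documents the models and procedures implemented in `habquant`,
the parameter defaults and why they were chosen, what the synthetic
generators do and do not emulate, and the numerical decisions that a
reader auditing results should know about.

## Single-cell preprocessing

QC metrics are computed per cell from raw UMI counts: `nUMI` (column
sum), `nGene` (genes with count > 0), and `percent.mito` (fraction of
UMIs on genes with the case-insensitive symbol prefix `mt-`, the mouse
mitochondrial nomenclature; the prefix is configurable). `percent.mito`
is stored as a fraction in [0, 1], so the conventional "10%" cutoff is
0.1. Cells with zero UMIs get `percent.mito = 0` rather than NaN.

Cell filters are inclusive on both ends (defaults 500 ≤ nUMI ≤ 18000,
200 ≤ nGene ≤ 6000, percent.mito ≤ 0.1). Gene filtering runs **after**
cell filtering, so detection fractions refer to the kept cells; the
total-count bound is strict (total UMI > 5) and the subset-level
detection bound (≥ 0.5% of cells) is applied when re-analyzing a cell
subset. Manual curation of low-quality libraries is not automated;
callers can pass a barcode blacklist instead.

Normalization is `ln(1 + s·c/total)` with scale factor s = 10⁴, which
makes `sum(expm1(x))` exactly 10⁴ per cell — an identity the tests
assert. Technical covariates (nUMI, percent.mito) are removed per gene
by ordinary least squares — the identity-link Gaussian GLM — and the
residuals are centered and scaled to unit variance. Collinear covariate
columns are dropped with a warning; constant genes become all-zero rows.
No z-score clipping is applied by default and no variable-gene selection
precedes PCA; both exist as options but default off to avoid adding
unstated steps.

## Clustering and cluster curation

PCA is a truncated SVD of the scaled matrix with cells as observations
(20 components by default). Component signs are fixed so the gene with
the largest |loading| is positive, making results deterministic.

The SNN graph uses each cell's k = 20 nearest neighbors in PC space,
*including the cell itself*; distance ties break by cell index (stable
sort). Edge weights are the Jaccard overlap of the two neighborhoods,
and weights below 1/15 are pruned — the conventions of the widely used
single-cell toolkit wrappers for this graph.

Modularity clustering maximizes resolution-scaled Newman–Girvan
modularity by Louvain-style local moving plus graph aggregation. The
named smart-local-moving variant differs only in its within-cluster
refinement; the contract that matters — returning a partition that
maximizes modularity at the given resolution — is tested directly
against exhaustive partition enumeration on graphs of ≤ 8 nodes and
against an independent igraph implementation on larger ones. The
optimizer restarts 10 times from seeded random node orders and keeps the
best partition; given a seed the result is bit-reproducible. Labels are
renumbered by decreasing cluster size. Defaults (resolution 1.2, 10
iterations) follow the habenula workflow this package reimplements.

Cluster dendrograms are average-linkage trees over Euclidean distances
between cluster-mean PC vectors (linkage is configurable; average was
chosen as the default because nothing in the source workflow pins it).

**ADG score and correction.** The activity-dependent-gene (ADG) score is
a module score: all genes are ranked by mean expression and cut into 25
equal-frequency bins; for each gene of the set, up to 100 control genes
are drawn from its bin (the whole bin when it is small); the score is
the mean expression of the set minus the mean of the pooled controls,
per cell. The default set is the eight immediate-early genes *Fos,
Fosb, Egr1, Junb, Nr4a1, Dusp18, Jun, Jund*. The ADG-dominated
principal component is identified by a hypergeometric upper-tail test of
the ADG overlap with each component's top 50 genes by |loading| — the
qualitative notion of a component dominated by ADGs needs an explicit,
testable form, and top-50 enrichment at p < 0.05 is the form chosen
here. "Regressing out" the
component is implemented as zeroing its coordinate in every cell's score
vector before rebuilding the SNN graph and reclustering — the simplest
faithful reading; re-scaling genes against the component would be an
alternative and is out of scope.

Doublet clusters are flagged when a cluster's mean module score exceeds
a threshold for two or more mutually exclusive class panels (e.g.
neuronal and glial markers). Poorly separated clusters are merged
bottom-up: each dendrogram node is tested by hurdle DE between its two
children, and the children merge when fewer than `min_markers = 5`
Bonferroni-significant markers distinguish them or when at least
`max_artifact_frac = 0.5` of the significant markers belong to a
provided housekeeping/ADG list. Those two defaults are exposed
configuration, not published values — the source workflow describes the
rule qualitatively. A side with fewer than 3 cells cannot support
marker evidence; its clusters are absorbed into the nearest cluster on
the other side (by PC centroid) instead of collapsing the whole node.
The tree is rebuilt after every merge and the procedure terminates
because the cluster count strictly decreases.

## Hurdle differential expression

Genes are prefiltered per contrast: tested iff detection fraction
max(pct.1, pct.2) ≥ 0.1 and |avg_logFC| ≥ 0.25, where
avg_logFC = ln(mean(expm1 x) + 1) in group 1 minus the same in group 2
(natural log, the convention of the wrapper used for filtering in the
source workflow).

The test itself is a two-part hurdle model: a logistic regression of
detection on group, and a Gaussian regression of expression on group
among detected cells. The per-cell detection rate (CDR — the fraction
of genes a cell expresses) is included in both parts by default, as in
the MAST model family; it can be toggled off. The combined statistic is
the sum of the two deviance differences, referred to a chi-square with
one degree of freedom per estimable part (2 when both fit, 1 otherwise,
p = 1 when neither). This is a deliberately reduced reimplementation of
the hurdle core: no empirical-Bayes variance shrinkage and no bayesglm
priors, so individual p-values will differ from full MAST; type-I error
calibration (0.03–0.07 at α = 0.05 on 1,000 null genes) and planted
marker sensitivity (≥ 0.9 at fold-change 4) are the tested guarantees.
Perfect separation in the logistic part (detection exactly aligned with
group) is detected explicitly and replaced by a Fisher exact test on the
2×2 detection table, converted to an equivalent chi-square deviance and
flagged in the output. Bonferroni correction is applied over the tested
genes only.

## FISH quantification

The measurand is **fluorescence coverage (%)**: the percentage of pixels
inside a cell ROI whose background-subtracted intensity strictly exceeds
the channel threshold. Decisions a user should know:

- One threshold per channel per image, computed from a 256-bin histogram
  of the whole background-subtracted channel spanning [0, max] — not per
  ROI — so all cells of an image are compared under identical
  thresholding.
- Background is the mean intensity outside all ROIs, per channel;
  subtraction clips at zero. The histogram for thresholding is built
  after subtraction (a documented choice; the alternative order is not
  implemented).
- The automatic threshold combines three Rényi-entropy thresholds
  (orders α = 0.5, α → 1 i.e. Shannon/Kapur, α = 2), each found by
  exhaustive search for the bin maximizing the summed foreground and
  background class entropies, then blended with the standard weighting
  rule: sorted candidates t₁ ≤ t₂ ≤ t₃ get weights (1,2,1)/4, (0,1,3)/4
  or (3,1,0)/4 depending on whether adjacent candidates agree within 5
  bins, with cumulative-probability factors. On bimodal histograms with
  a wide empty plateau between classes the entropy criterion is flat
  across the plateau and the first maximizer is taken, which places the
  threshold just above the background mode — users should expect
  detected ROI areas to dilate slightly when detection smoothing is
  heavy (the default smoothing sigma is 1.5 px; the blur-free boundary
  is recovered at ≲ 0.3 px).
- ROI detection: selected channels are summed, Gaussian-smoothed,
  thresholded, hole-filled, split into 4-connected components, and
  filtered by area (default min 30 px). Rabies-tracing mode detects from
  the RbV-N channel only. Externally supplied masks (the stand-in for
  manually adjusted ROIs, which cannot be automated faithfully) are
  adopted verbatim after label compaction.

## Coverage statistics

A cell is "positive" for a channel when its coverage meets an explicit
cutoff, default 5%, configurable per channel, and stamped into every
downstream report — the positivity criterion is the largest inferential
gap in this kind of analysis and is therefore never implicit. Error
bars on proportions are SEM across animals (biological replicates),
never across cells; a single-animal report carries SEM 0 with an
explicit undefined flag. Medial/lateral positions are scalar
projections onto a user-annotated medial→lateral anchor axis, clipped to
[0, 1]; density profiles are per-animal bin fractions (half-open bins,
last bin closed) averaged across animals. An anterior/posterior window
filter (e.g. −1.855 to −1.655 mm from bregma) restricts position
histograms to the central A/P range where subregional organization
holds. Condition comparisons use a two-sided Welch t-test on per-animal
proportions with Holm correction across markers — a declared,
conservative default; the method name is recorded in the output.

## Synthetic data: what it emulates and what it does not

The count generator draws per-gene baselines from a gamma distribution,
library sizes from a lognormal (default median 2,500 UMIs, σ = 0.4,
matching the magnitude of droplet habenula data), mitochondrial load
from a beta distribution (mean 5%), planted cell types as multiplicative
marker fold-changes, the ADG program as *additive* expected counts
(immediate-early-gene induction rides on top of the identity program;
default 8 extra expected counts on each of the 8 ADG genes in 35% of
cells of every type), doublets as sums of two cells' expected profiles
drawn before sampling (the generative story of co-encapsulation), and
counts as Poisson or negative binomial (gamma–Poisson, mean/
inverse-dispersion parameterization; Poisson is the infinite-θ limit).
The ADG program is applied across all types by default because the
artifact it models — activation-split clusters appearing in several
neuron classes — is a dataset-wide axis; restricting it to one type
entangles the activation axis with that type's identity axis and the
one-component correction is then not expected to be clean.

The FISH generator places non-overlapping ellipses (semi-axes 5–10 px,
2 px clearance) and paints puncta disks inside each cell until the
painted fraction reaches the subtype's target coverage, shrinking the
final punctum so the realized value lands near the target; the realized
fraction is the recorded truth. The image adds Poisson background
(rate 2) and a 0.3 px Gaussian PSF blur — a sharp, well-sampled optical
model chosen so the painted boundary, the truth definition, and the
entropy threshold agree to within a pixel. The tracing generator draws
each labeled cell's marker identity from a multinomial; published
rounded percentages that sum slightly above 1 (e.g. 101%) are
renormalized.

None of this reproduces real tissue: no autofluorescence texture,
illumination fields, z-structure, segmentation-defeating cell clumps,
ambient RNA, or batch effects. Passing recovery tests therefore shows
the pipeline is *self-consistent and correctly implemented* — that it
recovers planted structure under its own assumptions — not that it is
robust to every artifact of real data. Distributional parameters were
chosen once for realism at the scale of the emulated study and are not
tuned per test.

## Problem sizes

Recovery tests use 300–1,000 genes × 400–1,000 cells for the single-cell
track, 1,000 null genes at 200 cells per group for DE calibration, and
400–768 px images with 50–200 cells per animal for imaging — sizes at
which every stage's behavior is already asymptotic enough for the
quantities tested while keeping the full suite and the acceptance script
each around a minute of compute.

## Known limitations

- The hurdle test's per-gene p-values are not numerically interchangeable
  with MAST's (no shrinkage, no priors); only calibration and power are
  matched.
- The modularity optimizer is Louvain-style; the smart-local-moving
  refinement pass is not implemented (partition quality is verified
  against exhaustive search and igraph instead).
- Reported QC medians and cluster counts for the original deposited
  dataset are reproducible only with that dataset downloaded; the
  package reads its MTX-trio format but ships no data.
- Atlas registration, t-SNE/UMAP, ambient-RNA correction, per-cell
  doublet scores, and 3D imaging are out of scope.
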