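# Methods

This note documents the models and procedures devtraj implements, the
assumptions behind them, the defaults that matter, and what the
synthetic-data experiments do and do not demonstrate.

## Data model and preprocessing

The unit of analysis is a `CellTable`: a sparse genes × cells integer
UMI matrix with per-cell annotations (sample, age, sex, genotype, cell
type, region) tied to an ordered `AgeLadder` whose last label is the
adult reference. QC removes cells outside [400, 100 000] total UMIs,
with fewer than 250 expressed genes, with more than 20% of UMIs from a
single gene, with more than 10% mitochondrial or ribosomal UMIs, or
with more than 1% of UMIs from immediate-early, apoptotic, or red-blood-
cell flag lists. All flag lists are user-supplied configuration, never
hard-coded symbols. "Over"/"under" thresholds are strict, so a cell at
exactly 20% top-gene fraction is kept.

Normalization is log1p of counts-per-10k. Variance stabilization for
embeddings is per-gene standardization (n−1 denominator) clipped to
±10; zero-variance genes map to zero. This log-CPM + scale pipeline is
a deliberate, fully specified substitute for regression-based
variance-stabilizing transforms: everything downstream consumes only a
PC embedding, which is insensitive to the difference at the effect
sizes of interest. Residual covariate regression (mitochondrial
fraction, largest-gene fraction) is not implemented.

PCA is computed on gene-centered data; the sign of each component is
fixed so its largest-magnitude gene loading is positive, making scores
reproducible across runs and solvers. Variance fractions are relative
to total variance of the centered matrix.

## Maturation trajectories

Each cell type is processed independently: subset → log-normalize → top
2000 genes by log-normalized variance → scale → PCA (≤ 100 components).
The retained PC count is the smallest k whose cumulative variance
fraction reaches 0.20, capped at 100. Maturity at age *a* is the
Manhattan (L1) distance between the age-*a* centroid and the adult
centroid in that space. L1 over ~tens of dimensions weights each
component's displacement linearly and is the convention this statistic
was defined with.

Because transient programs (e.g. axon guidance) can move young cells
*away* from the adult state, the raw distance curve is clamped: scanning
from youngest to oldest, any value exceeding the previous clamped value
is replaced by it. Stage deltas are computed on the clamped curve over
the ladder's stage set. For the default 8-age E16→P65 ladder the stage
set is the five postnatal intervals (P0–P4, P4–P10, P10–P18, P18–P28,
P28–P65); embryonic distances are computed and reported but excluded
from staging. This is a documented choice, overridable via
`AgeLadder(stage_set=...)`.

Classification: k* is the minimum number of stages, taken largest
first, holding ≥ 90% of total change. With S stages the class is
stepwise (3) if k*/S ≤ 0.4, intermediate (2) if k*/S ≤ 0.6, else
gradual (1); at S = 5 this reduces to the 1–2 / 3 / 4–5 split. The
search uses a 1e-12 tolerance on the cumulative-sum comparison so that
exact-fraction inputs (e.g. deltas of 0.3 summing to 0.9) classify as
written.

A known bias of the centroid-distance statistic: sampling noise adds a
positive offset to every non-adult distance (the adult distance is
exactly 0 by construction), which inflates the final stage delta. The
offset shrinks with cells per age and with the fraction of variance the
retained PCs devote to signal; at ≥ 200 cells per age and HVG-panel
count depths it does not affect classification in our experiments.

The k-NN maturity alternative builds, per cell type, a 50-neighbor
Euclidean graph over all ages in the same PC space and reports, per
age, the fraction of neighbors originating from adult cells.

## Group contrasts

Per cell type, the same subset → HVG → scale → PCA → PC-selection
pipeline runs on cells of both groups combined; each sample is reduced
to its centroid. The effect size is mean(between-group L1 distances) /
mean(within-group distances pooled over both groups); the p-value is a
two-sided two-sample t-test between the between-group and within-group
distance lists, BH-corrected across cell types. The t-test treats
pairwise distances as independent although they share samples; this
replicates the procedure being reproduced, and
`group_distance_permutation_p` provides a label-permutation alternative
for users who want exchangeability-exact inference. Degenerate cases:
all distances zero → ratio 1, p 1; zero within-group distance with
nonzero between → ratio flagged infinite.

## Pseudobulk differential expression

Counts are summed per sample (pseudobulk), transformed to log(CPM+1),
and tested per gene with a one-way F-test across groups — ages for
devDEGs, sexes or genotypes for group DE — with BH adjustment and a 5%
FDR call threshold. For two groups the F-test is exactly the squared
two-sided t. Genes with zero residual variance are flagged untestable
(p = 1); exclusion lists (mitochondrial, ribosomal, Y, X-inactivation
genes for sex contrasts) are dropped before testing. The F-test on
log-CPM replaces moderated-variance engines (DESeq2 / limma-voom): the
estimand — per-gene group-mean differences at the replicate level — is
the same, the engine is exactly specifiable, and it sits behind the
`de_test` interface so a moderated engine can be slotted in.
Calibration was verified empirically: on null simulations the raw
p < 0.05 rate is ~4.8–4.9% (10 000 genes, n = 4 samples/age).

devDEG sharing uses strict boundaries on the fraction f of cell types
calling a gene: f > 0.7 shared, f < 0.2 specific, else intermediate.

Age trends are fit per gene by least squares on a cubic B-spline basis
with `df` degrees of freedom over the age index (df = 4, the default,
is a cubic polynomial; larger df adds interior knots at quantiles).
A fixed-df regression spline was chosen over a penalized smoother
because df alone controls flexibility, the fit is deterministic and
reproduces constant and linear signals exactly. Trends are z-scored
per gene and clustered with Ward agglomerative clustering on Euclidean
distance; labels are renumbered by first appearance on index-sorted
input so the partition is invariant to row order.

Module scores follow the binned-control convention: genes are ranked by
mean expression into 24 bins; each set gene contributes up to 100
control genes sampled (seeded, without replacement) from its bin; the
score is mean(set) − mean(controls) per cell. Scores are averaged per
age and z-scored across ages.

The refinement score of a gene set is (number of (gene, cell type)
combinations significant in a dedicated P10-vs-adult two-group
pseudobulk contrast) / (number of combinations with nonzero pseudobulk
at ≥ 1 age). The dedicated two-group contrast — not the omnibus
across-age test — is used because the quantity measures late
(P10→adult) change specifically.

## Regionalization

Cell-type profiles are mean scaled expression per type, computed
*within* each age (scaling across ages would leak the global age signal
into the correlation structure; this choice is overridable). The
within-region score at an age is the mean off-diagonal Pearson
correlation among the region's member types, normalized by its adult
value, so the adult entry is 1 by construction; regions need ≥ 2 member
types to be scorable. Region markers are one-vs-rest Wilcoxon rank-sum
tests on log-normalized values, BH within region, requiring higher
in-region mean. The module contains no RNG.

## Identity mapping

The soft classifier scores each query cell by Pearson correlation to
each reference cell type's mean profile, clips negatives to zero and
normalizes rows to sum 1 (uniform fallback for all-nonpositive rows).
Genes are standardized before correlating: raw log-normalized profiles
share a dominant baseline-expression axis across all cell types, which
would compress the score differences between types. The assignment
rules are exactly the published thresholds: reference mapping assigns
when the top score strictly exceeds 0.6; across-age mapping assigns
when top > 0.8, or when top > 0.5 and top ≥ 2 × second-best. The
identity ratio of a type's row in the type-averaged score matrix is
(diagonal − max off-diagonal)/diagonal: 1 for one-to-one mapping, 0 for
an exact two-way tie, negative for a mismatch, undefined (NaN) when the
diagonal is 0. Because the contract is over the score matrix, scores
from an external label-transfer tool can be imported as TSV and pushed
through the same rules.

## Pseudotime and delay testing

Per cell type, the reference genotype's cells define the space: 2000
HVGs, scaling parameters, and a 20-PC basis fitted on reference cells
only and frozen. The principal path joins the reference age centroids
in ladder order; pseudotime of any cell (reference or projected
mutant/control) is the arc length of its nearest point on the path
(per-segment orthogonal projection clamped to the segment; global
minimum; ties to the earlier segment). Projection clamps pseudotime to
[0, total length] so outliers beyond the endpoints cannot dominate
group means. The delay test averages pseudotime within samples and
compares per-sample means between genotypes with a two-sided t-test
(an across-cell-type aggregation mode mirrors designs where cell types
are the replication unit). A piecewise-linear centroid path replaces
principal-curve smoothing: with a single lineage over ordered ages the
two coincide in spirit, and the path is deterministic and exactly
specifiable.

## Synthetic-data generator

The generator emulates the multi-age atlas design: an age ladder, two
sexes × `samples_per_age_per_sex` samples, one or more genotypes, and
cell types with maturation schedules m(a) ∈ [0,1] (0 at the youngest
age, 1 at adult). Gene classes: maturation genes (signed log-effects ×
m(a)); cell-type markers (constant uplift in their own type); region
genes (uplift in the home region scaled by a sharpening factor rising
linearly 0.25 → 1 across ages, giving the regionalization statistic a
known monotone ground truth); sex genes (signed male-vs-female effects
active in a configurable age window and, optionally, a configurable
subset of cell types). Genotype delays shift the schedule look-back by
whole stages, clamped at the youngest age — a transient developmental
delay, not a permanent deficit. Counts are negative binomial with
shared dispersion θ = 10 (variance μ + μ²/θ) and log-normal per-cell
library factors (σ = 0.3); one generator seeded from `config.seed`
drives all draws in a fixed order, so identical configs are
bit-identical.

Defaults that matter: effect size log 4 for every planted class
(detectable but not trivial at replicate-level n); baseline log-mean
1.0, i.e. ≈ 4.5 mean counts/gene/cell — representative of the
highly-variable-gene panels the pipelines actually operate on rather
than of whole-transcriptome sparsity (at much lower depth the
centroid-noise offset discussed above starts to blur the trajectory
classes, which is a property of the statistic, not of the tests). The
intermediate schedule is a logistic with steepness 3.0 centered
mid-ladder, chosen so its noiseless stage-delta profile has balanced
slack to both classification boundaries (top-2 mass 0.807 < 0.9 <
top-3 mass 0.979 on a six-age ladder); the generator computes each
type's true class by running the classifier on the noiseless schedule,
so truth and rule are consistent by construction.

What the generator does *not* emulate: ambient RNA, doublets, batch
effects, gene–gene correlation beyond the planted programs,
cell-type-specific library sizes, or zero inflation beyond NB sparsity.
Passing recovery tests therefore demonstrates that the statistics
recover their estimands under a clean, correctly specified count model
— not robustness to real-data artifacts.

## Validation experiments and problem sizes

`devtraj.experiments` (driven by `scripts/acceptance.py` and the
acceptance test suite) uses: trajectory-class recovery — 30 cell types
(10 gradual, 10 intermediate, 10 stepwise split between two stages),
6 ages, 200 cells/type/age, 200 maturation genes of 400; contrast
calibration/power — 20 cell types, 4 samples/sex, 10 simulation seeds,
power arm with 50 sex genes in 5 types; delay — one gradual cell type,
delay of one stage, read out at a single intermediate age, 10 seeds per
arm; devDEG — 10 000 null genes for calibration, 200 step genes of
2000 for power at 4 samples/age; regionalization — 2 regions × 2 cell
types, 80 region genes; identity — 4 types with 40 markers each. These
sizes were chosen as the smallest designs at which the statistics'
operating characteristics are stable.

## Known limitations

- The distance t-test ignores dependence between pairwise distances;
  use the permutation p-value when exactness matters.
- The F-test has no variance moderation, so it loses power relative to
  empirical-Bayes engines at very small replicate counts.
- The trajectory classifier inherits the adult-anchor noise bias of the
  centroid-distance statistic at low depth/cell numbers.
- The soft classifier is a correlation method; it does not learn
  anchor weights and will under-separate cell types distinguished only
  by a few low-variance genes.
- The principal path does not smooth across centroids; a strongly
  non-monotone embedding layout could fold the path.
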