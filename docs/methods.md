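# Methods

## Scope and data model

The package analyses genus-level marker-gene surveys of the same stool
samples across three domains of life — bacteria and archaea (16S rDNA
amplicons) and fungi (ITS1) — together with two nutrient inventories per
subject (a food-frequency questionnaire scoring usual diet and multi-day
recalls scoring recent diet). Each domain's counts live in a validated
genus × sample integer table; ranked lineages (Phylum, Class, Order,
Family, Genus by default; the rank count L is configurable) drive all
between-genus distances. OTU-level tables can be collapsed to genus level:
OTUs with fewer than 5 reads in total are discarded before aggregation, and
lineages unclassified at genus are retained in `Other_<lowest classified
rank>` buckets rather than dropped.

## Inclusion rules

Samples enter the analysis if they reach the per-domain read floor
(200 reads for the ITS amplicon; no floor for the 16S tables, where the
source surveys applied none). Genera enter if they are present in at least
9 samples *and* carry at least 10 reads in total. All boundaries are
inclusive. Proportions are computed within each amplicon on the full
genus table *before* rare-genus removal — display proportions describe the
whole community — and the rare-genus rule is applied afterwards for
testing; the filter report records this order and every dropped item with
its single triggering rule. Filters are idempotent.

## Taxonomic distance and the UniFrac family

With no phylogeny available for a cross-domain genus set, relatedness is
read from the ranked taxonomy: `d(i,j) = 1 − k/L`, where k counts
consecutive ranks, from the top down, at which the two lineages agree. An
`unclassified` rank matches nothing, including another `unclassified`:
missing annotation must not manufacture shared ancestry. This distance is
an ultrametric, so its exact tree realization is the rank hierarchy itself
with unit branch lengths — every leaf sits at depth L and leaf-to-leaf path
length divided by 2L reproduces the formula (checked exhaustively in the
tests). Building the tree directly from the hierarchy, rather than
re-clustering the distance matrix, removes any dependence on linkage
arbitration. Unclassified ranks become genus-private chains that never
merge.

On this tree the package computes generalized UniFrac

d^(α)(A,B) = Σ_i b_i (p_Ai+p_Bi)^α · |p_Ai−p_Bi|/(p_Ai+p_Bi) / Σ_i b_i (p_Ai+p_Bi)^α

over branches i with subtree proportion totals p_Ai, p_Bi and lengths b_i,
skipping branches empty in both samples; α = 1 is the weighted-normalized
form, and the unweighted (presence/absence) form
Σ b_i |1(p_Ai>0) − 1(p_Bi>0)| / Σ b_i 1(p_Ai+p_Bi>0) completes the family.
The default screening family is α ∈ {0, 0.5, 1} plus unweighted. Samples
with zero reads are excluded from distance matrices (never imputed) and the
exclusion is recorded.

## Permutation tests

PERMANOVA uses the Gower-centered matrix G = −½ J D² J and the hat matrix H
of an intercept-plus-covariate design: the regression form for continuous
covariates (Prevotella/Bacteroides log-ratio, nutrient-cluster scores),
one-hot indicators for groups. The pseudo-F is
[tr(HGH)/q] / [tr((I−H)G(I−H))/(n−q−1)] with q the covariate rank. Because
G is double-centered, tr(GH_π) reduces to a quadratic form in an
orthonormal basis of the centered design, which makes thousands of
permutations cheap (vectorized over permutation blocks). p-values use the
add-one rule p = (1 + #{F_π ≥ F_obs})/(1 + n_perm), so p is never 0 and the
floor is 1/(n_perm+1); an exact mode enumerates all n! relabelings for
small n. The permutation count defaults to 9,999 and every stochastic call
takes an explicit seed. A constant covariate is an error; an all-zero
distance matrix (no community variation) returns F = 0, p = 1.

The omnibus test (PermanovaG) applies the *same* permutations jointly to a
family of distance matrices; the combined statistic is the minimum
per-matrix p, and each permuted dataset's min-p is computed from the ranks
of its pseudo-F values within the permutation distribution. A single
matrix reduces to plain PERMANOVA; duplicating a matrix changes nothing.

## Association suite

Co-occurrence uses presence calls at proportion ≥ 0.01 (inclusive) and the
Dice index 2|A∩B|/(|A|+|B|) over sample-presence sets; a pair of
never-present genera is defined as 0 (not NaN) so the matrix stays complete
for clustering. Heatmap ordering clusters genera by Ward linkage on
Euclidean distances between their Dice profiles (rows of the Dice matrix).

Archaeal status assigns each sample to Methanobrevibacter, Nitrososphaera
or `none`; when both are detected the predominant genus wins, and an exact
nonzero tie — never observed in practice because co-occurring samples are
always dominated by one lineage — falls back to `none` with a warning.

Rank tests (Kruskal–Wallis with χ² p on k−1 df, Dunn's pairwise z with
tie-corrected SE, Spearman with average ranks) all use tie-corrected
variances. A value vector with no variation gives H = 0, p = 1 by
definition. Fisher's exact test is two-sided by the minimum-likelihood rule
(sum over tables with hypergeometric probability ≤ observed), stated
explicitly because two-sided Fisher has competing conventions.

Multiple testing uses Benjamini–Hochberg step-up q-values with significance
tiers at 25/20/15/10% FDR. Each heatmap panel is its own FDR family
(fungi × bacteria Spearman; genera × archaeal status; nutrient clusters ×
status; genera × nutrient clusters), matching per-analysis adjustment;
results with undefined statistics (constant inputs) are flagged and
excluded from their family.

The Prevotella/Bacteroides covariate is log10 of the proportion ratio with
a 1e-6 pseudocount on both terms. Z-score heatmap summaries standardize
each feature across all samples (sd with one delta degree of freedom) and
report group means; group-size-weighted means sum to zero by construction.

## Dietary patterns

Each inventory is processed separately. Constant nutrient columns are
excluded up front. Nutrients are clustered on the dissimilarity
sqrt(1 − Spearman ρ) with Ward linkage — Ward for consistency with the
co-occurrence heatmap's clustering, the square root to embed the
correlation dissimilarity in Ward's Euclidean geometry — and cut into 20
clusters (about 10% of a ~200-nutrient panel; configurable). Members of
each cluster are z-standardized (correlation-scale PCA, since nutrients
carry incommensurate units) and summarized by their first principal
component, the per-sample nutrient cluster measurement (NCM). PC1 signs are
ambiguous, so each score is oriented to correlate non-negatively with the
mean of its members' z-scores; a singleton cluster's score is the z-scored
nutrient itself. Scores are mean-centered; they are invariant to affine
rescaling of raw nutrients and to nutrient input order (up to cluster
relabeling).

Screening is two-stage. Stage 1: PERMANOVA of every cluster score against
every distance matrix in the family; a cluster screens in when any test has
raw p < 0.05 (the stage-1 rule is configurable; the level is a design
choice, not an adjusted threshold, because stage 1 is a screen, not an
inference). Stage 2, for screened-in clusters only: Spearman of the cluster
score against each genus proportion (one BH family) and Kruskal–Wallis of
the score across archaeal status (a second family), both at FDR q = 0.25.
If nothing passes stage 1, stage 2 is empty by construction.

## Synthetic cohorts

The generator emulates the structure the analysis assumes, with defaults
matching the emulated study's margins: n = 96 samples; per-domain genus
counts (40 bacteria, 30 fungi, 5 archaea); log-normal sequencing depth with
median ~1,000 reads/sample (desk-scale); counts drawn
multinomial(depth, Dirichlet(c·p)) with concentration c = 200, so
sequencing-stage overdispersion stays minor relative to the explicitly
modeled biology; baseline genus log-abundances N(0, 1.5) plus fixed offsets
that give the well-known dominant genera (Saccharomyces, Candida,
Bacteroides, Prevotella, …) their empirically large baseline shares;
per-sample latent log-abundance noise N(0, 1).

Archaeal occupancy is categorical with defaults 24/96 Methanobrevibacter-
only, 10/96 Nitrososphaera-only, 6/96 both (the exclusivity parameter
ε = P(both)), the rest negative, plus rare archaeal genera at 3% per
sample; "both" samples split shares 80/20 so the predominance rule is
always decidable. Archaea-negative samples have all-zero archaeal columns.
A latent standard-normal axis u shifts the Prevotella and Bacteroides
log-means by ±2u, producing the reciprocal abundance pattern.

Nutrient panels (200 nutrients, 20 equal blocks) use block-exchangeable
correlation: within-block Spearman ≈ 0.7, between-block 0, with
unit-bearing scale factors per nutrient. Each inventory draws its own block
latents.

Planted taxon–nutrient effects are Gaussian-copula links between a block's
latent score and the genus's abundance, injected on the genus's *logit
share against the realized background community*, which makes the
Dirichlet-mean proportion a deterministic monotone function of the copula
latent — the planted rank correlation is not eroded by compositional noise
from the other genera. The planted ρ is a Spearman target (the copula uses
Pearson 2·sin(πρ/6)), and a planted taxon is pinned at a stable mean share
of 0.1: a correlation target is only meaningful for a detectable community
member. Even so, the realized sample correlation at n = 96 fluctuates
around ~0.46 for a nominal 0.5 (rank-scale conversion plus residual count
noise plus sampling spread ~0.1). Planted taxon–status effects add a fixed
log-scale shift in samples of the given archaeal state. Ground truth
(block membership, block latents, archaeal states, the Prevotella/
Bacteroides latent, the planted-effect list) is returned with the tables,
and all randomness flows from a single seed.

What the generator does *not* emulate: real taxonomic assignment error,
depth-abundance coupling, non-exchangeable within-block nutrient structure,
inventory-to-inventory correlation for the same subject, and the heavy
tail of genus abundance distributions. Tests passing on these cohorts show
the statistics and the workflow are implemented correctly and calibrated —
not that the biological effect sizes of any real cohort are recoverable.

## Calibration and recovery harnesses

Reported by `scripts/acceptance.py` and asserted in the test suite:

- **Type-I error**: PERMANOVA of a covariate independent of a random
  Euclidean distance matrix (n = 24, 5 dimensions, 99 permutations,
  1,000 replicates) must reject at a 0.05 level within [0.03, 0.07].
- **Unequal variance**: two groups with equal centroids and dispersion
  ratio r ∈ {1, 2, 4} (20 per group, 5 dimensions, 1,000 replicates);
  the r = 1 arm is a second type-I check, the r > 1 arms quantify how much
  heteroscedasticity alone moves the rejection rate (with balanced groups:
  very little).
- **Null dietary screen**: 200 zero-effect cohorts (reduced to 15 genera
  per domain, 60 nutrients in 6 blocks, 99 permutations — the calibration
  properties do not depend on table sizes); the fraction of cohorts in
  which each stage-2 BH family selects anything at q = 0.25 stays at or
  below q within Monte-Carlo error.
- **Block recovery**: adjusted Rand index between generated nutrient
  blocks and recovered clusters, averaged over 10 cohorts (≥ 0.9; in
  practice 1.0 at the default within-block correlation).
- **Planted-effect power**: a taxon–diet effect of ρ = 0.5 at n = 96,
  detected when the planted cluster's Spearman panel (cluster score vs all
  filtered fungal genera, one BH family) selects the genus with the correct
  sign at q = 0.25; ≥ 90% of 50 cohorts (measured ≈ 0.98). The full
  two-stage screen recovers the same effect in ≈ 80% of cohorts — the
  stage-1 whole-community PERMANOVA is the power bottleneck for a
  single-taxon effect — and that rate is reported as a diagnostic
  (`pipeline` quantities in the acceptance output) rather than asserted.
- **Exclusivity**: ε = 0 generates no sample carrying both archaeal
  genera.

## Numerical choices and degenerate inputs

Proportion columns must sum to 1 within 1e-9 (zero-depth samples are
flagged instead); distance matrices are symmetric within 1e-12 with zero
diagonals; pseudo-F comparisons in permutation counting use a 1e-12
tolerance so exact ties count as "as extreme". Hierarchical clustering
ties are resolved by scipy's deterministic linkage order; cluster ids are
assigned by scipy's `fcluster` labels and are arbitrary up to relabeling.
PCA is deterministic (SVD); the sign convention above removes its only
ambiguity. Seeds are mandatory throughout the API; derived seeds stay
below 2^31.

## Known limitations

Single-covariate designs only (no interactions, no PERMDISP dispersion
test); no rarefaction (proportions only, matching the emulated workflow);
the taxonomy tree carries no evolutionary branch lengths, so UniFrac here
measures taxonomic, not phylogenetic, turnover; the two-sided Fisher
convention follows the minimum-likelihood rule and may differ from
doubling-the-one-sided-p implementations; the real-data prevalence
harness requires the source cohort's genus read-count table, which is not
distributable with the package.
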