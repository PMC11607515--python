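# Methods

This note documents the statistical procedures, the synthetic-cohort
model behind the validation suite, the numerical conventions, and the
design choices made where the design was genuinely open.

## Statistical primitives

All tests are two-sided. The direction sign convention is *later minus
earlier* in the declared group order (HC < SCAD < MI), so a feature
elevated in disease carries direction +1.

**Mann–Whitney / Wilcoxon rank-sum.** The U statistic counts pairs in
which the case value exceeds the reference value, ties as ½. For pooled
sizes n + m ≤ 12 the permutation distribution is enumerated exactly
(two-sided p by the deviation rule, P(|U′ − nm/2| ≥ |U − nm/2|));
otherwise a normal approximation with tie-corrected variance and a 0.5
continuity correction is used. Against scipy's exact and asymptotic
implementations the two paths agree to numerical precision; under a
continuous Gaussian null at n = m = 30 the rejection rate at α = 0.05
is 0.046 with Kolmogorov–Smirnov distance 0.013 from uniform
(10,000 replicates).

**Welch t-test.** Definitional statistic with Welch–Satterthwaite
degrees of freedom. Zero pooled variance yields p = 1 for equal means
and p = 0 otherwise.

**Kruskal–Wallis.** H with the standard tie correction, referred to
χ²(k − 1).

**Jonckheere–Terpstra.** The trend statistic over k ≥ 3 ordered groups
is the sum of pairwise Mann–Whitney counts across all ordered group
pairs. The null mean is (N² − Σnᵢ²)/4 and the variance uses the
tie-adjusted three-term formula. Total n ≤ 12 triggers exact enumeration
of all distinct group assignments; larger samples use the normal
approximation with a 0.5 continuity correction. The correction matters:
it reduces the worst-case disagreement with exhaustive enumeration over
all 3-group configurations (each group ≥ 2, total ≤ 10) from ≈0.15 to
≈0.027 in two-sided p; the residual worst case sits at the minimal
configuration (2,2,2), where any continuous approximation of a
13-point discrete distribution is coarse. In practice the exact path
covers all such sizes.

**χ² and Fisher.** Pearson χ² without continuity correction for all
r×c tables, including zero-cell tables — this choice reproduces all
seven reproducible printed baseline-table p-values (0.097, 0.097,
0.020, 0.066, 0.003, 0.251, 0.309) to three decimals. Fisher's exact
test (hypergeometric summation, two-sided by the ≤-observed-probability
rule) is exposed separately and auto-selected by the baseline-table
builder only for 2×2 tables with any expected count below 5.

**Benjamini–Hochberg.** Step-up q-values with enforced monotonicity;
validated against statsmodels and the definitional rejection rule on
random vectors. Where a procedure involves several test families (e.g.
Wilcoxon and t-test in metabolite set A), each family is adjusted
separately; aggregating adjusted p-values (reporter scores) is avoided
because it would penalize multiplicity twice.

**Fold change.** Ratio of group means (configurable to medians) with a
shared pseudocount, case over reference; gates are strict and applied
to unrounded values, so FC = 0.8333 does not pass "< 0.83".

## Diversity and ordination

Shannon entropy uses the natural log; Simpson is the Gini–Simpson form
1 − Σpᵢ². Both are invariant to positive rescaling of the count vector,
so whether counts or relative abundances enter is immaterial.

PCoA double-centers the squared-distance matrix (Gower) and
eigendecomposes. Bray–Curtis is non-Euclidean, so negative eigenvalues
occur; they are truncated — dropped from the proportion-explained
denominator and reported separately — rather than Lingoes/Cailliez
corrected, matching common practice. "PCA" on compositional profiles is
implemented as PCoA of Euclidean distances of log relative abundances.

perMANOVA uses Anderson's pseudo-F computed from within-group sums of
squared distances via the indicator-vector identity
SSW = Σ_g z_gᵀD²z_g/(2n_g), which vectorizes over batches of label
permutations. The permutation p-value uses the "+1 in numerator and
denominator" convention, so p ∈ [1/(n_perm+1), 1] and is never zero;
the permutation stream is a seeded generator, making every p
bit-reproducible. Note that with very small groups a random permutation
can reproduce the observed split, so the attainable minimum p is only
reached when group sizes make that probability negligible.

dbRDA regresses the positive-eigenvalue PCoA embedding on centered
group indicators and eigendecomposes the fitted values; constrained
axes are at most k − 1 and the constrained proportion of total inertia
equals the perMANOVA among-group sum of squares divided by total
inertia (verified numerically on Euclidean embeddings).

## Reporter scores

The per-KO two-sided p is mapped to z = Φ⁻¹(1 − p/2)·direction
(p floored at 1e−300 so z stays finite), a module of k tested KOs
aggregates to Z_raw = Σz/√k, and the background correction subtracts
the mean and divides by the standard deviation of Z_raw over 1,000
(configurable) random size-k subsets of all tested KOs, drawn without
replacement from a seeded generator. Under a global null the corrected
scores are approximately standard normal (verified at 2,000 simulated
modules: |mean| < 0.05, sd within (0.9, 1.1)), so |Z| > 1.6 corresponds
to ≈95% one-tail confidence. Scores are invariant to module order and
to KO order within modules (the z-vector is sorted by KO id before the
seeded background draws). Random KO sets are the default background; a
sample-permutation background would be a reasonable alternative but
ties the correction to the contrast rather than to the KO universe.

Because reporter scores are group-level, sample-level "module activity"
for correlation analyses is the summed relative abundance of the
module's KOs per sample.

## Metabolite selection and metabotyping

Selection follows a two-branch cross-comparison scheme over the ordered
groups. Set A runs, for every pairwise group comparison, the Wilcoxon
test on raw intensities and the Welch t-test on log intensities; a
feature passes if within a single comparison both BH q-values fall
below 0.05 and the fold change (group means of raw intensities) is
outside (0.83, 1.2). Requiring all three conditions within the same
comparison is the stricter reading of the rule and the one implemented.
Set B keeps features with Jonckheere–Terpstra or Kruskal–Wallis raw
p < 0.05 across the ordered groups. The selected set is the union;
drug-derived features are removed via a user-supplied exclusion list,
since their identification is a chemistry step outside this package.

Clustering operates on log-transformed, per-feature standardized
intensities (a pseudocount of half the smallest positive value is added
only when zeros are present). The network is signed,
a = ((1 + r)/2)^β with β = 14 — the signed construction preserves
anti-correlation information and β = 14 is the characteristic soft
threshold for signed networks; an unsigned variant is available.
`scale_free_fit` reports the R² of the log-log connectivity-frequency
regression for β diagnostics. Topological overlap is

TOM_ij = (Σ_{u≠i,j} a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 − a_ij),

with k the connectivity excluding the diagonal; 1 − TOM is the
clustering dissimilarity.

**Dynamic tree cut.** The average-linkage tree is first cut statically
at 0.99·h_max, separating the main branches. Each branch is then
recursively split at its top merge whenever both sub-branches hold at
least `min_cluster_size` features and the merge height exceeds both
sub-branch tops by at least 0.75·(1 − q)·(0.99·h_max − h_min), with q
taken from the deepSplit ladder (0.64, 0.73, 0.82, 0.91, 0.95 for
levels 0–4). Higher deepSplit levels therefore demand smaller gaps and
can only refine the partition, so the cluster count is monotone
non-decreasing in deepSplit — the defining behaviour of the adaptive
branch decomposition this implements. A single flat cut at a
range-quantile height cannot reproduce both that monotonicity and
correct recovery on TOM dendrograms (whose within-cluster merges span
most of the height range), which is why the gap-guarded recursive form
was chosen; it is a deterministic simplification of the field's hybrid
algorithm without the PAM assignment stage. Branches below
`min_cluster_size` (default 5; clusters of fewer co-abundant features
are rarely interpretable) are left unassigned (label M00); surviving
clusters are relabelled M01, M02, … by descending size with the
smallest leaf index as the deterministic tie-break.

Eigen-features are the first principal component of the standardized
within-cluster feature matrix over samples, sign-oriented so the mean
correlation with cluster members is positive; a singleton cluster's
eigen-feature is the standardized feature itself.

## Integration and tiers

The module × metabotype grid is full Spearman with one BH family over
all cells. Phenotype associations use Mann–Whitney for two-group
contrasts and Spearman for continuous scores, BH-adjusted per call.
Tier bands are half-open and exhaustive: strong q < 0.001, moderate
0.001 ≤ q < 0.05, weak 0.05 ≤ q < 0.1, ns otherwise — the only
internally consistent ordering of the three significance marks used in
this style of association heatmap. Missing phenotype values are
excluded pairwise; cells with fewer than 4 complete pairs are reported
missing and excluded from the BH family.

## Synthetic cohort

The generator emulates the statistical structure the pipeline assumes,
with defaults fixed at the reference study conditions:

| parameter | default | meaning |
|---|---|---|
| group sizes | 36 / 64 / 46 | HC / SCAD / MI subjects |
| n_species, n_kos, n_modules | 150, 600, 30 | table sizes |
| n_diff_species, species_effect | 12, 3.0 | planted species, × multiplier in disease |
| carriers_per_ko | 3 | species carrying each KO |
| n_metabolites, n_latent_clusters | 200, 5 | feature table size |
| metabolite loading, noise sd | 0.8, 0.6 | factor-model geometry |
| cluster_shift | ±0.8 per stage | planted group shift on factors |
| species log-mean sd, log sd | 1.5, 1.0 | heavy-tailed abundance profile |
| ko_noise_sd | 0.3 | multiplicative log-normal KO noise |

Species are log-normal per feature (log-mean spread 1.5 creates the
heavy-tailed rank-abundance profile typical of gut communities),
multiplied by the planted effect in the disease groups, then closed to
sum 1 per sample. KO abundances are the species-by-KO incidence product
of the *pre-closure* abundances with multiplicative log-normal noise;
KOs of planted modules are carried exclusively by planted species of
the matching direction, so species-level effects propagate into
module-level reporter signal. Metabolite features follow a latent
factor model on the log scale and are exponentiated to intensities;
every factor receives an alternating-sign stage-monotone mean shift so
that all cluster members are selectable by the cross-comparison filter.
Phenotypes are stage-monotone with multiplicative log-normal noise;
their magnitudes are arbitrary and only their ordering is meaningful.
Species, KO, metabolite and phenotype streams draw from independent
child seeds, so regenerating one layer never perturbs the others.

What the generator does **not** emulate: compositional zero inflation
and sequencing depth variation, KO sharing across many species,
metabolite features outside any cluster, batch effects, and covariate
structure (age, sex, medication). Passing recovery tests therefore
demonstrates correctness of the chain under the planted model, not
performance on real cohort data.

## Validation problem sizes

The test and acceptance suites use: 10,000 simulated nulls per rank
test (n = 30 + 30 or 3 × 20); 500 perMANOVA nulls at 999 permutations,
n = 60; 50 seeded cohorts for reporter recovery; 20 for metabotype
recovery; exhaustive enumeration oracles up to total n = 8 (raw
permutations) and n = 10 (distinct assignments). These sizes give
binomial standard errors well inside the asserted bands while keeping
the default suite fast.

## Known limitations

- The dynamic tree cut is a deterministic simplification; borderline
  features that the hybrid PAM stage would reassign stay unassigned.
- Reporter-score backgrounds assume exchangeability of KOs; strongly
  size-stratified KO effects would bias μ_k.
- The set-A/set-B selection treats the ordered group list as given; no
  fourth-group extension is guessed.
- Fold-change gates on relative abundances inherit compositional
  coupling: a large planted change in one abundant species perturbs
  the fold changes of others.
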