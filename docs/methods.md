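# Methods

This note records the statistical model behind each stage of the
pipeline, the defaults and why they were chosen, what the synthetic-data
generators do and do not emulate, and the numerical choices that affect
results at the margins.

## Expression preprocessing

Counts are converted to RPKM as
`counts / ((length/10³) · (library_size/10⁶))`; genes with zero
expression in one or more samples are removed before any analysis, so
"measured gene" afterwards simply means row membership. The filter is
idempotent and applied per organism; for a multi-species matrix it keeps
genes positive in every sample, which is the intersection of the
per-organism rules and keeps one shared gene space.

Cross-species gene matching is by a user-provided one-to-one homolog map
(`parse_homolog_map`); many-to-many mappings are dropped with a logged
count rather than resolved heuristically, because any resolution rule
(highest identity, first match) silently changes gene-set membership.

## Process activity and normalization

Activity is the **sum** of member-gene expression. Summing versus
averaging is immaterial for the final per-stratum rank scale — dividing a
process by its gene count is a per-process monotone map that rank
normalization absorbs exactly. Note the caveat: the intermediate joint
quantile-normalization step is *not* invariant under per-process
rescaling (it re-orders processes within a sample when set sizes
differ), so sum- and mean-based pipelines agree exactly only through the
rank-scaling step. All downstream inference uses the rank scale.

Quantile normalization is performed per ontology over all samples of all
species jointly; ties within a sample are broken by input order (stable
sort), which makes the operation deterministic. Rank scaling maps each
process's within-stratum values to `(rank − 1)/(n − 1)` with average
ranks for ties. Consequently a process *tied at its extreme* does not
attain 0 or 1 exactly — e.g. values (4, 4, 8) scale to (0.25, 0.25, 1) —
while tie-free profiles always span [0, 1]. A stratum with a single
sample has no rank scale and is an error rather than a silent NaN.

## Differential process regulation

The per-process model is a fixed-effects factorial ANOVA with type-II
sums of squares, appropriate for unbalanced designs: the SS of term *T*
compares the models with and without *T* among all terms not containing
*T*, with the full model's residual mean square as the error term. The
implementation works directly on orthonormal bases of the candidate
model column spaces (cached per term set), so that hundreds of processes
and permutation replicates reuse one set of decompositions; degrees of
freedom come from rank differences, which also handles empty-cell
(inestimable) interactions — those are pruned with a logged note. The
engine is validated in the test suite against an explicit
sums-of-squares decomposition on balanced designs (to 1e-9) and against
`statsmodels.stats.anova.anova_lm(typ=2)` on unbalanced ones.

Assumption filtering precedes testing: Shapiro–Wilk on the full-model
residuals and the Brown–Forsythe variant of the Levene test (median
centring) across the full design cells (species × tissue × age group;
the grouping is our choice — the finest available stratification), both
at the deliberately strict p ≤ 0.005 so that only clear violations are
discarded. Degenerate (zero-residual-variance) responses fail with an
explicit reason.

Backward selection removes one term per iteration: the removable term
(not contained in any retained higher-order term) with the largest
p > 0.05, ties broken by higher order first and then lexicographically.
Selection stops when nothing is removable or when the age-group main
effect itself would be removed; in the latter case the process carries
the "age removed" sentinel and stays in the FDR family with p = 1, which
is conservative and keeps the family size fixed.

FDR control is Benjamini–Hochberg (the field default where a correction
method is unspecified); the main threshold is 0.05 and configurable.
Processes failing the assumption filter never enter the family. The
conservation rule requires the pooled direction of regulation (sign of
the old-minus-young foldchange on the rank scale) to recur in at least
one fish and one mammal species; per-species directions come from the
species-stratified foldchanges, without a per-species significance
requirement — the stratified per-species sample sizes would make such a
requirement mostly a test of power, not of direction.

Gene-level contrasts (ageing-induced U and repressed R sets) use a
two-sided Mann–Whitney rank-sum test of young versus pooled old samples
with BH-FDR and a median-log2-foldchange sign rule. The rank-sum test is
this package's own choice of a robust, distribution-free gene-level
procedure; exact p-values are used for small tie-free groups.

Lifespan association is computed longitudinally: for each individual
sampled at two time points, the activity change (later − earlier) is
correlated (Pearson) with the individual's lifespan, per process.
Activity *change* rather than level is used because the level conflates
cohort composition with individual progression; this is a design choice
of the package.

## Disease alignment

Disease case-vs-control foldchanges are rank-normalized to [−1, +1]
(`2·(rank − 1)/(N − 1) − 1`, average ranks for ties). The rank transform
is bounded and distribution-free, makes AMDA invariant under any
strictly monotone rescaling of the raw foldchanges, and fixes the
theoretical AMDA range at exactly ±2 — the documented anchor for the
score's scale. AMDA is the difference of mean normalized foldchanges
over U versus R genes, restricted to genes measured in the disease set;
genes claimed by both U and R (possible when merging ageing sets) are
dropped from both with a logged count. Empty intersections yield NaN
with a warning rather than an exception, so batch scoring can skip
undefined pairs.

Significance is a two-sided rank-sum test of the U- versus R-gene
normalized foldchanges, BH-corrected across all pairs tested together;
sides smaller than 2 genes give an undefined p. The randomization
control reassigns U/R labels over U ∪ R (sizes preserved) and recounts
significant alignments.

DAC scores: crude(P, C) = Σ over comparisons (a, d), d ∈ C, of
AMDA(a,d) − AMDA(a,d | genes of P removed). "Comparisons" are (ageing,
disease) pairs. Normalization divides by the number of comparisons and
scales to an absolute maximum of 1 within each disease category
(default; `scale="global"` scales across categories instead). A
comparison whose U or R side empties after removal is skipped for that
process and logged.

The condition map uses classical (Torgerson) metric MDS: double-centred
squared Euclidean distances, eigendecomposition, coordinates from the
top-k eigenpairs, variance explained as eigenvalue over the sum of
positive eigenvalues. Distances over partially missing feature vectors
use pairwise-complete features rescaled to the full feature count.

## Shared risk SNPs

Trait strings are matched case-insensitively against per-category
keyword lists; traits matching several categories join all of them, and
unmatched traits form the non-ageing pool. Sharing between two SNP sets
means identical rsID or linkage disequilibrium with r² ≥ 0.8 (the
"strong LD" threshold is configurable; it is a package default, not a
value taken from elsewhere). LD pairs carry an explicit allele phase
map, which must be a bijection; phase is never inferred from allele
frequencies, keeping classification deterministic. Classification maps
the second SNP's risk allele through the phase onto the first SNP's
alleles: same risk allele ⇒ synergistic, alternative ⇒ antagonistic,
irreconcilable alleles ⇒ unclassified with a reason. The rule is
symmetric in the pair order.

Independent loci are connected components of the graph joining shared
SNPs with r² ≥ 0.5 or same-chromosome distance ≤ 1 Mb (both
configurable; this clustering rule is our construction). The antagonism
bias test is an exact binomial tail P(X ≥ k | n, p₀) with p₀ the
antagonistic fraction among shared SNPs with non-ageing traits. The
resampling null redraws category-sized SNP sets from the non-ageing pool
without replacement (default 10,000 replicates) and reports add-one
corrected empirical p-values, which can never be exactly zero.

## Synthetic data

The expression generator emulates a cross-species bulk RNA-seq ageing
study: by default 4 pseudo-species (two labelled fish, two mammals, so
the conservation rule is exercised literally), 4 tissues, age groups
{young, old_1, old_2}, 6 samples per cell, 2000 genes partitioned into
200 ten-gene processes of which 20 carry a planted monotone trend.
Counts are negative-binomial with dispersion 0.1 (a standard bulk
RNA-seq noise model) and lognormal gene base means (median 200, log-sd
0.5) — high enough that the zero-expression filter removes almost
nothing, emulating an analysis restricted to ubiquitously detected
genes. The planted `effect` parameter is the natural-log expression fold
over the full age range; with ten-gene activities and this noise level
the induced shift in mean rank-scaled activity between old and young is
of the same order (≈ 0.3 at the default 0.3), which is how the parameter
should be read. Planted trends are identical across species; the
generator therefore does not emulate partially conserved signatures,
cohort effects, outlier samples, tissue-specific regulation or
correlated gene noise within processes — recovery results on it are
statements about the pipeline's behaviour under its own model
assumptions, not about real-data performance. The longitudinal mode
gives each pseudo-individual a trend slope ~N(1, 0.3), samples it at the
first and last age group, and assigns lifespans log-linearly decreasing
in the slope, so induced processes correlate negatively with lifespan.

The disease generator sets each gene's foldchange to
c · (planted ageing direction) + N(0, noise_sd) with alignment
coefficient c ∈ {+1, −1} and default noise 0.3; genes outside regulated
processes are pure noise. The SNP generator plants one shared
cancer/degenerative pair in each of `n_shared_loci` loci (identical-rsID
or phased LD mode at random), with a deterministic count
`round(fraction · n)` of antagonistic pairs so the planted fraction is
recovered exactly; loci are ≥ 20 Mb apart and therefore independent
under the default clustering parameters; a 500-SNP non-ageing pool
includes 20 background-shared SNPs at a 0.2 antagonistic fraction to
give the bias tests a realistic null rate.

All generators are pure functions of their parameters and seed, and the
returned truth object suffices to compute every expected downstream
outcome.

## Problem sizes used in the test suite

End-to-end recovery checks run the default study size (288 samples, 200
processes) over 50 seeds; the permutation-null checks use 100 replicates
at the default size; distributional properties that need hundreds of
replicates (null FDR calibration) use a reduced study (2 species × 2
tissues, 20–40 processes) so the suite stays fast while the statistical
claim is unchanged. The acceptance script's random search uses 10⁵
points. These sizes are the package's own test design.

## Known limitations

* The gene-level differential-expression procedure and the exact AMDA
  normalization are this package's reconstructions (rank-based
  throughout); they reproduce the documented score range and behaviours
  but are not guaranteed to match any specific external implementation.
* Type-II tests assume fixed effects and independent errors; repeated
  measures from the same animal across tissues are not modelled.
* The LD model is minimal: pairwise r² with explicit phase, no decay
  with distance, no haplotype frequencies.
* Keyword-based trait matching is as good as the keyword lists; the
  defaults cover the four standard categories but are not curated for
  any particular GWAS-catalog release.
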