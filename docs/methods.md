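# Methods

This note documents the statistical models implemented in `dysbioscan`,
the choices made where the procedures admit more than one reasonable
reading, and what the synthetic-data simulations do and do not establish.

## Moderated t-test (lipidomics)

For species *g* with group sizes n₁ (HC) and n₂ (CD), the pooled variance
s²_g on d = n₁+n₂−2 degrees of freedom is shrunk towards a prior s₀²
carrying d₀ prior degrees of freedom:

    s̃²_g = (d₀ s₀² + d s²_g) / (d₀ + d),
    t_g = (x̄₂_g − x̄₁_g) / sqrt(s̃²_g (1/n₁ + 1/n₂)),   t_g ~ t(d + d₀).

(d₀, s₀²) are estimated by moment matching of z_g = log s²_g against a
scaled-F model: with e_g = z_g − ψ(d/2) + log(d/2), the excess variance of
e over ψ′(d/2) is inverted through the trigamma function (Newton
iteration) to give d₀, and s₀² follows from the mean of e. When the excess
variance is non-positive the prior dominates (d₀ = ∞) and every species
uses s₀² with a normal reference — this keeps small fixtures with
homogeneous variances runnable. The implementation reproduces R
`limma::eBayes` to ~1e-8 on a frozen mixed-variance fixture (see
`tests/test_lipidomics.py`).

Concentrations are log₁₀-transformed before testing; zeros are replaced by
half the species' minimum positive value (the documented default
missing/zero handling of the web tool the lipidomics field commonly uses).
Scaling choices do not affect t. "Increased in CD" means BH-adjusted
P < α (default 0.05) *and* positive log₂ fold change; both tails are
always tested.

## Rank-order score, ROC and cutoff

Panel species are ranked 1…N (ascending concentration) with mid-ranks for
ties, chosen so each species' rank sum is exactly N(N+1)/2 — a testable
invariant; totals are the row sums. The AUC is the Mann–Whitney pair
statistic with ties counted ½, identical to the ROC trapezoid; its P value
tests AUC = 0.5 through the tie-corrected normal approximation of U (an
exactness-testable choice on small cohorts, unlike the Hanley–McNeil
variance some GUI packages use — their printed P for the same AUC can
therefore differ while the AUC itself agrees).

The full-specificity cutoff is read as the operating point with
specificity exactly 1 and maximal sensitivity, reported as an *attained*
case score: the smallest case total strictly greater than every control
total. This matches the worked example's integer cutoff (78 out of a
5-species, 23-subject score range 5…115). If no case exceeds all controls
the result is an empty outlier set with sensitivity 0. The packaged
23-subject table is a synthetic stand-in: the original per-subject list
exists only as a figure, so a score vector was constructed that satisfies
every printed summary of that cohort (group sizes, rank-sum consistency,
AUC 0.7992, cutoff 78, 6/11 outliers) and is clearly labelled as such.

## Metagenome quantification and filtering

Per-genome abundance is best-hit read count divided by genome length;
clade abundance at levels L2…L7 is the sum over member genomes, then each
level's columns are renormalised to relative abundance. Child clades
therefore sum exactly to their parents (hierarchical conservation, tested).

Features are removed when (a) detected in under 20% of samples, (b)
detected in no case sample or no control sample, or (c) — taxa only —
their mean relative abundance is below 0.001% (1e-5). "Detected" means
strictly positive; rule (b) is read as absence from *all* samples of either
group. The filter is idempotent. Two further exclusions from the original
workflow have no stated criterion and are exposed as optional switches,
default off: an external clade allow-list (batch-effect control against
prior cohorts, no cohort data shipped) and PCA-based sample exclusion
(beyond k·SD on PC1/PC2, default k = 6).

ORF abundance is mean per-base coverage over a 0-based half-open interval;
gene abundance sums its annotated ORFs and is normalised by the sample's
total ORF depth over all ORFs, annotated or not (scale invariance per
sample is tested).

## Transforms

Box-Cox: y^(λ) = (y^λ − 1)/λ, natural log for |λ| < 1e-6; λ maximises the
normal profile log-likelihood over [−3, 3] by bounded scalar optimisation,
checked in tests against a dense grid. Zeros are shifted by half the
feature's minimum positive value before transforming; the shift is
recorded per feature. λ for Normal-shaped data of low coefficient of
variation is weakly identified, so recovery claims are made about the mean
of λ̂ over replicates, not single draws.

RINT: value → Φ⁻¹((r − 3/8)/(n + 1/4)) with mid-ranks, the Blom offset.
Output is standard-normal-like (KS distance < 0.05 for n ≥ 500 tested).

## Association model and significance threshold

Each transformed feature is regressed on an intercept, case status, sex,
age and the top k principal components (default 15) of the transformed
feature matrix; the case coefficient's two-sided t-test on n − p residual
degrees of freedom gives β, SE, P. The direction — abundance as response,
Gaussian identity link — is chosen because the transforms normalise the
abundances, not the phenotype; a logistic alternative (phenotype ~
abundance + covariates) is available behind `family="logistic"` for
sensitivity analysis.

The family-wise threshold is empirical: phenotype labels are permuted
across samples with covariates fixed to their samples (breaking both
feature–phenotype and covariate–phenotype association under the null),
the per-iteration minimum P is recorded, and −log₁₀(P_sig) is the
Harrell–Davis estimate of the 95th percentile of −log₁₀(P_min):

    HD_q(x) = Σᵢ wᵢ x₍ᵢ₎,   wᵢ = I_{i/n}(a,b) − I_{(i−1)/n}(a,b),
    a = (n+1)q,  b = (n+1)(1−q),

with I the regularised incomplete beta function; the weights telescope to
1. The CI is a seeded percentile bootstrap (resample min-P, re-estimate,
2.5/97.5 percentiles; default 2,000 resamples). Permutations are computed
in one batched least-squares pass (features and permuted labels projected
off the covariate space once), which is what makes 500-replicate FWER
simulations tractable on one CPU.

Calibration properties verified by simulation: the threshold applied to
fresh null cohorts rejects at 0.05 ± 0.02 (500 replicates × 1,000
permutations × 30 features), and for m independent null features the
estimate matches the closed form −log₁₀(1 − 0.95^(1/m)) (m ∈ {1, 10, 50}).
Per-feature significance is declared against this family-wise threshold,
not by BH.

## Gene-set enrichment

Genes are sorted by β descending. For a set S, hit steps are |β|/Σ_S|β|
(weight exponent 1, the default of the enrichment tools this mirrors),
miss steps −1/(N−|S|); the ES is the running sum's maximum signed
deviation. Sets with fewer than 50 or more than 30,000 resolvable genes
are excluded after unresolvable ids are dropped (and counted). P values
come from a gene-label permutation null, two-sided on |ES| — the tool the
procedure mirrors does not state sidedness, so two-sided is this package's
commitment — with BH across retained sets.

## Diversity

Shannon H = −Σ p ln p (natural log, the vegan convention). Rarefaction is
seeded multinomial subsampling to a common depth — an approximation of
without-replacement subsampling that is accurate while depths are well
below totals — and every sample must reach the requested depth.
Bray–Curtis is Σ|x−y|/Σ(x+y); an all-zero pair is defined as distance 0
with a warning. PERMANOVA computes the pseudo-F from squared inter-point
distances (between/within decomposition) with freely permuted labels and
P = (1 + #{F* ≥ F})/(1 + n_perm); it matches exhaustive enumeration of the
20 balanced assignments at n = 6.

## Synthetic cohorts: what they emulate, and what they do not

Lipid cohort: log₂ concentration = baseline + planted case shift + Gaussian
noise, exponentiated (log-normal); defaults follow the study shape —
12 HC vs 11 CD, 529 species, 15 planted effects of log₂FC 2 with
log₂-scale SD 0.25 (chosen so planted species are clearly but not
trivially separable at n = 23), optional zero inflation.

Metagenome cohort: latent per-genome log₂ relative abundances are Gaussian
(spread SD 2, within-group SD 1), shifted in cases on the planted genomes,
softmax-normalised and sampled as multinomial counts at a per-sample depth
of 10⁵ reads — a desk-scale stand-in for real sequencing depths, large
enough that count noise is minor at 200 genomes. The default panel is 200
genomes nesting deterministically into a 7-rank taxonomy (genera of 2,
families of 3, orders of 6, classes of 12, phyla of 24 genomes): wide
enough that the top-15 PCs average over many features rather than aliasing
a single strong-effect clade, which is also why the end-to-end recovery
simulations use this size. Gene tables carry two ORFs per synthetic gene
plus an unannotated background pool; sex is Bernoulli(0.5) and age
Normal(45, 10) truncated at 18, with an optional case shift in years to
exercise covariate adjustment. All generators draw from named
`SeedSequence` substreams of one master seed, so outputs are bit-identical
across runs and independent of call order.

Not emulated: read-level error, real taxonomic correlation structure,
overdispersion beyond the log-normal-multinomial compound, batch effects,
missing covariates. Passing simulations therefore demonstrate correctness
and calibration of the statistics under a clean compositional model, not
robustness to every artefact of real sequencing data.

## Problem sizes and numerical choices

Default simulation sizes (500 FWER replicates at 30 features and 1,000
permutations; 4,000 permutations for closed-form checks; 20 end-to-end
pipeline replicates at 200 genomes) were chosen to keep Monte-Carlo error
comfortably inside the stated tolerances while remaining desk-scale.
Ties in ranks use mid-ranks throughout. Permutation P values are never 0
by construction ((1+exceed)/(1+n)). Floats are serialised at 12
significant digits so pipeline reruns are byte-identical; the manifest
hash covers output bytes only, not wall-clock runtime.

## Known limitations

- The logistic model direction fits one feature at a time and is slow for
  large gene tables; it exists for sensitivity analysis, not production.
- The ROC P value uses a normal approximation; for n < ~10 per group an
  exact permutation test would be preferable.
- PERMANOVA permutes freely; no strata/blocking support.
- No strain-level analysis, no mixed models, no KEGG topology, and no
  NMDS embedding (ordination is visualisation, not inference).
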