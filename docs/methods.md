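# Methods

This note documents the statistical models, numerical choices and known
limitations of `fstatkit`. It is written for a reader who knows the
population-genetics background and wants to know exactly what this
implementation does.

## Data model and conventions

Genotypes are alt-allele counts in {0, 1, 2} with −1 for missing; the
EIGENSTRAT text format counts reference alleles, so values are flipped at the
I/O boundary (`alt = 2 − ref_count`). Pseudo-haploid individuals carry one
sampled allele coded as 0/2; in frequency estimation such a genotype
contributes **one** allele observation (count 1), because the 0/2 code is a
haploid draw and counting it twice would understate the sampling variance of
the frequency. Coordinates are 1-based; SNPs must be grouped by chromosome
and position-sorted within it.

Merging intersects datasets on (chromosome, position), flips genotypes where
the ref/alt pair is exchanged, drops and logs incompatible allele pairs, and
canonicalizes the merged allele order (lexicographically smaller allele as
reference) so that `merge(a, b)` and `merge(b, a)` agree exactly.
Strand-ambiguous A/T and C/G sites are kept by default (a flag drops them);
ambiguity only matters when strand flips are plausible, which the simulator
never produces and which callers can decide for real data.

In pseudo-haploid calling, a base matching neither allele of the target SNP
yields a missing genotype. The behavior of the field's standard caller in
this corner is not documented; emitting missing is the conservative choice
and is flagged here rather than presented as that tool's behavior.

## f-statistics and the block jackknife

All statistics are ratios of per-site terms in sample allele frequencies
(complete cases per statistic: a site is used when every involved population
has ≥ 1 observed allele). D and f4 are unbiased in sample frequencies and
use none of the small-sample corrections; f2/f3 offer an optional
heterozygosity correction (`h = p(1−p)·n/(n−1)`, subtracted as `h/n` per
population for f2, for the target in f3), off by default so that corrections
are never silently applied.

Blocks span at most 0.05 morgans when a usable genetic map is present
(non-negative, nondecreasing within chromosomes, positive total span),
otherwise 5 Mb of physical distance; a new block starts at every chromosome
boundary. These defaults reproduce the conventions of the standard
ADMIXTOOLS workflow this package emulates.

Standard errors use the weighted delete-one-block jackknife (Busing, Meijer
& van der Leeden 1999) with block weights proportional to usable SNP counts:
with `g` blocks, weights `m_j`, `n = Σ m_j`, `h_j = n/m_j`, whole-data
estimate `θ` and delete-one estimates `θ_j`,

    θ_dot = g·θ − Σ_j (1 − m_j/n)·θ_j
    var   = (1/g) Σ_j (h_j·θ − (h_j − 1)·θ_j − θ_dot)² / (h_j − 1)

which reduces exactly to the textbook delete-one formula under equal
weights (a frozen acceptance check). A degenerate total denominator (no
polymorphism pattern) raises rather than returning 0/0. Statistics carry a
soft flag when usable SNPs fall at or below the 30,000-site reporting
threshold; values are still returned for inspection.

## Permutation tests

Two individual-relabeling schemes address the worry that a population-level
D-statistic is driven by one individual. The exhaustive scheme rotates each
member of a small cohort into the anchor's slot (with or without the anchor
joining the remainder); the random scheme redraws the smaller group of two
pooled cohorts uniformly without replacement, by default 1000 times, with
repeats allowed (deduplication would distort the sampling null). The
empirical P counts the identity grouping in both numerator and denominator —
`P = (1 + #{D_perm ≥ D_obs}) / (n_perm + 1)` — matching the 1001 denominator
convention and guaranteeing P > 0; ties count toward the numerator ("equal
to or greater"). Whether the original convention literally included the
identity run in the numerator is not documented; the inclusive convention is
recorded in the result object. Permuted statistics are plain ratio
estimates on their own usable-site sets; jackknife SEs play no role in the
empirical P.

## f4 matrices, rank tests, qpAdm

The f4 matrix `X[i, j] = f4(L0, Li; R0, Rj)` is computed on the intersection
of sites usable in **all** left and right populations (the classical
default of the tools this emulates; a per-cell mode was considered and
rejected as a default because mixing site sets breaks the single covariance
weighting). Its covariance is the multivariate analog of the weighted
jackknife above, symmetrized and PSD by construction.

The rank-r test minimizes `vec(X − AB)ᵀ Q⁻¹ vec(X − AB)` by alternating
generalized least squares (each of A given B, B given A is a linear GLS in
the whitened metric), initialized from the SVD of X, iterated until the
chi-square changes by < 1e-10 relative, with an iteration cap that raises a
diagnostic error (AWLS decreases the objective monotonically; the cap has
not been reached in any test). The statistic is referred to chi-square with
`(n_left − 1 − r)(n_right − 1 − r)` dof. When the jackknife covariance is
numerically singular, a ridge of `1e-5 ×` the mean diagonal is added with a
warning — small panels make Q ill-conditioned and silent failure would be
worse than a slightly conservative test.

qpAdm fits rank `k − 1` to the `k × (n_right − 1)` matrix with left =
(target, k sources). The mixture weights are the left null vector of the
fitted matrix scaled to sum to one (for the fitted rank-deficient matrix the
null vector is exact; a null-vector sum near zero raises a degeneracy
error). The model-fit p is the rank test at `r = k − 1` (dof
`n_right − k`); with one source this degenerates to the rank-0 cladality
test. Weight SEs re-estimate the whole weight vector on every delete-one
block replicate (warm-started from the full-data factors, with the
full-data whitener held fixed) and apply the weighted-jackknife variance per
coordinate — a full jackknife rather than a linearization, consistent with
the jackknife-everywhere architecture. Infeasible weights (outside [0, 1])
are flagged, never clipped or suppressed. The left base is the target and
the right base is the first listed outgroup; rank-test invariance to
reordering the remaining rights is covered by a test.

Basal-ancestry estimation is the standard deep-proxy trick: model the target
as proxy + non-basal source against outgroups that are all crown Eurasians
(no Africans, no basal-carrying West Eurasians). Because the proxy and the
true basal lineage are both outside the crown, every f4 involving only crown
outgroups cannot tell them apart, so the proxy's weight estimates the basal
fraction. The composed prediction multiplies an admixture leg by the
source's own α; its SE is first-order propagation under independence
(`sqrt(p²σ_α² + α²σ_p²)`), a documented simplification — the two estimates
come from different fits but share data.

## PCA projection

Components come from the SVD of the fitting panel's normalized matrix:
per-SNP centering by the panel mean genotype `2p̂` and scaling by
`sqrt(p̂(1 − p̂))` with `p̂ = mean/2`; monomorphic SNPs are dropped and
residual missingness (completeness below a configurable threshold raises) is
mean-imputed. Projection solves ordinary least squares of a sample's
normalized non-missing genotypes on the loadings restricted to those SNPs;
for a complete-data panel member this reproduces its fitted score exactly.
No shrinkage correction for projection bias is applied — a known limitation
shared with the plain least-squares projection this mirrors.

## The synthetic-data generator

Frequencies evolve on a rooted admixture graph: root frequencies uniform on
(0.05, 0.95) (truncated so fixation does not dominate small-drift edges),
Balding–Nichols Beta transitions with mean p and variance `p(1−p)F` per
drift edge, mixture frequencies `λ·A + (1−λ)·B` at admixture nodes (chained
for three-way mixtures). Genotypes are Binomial(2, p); pseudo-haploid
individuals keep one uniformly drawn allele coded 0/2; per-site missingness
is Bernoulli `exp(−coverage)` — the zero-read class of a Poisson read-count
model, which reproduces the sub-1× to ~3× capture regime qualitatively.
Sites are laid out on 22 chromosomes at 28 kb spacing with a uniform
1 cM/Mb map, giving ~560 jackknife blocks at 100k SNPs.

Balding–Nichols drift was chosen over coalescent simulation deliberately:
allele frequencies are sufficient statistics for every estimator in the
package, the moments are exact and testable, and it is orders of magnitude
faster. The price is realism the estimators do not consume: no linkage
disequilibrium within blocks, no site-frequency-spectrum realism, no
sequencing error or reference bias, and missingness independent across
sites. Passing tests therefore validate the estimators under the model's
own assumptions, not robustness to those artifacts of real data.

The four registered scenarios fix true mixing proportions at the published
point estimates they emulate (0.897; 0.787; 0.258/0.629/0.113; basal α
0.248 and 0.385) with cohort sizes and coverages mirroring the study regime
(one 2.9× pseudo-haploid hunter-gatherer, five 0.7–1.5× farmers, 25 later
farmers, a 0.16× and a 0.75× Levantine, modern diploid panels of 10).
Branch drifts were set once, on two grounds: leaf and minor internal edges
at F = 0.005–0.05 (the typical post-divergence drift scale of Holocene
panels), and the stems separating the admixture **sources** at F = 0.04–0.08,
matching the deep divergence of the real source lineages (European
hunter-gatherer vs Near-Eastern Fst is of order 0.1). The deep stems are
also what makes the models identifiable — the method's own prerequisite
that the outgroups distinguish the sources; with shallow stems the qpWave
prerequisite itself fails, which is a property of the design, not of the
estimator. In the basal scenario the basal lineage diverges before the
crown radiation, the African proxy sits outside both, and the outgroups
(three eastern non-Africans plus three early Eurasian singletons) are all
crown — making the proxy's weight identify α exactly in expectation.

At these design points the estimators reproduce the study's precision:
two-way weight SEs of 0.03–0.04 and three-way SEs of 0.05–0.08 at 100k
SNPs, with basal α noisier (SE ≈ 0.07–0.10) exactly as the real analysis is.

## Problem sizes and determinism

Calibration tests use 200 replicates (permutation uniformity at n_perm = 99;
rank-test uniformity at 20k SNPs), 500 replicates for the null-f4 star
phylogeny at 12k SNPs, and 100 replicates of 100k SNPs per scenario for
parameter recovery — sizes chosen so the whole suite runs in minutes on one
core while keeping binomial/KS resolution. The acceptance script averages
24 replicates of 100k SNPs per scenario. Every stochastic routine takes an
explicit seed or Generator; the pipeline derives per-stage seeds by stable
hashing of the stage name so runs are byte-reproducible and stages are
independent of which others are enabled. No multiple-testing correction is
applied across D-statistic batches (raw Z values are reported, as in the
workflow emulated); reports note this.

## Known limitations

* Frequencies, not genotyped reads: no damage, contamination or reference
  bias modeling (out of scope).
* The f4-matrix covariance is estimated from the same blocks it whitens;
  rank-test p-values are asymptotic and slightly liberal/conservative at few
  blocks (calibration is verified at ~560 blocks).
* `compose_alpha` assumes independence of its two inputs.
* The intersection SNP policy discards sites missing in any involved
  population; with many low-coverage populations the usable set shrinks
  (the 30k reporting flag makes this visible).
* PCA projection exhibits the usual attenuation of missing-data samples
  toward the origin at extreme missingness; the masking test bounds it only
  at 50%.
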