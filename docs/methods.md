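# Methods

This note documents the models, conventions, and numerical choices behind
`facesym`, and what the simulation-based tests do and do not establish.

## Object-symmetry asymmetry scores

**Model.** A structure with internal (object) symmetry — midline landmarks
plus mirrored left/right pairs — is compared with its own reflection. The
reflection negates the left–right coordinate axis and swaps the labels
within each landmark pair, so a perfectly symmetric configuration maps to
itself. Originals and reflected copies of all *n* individuals enter one
joint generalized Procrustes analysis (GPA): every configuration is
centered, scaled to unit centroid size, and rotated by the least-squares
(Kabsch) rotation onto an iteratively refined consensus. Reflections are
never allowed in the rotation step (determinant +1), so handedness is
preserved and the reflected copies remain genuinely "mirrored" relative to
the originals.

Individual *i*'s asymmetry vector is the flattened difference between its
aligned original and aligned reflection. TA is its Euclidean norm, DA the
sample mean vector, FA the norm of the deviation from DA. These are
small-deviation Procrustes distances in the aligned coordinate space; no
tangent-space projection is applied beyond the superimposition, and the
original-minus-reflection difference is not halved. Published
object-symmetry scores that include such factors are monotone
transformations of ours, so correlations and significance tests are
unaffected; the convention here is chosen for exact reproducibility.
Including the reflected copies in the consensus (standard object-symmetry
practice) makes the consensus symmetric in the limit and the decomposition
well defined.

**Numerics.** GPA initializes the consensus at the first configuration,
stops when the root-mean-square consensus change falls below `1e-10`
(`max_iter=100`, typically 4–6 iterations), and returns a `converged` flag
plus the per-iteration objective, which is provably non-increasing (both
steps are exact coordinate-descent minimizers; the consensus constrained to
the unit sphere is the renormalized mean). Degenerate rotation targets
(rank < 2) yield the identity with a warning. SVD sign ambiguities in the
rotation are resolved by the standard determinant correction on the smallest
singular vector; remaining ties are broken by the deterministic LAPACK SVD.

Because each individual is scaled to unit centroid size, scores are
dimensionless shape units. Arbitrary per-individual rotations, translations
and positive scalings of the input are removed exactly (verified to 1e-8
relative in the tests).

## Homozygosity by loci

`HL = ΣE_h / (ΣE_h + ΣE_j)` with `E = 2p(1−p)` per biallelic locus.
Frequencies are plug-in estimates from the analyzed cohort itself (an
optional `2n/(2n−1)` small-sample correction is available but off by
default, matching common HL implementations); the `HomozygosityByLoci`
estimator separates frequency estimation (`fit`) from scoring
(`transform`), so a reference cohort's frequencies can be applied to new
individuals, and per-group estimation is possible by fitting per group.
Missing genotypes are simply dropped per individual (no locus-set
harmonization); `n_loci_used` is reported so downstream filters can be
applied. Monomorphic loci carry zero weight automatically. Percentile
summaries use linear interpolation between closest order statistics.

## Association models

**GLM.** Treatment coding throughout: sex male vs female, second cohort
label vs first, and per SNP two indicators (genotype 1 vs 0, 2 vs 0; if
genotype 0 is unobserved the lowest observed class becomes the reference,
with a warning). Fits go through statsmodels OLS; standard errors use the
unbiased residual variance and p-values the t distribution with residual
degrees of freedom. Rank-deficient designs are refused with the collinear
terms named (pivoted QR). Complete-case analysis per model, with the
dropped count logged.

**Interaction pruning.** Only the three pairwise interactions among sex,
age and HL are candidates. The procedure refits repeatedly, removing the
candidate with the largest p-value while it exceeds `alpha` (default 0.05),
one at a time. "Stepwise" is under-determined in general; largest-p-first
with refitting is the choice here, cross-checked in the tests against an
independently coded implementation of the same rule on null data.

**ANOVA tree.** Recursive binary partitioning with the CART ANOVA rule: at
each node, every locus is scanned over the non-redundant binary partitions
of its observed genotype classes (three partitions when all of {0,1,2} are
observed), and the split maximizing the sum-of-squares reduction is
accepted if the improvement is at least `cp · SS_root` (default `cp=0.01`),
the node has at least `minsplit=20` individuals, and both children at least
`round(minsplit/3)`. Individuals missing the split locus follow the
majority branch (no surrogate splits); the routed count is recorded per
node. Ties prefer the lowest locus index, then the partition enumeration
order, making fits deterministic. There is no cross-validation pruning —
the `cp` gate is the only complexity control, which is the relevant
behavior for the null/planted-signal questions this package answers, and
the split search is verified against exhaustive enumeration in the tests.
Note that the null probability of an accepted split depends on `n`: with
~300 candidate partitions, the largest null improvement is roughly a
max-of-chi-square and exceeds `0.01 · SS_root` routinely below n ≈ 1000,
while at n ≥ 2000 null trees are root-only in the large majority of runs.

p-values are never multiplicity-adjusted in the tables; genome-wide
significance (default `P ≤ 1e-8`) is a separate per-term flag.

## Synthetic cohorts

The generator emulates the statistical structure the analysis assumes, with
defaults fixed at the study conditions: n = 3215 individuals, ages
truncated-normal 59.5 ± 8.0 on [45, 92] years, two cohort waves in
proportions 0.768/0.232, male fraction 0.45 (not reported for the original
cohort; chosen once as typical for an elderly population cohort), and 102
independent biallelic SNPs with frequencies drawn Uniform(0.1, 0.9) unless
supplied (avoiding near-monomorphic loci where HL is ill-conditioned).
Genotypes follow the inbreeding-coefficient model
`P(het) = 2p(1−p)(1−F)`, with `F = 0` by default. Ages are sampled by the
exact inverse-CDF truncated-normal sampler (scipy), which is equivalent to
rejection sampling without discarding draws.

Faces are built on a symmetric nine-landmark template (millimetre scale,
centroid size ≈ 157 mm): template + symmetric Gaussian shape deviation
(`sym_sigma = 2` mm) + half the asymmetry field, where the asymmetry field
is the planted DA plus an isotropic Gaussian draw projected onto the
antisymmetric subspace and scaled by the individual's FA scale
`sigma_i = fa_sigma0 + beta_hl·HL_i + beta_snp[g_i] + beta_male·male_i +
beta_age·(age_i − mean)`. The half factor makes the
original-minus-reflection difference equal the planted field exactly.
Defaults `fa_sigma0 = 0.1` mm and `noise_sigma = 0.01` mm give FA scores
≈ 0.0019 Procrustes units, and the default planted DA (a lateral nose-tip
shift) has norm `0.05 · fa_sigma0` — the small-DA regime in which TA and FA
are nearly redundant. Each stage draws from an independently seeded random
stream, so switching the nuisance transforms on or off does not perturb the
other draws, and a fixed seed reproduces every output bit for bit.

**A useful closed form.** The antisymmetric subspace of 3 pairs + 3
midline landmarks has dimension 12; the joint GPA absorbs 3 of these
directions (left-right translation and the two rotations tipping the
midline plane), leaving 9 effective dimensions. An isotropic antisymmetric
Gaussian of scale `sigma` therefore yields
`E[FA] = sigma · E[chi_9] / CS` with `CS` the template centroid size, and a
planted HL effect `beta_hl` induces an FA-on-HL slope of
`beta_hl · E[chi_9] / CS`. This is the independent oracle used in the
parameter-recovery tests.

**What the generator does not emulate:** linkage disequilibrium between
loci, landmark-wise heteroscedastic measurement error, age- or sex-related
mean-shape differences, ancestry structure, or non-Gaussian asymmetry.
Passing tests therefore demonstrate correctness of the estimators under the
stated model, not robustness to those real-data features.

## Problem sizes in the test suite

Simulation-backed checks use sizes chosen to make Monte-Carlo error small
relative to the tested effect while keeping the default suite quick:
TA–FA coupling at n = 3000; DA recovery over 20 cohorts of n = 2000
(compared with a noiseless-pipeline reference, within 3 Monte-Carlo SEs);
HL-slope recovery over 200 cohorts of n = 1000 against the closed form
above; HL-term type-I error over 1000 null fits of n = 400 (score-space
responses, which preserve the chi-type FA distribution without re-running
GPA); and null association behavior over 100 cohorts of n = 2000 (where the
`cp` gate is informative, see above).

## Known limitations

* Scores are full-Procrustes small-deviation distances; for very large
  asymmetries (far outside the facial range) the linear-tangent reasoning
  behind the FA/DA decomposition degrades.
* The tree's missing-data policy (majority branch) is simpler than rpart's
  surrogate splits; with heavy genotype missingness the two can differ.
* HL with few loci is coarse: with 102 markers individual HL has
  substantial sampling noise around genome-wide homozygosity, which caps
  the attainable power of any HL–FA regression.
* The GLM assumes homoscedastic errors, whereas chi-type FA scores are mildly
  heteroscedastic under planted effects; at the cohort sizes used the
  resulting t-test size distortion is negligible (verified empirically).
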