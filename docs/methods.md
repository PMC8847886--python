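# Methods

This note documents the statistical model, the preparation stages, the
permutation scheme, the synthetic-cohort generator, and the numerical and
design choices behind `conncca`.

## Views and preparation stages

The analysis relates two per-subject views: a connectivity view (edges of a
node-by-node functional network matrix) and a phenotype view (subject
measures, SMs). Both are reduced to d-dimensional score matrices before the
CCA; d defaults to 70 at production scale and 30 at desk scale (results of
this family of analyses are known to be stable down to ~30 components).

**SM side (S₁…S₅).** Raw SMs are first screened by three quantitative
criteria applied in order (≥50% of subjects observed; <95% of observed
values identical; no extreme outlier, defined as max(Y) > 100·mean(Y) for
Y = (X − median(X))²). Note the outlier rule is scale-dependent: since
max(Y)/mean(Y) ≤ n, it can only fire in cohorts of more than 100 subjects.
Kept SMs are Gaussianized by the rank-based inverse normal transform with
the Blom offset, Φ⁻¹((rank − 3/8)/(m + 1/4)), average ranks for ties —
the transform is rank-invariant, so any monotone re-expression of an SM
yields identical output. Twelve confound regressors are then projected out
of each column over its observed rows (intercept included, which subsumes
demeaning): 7 base confounds (site, scanner, mean framewise displacement,
weight, BMI, cube-root brain and intracranial volumes) demeaned with
missing values imputed to the mean, plus the demeaned squares of the five
quantitative ones. Categorical confounds are expanded to one-of-K indicator
blocks (last level dropped against the intercept) but count as one logical
confound and are never squared. Missing data are never imputed in the SMs
themselves: the subjects-by-subjects covariance is estimated one SM at a
time over pairs of subjects that both observe it, completed to the nearest
symmetric positive-definite matrix by eigenvalue clipping (floor
1e-10 × largest eigenvalue, doubled until Cholesky succeeds — for symmetric
input this is the Frobenius-nearest PSD matrix up to the floor), and the
top-d eigenpairs give subject scores u_k√λ_k. Downstream canonical
correlations are invariant to that √λ scaling (CCA is invariant to any
invertible linear recombination of a view); the scaling is kept so the
score Gram matrix approximates the covariance.

**Connectome side (N₀…N₅).** Per-subject partial correlation netmats are
estimated from T×N node time series by inverting the ridge-regularized
sample covariance: the covariance is rescaled by its mean diagonal so the
regularization weight rho (default 0.01) is scale-free, and
r_ij = −P_ij/√(P_ii P_jj) from the inverse P. Values are Fisher
r-to-z transformed (|r| capped at 1 − 1e-15 first) and half-vectorized in
row-major upper-triangle order (edge k ↔ node pair (i, j), i < j; 19 900
edges at 200 nodes). Two normalized copies of the resulting N₀ are built:
N₁ (column-demeaned, globally variance-normalized) captures additive edge
variation; N₂ divides each column by |column mean| — emphasizing
proportional variation — and drops columns with |mean| < 0.1, since
division by a near-zero (possibly signed) mean is unstable for z-valued
edges. Their concatenation is deconfounded and reduced by truncated SVD.

## CCA and inference

The fit is the classical whitened cross-covariance SVD (the `canoncorr`
algorithm): orthonormalize each centred view (SVD-based, rank-truncating
with a warning when a view is degenerate), take the SVD of Q_xᵀQ_y, and map
singular vectors back through the whitening transforms. Canonical variates
are unit-variance with mutually uncorrelated columns, and
corr(U_k, V_k) = r_k, the k-th singular value. Each mode's sign is fixed
deterministically (largest-|entry| of the SM-side demixing column positive
at fit time; re-anchored after fitting so the strongest SM correlation is
positive, which makes the positive–negative axis orientation reproducible
across runs and cohorts).

**Restricted permutations.** The exchangeability structure has two layers:
within a family, members holding the same role (MZ co-twins, DZ co-twins,
non-twin siblings) may exchange; across families, whole families whose
multiset of roles ("signature") is identical may exchange, with singles
forming one signature group. A lone MZ/DZ twin (no same-type co-twin in the
family) is demoted to a non-twin sibling with a warning. Every valid
permutation factors uniquely into these layers, so sampling each layer
uniformly and independently samples the group uniformly — verified by
enumeration and χ² on toy pedigrees.

**Permutation null.** Only the SM-side rows are permuted; per permutation
the CCA is re-fit and canonical correlations plus per-mode variance
explained are recorded. Because permuting the rows of a centred matrix
permutes its orthonormal basis rows identically, each permutation costs one
small d×d SVD rather than a full re-fit. One correction proved necessary:
both prepared views are residualized against the same confounds, so the
observed pair lives in the (n − p − 1)-dimensional constrained space while
a plainly row-permuted view sits in general position. That deflates the
null and inflates the type-I error badly when p is not negligible against n
(rejection rate 0.25 instead of 0.05 at n = 120 with 16 confound columns).
The null therefore re-applies the confound projection to the permuted
SM-side scores before re-fitting (a Freedman–Lane-style re-residualization,
equivalent to re-running the preparation's deconfounding step on each
permuted SM matrix). After the correction the test is exactly calibrated:
rejection rate 0.05 at α = 0.05 over 100 null cohorts, p-values
indistinguishable from uniform (KS p = 0.32). The PCA step is not
recomputed per permutation; it is a fixed linear map and does not affect
validity. The same projection is applied in the cross-validation and
per-SM axis permutation nulls.

Familywise error uses the max-statistic: the null of the first (largest)
canonical correlation calibrates every mode, p_k = (1 + #{max-r ≥ r_k}) /
(1 + P) — the (1+b)/(1+P) convention avoids zero p-values. Per-mode
variance-explained nulls are taken at the matched mode index (the pooled
alternative would mix the strongly ordered mode spectra); z = (observed −
null mean)/null sd, and 5th/95th null percentiles bound the significance
bands.

**Variance explained.** ve_k = Σ_j r²(weight_k, col_j)·var(col_j) /
Σ_j var(col_j) with missing entries skipped pairwise — the fraction of a
matrix's total variance captured by rank-1 regression of each column on the
mode's subject weights. The SM side is anchored on S₂ (Gaussianized,
pre-deconfounding) and the connectome side on raw N₀; a flag could anchor
the SM side on S₃ instead, but S₂ is the default as the closer analogue of
"the original SM matrix". Because the U columns are uncorrelated, Σ_k ve_k
≤ 1 per view.

**Replication criteria.** A primary mode must (1) exceed the 95th null
percentile of variance explained in both views (ties between candidates
broken by the larger SM-side z); (2) have z-scores at least 2× (connectome)
and 3× (SM) the next-best mode's; (3) have a familywise-corrected weight
correlation p below α = 0.001. Note criterion 3 is only resolvable when the
permutation count exceeds 1/α — the smallest achievable p is 1/(P+1), so
the desk default P = 500 cannot certify p < 0.001 and the acceptance script
uses P = 2000 for the planted run.

## Post hoc analyses

The positive–negative axis correlates each column of the deconfounded *raw*
SM matrix (including any SMs deliberately held out of the CCA, flagged in
the output) with the primary mode's SM-side subject weights. Per-SM percent
variance uses the projection formula variance(V₁·pinv(V₁)·s)/variance(s),
which for demeaned vectors is algebraically 100·r² (asserted to 1e-8 in
tests); it is computed by the formula, not the shortcut, to stay faithful
to the published expression. Per-SM z-scores come from the family
permutation null of r by default (a Fisher-transform alternative,
atanh(r)·√(m−3), is available via flag; the permutation version is the
default because it respects the familial dependence).

Edge-level mapping correlates the primary connectome variate U₁ with every
raw N₀ column, yielding the full-length edge-weight vector; the top-K
(default 30) edges are ranked by |weight| with deterministic ties broken by
edge id, and the vector is also correlated against the half-vectorized
group-mean partial netmat. Node clusters come from Ward linkage on
Euclidean distances between rows of the group full-correlation netmat
(k configurable, default 4), with optimal leaf ordering for deterministic
display.

## Cross-validation

Whole families are assigned greedily (largest first, randomized among equal
sizes) to the training set until its count would exceed the 80% target, so
the achieved fraction is within one family of the target and no family ever
spans both sets. The default test-side convention re-estimates the
deconfounding and PCA on the test subset — the literal published procedure —
with one necessary addition: a data subset's principal components carry
arbitrary signs (and subject-space eigenvectors cannot be sign-matched
across disjoint subject sets directly), so each test component is
sign-aligned to its training counterpart through feature space (SM-space
loadings S₃ᵀu_k on the SM side; the shared N₁ block of the right singular
vectors on the connectome side). A strict-generalization mode instead
applies training betas, normalization constants, and bases unchanged to the
test rows (the SM-side feature basis is the least-squares map from
zero-filled deconfounded SMs to training scores). Held-out weights are
U_test = N₅,test·A_train and V_test = S₅,test·B_train; the first-mode
correlation is calibrated per repetition against permutations of the test
SM-side weights within the test set's own family blocks (two-sided, since
subset-PCA sign alignment makes the sign meaningful but a two-sided test is
the conservative contract), and the split/test/permute cycle repeats 10
times by default.

## The synthetic cohort generator

The study this pipeline targets is observational and publishes no
generative model, so the generator's distributional choices are artifact
decisions, made once:

* **Families and scores.** Counts default to 25 MZ pair families, 25 DZ, 25
  two-sibling families and 150 singles (300 subjects) — a desk-scale cohort
  preserving the real data's mix of family types with familial share large
  enough to exercise the restricted permutations. Latent scores use the
  shared/unique construction score = √ρ·family + √(1−ρ)·unique with
  ρ_MZ = 0.8 ≥ ρ_DZ = 0.5 ≥ ρ_sib = 0.4 (ballpark twin-study heritability
  ordering for cognitive scores), giving exactly the target co-twin
  correlation in expectation and standard normal marginals.
* **SMs.** Twelve of 40 SMs load on the planted mode at 0.7 with
  alternating signs (so the recovered axis must get signs right); every SM
  receives a common confound component (standardized quantitative confounds
  weighted 0.2 each) and N(0, 0.7²) noise, yielding per-SM score
  correlations ≈ 0.7 — strong but realistic for summary cognitive measures.
  2% of entries are missing completely at random (the real table's
  missingness is of that order). Four pathological columns are appended in
  fixed trailing positions (constant; 96% identical; one extreme outlier;
  60% missing) so the quantitative filter is exercised deterministically.
* **Connectomes.** Subject i's node time series are drawn from a zero-mean
  Gaussian with precision Ω_i = Ω_base − score_i·Λ, so ridge partial
  correlation is the matched estimator. Ω_base is the identity plus a chain
  of −0.3 couplings (giving the group netmat nonzero structure so the N₂
  low-mean drop rule has survivors), and Λ places ±0.12 on 30 edges (a
  25-edge perfect matching plus 5 cross-pair edges), keeping ‖Λ‖₂ small so
  every subject's precision stays positive definite; if it would not, the
  whole loading set is scaled down uniformly (preserving linearity in the
  score) and an error names the offending subject if even that fails. At
  T = 750 the per-edge estimation noise (≈T^−½ ≈ 0.04) is well below the
  planted across-subject edge variation (0.12), giving an SNR at which the
  pipeline should — and does — recover the mode.
* **Motion.** Per-run FD is lognormal (median 0.1 mm, σ = 0.3) plus
  exponential spikes at 2% of time points, with an optional fraction of
  deliberately bad runs (shortened to 150 points or shifted +0.4 mm).

Everything derives from a single seeded RNG stream in fixed order, so an
identical spec reproduces the cohort bit for bit.

**What passing tests do and do not show.** The generator's Gaussian,
linear, single-mode world demonstrates correctness of the machinery —
calibration of the restricted permutation test, recovery of a mode that is
truly there, validity of the bookkeeping — not performance on real data. It
omits scanner/site batch structure beyond additive confounds, non-Gaussian
SM families, temporal autocorrelation in the node time series,
heritability of connectivity itself, and any model misspecification; real
effect sizes are also far smaller (held-out correlations of ~0.2 rather
than ~0.9).

## Problem sizes and runtime

Desk-scale defaults are chosen so the full pipeline runs in seconds and the
calibration studies in minutes on one CPU: 300 subjects / 50 nodes / d = 30
/ 500 permutations for the planted analysis (the acceptance script raises
P to 2000 to resolve the p < 0.001 criterion), 100 cohorts of 120 subjects
/ 30 nodes / d = 10 / 200 permutations for type-I calibration, and 10
repetitions × 99–199 permutations for cross-validation. Production-scale
values (200 nodes, d = 70, 10⁵ permutations, 1000 CV permutations) are the
documented defaults of the corresponding functions and are reachable by
configuration.

## Known limitations

* The permutation group treats only the four roles MZ/DZ/SIB/SINGLE;
  arbitrary exchangeability trees (half-siblings, unknown-zygosity
  handling beyond the sibling demotion) are out of scope.
* The SM-side strict cross-validation basis is a least-squares
  approximation on zero-filled residuals; with heavy missingness the
  re-estimation mode is the safer choice.
* `nearest_spd` clips eigenvalues of the symmetrized input; for severely
  indefinite inputs the result is SPD but can be far (in Frobenius norm)
  from the original pairwise estimates — the before/after correlation is
  worth checking, as the pipeline does.
* The per-SM axis z-scores share one set of sampled permutations across
  SMs, which is efficient but induces slight dependence between the
  z-scores of correlated SMs.
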