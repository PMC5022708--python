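# Methods

This note records the models implemented in `quantmat`, the numerical and
design choices made where the underlying literature leaves them open, and
what the synthetic-data tests do and do not establish.

## Objects and conventions

The central object is a labeled p×p symmetric trait matrix with a declared
role, covariance or correlation. Loading symmetrizes entries when the
asymmetry is within 1e-8 (CSV round-trip noise) and rejects anything
larger; correlation matrices get an exactly unit diagonal; covariance
matrices must be PSD within 1e-10 of their trace. All binary operations
require identical label sets and order (a reorder-by-label helper is
provided). Eigendecompositions return descending eigenvalues and fix the
eigenvector sign gauge by making each vector's largest-magnitude entry
positive, which removes sign ambiguity from the constraints statistic and
subspace comparisons. Matrix log, exp and square root act on the spectrum
through the eigendecomposition; log and sqrt require strictly positive
eigenvalues.

Every stochastic operation takes an explicit seed, stream or numpy
generator; there is no global RNG, and equal seeds give bit-identical
results. Random selection gradients are standard normal draws normalized
to the unit sphere.

## Estimation

`calculate_matrix` regresses each trait on an intercept-plus-dummy design
of the requested factors and divides the residual cross-product by
n − rank(design); with no factors this is exactly the n−1 sample
covariance. The Bayesian estimator uses the conjugate inverse-Wishart
prior with scale Λ₀ = ν₀·diag(sample variances). The prior degrees of
freedom default to ν₀ = p + 2, the weakest proper prior with a finite
mean; the MAP is the posterior mode Λₙ/(νₙ + p + 1) with Λₙ = Λ₀ + S and
νₙ = ν₀ + n. Passing a ν₀ ≤ p − 1 is allowed (the math goes through) but
flagged as an improper-prior regime in the result notes. Posterior draws
use `scipy.stats.invwishart`.

ANOVA repeatability uses the one-way decomposition per trait with
s²_W = MS_within and s²_A = (MS_among − MS_within)/n₀, where
n₀ = (N − Σnᵢ²/N)/(a − 1) handles unbalanced replicate counts (it reduces
to the replicate count for balanced designs). Negative among-individual
components are clamped to zero — standard ANOVA practice — so repeatability
is 0 rather than negative for pure noise.

Cheverud's analytic matrix repeatability is implemented as
α = (σ²_r − ε²)/σ²_r with ε² = (1 − r̄²)²/(n − 2), where r̄ is the mean
below-diagonal correlation and σ²_r their variance. The expression is
asymptotic; a note is attached when the sample size does not exceed the
trait count.

## Skewer statistics

All β-statistics are Monte-Carlo expectations over uniform unit
gradients, vectorized over a shared draw matrix; per-draw values can be
retained for plotting. Autonomy is computed as the per-draw ratio c/e
(equivalently the joint expectation ((β·G⁻¹β)(β·Gβ))⁻¹ evaluated
draw-wise), which makes the identity ā = E[c/e] hold exactly on paired
draws and preserves c̄ ≤ ē pointwise (Cauchy–Schwarz). The constraints
statistic uses the absolute cosine |cos(Gβ, Λ₁)| because the sign of an
eigenvector is arbitrary. ICV uses the sample (n−1) standard deviation of
the eigenvalues. Default n_vectors is 1000; standard errors (SD/√n) are
attached so users can judge Monte-Carlo error directly.

## Comparison

Random Skewers significance uses the empirical null of cosines between
10,000 independent random unit-vector pairs in the same dimension, rather
than a random-matrix null, with the comparison flagged significant above
the null's 95th percentile. The Mantel test permutes rows and columns of
one matrix jointly and uses the add-one convention
p = (1 + #{≥ observed})/(m + 1), so p is never exactly zero; it refuses
covariance input (scale differences inflate the element-wise correlation)
and inputs with constant off-diagonals (the correlation is undefined).

Krzanowski correlation defaults to k = max(1, ⌊p/2⌋ − 1) retained
components, user-overridable. The PCA-similarity denominator pairs
eigenvalues sorted descending, Σᵢ λᵢᴬλᵢᴮ — the normalization under which
self-similarity is exactly 1.

The overlap distance estimates the misclassification probability q by
plain Monte Carlo in log-density space (10⁴ draws per direction by
default), symmetrized over the two directions, then d = √(1 − 2q). The
Riemannian distance is computed from the eigenvalues of A⁻¹B; it is
symmetric, inversion-invariant and congruence-invariant, which the tests
verify numerically.

## Decomposition

SRD correlates, per trait and per draw, the row-wise response terms
(A_ijβ_j)_j of the two matrices; the flagging rule (centered mean score
below zero) is a reporting convenience — raw scores are always emitted.

The geometric mean of an SPD sample is the Fréchet mean under the affine
metric, found by the fixed-point iteration
M ← M^{1/2} exp(mean log(M^{-1/2}XᵢM^{-1/2})) M^{1/2}, initialized at the
arithmetic mean (guaranteed SPD) and stopped when the mean tangent-space
log has Frobenius norm ≤ 1e-10 (max 100 iterations, error on
non-convergence). Eigentensor analysis maps each member to the tangent
space at M, vectorizes symmetric matrices with off-diagonals scaled by √2
so the Euclidean inner product equals the Frobenius one (this is what
makes the eigentensors orthonormal as matrices), and eigendecomposes the
across-sample covariance of the vectorized maps. Scores are Frobenius
inner products; reconstruction X = M^{1/2} exp(Σsᵢ ETᵢ) M^{1/2} is SPD for
any finite scores. All eigentensors are computed; truncation is left to
the user.

Random-skewer projection summarizes, per random direction β, the posterior
distribution of β·Gβ for each population by an equal-tailed credible
interval (default 95%; equal-tailed rather than HPD for simplicity and
determinism) and flags directions where two populations' intervals do not
overlap.

## Modularity

Hypothesis testing compares each binary module matrix to the observed
correlations by Mantel correlation and reports AVG+ (mean within-module
correlation), AVG− (between), their ratio and MHI = (AVG+ − AVG−)/ICV,
with ICV computed from the correlation matrix itself; a combined union
("full model") hypothesis is appended. The AVG ratio is only
interpretable when correlations share a sign — MHI is the right summary
for size-removed residual matrices.

L-modularity treats the correlation matrix as a fully connected weighted
graph. Negative correlations enter by absolute value — a weighted graph
needs nonnegative weights; users with mixed-sign matrices should remove
the size factor first. With kᵢ = Σ_{j≠i}|r_ij| and total weight Σkᵢ, the
score is L(g) = Σ_{i≠j} w_ij δ(gᵢ,gⱼ) − Σ_{i,j} kᵢkⱼ/(Σk) δ(gᵢ,gⱼ). The
null sum deliberately includes the i = j terms: with that bookkeeping the
single-module partition scores exactly zero, giving L a clean baseline
(subdividing a structureless matrix can only go negative). The optimizer
is agglomerative merging plus single-trait relocation passes with 20
seeded restarts; exhaustive enumeration of all set partitions is available
for p ≤ 12 and serves as the test oracle.

Size removal subtracts the rank-1 component along the leading eigenvector,
residual = m − (mv)(mv)ᵀ/(vᵀmv); tiny negative residual eigenvalues from
floating-point cancellation are clipped to zero. A warning is emitted when
the leading eigenvector has mixed signs, since the "size" reading then
fails.

## Drift

The regression test projects taxon means on the eigenvectors of the
within-group matrix W, regresses log between-group variance on log
eigenvalue, and rejects drift when the 95% t-based CI of the slope
excludes 1 (with a 1e-9 epsilon guard so exactly proportional input is
never rejected). PCs below a relative eigenvalue cutoff (default 1e-8 of
λ₁) are dropped to avoid logs of numerical zeros. The multivariate test
simulates derived means from MVN(z₀, (t/Nₑ)W + diag(se²)) — the drift
scale t/Nₑ must be supplied because the data do not identify it, and the
measurement error of the derived mean enters the null additively on the
diagonal. PC-score correlations use Bonferroni adjustment over the
p(p−1)/2 pairs. All verdicts state explicitly that failing to reject
drift is not evidence against selection. The trait/taxon guideline (≥ 20
traits, ≥ 8 taxa) is a warning, not a precondition.

A power caveat established during development: when the within-group
spectrum is diffuse, variance inflation confined to a single PC cannot be
detected by the slope test at any effect size — the outlying point
inflates the residual variance in proportion to its own displacement, so
the t-statistic saturates below the critical value. Detection of selection
along PC1 requires PC1 to have leverage in the log-eigenvalue regression,
i.e. an integrated matrix with a dominant leading eigenvalue — which is
the typical structure of morphological covariance matrices. The
calibration and power checks therefore use an integrated spectrum (leading
eigenvalue 30 against a log-uniform [0.5, 3] remainder over 20 traits, 20
taxa, t/Nₑ = 0.5): slope-CI coverage 94/100 under drift and 100/100
rejection under selection at 10× the drift scale along PC1.

## Phylogenetic pooling

Internal nodes receive the sample-size-weighted mean of their children's
matrices in a post-order pass; the root equals the global weighted mean
regardless of topology (weighted-mean associativity, verified in tests).
Branch lengths are ignored and a warning is emitted when the tree carries
them; weights are always user-supplied because mixed-model G-matrix
estimates carry no obvious degrees of freedom. Multifurcations are
compared all-pairs with a note.

## Synthetic data

`random_matrix` builds correlation matrices with a requested integration
level (ICV of the correlation eigenvalues) from a random orthogonal basis
and an exponentially decaying spectrum, bisecting on the decay rate —
integration is monotone in it. This is a purpose-built generator covering
a controllable range of integration, intended for informal tests rather
than as a calibrated null distribution of biological matrices.
`modular_matrix` builds exact block-correlation structure and rejects
combinations that cannot be completed to a PSD matrix (three mutually
negatively correlated blocks, for instance). Populations are MVN draws
with optional replicated measurements under i.i.d. Gaussian measurement
error; radiations draw taxon means from MVN(0, (t/Nₑ)W) with an optional
deterministic ramp along a selection vector.

What the synthetic tests show: that the implementations satisfy their
defining identities, closed forms, brute-force equivalences and
statistical calibration under the exact generating model. What they do not
show: robustness to non-Gaussian trait distributions, missing data,
measurement error correlated across traits, or model misspecification in
the drift tests — real data violate all of these to some degree.

## Default parameters

| parameter | default | rationale |
|---|---|---|
| bootstrap / Monte-Carlo iterations | 1000 | error of a mean of bounded comparisons is ≲ 0.01 |
| skewer vectors n_vectors | 1000 | MC SE reported alongside; raise for tighter estimates |
| RS significance null size | 10,000 | smooth 95th percentile of the cosine null |
| overlap MC draws | 10,000 per direction | q SE ≤ 0.005 |
| Krzanowski k | max(1, ⌊p/2⌋ − 1) | half-spectrum subspace, exposed |
| Bayesian prior df ν₀ | p + 2 | weakest proper prior with finite mean |
| Fréchet tol / max_iter | 1e-10 / 100 | fixed-point contraction converges in a handful of steps |
| drift PC cutoff | λᵢ/λ₁ ≥ 1e-8 | avoids log of numerical zeros |
| credible level (RS projection) | 0.95 | convention; nesting verified in tests |
| greedy restarts (L-modularity) | 20 | matches exhaustive optimum on all tested 8-trait cases |

## Known limitations

Mixed-model or animal-model G-matrix estimation is out of scope; matrices
from such models can be imported and analyzed, but their sampling error
must be quantified externally (e.g. from posterior samples). Per-element
maximum-likelihood ancestral reconstruction is deliberately omitted (it
can produce non-PSD estimates). The exhaustive L-modularity oracle is
limited to 12 traits by the Bell-number explosion; the greedy optimizer
has no global guarantee beyond the tested regimes. The overlap distance
assumes zero-mean Gaussian phenotype distributions when used on bare
covariance matrices.
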