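# Methods

## Model

Let **Y** be an N × p table of species counts with a group label g(i) for
each sampling unit.  Within each group, species j follows a count
distribution F_j from {Poisson(μ), ZIP(μ, π), NB(μ, θ), ZINB(μ, θ, π)},
where μ > 0 is the mean of the count component, θ > 0 the NB dispersion
(variance μ + μ²/θ), and π ∈ [0, 1) the structural-zero mixture weight.
The joint distribution within a group is a Gaussian copula: a latent
vector z ~ MVN(0, Σ) with correlation matrix Σ, mapped coordinate-wise to
counts by y_j = F_j⁻¹(Φ(z_j)), where F_j⁻¹(q) is the generalized inverse
(smallest y with F_j(y) ≥ q).  Marginals and copula parameters are allowed
to differ across groups; associations therefore live entirely in Σ and
never distort the marginal fits — the central design property of a copula
model.

Sampling units are assumed independent; there is no spatial or temporal
autocorrelation in the model.

## Fitting pipeline

**Marginal selection.**  Each family is fitted by maximum likelihood
(Poisson in closed form; NB by profiling μ̂ = ȳ and optimizing θ on the log
scale; ZIP/ZINB by Nelder–Mead on (log μ, log θ, logit π) with multi-start
π₀ ∈ {0.01, 0.25, 0.5} to avoid the boundary local optimum at π = 0).
Families are compared by AICc = −2ℓ + 2k + 2k(k+1)/(n−k−1); candidates
with n ≤ k + 1 are excluded with a warning, ties go to the fewer-parameter
family.  Selection defaults to per-group sample sizes; pooled selection is
available (`per_group=False`) since either reading of "per species, per
group" is defensible when group sizes are small.  A species never observed
in a group is represented by a point mass at zero: its cdf step at 0 is 1,
so it carries no latent-scale information, is barred from copula
estimation, and simulates as constant zero.

**Association screen.**  The index of association I_kℓ compares two
species' relative-abundance profiles and ignores units where both are
absent.  Each pair is tested by permuting one species' values across units
within the group (valid under exchangeability).  All pairs in a group share
one permutation-index matrix — required for the family-wise procedure and
harmless otherwise.  PCER flags a pair when its observed I falls outside
the pair-specific empirical (rate/2, 1 − rate/2) quantile bounds.  FWER
uses a max-statistic construction: per permutation, record the most
extreme per-pair tail probability across all pairs; flag pairs whose
observed tail probability is at or below the rate-quantile of that
minimum-tail distribution.  Reported p-values follow (b+1)/(n_perm+1);
the two-tailed p doubles the smaller one-sided value (the one-sided values
are also returned).  With fewer than ceil(1/rate) − 1 permutations the
requested rate is unresolvable and the screen refuses to run.

**Copula estimation (MCEM).**  Discrete marginals make the latent value of
an observation non-unique: y_ij only constrains z_ij to the interval
(Φ⁻¹(F_j(y_ij − 1)), Φ⁻¹(F_j(y_ij))].  Conditioning on the fixed fitted
marginals, Σ is estimated by Monte Carlo EM over these hyper-rectangles:

- *E-step*: for each observation, sample latent vectors from MVN(0, Σ)
  truncated to its hyper-rectangle by coordinate-wise Gibbs (inverse-cdf
  sampling from each full-conditional truncated normal).  All
  observations × Monte Carlo replicates are updated in one vectorized
  pass per coordinate; chains are warm-started across EM iterations, with
  `burnin` (default 8) sweeps per E-step.
- *M-step*: Σ ← nearest correlation matrix to the average outer product
  of the sampled latent vectors (rescale to unit diagonal; if indefinite,
  clip eigenvalues at 1e-8 and rescale), so every iterate is a valid
  correlation matrix by construction.

Σ₀ comes from normal-scores (midrank) correlations shrunk 10 % toward the
identity.  The Monte Carlo sample size starts at `n_mc = 20` per
observation and grows by a factor 1.2 per iteration (capped at 200) so
late iterations average over more draws.  Convergence is declared when the
maximum entrywise change of a Polyak average over the last 5 iterates
falls below `tol = 0.005`; non-convergence is flagged, never silent.  A
master seed spawns all streams, so fits are bit-reproducible.

The estimated m × m block is embedded at the associated species' indices
in a p × p identity; rare and unassociated species remain in the model as
independent marginals.

## Simulation and the ρ ↔ I map

Simulation inverts the construction: z ~ MVN(0, Σ̂) (eigen-factor of Σ̂),
u = Φ(z), y_j = F_j⁻¹(u_j).  Quantile inversion uses a per-marginal cdf
table and binary search; the q = 1 clamp returns the smallest y with upper
tail mass below 1e-12, keeping every simulated count finite.  For a pair
of marginals the map from copula correlation ρ to the expected index of
association is traced by Monte Carlo (`rho_to_I_curve`) and inverted by
linear interpolation of the monotone mean curve (`choose_rho_for_I`).
Replicates in which a simulated species is entirely absent (possible at
small n with strong zero-inflation) are resampled and counted.

A caution established while validating this map with an independent
deterministic oracle (numeric integration of the joint pmf via
bivariate-normal rectangle probabilities): for the reference marginal pair
NB(2.714, 1.635) / ZINB(15.375, 1.857, 0.095), the expected index at
ρ = 0.574 is 0.676 (a correlation of ≈ 0.633 would be needed for
I = 0.698).  An MCEM estimate ρ̂ obtained from real data therefore need
not reproduce the sample index exactly — the model preserves the index
only as well as it fits the pair.  The acceptance test asserting the
0.698/0.574 correspondence documents this gap by failing at its stated
±0.01 tolerance; the computed value is reported as-is.

## Dissimilarity space

Bray–Curtis dissimilarities are computed on (optionally √- or ⁴√-)
transformed abundances, with √ the default used by all downstream
analyses; a pair of all-zero units gets d = 0 by convention (logged).
Group centroids are never coordinate averages: squared centroid distances
come directly from the dissimilarity matrix,

d²(c_a, c_b) = (1/n_a n_b) Σ_{i∈a, j∈b} d²_ij − (1/2n_a²) Σ_{i,i′∈a} d²_ii′
− (1/2n_b²) Σ_{j,j′∈b} d²_jj′,

with negative squared values (possible because Bray–Curtis is semi-metric)
clamped to zero and counted; a signed-root convention was rejected to keep
centroid distances a valid dissimilarity.  PCoA Gower-centers −½D² and
reports *all* eigenvalues — negative ones are informative about the
semi-metric — returning coordinate axes for the positive part (this is
why the decomposition is written out with `eigh` rather than delegated to
a library routine that post-processes negatives away; library PCoA and
PERMANOVA serve as independent cross-checks in the test suite).

MDS runs SMACOF majorization (best of `n_starts = 8` random starts plus a
PCoA start), metric by default for centroid clouds, non-metric (isotonic
regression of configuration distances on dissimilarities) for raw-data
diagnostics.  Stress is reported as normalized Kruskal stress-1 in both
modes and is surfaced, never hidden — high stress is itself evidence of
weak low-dimensional structure.

The centroid-cloud pipeline stacks the observed table with N_sim simulated
tables (H_A), computes the super dissimilarity matrix once, reduces it to
centroid distances, and embeds by metric MDS; H₀ clouds add centroids of
random permutations of the observed units' labels (no new data — the null
is exchangeability of the observed rows).  A 2-D Gaussian KDE per
(source, group) summarizes cloud shape.

## Inference and power

The one-way PERMANOVA pseudo-F is computed from sums of squared
dissimilarities and reduces exactly to the classical ANOVA F for
univariate Euclidean input (a unit test asserts 1e-10 agreement).  Its
p-value comes from random label permutations, or from a model-based null:
each simulated unit's generating group is drawn multinomially with
probability 1/g (or n_i/N, or from a single pooled model), counts are
simulated from that group's copula model, and the statistic recomputed
with the nominal labels.  All p-values use (b+1)/(B+1).

CAP performs canonical discriminant analysis on the first m PCoA axes
(positive eigenvalues only).  The test statistic is the sum of squared
canonical correlations (the first squared correlation is also reported);
permutations relabel units with the PCoA fixed.  Leave-one-out allocation
refits the canonical axes without each unit and classifies it to the
nearest group centroid in canonical space; when m is unspecified it is
chosen to maximize LOO success (ties to the smaller m).  The full CAP of
the literature re-derives the PCoA per left-out unit; fixing the PCoA is a
deliberate simplification that leaves the allocation estimate marginally
optimistic at small N.

Power curves follow P_k = (1 − f_k) P₀ + f_k P_A with f from 0 to 1
(default: equiprobable P₀, identity P_A, 20 steps).  Group sizes stay at
the nominal design; the mixture chooses each unit's generating model.
Power at step k is the fraction of simulated datasets with p ≤ α.

## Synthetic fixtures

The generator's default spec mirrors a temperate reef-fish survey: p = 47
species, 3 groups of (15, 21, 20) units, ≈ 40 % rare species (tiny
Poisson means), NB/ZINB marginals with dispersion θ ∈ [0.5, 3] and
zero-inflation π ∈ [0, 0.35], group-wise mean shifts up to a factor 1.6,
and one correlated block of 8–17 species per group with pairwise ρ ∈
[0.3, 0.8] built from one-factor loadings (Σ = λλ′ off-diagonal), which
guarantees a valid correlation matrix.  Fixtures emulate over-dispersion,
zero-inflation, rarity, and group-varying association structure; they do
not emulate spatial/temporal autocorrelation, observer effects, or
abundance-dependent detectability, so passing tests speak to the
statistical machinery, not to those field realities.  All generators are
bit-reproducible under a fixed seed.

## Problem sizes used by the test suite

Stochastic checks are sized to be decisive yet quick: marginal recovery
uses n = 2000 over 20 seeds; MCEM recovery uses n = 500–1000 over 10–20
seeds; test-size checks use 1,000 null simulations with 99 permutations
each; the power comparison uses the full 47-species fixture with 5 mixture
steps × 200 simulations × 199 permutations.  These sizes are the package's
own choices for routine verification; all are plain function arguments and
scale up directly.

## Known limitations

- No regularization/shrinkage of Σ̂: with m approaching the group sample
  size the MCEM estimate becomes unstable; screen first, or extend the
  M-step with shrinkage.
- Marginals carry no covariates (ANOVA-type designs only), and the copula
  is Gaussian only.
- The FWER screen is an empirical max-statistic construction, slightly
  conservative relative to an exact family-wise bound.
- Rare species are modelled as independent; coincident rarity is not
  captured.
- MCEM standard errors are not computed; uncertainty in Σ̂ must come from
  resimulation.
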