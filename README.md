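# ecocop

Gaussian copula models with discrete marginals for multivariate analysis of
ecological count communities.

## The problem

A community survey yields an N × p table **Y** of counts (N sampling units,
p species) plus a group label per unit — e.g. fish counted on transects at
several sampling times around the establishment of a marine reserve.  Such
data are high-dimensional (often p > N), over-dispersed, zero-inflated and
full of rare species, and different species' counts are incommensurable.
Dissimilarity-based methods (Bray–Curtis ordination, PERMANOVA, CAP) detect
community-level change robustly but build no model of the species, so they
cannot simulate, predict, or compute power.  Classical joint models
(GLLVMs, GJAMs) entangle the association structure with the marginal
distributions.

`ecocop` implements a pathway that combines both worlds:

1. **Marginals** — each species, per group, gets its own count
   distribution: Poisson, zero-inflated Poisson (ZIP), negative binomial
   (NB, variance μ + μ²/θ) or zero-inflated NB (ZINB, structural-zero
   weight π), chosen by AICc; species occurring as singletons or in < 5 %
   of units can be flagged as rare.
2. **Association screen** — the index of association, which excludes joint
   absences,

   I_kℓ = 1 − ½ Σᵢ | y_ik / Σⱼ y_jk − y_iℓ / Σⱼ y_jℓ |,

   is tested for every species pair by permutation, with per-comparison
   (PCER) or empirical family-wise (FWER) error control, to pick the m ≤ p
   species whose associations are worth modelling.
3. **Copula** — a Gaussian copula couples the m fixed marginals.  Because
   the marginals are discrete, each observed count vector corresponds to a
   whole hyper-rectangle of the latent Gaussian space, so the correlation
   matrix Σ is estimated by Monte Carlo EM: truncated-normal Gibbs sampling
   over the hyper-rectangles (E-step) and a projected outer-product update
   (M-step).  Σ̂ is then expanded to p × p with independence elsewhere.
4. **Simulation, ordination, inference, power** — the fitted per-group
   models simulate realistic communities under H₀ or H_A; simulated-centroid
   clouds are ordinated by metric MDS of centroid distances computed
   directly from the dissimilarity matrix; PERMANOVA pseudo-F gets both
   permutation and model-based p-values; power curves follow the multinomial
   mixture continuum P_k = (1 − f_k) P₀ + f_k P_A between null and
   alternative.

## Worked example

A bivariate toy community — an over-dispersed species, NB(μ=2.714,
θ=1.635), and a zero-inflated one, ZINB(μ=15.375, θ=1.857, π=0.095),
coupled at copula correlation ρ = 0.574:

```python
import numpy as np
from ecocop import (CountMarginal, GroupCopulaModel, simulate_counts,
                    index_of_association, pair_permutation_test,
                    mcem_fit, McemSettings)

mk = CountMarginal("nb", mu=2.714, theta=1.635)
ml = CountMarginal("zinb", mu=15.375, theta=1.857, pi=0.095)
pair = GroupCopulaModel(marginals=[mk, ml],
                        sigma=np.array([[1.0, 0.574], [0.574, 1.0]]))
Y = simulate_counts(pair, 56, seed=0)
print("observed I:", round(index_of_association(Y[:, 0], Y[:, 1]), 3))
print("two-tailed p:", pair_permutation_test(Y[:, 0], Y[:, 1],
                                             n_perm=9999, seed=1).p)
sigma, info = mcem_fit(Y, [mk, ml], McemSettings(seed=2))
print("MCEM rho-hat:", round(sigma[0, 1], 3), "| converged:", info["converged"])
```

```
observed I: 0.701
two-tailed p: 0.0002
MCEM rho-hat: 0.587 | converged: True
```

The 56 simulated pairs carry a strong association (I near 0.7, no
permuted dataset reached it), and MCEM recovers the generating correlation
from counts alone.  A full community analysis on a synthetic 47-species,
3-group survey (groups of 15, 21 and 20 units):

```python
from ecocop import (default_spec, generate_community, fit_community,
                    bray_curtis, permanova, model_based_null, cap)

spec = default_spec(seed=11)                       # p=47, sizes (15, 21, 20)
Yc, groups, truth = generate_community(spec, seed=12)
model = fit_community(Yc, groups, seed=13,
                      screen_kwargs={"n_perm": 999, "error_rate": 0.01})
D = bray_curtis(Yc, transform="sqrt")
pf = permanova(D, groups, n_perm=4999, seed=14)
print("pseudo-F:", round(pf.statistic, 3), " permutation p:", pf.p_permutation)
mb = model_based_null(Yc, groups, model, n_sim=999, seed=15)
print("model-based p:", mb.p_model_based)
cr = cap(D, groups, n_perm=999, seed=16)
print("CAP: m =", cr.m_axes, " LOO allocation =", round(cr.allocation_success, 3),
      " p =", cr.p_permutation)
```

```
pseudo-F: 2.363  permutation p: 0.0016
model-based p: 0.002
CAP: m = 25  LOO allocation = 0.679  p = 0.001
```

The group effect planted in the generator is detected by the
distribution-free permutation test and — nearly identically — by the
model-based null simulated from the fitted copulas; the agreement of the
two null distributions is itself a diagnostic of model adequacy.

## Command line

Every stage is also a subcommand writing CSV/JSON artifacts plus a sidecar
metadata file (seed, settings), so analyses are resumable and reproducible:

```sh
ecocop fit-marginals --counts counts.csv --group-col group --out run/
ecocop screen        --counts counts.csv --group-col group --n-perm 99999 --out run/
ecocop fit-copula    --counts counts.csv --group-col group --out run/
ecocop ordinate      --counts counts.csv --group-col group --model run/model.json --out run/
ecocop permanova     --counts counts.csv --group-col group --model run/model.json --n-sim 4999 --out run/
ecocop power         --model run/model.json --n-steps 20 --out run/
```

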