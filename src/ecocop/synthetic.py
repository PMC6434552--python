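"""Seeded synthetic communities with known ground truth.

The default specification mirrors the shape of a temperate reef-fish
survey: p = 47 species in g = 3 groups of sampling units with sizes
(15, 21, 20), over-dispersed and zero-inflated marginals whose parameters
vary across groups, roughly 40% rare species, and one correlated block of
species per group with copula correlations in [0.3, 0.8].  Correlation
blocks are built from a single-factor loading structure (Sigma = ll' off
the diagonal), which keeps every planted block a valid correlation matrix
by construction.

These generators define the study conditions for the package's own
recovery and size/power tests; they emulate count marginals and a
group-varying Gaussian-copula association structure, but not spatial or
temporal autocorrelation of sampling units.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .copula import CommunityModel, GroupCopulaModel, expand_correlation, simulate_counts
from .marginals import CountMarginal

__all__ = ["SyntheticSpec", "default_spec", "generate_community", "make_mock_null"]


@dataclass
class SyntheticSpec:
    """Ground-truth description of a synthetic community."""

    p: int
    sizes: tuple
    marginals: list  # per group: list of p CountMarginal
    blocks: list  # per group: (index array, correlation matrix)
    seed: int | None = None
    group_labels: tuple = None

    def __post_init__(self):
        g = len(self.sizes)
        if len(self.marginals) != g or len(self.blocks) != g:
            raise ValueError("need one marginal list and one block per group")
        for ms in self.marginals:
            if len(ms) != self.p:
                raise ValueError("each group needs p marginals")
        for idx, C in self.blocks:
            idx = np.asarray(idx)
            C = np.asarray(C)
            if C.shape != (idx.size, idx.size):
                raise ValueError("block matrix must match its index set")
            if idx.size and np.linalg.eigvalsh(C).min() < -1e-10:
                raise ValueError("block correlation matrix must be PSD")
        if self.group_labels is None:
            self.group_labels = tuple(f"g{i + 1}" for i in range(g))

    @property
    def g(self) -> int:
        return len(self.sizes)

    def to_model(self) -> CommunityModel:
        groups = []
        for i in range(self.g):
            idx, C = self.blocks[i]
            sigma = expand_correlation(np.asarray(C), np.asarray(idx, dtype=int), self.p)
            groups.append(
                GroupCopulaModel(
                    marginals=list(self.marginals[i]),
                    sigma=sigma,
                    assoc_index=np.asarray(idx, dtype=int),
                    group=self.group_labels[i],
                    n=self.sizes[i],
                )
            )
        return CommunityModel(groups=groups, sizes=list(self.sizes))


def _one_factor_block(rho_range, size, rng) -> np.ndarray:
    """Correlation block with pairwise rho = l_i l_j in roughly rho_range."""
    lo, hi = np.sqrt(rho_range[0]), np.sqrt(rho_range[1])
    lam = rng.uniform(lo, hi, size=size)
    C = np.outer(lam, lam)
    np.fill_diagonal(C, 1.0)
    return C


def default_spec(
    p: int = 47,
    sizes: tuple = (15, 21, 20),
    rare_fraction: float = 0.4,
    block_size_range: tuple = (8, 17),
    rho_range: tuple = (0.3, 0.8),
    group_mean_shift: float = 1.6,
    seed: int = 0,
) -> SyntheticSpec:
    """Fish-survey-scale synthetic community with group-varying structure.

    A ``rare_fraction`` of species get tiny means (so most flag as rare);
    common species draw NB or ZINB marginals whose means shift by a factor
    of up to ``group_mean_shift`` across groups; each group plants one
    one-factor correlation block over a random subset of common species.
    """
    rng = np.random.default_rng(seed)
    g = len(sizes)
    n_rare = int(round(rare_fraction * p))
    rare_idx = rng.choice(p, size=n_rare, replace=False)
    is_rare = np.zeros(p, dtype=bool)
    is_rare[rare_idx] = True
    common_idx = np.flatnonzero(~is_rare)

    base_mu = np.where(is_rare, rng.uniform(0.02, 0.12, p), rng.gamma(2.0, 3.0, p) + 0.5)
    base_theta = rng.uniform(0.5, 3.0, p)
    base_pi = rng.uniform(0.0, 0.35, p)
    fam = np.where(
        is_rare, "poisson", rng.choice(["nb", "zinb"], size=p, p=[0.55, 0.45])
    )

    marginals, blocks = [], []
    for i in range(g):
        shift = rng.uniform(1.0 / group_mean_shift, group_mean_shift, size=p)
        ms = []
        for j in range(p):
            mu = float(base_mu[j] * shift[j])
            if fam[j] == "poisson":
                ms.append(CountMarginal("poisson", mu=mu))
            elif fam[j] == "nb":
                ms.append(CountMarginal("nb", mu=mu, theta=float(base_theta[j])))
            else:
                ms.append(
                    CountMarginal(
                        "zinb", mu=mu, theta=float(base_theta[j]), pi=float(base_pi[j])
                    )
                )
        size = int(rng.integers(block_size_range[0], block_size_range[1] + 1))
        size = min(size, common_idx.size)
        idx = np.sort(rng.choice(common_idx, size=size, replace=False))
        blocks.append((idx, _one_factor_block(rho_range, size, rng)))
        marginals.append(ms)
    return SyntheticSpec(
        p=p, sizes=tuple(sizes), marginals=marginals, blocks=blocks, seed=seed
    )


def generate_community(spec: SyntheticSpec, seed=None):
    """Simulate a community table from a spec.

    Returns ``(Y, groups, truth)`` where truth is the generating
    :class:`CommunityModel` for recovery tests.
    """
    truth = spec.to_model()
    use_seed = spec.seed if seed is None else seed
    Y, groups = truth.simulate(seed=use_seed)
    return Y, groups, truth


def make_mock_null(
    Y,
    sizes,
    seed=None,
    families=None,
    screen_kwargs: dict | None = None,
    mcem_kwargs: dict | None = None,
):
    """Mock community data for which the null hypothesis is true by design.

    Fits one pooled model (marginals, association screen, copula) to the
    full table ignoring any groups, then simulates groups of the requested
    sizes from that single model.  Returns ``(Y_mock, groups_mock,
    pooled_model)``; because every "group" came from the same model, any
    downstream test's rejection rate estimates its true size.
    """
    from .pipeline import fit_community

    Y = np.asarray(Y)
    pooled = fit_community(
        Y,
        groups=None,
        seed=seed,
        families=families,
        screen_kwargs=screen_kwargs,
        mcem_kwargs=mcem_kwargs,
    )
    gm = pooled.groups[0]
    rng = np.random.default_rng(seed)
    blocks, labels = [], []
    for i, n_i in enumerate(sizes):
        blocks.append(simulate_counts(gm, n_i, seed=rng.integers(2**31)))
        labels.extend([f"mock{i + 1}"] * n_i)
    return np.vstack(blocks), np.asarray(labels), pooled
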