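"""Inter-specific association: the joint-absence-excluding index and its
permutation-based screening filter.

The index of association between species k and l across N sampling units is

    I_kl = 1 - (1/2) * sum_i | y_ik / sum_j y_jk  -  y_il / sum_j y_jl |

i.e. one minus half the L1 distance between the two species'
relative-abundance profiles.  Units where both species are absent
contribute nothing, so I discounts joint absences; I = 1 for identical
profiles and I = 0 for disjoint ones.

Screening tests every retained species pair within a group by permuting
one species' values across sampling units.  Significance is decided from
the pair-specific two-tailed empirical bounds of the permutation
distribution of I (per-comparison error rate, PCER), or from the
distribution of the most extreme per-permutation tail probability across
all pairs (family-wise error rate, FWER).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "index_of_association",
    "pair_permutation_test",
    "screen_associations",
    "AssociationScreen",
    "PairTestResult",
]


def index_of_association(yk, yl) -> float:
    """Index of association between two species' count vectors.

    Both vectors must have at least one positive entry; the index is
    undefined for an empty (all-zero) species and callers must exclude
    such species beforehand.
    """
    yk = np.asarray(yk, dtype=float)
    yl = np.asarray(yl, dtype=float)
    if yk.shape != yl.shape or yk.ndim != 1:
        raise ValueError("species vectors must be 1-D and of equal length")
    sk, sl = yk.sum(), yl.sum()
    if sk <= 0 or sl <= 0:
        raise ValueError("index of association undefined for an all-zero species")
    return 1.0 - 0.5 * float(np.abs(yk / sk - yl / sl).sum())


@dataclass(frozen=True)
class PairTestResult:
    """Permutation test of no association for one species pair."""

    I: float
    p: float  # two-tailed, doubled one-sided convention
    p_lower: float
    p_upper: float
    lower_bound: float
    upper_bound: float
    n_perm: int


def _permuted_index(pk: np.ndarray, pl: np.ndarray, perm_idx: np.ndarray) -> np.ndarray:
    """I for each row of permutation indices, given relative profiles."""
    return 1.0 - 0.5 * np.abs(pk[None, :] - pl[perm_idx]).sum(axis=1)


def pair_permutation_test(
    yk,
    yl,
    n_perm: int = 999,
    seed=None,
    error_rate: float = 0.01,
) -> PairTestResult:
    """Two-tailed permutation test of I_kl against no association.

    One species' values are randomly permuted across sampling units each
    iteration (the other held fixed, which is equivalent under
    exchangeability).  P-values follow (b+1)/(n_perm+1); the reported
    two-tailed ``p`` doubles the smaller one-sided value.  ``lower_bound``
    and ``upper_bound`` are the empirical error_rate/2 and 1-error_rate/2
    quantiles of the permutation distribution (the decision bounds used by
    PCER screening).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    yk = np.asarray(yk, dtype=float)
    yl = np.asarray(yl, dtype=float)
    obs = index_of_association(yk, yl)
    rng = np.random.default_rng(seed)

    if np.all(yl == yl[0]) or np.all(yk == yk[0]):
        # a constant column is invariant under permutation
        warnings.warn("constant species column: permutation p-value is 1", RuntimeWarning)
        return PairTestResult(obs, 1.0, 1.0, 1.0, obs, obs, n_perm)

    n = yk.size
    perm_idx = np.argsort(rng.random((n_perm, n)), axis=1)
    perms = _permuted_index(yk / yk.sum(), yl / yl.sum(), perm_idx)
    b_low = int(np.count_nonzero(perms <= obs))
    b_up = int(np.count_nonzero(perms >= obs))
    p_lower = (b_low + 1) / (n_perm + 1)
    p_upper = (b_up + 1) / (n_perm + 1)
    p = min(1.0, 2.0 * min(p_lower, p_upper))
    lo, hi = np.quantile(perms, [error_rate / 2.0, 1.0 - error_rate / 2.0])
    return PairTestResult(obs, p, p_lower, p_upper, float(lo), float(hi), n_perm)


@dataclass
class AssociationScreen:
    """Result of screening all species pairs within one group.

    ``I``, ``pvals`` and ``significant`` are symmetric p x p arrays over
    the full species set; entries involving excluded (rare or all-zero)
    species are NaN / False.  ``retained`` gives the column indices that
    were actually tested.
    """

    I: np.ndarray
    pvals: np.ndarray
    significant: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    error_rate: float
    method: str
    n_perm: int
    group: object
    retained: np.ndarray
    species: list

    @property
    def significant_pairs(self) -> list[tuple[int, int]]:
        iu = np.triu_indices_from(self.significant, k=1)
        mask = self.significant[iu]
        return list(zip(iu[0][mask], iu[1][mask]))

    @property
    def associated_species(self) -> np.ndarray:
        """Indices of species involved in at least one significant pair."""
        pairs = self.significant_pairs
        if not pairs:
            return np.array([], dtype=int)
        return np.unique(np.concatenate([np.array(p) for p in pairs]))

    def to_frame(self) -> pd.DataFrame:
        rows = []
        r = list(self.retained)
        for a_i, a in enumerate(r):
            for b in r[a_i + 1 :]:
                rows.append(
                    {
                        "group": self.group,
                        "species_a": self.species[a],
                        "species_b": self.species[b],
                        "I": self.I[a, b],
                        "p_value": self.pvals[a, b],
                        "lower_bound": self.lower[a, b],
                        "upper_bound": self.upper[a, b],
                        "significant": bool(self.significant[a, b]),
                    }
                )
        return pd.DataFrame(rows)


def _screen_one_group(
    Yg: np.ndarray,
    error_rate: float,
    method: str,
    n_perm: int,
    rng: np.random.Generator,
    retained: np.ndarray,
    species: list,
    group,
) -> AssociationScreen:
    p = Yg.shape[1]
    n = Yg.shape[0]
    I = np.full((p, p), np.nan)
    pvals = np.full((p, p), np.nan)
    lower = np.full((p, p), np.nan)
    upper = np.full((p, p), np.nan)
    sig = np.zeros((p, p), dtype=bool)
    np.fill_diagonal(I, 1.0)

    m = retained.size
    pairs = [(retained[a], retained[b]) for a in range(m) for b in range(a + 1, m)]
    profiles = {j: Yg[:, j] / Yg[:, j].sum() for j in retained}

    # shared permutations across pairs (required for the FWER max-statistic);
    # one permutation index matrix per screen, seeded from the master stream
    perm_idx = np.argsort(rng.random((n_perm, n)), axis=1)

    # per-pair one-sided tail probabilities of the observed I; for FWER we
    # also need the per-permutation minimal tail probability across pairs
    perm_tail_min = np.full(n_perm, np.inf) if method == "FWER" else None

    obs_tail = {}
    for a, b in pairs:
        pk, pl = profiles[a], profiles[b]
        obs = 1.0 - 0.5 * float(np.abs(pk - pl).sum())
        perms = _permuted_index(pk, pl, perm_idx)
        b_low = int(np.count_nonzero(perms <= obs))
        b_up = int(np.count_nonzero(perms >= obs))
        p_lower = (b_low + 1) / (n_perm + 1)
        p_upper = (b_up + 1) / (n_perm + 1)
        lo, hi = np.quantile(perms, [error_rate / 2.0, 1.0 - error_rate / 2.0])
        I[a, b] = I[b, a] = obs
        pvals[a, b] = pvals[b, a] = min(1.0, 2.0 * min(p_lower, p_upper))
        lower[a, b] = lower[b, a] = lo
        upper[a, b] = upper[b, a] = hi
        obs_tail[(a, b)] = min(p_lower, p_upper)
        if method == "PCER":
            sig[a, b] = sig[b, a] = (obs < lo) or (obs > hi)
        else:
            # tail probability of each permuted value within its own
            # permutation distribution (smaller = more extreme); ties
            # handled exactly via searchsorted counts
            srt = np.sort(perms)
            le = np.searchsorted(srt, perms, side="right")
            ge = n_perm - np.searchsorted(srt, perms, side="left")
            tail = (np.minimum(le, ge) + 1) / (n_perm + 1)
            np.minimum(perm_tail_min, tail, out=perm_tail_min)

    if method == "FWER" and pairs:
        # declare pairs whose observed tail probability is at or below the
        # error_rate quantile of the per-permutation minimum tail probability
        crit = np.quantile(perm_tail_min, error_rate)
        for (a, b), t in obs_tail.items():
            s = t <= crit
            sig[a, b] = sig[b, a] = s

    return AssociationScreen(
        I=I,
        pvals=pvals,
        significant=sig,
        lower=lower,
        upper=upper,
        error_rate=error_rate,
        method=method,
        n_perm=n_perm,
        group=group,
        retained=retained,
        species=species,
    )


def screen_associations(
    Y,
    groups=None,
    error_rate: float = 0.01,
    method: str = "PCER",
    n_perm: int = 999,
    seed=None,
    exclude_rare: bool = True,
    min_prevalence: float = 0.05,
    species=None,
) -> dict:
    """Screen all species pairs for significant association, per group.

    Returns ``{group label: AssociationScreen}``.  All-zero species within
    a group are always excluded (their index is undefined); rare species
    are additionally excluded when ``exclude_rare`` is set.  PCER declares
    a pair significant when its observed I falls outside the pair-specific
    two-tailed empirical bounds at ``error_rate``; FWER uses the
    distribution across permutations of the most extreme per-pair tail
    probability, an empirical max-statistic family-wise bound.
    """
    from .marginals import flag_rare

    if method not in ("PCER", "FWER"):
        raise ValueError("method must be 'PCER' or 'FWER'")
    if error_rate * (n_perm + 1) < 1:
        raise ValueError(
            f"n_perm={n_perm} cannot resolve error_rate={error_rate}; "
            f"need n_perm >= {int(np.ceil(1 / error_rate)) - 1}"
        )
    Y = np.asarray(Y)
    N, p = Y.shape
    if species is None:
        species = [f"sp{j + 1}" for j in range(p)]
    if groups is None:
        groups = np.zeros(N, dtype=int)
    groups = np.asarray(groups)

    master = np.random.default_rng(seed)
    out = {}
    for g in pd.unique(groups):
        idx = np.flatnonzero(groups == g)
        if idx.size < 3:
            raise ValueError(f"group {g!r} has fewer than 3 sampling units")
        Yg = Y[idx]
        present = Yg.sum(axis=0) > 0
        keep = present.copy()
        if exclude_rare:
            keep &= ~flag_rare(Yg, min_prevalence)
        retained = np.flatnonzero(keep)
        rng = np.random.default_rng(master.integers(2**31))
        out[g] = _screen_one_group(
            Yg, error_rate, method, n_perm, rng, retained, list(species), g
        )
    return out
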