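"""Dissimilarity-based inference: PERMANOVA, CAP, and copula-model power.

The one-way PERMANOVA pseudo-F is computed from sums of squared
inter-point dissimilarities,

    SS_total  = (1/N)   sum_{i<j} d_ij^2
    SS_within = sum_g (1/n_g) sum_{i<j in g} d_ij^2
    pseudo-F  = (SS_among / (g - 1)) / (SS_within / (N - g)),

which reduces exactly to the classical one-way ANOVA F for univariate
Euclidean distances.  P-values follow the (b+1)/(B+1) convention
throughout, for both permutation nulls and copula-model-based nulls
(each simulated sampling unit's generating group drawn multinomially).

CAP (canonical analysis of principal coordinates) performs a canonical
discriminant analysis on the first m PCoA axes; its statistic is the sum
of squared canonical correlations, and classification quality is measured
by leave-one-out nearest-group-centroid allocation in the canonical
space.  Power curves trace either test's rejection rate along the
multinomial mixture continuum P_k = (1 - f_k) P0 + f_k PA from the null
to a fully specified alternative.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import ndtr

from .dissimilarity import DissimilarityMatrix, bray_curtis, euclidean, pcoa, _as_values

__all__ = [
    "TestResult",
    "pseudo_f",
    "permanova",
    "model_based_null",
    "cap",
    "CapResult",
    "MixtureSchedule",
    "simulate_mixture",
    "power_curve",
]


@dataclass
class TestResult:
    statistic: float
    p_permutation: float = None
    p_model_based: float = None
    n_perm: int = 0
    n_sim: int = 0
    null_distribution: np.ndarray = None

    @property
    def p(self) -> float:
        return self.p_permutation if self.p_permutation is not None else self.p_model_based


def _group_codes(groups) -> tuple[np.ndarray, int]:
    groups = np.asarray(groups)
    codes = pd.factorize(groups)[0]
    return codes, codes.max() + 1


def _ss_within(D2: np.ndarray, codes: np.ndarray, g: int) -> float:
    ssw = 0.0
    for k in range(g):
        ix = np.flatnonzero(codes == k)
        ssw += D2[np.ix_(ix, ix)].sum() / (2.0 * ix.size)
    return ssw


def pseudo_f(D, groups) -> float:
    """One-way PERMANOVA pseudo-F from a dissimilarity matrix."""
    D2 = _as_values(D) ** 2
    codes, g = _group_codes(groups)
    N = D2.shape[0]
    if g < 2:
        raise ValueError("need at least two groups")
    if N <= g:
        raise ValueError("need more sampling units than groups")
    ss_total = D2.sum() / (2.0 * N)
    ss_within = _ss_within(D2, codes, g)
    if ss_total <= 0:
        return 0.0
    ss_among = ss_total - ss_within
    if ss_within <= 0:
        return np.inf
    return (ss_among / (g - 1)) / (ss_within / (N - g))


def permanova(D, groups, n_perm: int = 999, seed=None) -> TestResult:
    """PERMANOVA pseudo-F with a random-permutation p-value."""
    D2 = _as_values(D) ** 2
    codes, g = _group_codes(groups)
    N = D2.shape[0]
    obs = pseudo_f(D, groups)
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    ss_total = D2.sum() / (2.0 * N)
    for b in range(n_perm):
        perm = rng.permutation(N)
        ssw = _ss_within(D2, codes[perm], g)
        if ss_total <= 0:
            null[b] = 0.0
        elif ssw <= 0:
            null[b] = np.inf
        else:
            null[b] = ((ss_total - ssw) / (g - 1)) / (ssw / (N - g))
    if ss_total <= 0:
        p = 1.0
    else:
        p = (np.count_nonzero(null >= obs) + 1) / (n_perm + 1)
    return TestResult(
        statistic=obs, p_permutation=float(p), n_perm=n_perm, null_distribution=null
    )


def model_based_null(
    Y,
    groups,
    model,
    n_sim: int = 999,
    seed=None,
    measure: str = "braycurtis",
    transform: str = "sqrt",
    probs: str = "equal",
    statistic: str = "permanova",
    m_axes: int | None = None,
) -> TestResult:
    """Model-based test: null distribution simulated from the fitted copulas.

    Under H_0 every simulated sampling unit's generating group is drawn
    multinomially -- with probability 1/g per group (``probs="equal"``),
    proportional to group sizes (``probs="sizes"``), or all units from a
    single pooled model (``probs="pooled"``, requires a one-group model).
    The observed statistic is compared against statistics recomputed on
    each simulated dataset with the nominal group labels.
    """
    Y = np.asarray(Y)
    groups = np.asarray(groups)
    rng = np.random.default_rng(seed)
    D = _dissim(Y, measure, transform)
    if statistic == "permanova":
        obs = pseudo_f(D, groups)
    elif statistic == "cap":
        obs = cap(D, groups, m_axes=m_axes, n_perm=0).statistic
    else:
        raise ValueError("statistic must be 'permanova' or 'cap'")

    g = model.g
    sizes = np.asarray(model.sizes)
    if probs == "equal":
        P_rows = np.full((g, g), 1.0 / g)
    elif probs == "sizes":
        P_rows = np.tile(sizes / sizes.sum(), (g, 1))
    elif probs == "pooled":
        if g != 1:
            raise ValueError("probs='pooled' requires a single pooled-model group")
        P_rows = np.ones((1, 1))
    else:
        raise ValueError("probs must be 'equal', 'sizes' or 'pooled'")

    null = np.empty(n_sim)
    nominal = np.asarray(
        [lab for lab, n_i in zip(model.group_labels(), model.sizes) for _ in range(n_i)]
    )
    if probs == "pooled":
        nominal = groups  # nominal design labels on pooled-model draws
    for b in range(n_sim):
        Ysim, _ = simulate_mixture(model, P_rows, rng)
        Db = _dissim(Ysim, measure, transform)
        if statistic == "permanova":
            null[b] = pseudo_f(Db, nominal)
        else:
            null[b] = cap(Db, nominal, m_axes=m_axes, n_perm=0).statistic
    p = (np.count_nonzero(null >= obs) + 1) / (n_sim + 1)
    return TestResult(
        statistic=obs, p_model_based=float(p), n_sim=n_sim, null_distribution=null
    )


def _dissim(Y, measure: str, transform: str) -> DissimilarityMatrix:
    if measure == "braycurtis":
        return bray_curtis(Y, transform=transform)
    if measure == "euclidean":
        return euclidean(Y, transform=transform)
    raise ValueError(f"unknown measure {measure!r}")


# ---------------------------------------------------------------------------
# CAP


@dataclass
class CapResult:
    statistic: float  # sum of squared canonical correlations (trace)
    first_canonical_sq: float
    m_axes: int
    allocation_success: float  # leave-one-out, overall fraction correct
    p_permutation: float = None
    n_perm: int = 0
    null_distribution: np.ndarray = None
    canonical_scores: np.ndarray = None


def _canonical_sq_correlations(Q: np.ndarray, codes: np.ndarray, g: int) -> np.ndarray:
    """Squared canonical correlations between coordinates Q and group dummies."""
    N, m = Q.shape
    X = np.zeros((N, g))
    X[np.arange(N), codes] = 1.0
    Qc = Q - Q.mean(axis=0)
    Xc = X - X.mean(axis=0)
    Sqq = Qc.T @ Qc
    Sxx = Xc.T @ Xc
    Sqx = Qc.T @ Xc
    # use pseudo-inverses: Sxx is rank g-1 by construction
    M = np.linalg.pinv(Sqq) @ Sqx @ np.linalg.pinv(Sxx) @ Sqx.T
    ev = np.linalg.eigvals(M).real
    ev = np.clip(np.sort(ev)[::-1], 0.0, 1.0)
    return ev[: min(m, g - 1)]


def _canonical_axes(Q: np.ndarray, codes: np.ndarray, g: int) -> np.ndarray:
    """Canonical discriminant axes (columns) for Q given group codes."""
    N, m = Q.shape
    Qc = Q - Q.mean(axis=0)
    means = np.stack([Qc[codes == k].mean(axis=0) for k in range(g)])
    counts = np.bincount(codes, minlength=g).astype(float)
    B = (means.T * counts) @ means
    W = Qc.T @ Qc - B
    # regularize W slightly for near-singular within-group scatter
    W = W + 1e-10 * np.trace(W) / m * np.eye(m)
    ev, vec = np.linalg.eig(np.linalg.solve(W, B))
    order = np.argsort(ev.real)[::-1]
    return vec.real[:, order[: g - 1]]


def cap(
    D,
    groups,
    m_axes: int | None = None,
    n_perm: int = 999,
    seed=None,
    max_m: int | None = None,
    compute_loo: bool = True,
) -> CapResult:
    """Canonical analysis of principal coordinates with LOO allocation.

    PCoA axes (positive eigenvalues only) feed a canonical discriminant
    analysis on the group labels.  When ``m_axes`` is None it is chosen to
    maximize leave-one-out allocation success (ties to the smaller m).
    The test statistic is the sum of squared canonical correlations; its
    p-value comes from permuting group labels with the PCoA fixed.
    """
    codes, g = _group_codes(groups)
    pc = pcoa(D)
    Qfull = pc.coordinates
    N, n_pos = Qfull.shape
    if m_axes is not None and m_axes > n_pos:
        raise ValueError(f"m_axes={m_axes} exceeds the {n_pos} positive-eigenvalue axes")

    def loo_success(m: int) -> float:
        Q = Qfull[:, :m]
        correct = 0
        for i in range(N):
            mask = np.ones(N, dtype=bool)
            mask[i] = False
            ci = codes[mask]
            if np.unique(ci).size < g:
                continue
            axes = _canonical_axes(Q[mask], ci, g)
            scores = Q[mask] @ axes
            cents = np.stack([scores[ci == k].mean(axis=0) for k in range(g)])
            zi = Q[i] @ axes
            if np.argmin(np.linalg.norm(cents - zi, axis=1)) == codes[i]:
                correct += 1
        return correct / N

    if m_axes is None:
        upper = min(n_pos, N - g - 1 if N - g - 1 >= 1 else n_pos)
        if max_m is not None:
            upper = min(upper, max_m)
        successes = [(loo_success(m), -m) for m in range(1, upper + 1)]
        best = max(successes)
        m_axes = -best[1]
        alloc = best[0]
    else:
        alloc = loo_success(m_axes) if compute_loo else np.nan

    Q = Qfull[:, :m_axes]
    ev = _canonical_sq_correlations(Q, codes, g)
    stat = float(ev.sum())
    first = float(ev[0]) if ev.size else 0.0

    p = None
    null = None
    if n_perm > 0:
        rng = np.random.default_rng(seed)
        null = np.empty(n_perm)
        for b in range(n_perm):
            null[b] = _canonical_sq_correlations(Q, codes[rng.permutation(N)], g).sum()
        p = float((np.count_nonzero(null >= stat) + 1) / (n_perm + 1))

    axes = _canonical_axes(Q, codes, g)
    return CapResult(
        statistic=stat,
        first_canonical_sq=first,
        m_axes=m_axes,
        allocation_success=alloc,
        p_permutation=p,
        n_perm=n_perm,
        null_distribution=null,
        canonical_scores=Q @ axes,
    )


# ---------------------------------------------------------------------------
# Power along the multinomial mixture continuum


@dataclass
class MixtureSchedule:
    """The H_0 -> H_A continuum P_k = (1 - f_k) P0 + f_k PA.

    P0 and PA are g x g row-stochastic matrices: entry (i, j) is the
    probability that a unit nominally in group i is generated from group
    j's model.  ``f`` runs from 0 (null) to 1 (alternative).
    """

    P0: np.ndarray
    PA: np.ndarray
    f: np.ndarray

    def __post_init__(self):
        self.P0 = np.asarray(self.P0, dtype=float)
        self.PA = np.asarray(self.PA, dtype=float)
        self.f = np.asarray(self.f, dtype=float)
        for name, P in (("P0", self.P0), ("PA", self.PA)):
            if P.ndim != 2 or P.shape[0] != P.shape[1]:
                raise ValueError(f"{name} must be square")
            if not np.allclose(P.sum(axis=1), 1.0):
                raise ValueError(f"rows of {name} must sum to 1")
            if np.any(P < 0):
                raise ValueError(f"{name} must be non-negative")
        if np.any((self.f < 0) | (self.f > 1)):
            raise ValueError("fractions must lie in [0, 1]")
        if self.f.size and (self.f[0] != 0.0 or self.f[-1] != 1.0):
            raise ValueError("schedule must start at f=0 and end at f=1")

    @classmethod
    def equal_to_identity(cls, g: int, n_steps: int = 20) -> "MixtureSchedule":
        """Default schedule: equiprobable null to fully distinct groups."""
        return cls(
            P0=np.full((g, g), 1.0 / g), PA=np.eye(g), f=np.linspace(0.0, 1.0, n_steps)
        )

    def P(self, k: int) -> np.ndarray:
        return (1.0 - self.f[k]) * self.P0 + self.f[k] * self.PA


def simulate_mixture(model, P_rows: np.ndarray, rng) -> tuple[np.ndarray, np.ndarray]:
    """Simulate one dataset where each unit's generating group is multinomial.

    Group sizes follow the nominal design (model.sizes); the mixture picks
    each unit's generating model, not the sizes.  Returns the counts and
    the nominal group labels.
    """
    from .copula import simulate_counts

    sizes = np.asarray(model.sizes)
    g = model.g
    labels = model.group_labels()
    N = int(sizes.sum())
    p = model.p
    gen = np.empty(N, dtype=int)
    nominal = np.empty(N, dtype=object)
    pos = 0
    for i in range(g):
        n_i = int(sizes[i])
        gen[pos : pos + n_i] = rng.choice(g, size=n_i, p=P_rows[i])
        nominal[pos : pos + n_i] = labels[i]
        pos += n_i
    Y = np.empty((N, p), dtype=np.int64)
    for j in range(g):
        rows = np.flatnonzero(gen == j)
        if rows.size:
            Y[rows] = simulate_counts(model.groups[j], rows.size, seed=rng.integers(2**31))
    return Y, nominal


def power_curve(
    model,
    schedule: MixtureSchedule | None = None,
    test: str = "permanova",
    n_sims_per_step: int = 200,
    alpha: float = 0.05,
    n_perm: int = 199,
    seed=None,
    measure: str = "braycurtis",
    transform: str = "sqrt",
    m_axes: int | None = None,
) -> pd.DataFrame:
    """Empirical power of PERMANOVA or CAP along the mixture continuum.

    At step k each simulated unit in nominal group i draws its generating
    group j with probability P_k[i, j] and its counts from group j's
    copula model; the chosen test is run with ``n_perm`` permutations and
    power is the fraction of p-values <= alpha.  Returns a DataFrame with
    columns f, n_sims, power, se (binomial standard error).
    """
    if test not in ("permanova", "cap"):
        raise ValueError("test must be 'permanova' or 'cap'")
    if n_sims_per_step < 1:
        raise ValueError("n_sims_per_step must be >= 1")
    if schedule is None:
        schedule = MixtureSchedule.equal_to_identity(model.g)
    if schedule.P0.shape[0] != model.g:
        raise ValueError("schedule dimension must match the number of groups")
    rng = np.random.default_rng(seed)
    rows = []
    for k in range(schedule.f.size):
        Pk = schedule.P(k)
        rejections = 0
        for _ in range(n_sims_per_step):
            Y, nominal = simulate_mixture(model, Pk, rng)
            D = _dissim(Y, measure, transform)
            if test == "permanova":
                res = permanova(D, nominal, n_perm=n_perm, seed=rng.integers(2**31))
                pval = res.p_permutation
            else:
                res = cap(
                    D,
                    nominal,
                    m_axes=m_axes,
                    n_perm=n_perm,
                    seed=rng.integers(2**31),
                    compute_loo=False,
                )
                pval = res.p_permutation
            rejections += pval <= alpha
        power = rejections / n_sims_per_step
        rows.append(
            {
                "f": schedule.f[k],
                "n_sims": n_sims_per_step,
                "power": power,
                "se": np.sqrt(power * (1 - power) / n_sims_per_step),
            }
        )
    return pd.DataFrame(rows)
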