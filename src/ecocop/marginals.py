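"""Discrete marginal distributions for species counts.

Each species in a community table is modelled by one of four count
families -- Poisson, zero-inflated Poisson (ZIP), negative binomial (NB)
or zero-inflated NB (ZINB) -- parameterized by the mean of the count
component ``mu``, the NB dispersion ``theta`` (variance ``mu + mu**2/theta``)
and the structural-zero mixture weight ``pi``.  Maximum-likelihood fits are
compared with the small-sample corrected AIC (AICc) to pick a family per
species (optionally per group of sampling units).

Species observed as all zeros are represented by a degenerate point mass
at zero: their cdf jumps to 1 at y=0, which makes the latent Gaussian
bounds used by the copula unbounded, so they are simulated as constant
zero and excluded from copula estimation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.base import BaseEstimator

__all__ = [
    "FAMILIES",
    "CountMarginal",
    "FittedMarginal",
    "MarginalModel",
    "fit_marginal",
    "select_marginal",
    "flag_rare",
    "fit_marginal_table",
]

#: model-selection candidate families, in tie-breaking order
FAMILIES = ("poisson", "zip", "nb", "zinb")

_N_PARAMS = {"poisson": 1, "zip": 2, "nb": 2, "zinb": 3, "zero": 0}
_ZERO_INFLATED = {"zip", "zinb"}
_HAS_THETA = {"nb", "zinb"}

# quantile clamp: q=1 maps to the smallest y with 1 - F(y) below this
_TAIL_EPS = 1e-12


class ParameterError(ValueError):
    """Marginal parameters outside their admissible range."""


@dataclass(frozen=True)
class CountMarginal:
    """A single species' count distribution.

    Parameters
    ----------
    family : {"poisson", "zip", "nb", "zinb", "zero"}
        Distribution family; ``"zero"`` is the degenerate point mass at 0
        used for species never observed.
    mu : float
        Mean of the count component (> 0; ignored for ``"zero"``).
    theta : float, optional
        NB dispersion (> 0); required for "nb"/"zinb".
    pi : float, optional
        Structural-zero probability in [0, 1); required for "zip"/"zinb".
    """

    family: str
    mu: float | None = None
    theta: float | None = None
    pi: float | None = None

    def __post_init__(self) -> None:
        fam = self.family
        if fam not in _N_PARAMS:
            raise ParameterError(f"unknown family {fam!r}")
        if fam == "zero":
            return
        if self.mu is None or not (self.mu > 0) or not math.isfinite(self.mu):
            raise ParameterError(f"mu must be positive and finite, got {self.mu}")
        if fam in _HAS_THETA:
            if self.theta is None or not (self.theta > 0):
                raise ParameterError(f"theta must be positive for {fam}, got {self.theta}")
        elif self.theta is not None:
            raise ParameterError(f"theta is not a parameter of {fam}")
        if fam in _ZERO_INFLATED:
            if self.pi is None or not (0.0 <= self.pi < 1.0):
                raise ParameterError(f"pi must lie in [0, 1) for {fam}, got {self.pi}")
        elif self.pi is not None:
            raise ParameterError(f"pi is not a parameter of {fam}")

    # -- internals ---------------------------------------------------------

    @property
    def is_degenerate(self) -> bool:
        return self.family == "zero"

    def _base(self):
        """Frozen scipy distribution of the count component."""
        if self.family in ("poisson", "zip"):
            return stats.poisson(self.mu)
        # NB parameterized by size theta and p = theta / (theta + mu)
        return stats.nbinom(self.theta, self.theta / (self.theta + self.mu))

    @property
    def _pi(self) -> float:
        return self.pi if self.family in _ZERO_INFLATED else 0.0

    # -- distribution interface -------------------------------------------

    def mean(self) -> float:
        if self.is_degenerate:
            return 0.0
        return (1.0 - self._pi) * self.mu

    def var(self) -> float:
        if self.is_degenerate:
            return 0.0
        pi = self._pi
        base_var = self.mu if self.family in ("poisson", "zip") else self.mu + self.mu**2 / self.theta
        # mixture variance of pi*delta_0 + (1-pi)*base
        return (1 - pi) * (base_var + pi * self.mu**2)

    def pmf(self, y) -> np.ndarray | float:
        y = np.asarray(y)
        if self.is_degenerate:
            return np.where(y == 0, 1.0, 0.0)[()]
        pi = self._pi
        out = (1.0 - pi) * self._base().pmf(y)
        return np.where(y == 0, pi + out, out)[()]

    def cdf(self, y) -> np.ndarray | float:
        """F(y) on integers; F(-1) = 0 by convention."""
        y = np.asarray(y, dtype=float)
        if np.any(y < -1):
            raise ValueError("cdf defined on integers >= -1")
        if self.is_degenerate:
            return np.where(y >= 0, 1.0, 0.0)[()]
        pi = self._pi
        out = pi + (1.0 - pi) * self._base().cdf(y)
        return np.where(y < 0, 0.0, out)[()]

    @property
    def cdf_table(self) -> np.ndarray:
        """F(0), F(1), ..., F(ymax), where ymax is the q=1 tail clamp.

        Quantiles are inverted against this table (computed by the same
        cdf path), which makes quantile(cdf(y)) = y hold exactly on the
        support.  Cached per instance.
        """
        cached = self.__dict__.get("_cdf_table")
        if cached is not None:
            return cached
        # upper support bound: start from scipy's ppf and extend if needed
        ymax = int(self._base().ppf(1.0 - _TAIL_EPS * (1.0 - self._pi)))
        table = np.asarray(self.cdf(np.arange(ymax + 1)), dtype=float)
        while 1.0 - table[-1] >= _TAIL_EPS:
            ymax = 2 * ymax + 10
            table = np.asarray(self.cdf(np.arange(ymax + 1)), dtype=float)
        self.__dict__["_cdf_table"] = table
        return table

    def quantile(self, q) -> np.ndarray | float:
        """Smallest integer y >= 0 with F(y) >= q.

        q = 1 is clamped to the smallest y whose upper tail probability is
        below 1e-12, so the copula inverse map always yields finite counts.
        """
        q = np.asarray(q, dtype=float)
        if np.any((q < 0) | (q > 1)):
            raise ValueError("quantile levels must lie in [0, 1]")
        if self.is_degenerate:
            return np.zeros_like(q)[()]
        table = self.cdf_table
        out = np.searchsorted(table, q, side="left")
        return np.minimum(out, table.size - 1).astype(float)[()]

    # alias matching scipy naming
    ppf = quantile

    def rvs(self, size: int, random_state=None) -> np.ndarray:
        """Direct (non-copula) sampling, used as a distributional oracle."""
        rng = np.random.default_rng(random_state)
        if self.is_degenerate:
            return np.zeros(size, dtype=np.int64)
        draws = self._base().rvs(size=size, random_state=rng).astype(np.int64)
        pi = self._pi
        if pi > 0:
            draws[rng.random(size) < pi] = 0
        return draws

    def loglik(self, counts: np.ndarray) -> float:
        counts = np.asarray(counts)
        if self.is_degenerate:
            return 0.0 if np.all(counts == 0) else -np.inf
        pi = self._pi
        logpmf = self._base().logpmf(counts)
        if pi > 0:
            is0 = counts == 0
            with np.errstate(divide="ignore"):
                out = np.where(
                    is0,
                    np.logaddexp(np.log(pi), np.log1p(-pi) + logpmf),
                    np.log1p(-pi) + logpmf,
                )
        else:
            out = logpmf
        return float(np.sum(out))

    def to_dict(self) -> dict:
        d = {"family": self.family}
        for key in ("mu", "theta", "pi"):
            v = getattr(self, key)
            if v is not None:
                d[key] = float(v)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CountMarginal":
        return cls(
            family=d["family"],
            mu=d.get("mu"),
            theta=d.get("theta"),
            pi=d.get("pi"),
        )


@dataclass(frozen=True)
class FittedMarginal:
    """A maximum-likelihood fit of one family to one species' counts."""

    marginal: CountMarginal
    loglik: float
    aicc: float
    n: int
    k: int
    converged: bool = True

    @property
    def family(self) -> str:
        return self.marginal.family


def _aicc(loglik: float, k: int, n: int) -> float:
    if n <= k + 1:
        return np.inf
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def _validate_counts(counts) -> np.ndarray:
    y = np.asarray(counts)
    if y.ndim != 1 or y.size < 2:
        raise ValueError("counts must be a 1-D vector of length >= 2")
    if np.any(y < 0) or not np.all(np.equal(np.mod(y, 1), 0)):
        raise ValueError("counts must be non-negative integers")
    return y.astype(np.int64)


def _count_logpmf(y: np.ndarray, mu: float, theta: float | None) -> np.ndarray:
    """Log-pmf of the count component (Poisson when theta is None, else NB)."""
    from scipy.special import gammaln

    if theta is None:
        return y * math.log(mu) - mu - gammaln(y + 1)
    return (
        gammaln(y + theta)
        - gammaln(theta)
        - gammaln(y + 1)
        + theta * math.log(theta / (theta + mu))
        + y * math.log(mu / (theta + mu))
    )


def _nll(family: str, params: np.ndarray, y: np.ndarray) -> float:
    """Negative log-likelihood on the unconstrained scale.

    params are (log mu[, log theta][, logit pi]) depending on the family.
    """
    if np.any(np.abs(params) > 40):
        return np.inf
    mu = math.exp(params[0])
    theta = None
    i = 1
    if family in _HAS_THETA:
        theta = math.exp(params[i])
        i += 1
    logpmf = _count_logpmf(y, mu, theta)
    if family in _ZERO_INFLATED:
        pi = 1.0 / (1.0 + math.exp(-params[i]))
        is0 = y == 0
        out = np.where(
            is0,
            np.logaddexp(math.log(pi), math.log1p(-pi) + logpmf),
            math.log1p(-pi) + logpmf,
        )
    else:
        out = logpmf
    ll = float(np.sum(out))
    return np.inf if not np.isfinite(ll) else -ll


def fit_marginal(counts, family: str = "nb") -> FittedMarginal:
    """Fit one count family to a species by maximum likelihood.

    All-zero species yield the degenerate point-mass-at-zero marginal
    (flagged ``converged=True`` with k=0) regardless of the requested
    family.  Zero-inflated fits use multi-start Nelder-Mead over
    ``pi in {0.01, 0.25, 0.5}`` to avoid boundary local optima.
    """
    y = _validate_counts(counts)
    n = y.size
    if family not in FAMILIES:
        raise ValueError(f"family must be one of {FAMILIES}, got {family!r}")
    if np.all(y == 0):
        m = CountMarginal("zero")
        return FittedMarginal(m, loglik=0.0, aicc=_aicc(0.0, 0, n), n=n, k=0)

    ybar = float(np.mean(y))
    k = _N_PARAMS[family]

    if family == "poisson":
        m = CountMarginal("poisson", mu=ybar)
        ll = m.loglik(y)
        return FittedMarginal(m, loglik=ll, aicc=_aicc(ll, k, n), n=n, k=k)

    if family == "nb":
        # mu-MLE is the sample mean for any theta; profile over log theta
        def prof(logth):
            return _nll("nb", np.array([math.log(ybar), logth]), y)

        res = optimize.minimize_scalar(prof, bounds=(-7.0, 16.0), method="bounded")
        theta = math.exp(res.x)
        m = CountMarginal("nb", mu=ybar, theta=theta)
        ll = -res.fun
        return FittedMarginal(
            m, loglik=ll, aicc=_aicc(ll, k, n), n=n, k=k, converged=bool(res.success)
        )

    # zero-inflated families: multi-start simplex on the full likelihood
    best = None
    mu0 = max(ybar, 0.1)
    for pi0 in (0.01, 0.25, 0.5):
        x0 = [math.log(mu0 / (1 - pi0))]
        if family == "zinb":
            x0.append(0.0)  # log theta = 0
        x0.append(math.log(pi0 / (1 - pi0)))
        res = optimize.minimize(
            lambda p: _nll(family, p, y),
            np.array(x0),
            method="Nelder-Mead",
            options={"xatol": 1e-5, "fatol": 1e-8, "maxiter": 2000},
        )
        if best is None or res.fun < best.fun:
            best = res
        # prefer a cleanly converged start that reached the same optimum
        # (theta can wander on a flat ridge when the NB degenerates to Poisson)
        elif res.success and not best.success and res.fun <= best.fun + 1e-6:
            best = res
    p = best.x
    mu = math.exp(p[0])
    if family == "zinb":
        theta, pi = math.exp(p[1]), 1.0 / (1.0 + math.exp(-p[2]))
        m = CountMarginal("zinb", mu=mu, theta=theta, pi=pi)
    else:
        pi = 1.0 / (1.0 + math.exp(-p[1]))
        m = CountMarginal("zip", mu=mu, pi=pi)
    ll = -best.fun
    converged = bool(best.success) and np.isfinite(ll)
    if not converged:
        warnings.warn(f"{family} fit did not converge (n={n})", RuntimeWarning)
    return FittedMarginal(m, loglik=ll, aicc=_aicc(ll, k, n), n=n, k=k, converged=converged)


def select_marginal(counts, families: Sequence[str] = FAMILIES) -> FittedMarginal:
    """Fit each candidate family and return the one with minimal AICc.

    Candidates with n <= k+1 (AICc denominator non-positive) are excluded
    with a warning.  Ties are broken by fewest parameters, then by the
    order of :data:`FAMILIES`.
    """
    if not families:
        raise ValueError("families must be non-empty")
    y = _validate_counts(counts)
    if np.all(y == 0):
        return fit_marginal(y, families[0])
    fits: list[tuple[float, int, int, FittedMarginal]] = []
    failures = []
    for fam in FAMILIES:  # fixed order for deterministic tie-breaks
        if fam not in families:
            continue
        k = _N_PARAMS[fam]
        if y.size <= k + 1:
            warnings.warn(
                f"excluding {fam}: n={y.size} <= k+1={k + 1} (AICc undefined)",
                RuntimeWarning,
            )
            continue
        try:
            fit = fit_marginal(y, fam)
        except Exception as exc:  # pragma: no cover - defensive
            failures.append(f"{fam}: {exc}")
            continue
        if not np.isfinite(fit.aicc):
            failures.append(f"{fam}: non-finite AICc")
            continue
        fits.append((fit.aicc, fit.k, FAMILIES.index(fam), fit))
    if not fits:
        raise RuntimeError("no candidate family could be fitted: " + "; ".join(failures))
    fits.sort(key=lambda t: (t[0], t[1], t[2]))
    return fits[0][3]


class MarginalModel(BaseEstimator):
    """Scikit-learn style estimator for a single species' marginal.

    Parameters
    ----------
    family : str, default "auto"
        One of :data:`FAMILIES`, or "auto" for AICc selection among
        ``families``.
    families : tuple of str
        Candidate set used when ``family="auto"``.

    Attributes
    ----------
    marginal_ : CountMarginal
    family_, mu_, theta_, pi_, loglik_, aicc_, converged_
    """

    def __init__(self, family: str = "auto", families: Sequence[str] = FAMILIES):
        self.family = family
        self.families = families

    def fit(self, y, X=None):
        if self.family == "auto":
            fit = select_marginal(y, self.families)
        else:
            fit = fit_marginal(y, self.family)
        self.fit_ = fit
        self.marginal_ = fit.marginal
        self.family_ = fit.marginal.family
        self.mu_ = fit.marginal.mu
        self.theta_ = fit.marginal.theta
        self.pi_ = fit.marginal.pi
        self.loglik_ = fit.loglik
        self.aicc_ = fit.aicc
        self.converged_ = fit.converged
        return self


def flag_rare(Y, min_prevalence: float = 0.05) -> np.ndarray:
    """Flag species occurring as singletons or in < ``min_prevalence`` of units.

    The singleton rule applies regardless of the threshold; the prevalence
    comparison is strict, so a species exactly at the threshold is kept.
    """
    if not (0.0 < min_prevalence < 1.0):
        raise ValueError("min_prevalence must lie in (0, 1)")
    Y = np.asarray(Y)
    occ = np.count_nonzero(Y > 0, axis=0)
    prevalence = occ / Y.shape[0]
    return (occ <= 1) | (prevalence < min_prevalence)


def fit_marginal_table(
    Y,
    groups=None,
    species: Iterable[str] | None = None,
    families: Sequence[str] = FAMILIES,
    per_group: bool = True,
) -> tuple[pd.DataFrame, dict]:
    """AICc-select a marginal for every species (optionally per group).

    Returns a tidy report DataFrame (species, group, family, mu, theta, pi,
    loglik, aicc, n, converged) and a dict mapping group label -> list of
    :class:`CountMarginal` in species-column order.  With ``per_group=False``
    (or no groups) a single pooled fit per species is computed under the
    group label ``"pooled"``.
    """
    Y = np.asarray(Y)
    N, p = Y.shape
    if species is None:
        species = [f"sp{j + 1}" for j in range(p)]
    species = list(species)
    if groups is None or not per_group:
        group_index = {"pooled": np.arange(N)}
    else:
        groups = np.asarray(groups)
        group_index = {g: np.flatnonzero(groups == g) for g in pd.unique(groups)}

    rows = []
    models: dict = {}
    for g, idx in group_index.items():
        fitted = []
        for j, name in enumerate(species):
            fit = select_marginal(Y[idx, j], families)
            fitted.append(fit.marginal)
            m = fit.marginal
            rows.append(
                {
                    "species": name,
                    "group": g,
                    "family": m.family,
                    "mu": m.mu,
                    "theta": m.theta,
                    "pi": m.pi,
                    "loglik": fit.loglik,
                    "aicc": fit.aicc,
                    "n": fit.n,
                    "converged": fit.converged,
                }
            )
        models[g] = fitted
    return pd.DataFrame(rows), models
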