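"""Gaussian copula over discrete marginals, estimated by Monte Carlo EM.

An observed count vector y = (y_1, ..., y_p) does not pin down a single
point in the latent Gaussian space: each coordinate is only known to lie
in the interval (Phi^{-1}(F_j(y_j - 1)), Phi^{-1}(F_j(y_j))], so y maps to
a hyper-rectangle.  The copula correlation matrix Sigma is therefore
estimated by an MCEM algorithm, conditioning on the fixed marginal fits:

  E-step  sample latent vectors from MVN(0, Sigma) truncated to each
          observation's hyper-rectangle via coordinate-wise Gibbs sweeps
          (all observations x Monte Carlo replicates updated in one
          vectorized pass per coordinate);
  M-step  average the sampled outer products and project the result to the
          nearest valid correlation matrix (unit-diagonal rescale plus
          eigenvalue clipping).

Monte Carlo sample size grows geometrically across iterations to damp
simulation noise near convergence; convergence is declared on a Polyak
average of recent iterates.

Simulation goes the other way: draw z ~ MVN(0, Sigma), push each
coordinate through Phi, and invert the species' marginal cdf to get a
count.  Species outside the modelled association set are independent
(zero off-diagonals); degenerate (never-observed) species are emitted as
constant zero.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.special import ndtr, ndtri
from sklearn.base import BaseEstimator

from .association import index_of_association
from .marginals import CountMarginal

__all__ = [
    "latent_bounds",
    "expand_correlation",
    "nearest_correlation",
    "mcem_fit",
    "GaussianCopula",
    "McemSettings",
    "GroupCopulaModel",
    "CommunityModel",
    "simulate_counts",
    "rho_to_I_curve",
    "choose_rho_for_I",
]

_U_EPS = 1e-14  # clamp for uniform draws inside truncated intervals


def latent_bounds(y, marginal: CountMarginal) -> tuple[np.ndarray, np.ndarray]:
    """Hyper-rectangle bounds on the latent Gaussian scale for counts ``y``.

    Returns ``(Phi^{-1}(F(y-1)), Phi^{-1}(F(y))]`` with the conventions
    ``Phi^{-1}(0) = -inf`` and ``Phi^{-1}(1) = +inf``.  A degenerate
    point-mass-at-zero marginal yields (-inf, +inf): such species carry no
    latent information and must be excluded upstream.
    """
    y = np.asarray(y)
    if marginal.is_degenerate:
        shape = y.shape
        return np.full(shape, -np.inf), np.full(shape, np.inf)
    lo_cdf = np.asarray(marginal.cdf(y - 1), dtype=float)
    hi_cdf = np.asarray(marginal.cdf(y), dtype=float)
    with np.errstate(divide="ignore"):
        lo = np.where(lo_cdf <= 0.0, -np.inf, ndtri(np.clip(lo_cdf, 0.0, 1.0)))
        hi = np.where(hi_cdf >= 1.0, np.inf, ndtri(np.clip(hi_cdf, 0.0, 1.0)))
    return lo, hi


def expand_correlation(sigma_m: np.ndarray, idx, p: int) -> np.ndarray:
    """Embed an m x m correlation block at ``idx`` in a p x p identity."""
    idx = np.asarray(idx, dtype=int)
    sigma_m = np.asarray(sigma_m, dtype=float)
    if idx.size != sigma_m.shape[0] or sigma_m.shape[0] != sigma_m.shape[1]:
        raise ValueError("idx length must match sigma_m dimension")
    if idx.size != np.unique(idx).size:
        raise ValueError("duplicate species indices")
    if idx.size and (idx.min() < 0 or idx.max() >= p):
        raise ValueError("species indices out of range")
    sigma = np.eye(p)
    sigma[np.ix_(idx, idx)] = sigma_m
    return sigma


def nearest_correlation(S: np.ndarray, eig_floor: float = 1e-8) -> np.ndarray:
    """Project a symmetric second-moment matrix to a valid correlation matrix.

    Rescales to unit diagonal (D^{-1/2} S D^{-1/2}); if any eigenvalue is
    negative, clips eigenvalues at ``eig_floor`` and rescales again.
    """
    S = 0.5 * (S + S.T)
    d = np.sqrt(np.clip(np.diag(S), 1e-300, None))
    C = S / np.outer(d, d)
    w, V = np.linalg.eigh(C)
    if w.min() < 0:
        w = np.clip(w, eig_floor, None)
        C = (V * w) @ V.T
        d = np.sqrt(np.diag(C))
        C = C / np.outer(d, d)
        C = 0.5 * (C + C.T)
    np.fill_diagonal(C, 1.0)
    return C


@dataclass
class McemSettings:
    """Tuning knobs of the MCEM fit.

    n_mc grows by a factor 1.2 per EM iteration (capped at ``n_mc_cap``)
    so late iterations average over more latent draws; ``burnin`` Gibbs
    sweeps are run per E-step with chains warm-started across iterations.
    """

    n_mc: int = 20
    max_iter: int = 100
    tol: float = 0.005
    seed: int | None = None
    burnin: int = 8
    n_mc_cap: int = 200
    polyak_window: int = 5

    def __post_init__(self):
        if self.n_mc < 10:
            raise ValueError("n_mc must be >= 10")
        if self.tol <= 0:
            raise ValueError("tol must be positive")


def _normal_scores_init(Y: np.ndarray, shrink: float = 0.1) -> np.ndarray:
    """Initial Sigma from pairwise normal-scores rank correlations (midranks)."""
    from scipy.stats import rankdata

    n, m = Y.shape
    Z = ndtri((rankdata(Y, axis=0, method="average") - 0.5) / n)
    C = np.corrcoef(Z, rowvar=False)
    C = np.atleast_2d(C)
    C = (1.0 - shrink) * C + shrink * np.eye(m)
    np.fill_diagonal(C, 1.0)
    return C


def _gibbs_sweeps(
    Z: np.ndarray,
    lo: np.ndarray,
    hi: np.ndarray,
    sigma: np.ndarray,
    n_sweeps: int,
    rng: np.random.Generator,
) -> None:
    """In-place Gibbs sweeps of truncated-MVN chains.

    Z has shape (n_chains, m); lo/hi broadcast to the same shape.  Each
    sweep updates every coordinate from its full conditional normal
    truncated to (lo, hi], using inverse-cdf sampling.
    """
    m = sigma.shape[0]
    prec = np.linalg.inv(sigma)
    cond_sd = 1.0 / np.sqrt(np.diag(prec))
    for _ in range(n_sweeps):
        for j in range(m):
            # conditional mean given the other coordinates
            mu_j = Z[:, j] - (Z @ prec[:, j]) / prec[j, j]
            a = ndtr((lo[:, j] - mu_j) / cond_sd[j])
            b = ndtr((hi[:, j] - mu_j) / cond_sd[j])
            u = a + (b - a) * rng.random(Z.shape[0])
            np.clip(u, _U_EPS, 1.0 - _U_EPS, out=u)
            Z[:, j] = mu_j + cond_sd[j] * ndtri(u)


def mcem_fit(
    Y_group,
    marginals,
    settings: McemSettings | None = None,
) -> tuple[np.ndarray, dict]:
    """Estimate the copula correlation matrix for one group of sampling units.

    Marginals are held fixed (the estimation is conditioned on the fitted
    per-species distributions).  Returns ``(sigma_hat, diagnostics)`` where
    diagnostics holds ``n_iter``, ``converged`` and the per-iteration
    maximal change history.
    """
    settings = settings or McemSettings()
    Y = np.asarray(Y_group)
    if Y.ndim != 2:
        raise ValueError("Y_group must be a 2-D count matrix slice")
    n, m = Y.shape
    if m < 2:
        raise ValueError("need at least two species to estimate a copula")
    for j, mg in enumerate(marginals):
        if mg.is_degenerate:
            raise ValueError(f"species {j} is degenerate (all zero) in this group")

    lo = np.empty((n, m))
    hi = np.empty((n, m))
    for j, mg in enumerate(marginals):
        lo[:, j], hi[:, j] = latent_bounds(Y[:, j], mg)

    rng = np.random.default_rng(settings.seed)
    sigma = _normal_scores_init(Y)

    # initialize chains at the midpoint (in probability) of each interval
    n_mc = int(settings.n_mc)
    u_mid = 0.5 * (ndtr(lo) + ndtr(hi))
    Z0 = ndtri(np.clip(u_mid, _U_EPS, 1.0 - _U_EPS))
    Z = np.repeat(Z0, n_mc, axis=0)  # (n * n_mc, m)
    LO = np.repeat(lo, n_mc, axis=0)
    HI = np.repeat(hi, n_mc, axis=0)

    history = []
    recent: list[np.ndarray] = []
    prev_avg = sigma.copy()
    converged = False
    n_iter = 0
    for n_iter in range(1, settings.max_iter + 1):
        _gibbs_sweeps(Z, LO, HI, sigma, settings.burnin, rng)
        S = (Z.T @ Z) / Z.shape[0]
        sigma = nearest_correlation(S)

        recent.append(sigma)
        if len(recent) > settings.polyak_window:
            recent.pop(0)
        avg = np.mean(recent, axis=0)
        delta = float(np.max(np.abs(avg - prev_avg)))
        history.append(delta)
        prev_avg = avg
        if len(recent) == settings.polyak_window and delta < settings.tol:
            converged = True
            break

        # grow the Monte Carlo sample geometrically (new chains copy old ones)
        new_n_mc = min(int(np.ceil(n_mc * 1.2)), settings.n_mc_cap)
        if new_n_mc > n_mc:
            extra = new_n_mc - n_mc
            Zb = Z.reshape(n, n_mc, m)
            Z = np.concatenate([Zb, Zb[:, :extra]], axis=1).reshape(n * new_n_mc, m)
            LO = np.repeat(lo, new_n_mc, axis=0)
            HI = np.repeat(hi, new_n_mc, axis=0)
            n_mc = new_n_mc

    sigma_hat = nearest_correlation(prev_avg)
    if not converged:
        warnings.warn(
            f"MCEM did not reach tol={settings.tol} in {settings.max_iter} iterations "
            f"(last max|dSigma| = {history[-1]:.4g})",
            RuntimeWarning,
        )
    diagnostics = {"n_iter": n_iter, "converged": converged, "history": history}
    return sigma_hat, diagnostics


class GaussianCopula(BaseEstimator):
    """Gaussian copula with fixed discrete marginals (scikit-learn style).

    Parameters mirror :class:`McemSettings`; ``marginals`` is the list of
    :class:`~ecocop.marginals.CountMarginal` for the columns of the data
    passed to :meth:`fit`.

    Attributes
    ----------
    sigma_ : (m, m) ndarray
        Estimated copula correlation matrix.
    n_iter_, converged_, history_ : MCEM diagnostics.
    """

    def __init__(
        self,
        marginals=None,
        n_mc: int = 20,
        max_iter: int = 100,
        tol: float = 0.005,
        burnin: int = 8,
        n_mc_cap: int = 200,
        random_state: int | None = None,
    ):
        self.marginals = marginals
        self.n_mc = n_mc
        self.max_iter = max_iter
        self.tol = tol
        self.burnin = burnin
        self.n_mc_cap = n_mc_cap
        self.random_state = random_state

    def fit(self, Y, y=None):
        if self.marginals is None:
            raise ValueError("marginals must be provided before fitting")
        settings = McemSettings(
            n_mc=self.n_mc,
            max_iter=self.max_iter,
            tol=self.tol,
            seed=self.random_state,
            burnin=self.burnin,
            n_mc_cap=self.n_mc_cap,
        )
        self.sigma_, diag = mcem_fit(Y, self.marginals, settings)
        self.n_iter_ = diag["n_iter"]
        self.converged_ = diag["converged"]
        self.history_ = diag["history"]
        return self

    def sample(self, n: int, random_state=None) -> np.ndarray:
        """Simulate n count vectors from the fitted copula model."""
        model = GroupCopulaModel(
            marginals=list(self.marginals),
            sigma=self.sigma_,
            assoc_index=np.arange(len(self.marginals)),
        )
        return simulate_counts(model, n, seed=random_state)


@dataclass
class GroupCopulaModel:
    """Fully specified copula model for one group: p marginals plus Sigma.

    Off-diagonal correlation is only allowed among ``assoc_index`` (the
    species whose associations were modelled jointly); everywhere else
    Sigma is the identity fill.
    """

    marginals: list
    sigma: np.ndarray
    assoc_index: np.ndarray = None
    group: object = None
    n: int | None = None

    def __post_init__(self):
        self.sigma = np.asarray(self.sigma, dtype=float)
        p = len(self.marginals)
        if self.sigma.shape != (p, p):
            raise ValueError("sigma dimension must match the number of marginals")
        if not np.allclose(self.sigma, self.sigma.T, atol=1e-10):
            raise ValueError("sigma must be symmetric")
        if not np.allclose(np.diag(self.sigma), 1.0, atol=1e-8):
            raise ValueError("sigma must have unit diagonal")
        if self.assoc_index is None:
            self.assoc_index = np.arange(p)
        self.assoc_index = np.asarray(self.assoc_index, dtype=int)
        outside = np.setdiff1d(np.arange(p), self.assoc_index)
        if outside.size:
            off = self.sigma[np.ix_(outside, np.arange(p))].copy()
            off[np.arange(outside.size), outside] = 0.0
            if np.any(off != 0.0):
                raise ValueError("off-diagonal entries outside assoc_index must be 0")

    @property
    def p(self) -> int:
        return len(self.marginals)

    def to_dict(self) -> dict:
        return {
            "group": self.group,
            "n": self.n,
            "assoc_index": self.assoc_index.tolist(),
            "marginals": [m.to_dict() for m in self.marginals],
            "sigma": self.sigma.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GroupCopulaModel":
        return cls(
            marginals=[CountMarginal.from_dict(m) for m in d["marginals"]],
            sigma=np.asarray(d["sigma"]),
            assoc_index=np.asarray(d["assoc_index"], dtype=int),
            group=d.get("group"),
            n=d.get("n"),
        )


@dataclass
class CommunityModel:
    """Per-group copula models sharing one species set and ordering."""

    groups: list  # of GroupCopulaModel
    sizes: list
    species: list = None

    def __post_init__(self):
        p = self.groups[0].p
        if any(g.p != p for g in self.groups):
            raise ValueError("all groups must share the species dimension")
        if len(self.sizes) != len(self.groups):
            raise ValueError("one sample size per group required")
        if self.species is None:
            self.species = [f"sp{j + 1}" for j in range(p)]

    @property
    def p(self) -> int:
        return self.groups[0].p

    @property
    def g(self) -> int:
        return len(self.groups)

    def group_labels(self) -> list:
        return [gm.group if gm.group is not None else i for i, gm in enumerate(self.groups)]

    def simulate(self, seed=None, sizes=None) -> tuple[np.ndarray, np.ndarray]:
        """One simulated community table: (counts, group labels)."""
        rng = np.random.default_rng(seed)
        sizes = self.sizes if sizes is None else sizes
        blocks, labels = [], []
        for gm, n_i, lab in zip(self.groups, sizes, self.group_labels()):
            blocks.append(simulate_counts(gm, n_i, seed=rng.integers(2**31)))
            labels.extend([lab] * n_i)
        return np.vstack(blocks), np.asarray(labels)

    def to_json(self, path=None) -> str:
        doc = {
            "schema": "ecocop-community-model/1",
            "species": list(self.species),
            "sizes": [int(s) for s in self.sizes],
            "groups": [g.to_dict() for g in self.groups],
        }
        text = json.dumps(doc, indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source: str) -> "CommunityModel":
        import os

        if os.path.exists(source):
            with open(source) as fh:
                doc = json.load(fh)
        else:
            doc = json.loads(source)
        return cls(
            groups=[GroupCopulaModel.from_dict(g) for g in doc["groups"]],
            sizes=doc["sizes"],
            species=doc["species"],
        )


def _quantile_table(m: CountMarginal) -> np.ndarray:
    """cdf values F(0), F(1), ..., F(ymax) up to the q=1 tail clamp.

    Quantile lookup then reduces to a searchsorted: the smallest y with
    F(y) >= u.
    """
    return m.cdf_table


def simulate_counts(model: GroupCopulaModel, n: int, seed=None) -> np.ndarray:
    """Draw n count vectors: z ~ MVN(0, Sigma) mapped through marginal cdfs."""
    rng = np.random.default_rng(seed)
    p = model.p
    w, V = np.linalg.eigh(model.sigma)
    L = V * np.sqrt(np.clip(w, 0.0, None))
    Z = rng.standard_normal((n, p)) @ L.T
    U = ndtr(Z)
    Y = np.zeros((n, p), dtype=np.int64)
    for j, mg in enumerate(model.marginals):
        if mg.is_degenerate:
            continue
        table = _quantile_table(mg)
        Y[:, j] = np.searchsorted(table, U[:, j], side="left")
    return Y


def rho_to_I_curve(
    mk: CountMarginal,
    ml: CountMarginal,
    rho_grid=None,
    n_per_dataset: int = 5000,
    n_reps: int = 100,
    seed=None,
    quantiles=(0.025, 0.975),
) -> dict:
    """Monte Carlo map from copula correlation rho to the index of association.

    For each rho, ``n_reps`` bivariate datasets of ``n_per_dataset`` counts
    are simulated and I computed per dataset; the mean and empirical
    quantile curves are returned.  Replicates where a species comes out
    all-zero (possible for tiny n with heavy zero-inflation) are resampled,
    with the number of resamples logged in the result.
    """
    if rho_grid is None:
        rho_grid = np.arange(-0.98, 1.0001, 0.02)
    rho_grid = np.asarray(rho_grid, dtype=float)
    if n_reps < 2:
        raise ValueError("n_reps must be >= 2")
    rng = np.random.default_rng(seed)
    tk, tl = _quantile_table(mk), _quantile_table(ml)
    mean_I = np.empty(rho_grid.size)
    q_lo = np.empty(rho_grid.size)
    q_hi = np.empty(rho_grid.size)
    n_resampled = 0
    for r, rho in enumerate(rho_grid):
        vals = np.empty(n_reps)
        L = np.array([[1.0, 0.0], [rho, np.sqrt(max(0.0, 1.0 - rho**2))]])
        for rep in range(n_reps):
            while True:
                Z = rng.standard_normal((n_per_dataset, 2)) @ L.T
                yk = np.searchsorted(tk, ndtr(Z[:, 0]), side="left")
                yl = np.searchsorted(tl, ndtr(Z[:, 1]), side="left")
                if yk.sum() > 0 and yl.sum() > 0:
                    break
                n_resampled += 1
            vals[rep] = index_of_association(yk, yl)
        mean_I[r] = vals.mean()
        q_lo[r], q_hi[r] = np.quantile(vals, quantiles)
    return {
        "rho": rho_grid,
        "mean": mean_I,
        "lower": q_lo,
        "upper": q_hi,
        "n_resampled": n_resampled,
    }


def choose_rho_for_I(
    mk: CountMarginal,
    ml: CountMarginal,
    target_I: float,
    rho_grid=None,
    n_per_dataset: int = 2000,
    n_reps: int = 20,
    seed=None,
) -> float:
    """Invert the monotone rho -> I map by linear interpolation of the curve."""
    curve = rho_to_I_curve(
        mk, ml, rho_grid=rho_grid, n_per_dataset=n_per_dataset, n_reps=n_reps, seed=seed
    )
    mean = np.maximum.accumulate(curve["mean"])  # enforce monotonicity
    return float(np.interp(target_I, mean, curve["rho"]))
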