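"""Dissimilarity-space machinery: Bray-Curtis, centroid geometry, PCoA, MDS.

Group centroids are never computed as coordinate averages of the raw
counts: in a semi-metric dissimilarity space (such as Bray-Curtis) the
centroid is only defined implicitly, and distances among centroids are
obtained directly from the dissimilarity matrix via

    d^2(c_a, c_b) = (1/(n_a n_b)) sum_{i in a, j in b} d_ij^2
                    - (1/(2 n_a^2)) sum_{i, i' in a} d_ii'^2
                    - (1/(2 n_b^2)) sum_{j, j' in b} d_jj'^2

Negative squared distances (possible because Bray-Curtis is semi-metric)
are clamped to zero and counted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from sklearn.isotonic import IsotonicRegression
from sklearn.manifold import smacof

__all__ = [
    "DissimilarityMatrix",
    "bray_curtis",
    "euclidean",
    "apply_transform",
    "centroid_distances",
    "centroid_distances_from_indices",
    "pcoa",
    "PcoaResult",
    "mds",
    "MdsResult",
    "CentroidCloud",
    "centroid_cloud_pipeline",
]

TRANSFORMS = ("none", "sqrt", "fourth-root")


def apply_transform(Y, transform: str = "none") -> np.ndarray:
    Y = np.asarray(Y, dtype=float)
    if transform != "none" and np.any(Y < 0):
        raise ValueError("abundances must be non-negative under a root transform")
    if transform == "none":
        return Y
    if transform == "sqrt":
        return np.sqrt(Y)
    if transform == "fourth-root":
        return Y**0.25
    raise ValueError(f"unknown transform {transform!r}; choose from {TRANSFORMS}")


@dataclass
class DissimilarityMatrix:
    """Symmetric dissimilarities with provenance (measure and transform)."""

    values: np.ndarray
    labels: list = None
    measure: str = "unknown"
    transform: str = "none"

    def __post_init__(self):
        D = np.asarray(self.values, dtype=float)
        if D.ndim != 2 or D.shape[0] != D.shape[1]:
            raise ValueError("dissimilarity matrix must be square")
        if not np.allclose(D, D.T, atol=1e-10):
            raise ValueError("dissimilarity matrix must be symmetric")
        if np.any(np.diag(D) != 0):
            raise ValueError("diagonal must be zero")
        if np.any(D < 0):
            raise ValueError("dissimilarities must be non-negative")
        self.values = D
        if self.labels is None:
            self.labels = list(range(D.shape[0]))

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, measure="unknown", transform="none"):
        return cls(df.to_numpy(dtype=float), list(df.columns), measure, transform)


def bray_curtis(Y, transform: str = "sqrt") -> DissimilarityMatrix:
    """Bray-Curtis dissimilarities of (optionally transformed) abundances.

    d_ij = sum_k |t(y_ik) - t(y_jk)| / sum_k (t(y_ik) + t(y_jk)); a pair of
    all-zero sampling units is assigned d = 0 by convention (logged).
    """
    if np.any(np.asarray(Y) < 0):
        raise ValueError("Bray-Curtis requires non-negative abundances")
    Yt = apply_transform(Y, transform)
    with np.errstate(invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        D = squareform(pdist(Yt, metric="braycurtis"))
    bad = ~np.isfinite(D)
    if np.any(bad):
        warnings.warn(
            f"{np.count_nonzero(bad) // 2} all-zero unit pairs assigned d=0", RuntimeWarning
        )
        D[bad] = 0.0
    return DissimilarityMatrix(D, measure="braycurtis", transform=transform)


def euclidean(Y, transform: str = "none") -> DissimilarityMatrix:
    Yt = apply_transform(Y, transform)
    return DissimilarityMatrix(
        squareform(pdist(Yt, metric="euclidean")), measure="euclidean", transform=transform
    )


def _as_values(D) -> np.ndarray:
    return D.values if isinstance(D, DissimilarityMatrix) else np.asarray(D, dtype=float)


def centroid_distances_from_indices(D, index_sets, labels=None) -> DissimilarityMatrix:
    """Distances among centroids of arbitrary (possibly overlapping) unit sets.

    The squared-distance identity above is evaluated directly on the
    dissimilarity matrix; negative squared values are clamped to 0 and the
    clamp count reported via warning.
    """
    D2 = _as_values(D) ** 2
    sets = [np.asarray(ix, dtype=int) for ix in index_sets]
    if any(ix.size == 0 for ix in sets):
        raise ValueError("every centroid set must be non-empty")
    k = len(sets)
    # within-set mean squared dissimilarity terms, halved
    within = np.array([D2[np.ix_(ix, ix)].sum() / (2.0 * ix.size**2) for ix in sets])
    out = np.zeros((k, k))
    for a in range(k):
        for b in range(a + 1, k):
            cross = D2[np.ix_(sets[a], sets[b])].sum() / (sets[a].size * sets[b].size)
            out[a, b] = out[b, a] = cross - within[a] - within[b]
    n_clamped = int(np.count_nonzero(out < 0) // 2)
    if n_clamped:
        warnings.warn(f"{n_clamped} negative squared centroid distances clamped to 0",
                      RuntimeWarning)
    np.clip(out, 0.0, None, out=out)
    Dc = np.sqrt(out)
    measure = D.measure if isinstance(D, DissimilarityMatrix) else "unknown"
    return DissimilarityMatrix(Dc, labels=labels, measure=f"centroid[{measure}]")


def centroid_distances(D, groups) -> DissimilarityMatrix:
    """Distances among group centroids computed directly from ``D``."""
    groups = np.asarray(groups)
    n = _as_values(D).shape[0]
    if groups.size != n:
        raise ValueError("one group label per sampling unit required")
    labels = list(pd.unique(groups))
    sets = [np.flatnonzero(groups == g) for g in labels]
    return centroid_distances_from_indices(D, sets, labels=labels)


@dataclass
class PcoaResult:
    eigenvalues: np.ndarray  # all, descending (negatives retained)
    coordinates: np.ndarray  # axes for positive eigenvalues only
    proportion_explained: np.ndarray

    @property
    def n_positive(self) -> int:
        return self.coordinates.shape[1]


def pcoa(D, eig_tol: float = 1e-9) -> PcoaResult:
    """Principal coordinates analysis via Gower centering.

    Eigen-decomposes -1/2 J D^2 J; negative eigenvalues (present whenever
    D is semi-metric, e.g. Bray-Curtis) are retained and reported, but
    coordinate axes are returned only for eigenvalues > ``eig_tol`` times
    the largest.
    """
    Dv = _as_values(D)
    n = Dv.shape[0]
    A = -0.5 * Dv**2
    J = np.eye(n) - np.ones((n, n)) / n
    G = J @ A @ J
    w, V = np.linalg.eigh(0.5 * (G + G.T))
    order = np.argsort(w)[::-1]
    w, V = w[order], V[:, order]
    pos = w > eig_tol * max(w.max(), 1e-300)
    coords = V[:, pos] * np.sqrt(w[pos])
    denom = np.abs(w).sum()
    prop = w / denom if denom > 0 else np.zeros_like(w)
    return PcoaResult(eigenvalues=w, coordinates=coords, proportion_explained=prop)


@dataclass
class MdsResult:
    coordinates: np.ndarray
    stress: float  # Kruskal stress-1 (normalized)
    mode: str
    converged: bool = True


def _stress1(D: np.ndarray, X: np.ndarray, mode: str) -> float:
    """Normalized Kruskal stress-1 of configuration X against D."""
    dhat = squareform(pdist(X))
    iu = np.triu_indices_from(D, k=1)
    d, e = D[iu], dhat[iu]
    if mode == "metric":
        target = d
    else:
        iso = IsotonicRegression(increasing=True, out_of_bounds="clip")
        target = iso.fit(d, e).predict(d)
    denom = np.sum(e**2)
    if denom <= 0:
        return 0.0
    return float(np.sqrt(np.sum((e - target) ** 2) / denom))


def mds(
    D,
    n_dim: int = 2,
    mode: str = "metric",
    seed=None,
    n_starts: int = 8,
    max_iter: int = 300,
) -> MdsResult:
    """Metric or non-metric MDS by SMACOF majorization, best of several starts.

    Random starts plus a PCoA start are run; the configuration with the
    lowest normalized stress-1 wins.  Non-metric mode uses monotone
    (isotonic) regression of configuration distances on dissimilarities.
    High stress is reported, never hidden: it is itself a diagnostic of
    weak low-dimensional structure.
    """
    if n_dim < 1:
        raise ValueError("n_dim must be >= 1")
    Dv = _as_values(D)
    metric = mode == "metric"
    if mode not in ("metric", "nonmetric"):
        raise ValueError("mode must be 'metric' or 'nonmetric'")
    rng = np.random.default_rng(seed)

    candidates = []
    # PCoA start (pad with zeros if fewer positive axes than requested)
    pc = pcoa(Dv).coordinates
    init = np.zeros((Dv.shape[0], n_dim))
    k = min(n_dim, pc.shape[1])
    if k:
        init[:, :k] = pc[:, :k]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        X, _ = smacof(
            Dv, metric=metric, n_components=n_dim, init=init, n_init=1,
            max_iter=max_iter, random_state=rng.integers(2**31), normalized_stress=False,
        )
        candidates.append(X)
        for _ in range(n_starts):
            X, _ = smacof(
                Dv, metric=metric, n_components=n_dim, n_init=1,
                max_iter=max_iter, random_state=rng.integers(2**31),
                normalized_stress=False,
            )
            candidates.append(X)
    stresses = [_stress1(Dv, X, mode) for X in candidates]
    best = int(np.argmin(stresses))
    return MdsResult(coordinates=candidates[best], stress=stresses[best], mode=mode)


@dataclass
class CentroidCloud:
    """Observed + simulated group centroids embedded in ordination space."""

    coordinates: np.ndarray  # (n_centroids, n_dim)
    group: np.ndarray  # group label per centroid
    source: np.ndarray  # "observed" | "simulated_HA" | "simulated_H0"
    stress: float
    centroid_dissimilarities: DissimilarityMatrix = None
    kde: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.coordinates,
            columns=[f"axis{i + 1}" for i in range(self.coordinates.shape[1])],
        )
        df.insert(0, "source", self.source)
        df.insert(0, "group", self.group)
        return df


def centroid_cloud_pipeline(
    Y,
    groups,
    model,
    N_sim: int = 100,
    measure: str = "braycurtis",
    transform: str = "sqrt",
    include_null: bool = False,
    n_dim: int = 2,
    mode: str = "metric",
    seed=None,
    n_starts: int = 8,
) -> CentroidCloud:
    """Simulated-centroid clouds around the observed group centroids.

    Stacks the observed table with ``N_sim`` tables simulated under the
    fitted per-group models (H_A); computes the super dissimilarity matrix,
    reduces it to centroid-level distances, and embeds the centroids by
    (default metric) MDS.  With ``include_null=True`` an additional cloud
    of centroids under H_0 is added, obtained by randomly permuting the
    observed units' group labels ``N_sim`` times (no new data are
    simulated: exchangeability of the observed rows is the null).
    A 2-D Gaussian kernel density estimate per (source, group) summarizes
    each cloud when the embedding is 2-D and the cloud is large enough.
    """
    from scipy.stats import gaussian_kde

    Y = np.asarray(Y)
    groups = np.asarray(groups)
    rng = np.random.default_rng(seed)
    N = Y.shape[0]
    glabels = list(pd.unique(groups))

    blocks = [Y]
    for s in range(N_sim):
        Ysim, _ = model.simulate(seed=rng.integers(2**31))
        blocks.append(Ysim)
    Ysuper = np.vstack(blocks)

    if measure == "braycurtis":
        Dsuper = bray_curtis(Ysuper, transform=transform)
    elif measure == "euclidean":
        Dsuper = euclidean(Ysuper, transform=transform)
    else:
        raise ValueError(f"unknown measure {measure!r}")

    index_sets, cen_group, cen_source = [], [], []
    for g in glabels:
        index_sets.append(np.flatnonzero(groups == g))
        cen_group.append(g)
        cen_source.append("observed")
    # simulated blocks occupy rows N + s*N ... N + (s+1)*N, labeled by the
    # model's own group layout
    model_labels = np.asarray(
        [lab for lab, n_i in zip(model.group_labels(), model.sizes) for _ in range(n_i)]
    )
    for s in range(N_sim):
        off = N + s * N
        for g in glabels:
            index_sets.append(off + np.flatnonzero(model_labels == g))
            cen_group.append(g)
            cen_source.append("simulated_HA")
    if include_null:
        for s in range(N_sim):
            perm = rng.permutation(N)
            for g in glabels:
                index_sets.append(perm[np.flatnonzero(groups == g)])
                cen_group.append(g)
                cen_source.append("simulated_H0")

    Dcen = centroid_distances_from_indices(Dsuper, index_sets)
    emb = mds(Dcen, n_dim=n_dim, mode=mode, seed=rng.integers(2**31), n_starts=n_starts)

    cen_group = np.asarray(cen_group, dtype=object)
    cen_source = np.asarray(cen_source, dtype=object)
    kde = {}
    if n_dim == 2:
        for src in ("simulated_HA", "simulated_H0"):
            for g in glabels:
                pts = emb.coordinates[(cen_source == src) & (cen_group == g)]
                if pts.shape[0] >= 5 and np.linalg.matrix_rank(np.cov(pts.T)) == 2:
                    kde[(src, g)] = gaussian_kde(pts.T)
    return CentroidCloud(
        coordinates=emb.coordinates,
        group=cen_group,
        source=cen_source,
        stress=emb.stress,
        centroid_dissimilarities=Dcen,
        kde=kde,
    )
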