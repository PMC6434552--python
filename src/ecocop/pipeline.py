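"""End-to-end model building: marginals -> screening -> copula, per group.

This ties the per-species marginal selection, the pairwise association
screen, and the MCEM copula fit into one call producing a
:class:`~ecocop.copula.CommunityModel` ready for simulation, ordination,
inference and power analysis.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .association import screen_associations
from .copula import CommunityModel, GroupCopulaModel, McemSettings, expand_correlation, mcem_fit
from .marginals import FAMILIES, fit_marginal_table

__all__ = ["fit_community"]


def fit_community(
    Y,
    groups=None,
    species=None,
    families=None,
    seed=None,
    screen: bool = True,
    screen_kwargs: dict | None = None,
    mcem_kwargs: dict | None = None,
) -> CommunityModel:
    """Fit the full copula-based community model.

    Per group (or pooled when ``groups`` is None): AICc-select a marginal
    for every species; screen species pairs for significant association
    (optional -- with ``screen=False`` all non-rare, non-degenerate species
    enter the copula jointly); estimate the copula correlation block among
    the associated species by MCEM; expand it to the full p x p matrix
    with independence elsewhere.  Rare and unassociated species stay in
    the model as independent marginals; all-zero species are degenerate
    point masses at zero.
    """
    Y = np.asarray(Y)
    N, p = Y.shape
    if species is None:
        species = [f"sp{j + 1}" for j in range(p)]
    if groups is None:
        groups_arr = np.array(["pooled"] * N)
    else:
        groups_arr = np.asarray(groups)
    families = tuple(families) if families else FAMILIES
    screen_kwargs = dict(screen_kwargs or {})
    mcem_kwargs = dict(mcem_kwargs or {})
    master = np.random.default_rng(seed)

    _, marginal_models = fit_marginal_table(
        Y, groups_arr, species=species, families=families, per_group=True
    )

    if screen:
        screen_kwargs.setdefault("n_perm", 999)
        screen_kwargs.setdefault("error_rate", 0.01)
        screens = screen_associations(
            Y, groups_arr, seed=master.integers(2**31), species=species, **screen_kwargs
        )
    else:
        screens = None

    group_models = []
    sizes = []
    labels = list(pd.unique(groups_arr))
    for g in labels:
        idx = np.flatnonzero(groups_arr == g)
        sizes.append(idx.size)
        marginals = marginal_models[g]
        if screens is not None:
            assoc = screens[g].associated_species
        else:
            nondeg = np.array(
                [j for j, m in enumerate(marginals) if not m.is_degenerate], dtype=int
            )
            assoc = nondeg
        assoc = np.asarray(
            [j for j in assoc if not marginals[j].is_degenerate], dtype=int
        )
        if assoc.size >= 2:
            settings = McemSettings(seed=int(master.integers(2**31)), **mcem_kwargs)
            sigma_m, _ = mcem_fit(Y[np.ix_(idx, assoc)], [marginals[j] for j in assoc],
                                  settings)
            sigma = expand_correlation(sigma_m, assoc, p)
        else:
            sigma = np.eye(p)
            assoc = np.array([], dtype=int)
        group_models.append(
            GroupCopulaModel(
                marginals=marginals, sigma=sigma, assoc_index=assoc, group=g, n=idx.size
            )
        )
    return CommunityModel(groups=group_models, sizes=sizes, species=list(species))
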