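import numpy as np
import pytest

from ecocop import CountMarginal, GroupCopulaModel, default_spec, generate_community


@pytest.fixture(scope="session")
def fish_pair():
    """The bivariate reference pair: an over-dispersed NB species and a
    zero-inflated NB species with a moderate positive copula correlation."""
    mk = CountMarginal("nb", mu=2.714, theta=1.635)
    ml = CountMarginal("zinb", mu=15.375, theta=1.857, pi=0.095)
    return mk, ml


@pytest.fixture(scope="session")
def fish_pair_model(fish_pair):
    mk, ml = fish_pair
    sigma = np.array([[1.0, 0.574], [0.574, 1.0]])
    return GroupCopulaModel(marginals=[mk, ml], sigma=sigma)


@pytest.fixture(scope="session")
def small_community():
    """A 12-species, 3-group synthetic community with known ground truth."""
    spec = default_spec(p=12, sizes=(15, 21, 20), rare_fraction=0.25, seed=11,
                        block_size_range=(4, 6))
    Y, groups, truth = generate_community(spec, seed=12)
    return Y, groups, truth, spec
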