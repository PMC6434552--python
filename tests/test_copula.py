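"""Gaussian copula: latent bounds, MCEM estimation, expansion, simulation."""

import numpy as np
import pytest
from scipy import stats
from scipy.special import ndtri

from ecocop import (
    CommunityModel,
    CountMarginal,
    GaussianCopula,
    GroupCopulaModel,
    McemSettings,
    expand_correlation,
    latent_bounds,
    mcem_fit,
    rho_to_I_curve,
    simulate_counts,
)
from ecocop.copula import nearest_correlation


class TestLatentBounds:
    def test_zero_count_has_unbounded_lower(self):
        lo, hi = latent_bounds(0, CountMarginal("poisson", mu=2.5))
        assert lo == -np.inf and np.isfinite(hi)

    def test_poisson_bounds_match_brute_force_cdf(self):
        # brute-force cumulative pmf: F(2)=0.5438, F(3)=0.7576
        m = CountMarginal("poisson", mu=2.5)
        F2 = float(sum(m.pmf(v) for v in range(3)))
        F3 = float(sum(m.pmf(v) for v in range(4)))
        lo, hi = latent_bounds(3, m)
        assert lo == pytest.approx(ndtri(F2), rel=1e-10)
        assert hi == pytest.approx(ndtri(F3), rel=1e-10)
        assert F2 == pytest.approx(0.5438, abs=5e-5)
        assert F3 == pytest.approx(0.7576, abs=5e-5)

    def test_degenerate_marginal_is_unbounded(self):
        lo, hi = latent_bounds(0, CountMarginal("zero"))
        assert lo == -np.inf and hi == np.inf

    def test_bounds_partition_the_latent_line(self):
        m = CountMarginal("nb", mu=3.0, theta=1.2)
        ys = np.arange(0, 30)
        lo, hi = latent_bounds(ys, m)
        assert np.all(lo[1:] == hi[:-1])
        assert np.all(hi > lo)


class TestExpandCorrelation:
    def test_empty_block_gives_identity(self):
        np.testing.assert_array_equal(
            expand_correlation(np.empty((0, 0)), [], 4), np.eye(4)
        )

    def test_full_block_returned_unchanged(self):
        C = np.array([[1.0, 0.4], [0.4, 1.0]])
        np.testing.assert_array_equal(expand_correlation(C, [0, 1], 2), C)

    def test_block_placement(self):
        C = np.array([[1.0, 0.574], [0.574, 1.0]])
        S = expand_correlation(C, [2, 6], 10)
        assert S[2, 6] == 0.574 and S[6, 2] == 0.574
        assert S[0, 1] == 0.0
        assert np.trace(S) == 10.0

    def test_invalid_indices_rejected(self):
        C = np.eye(2)
        with pytest.raises(ValueError):
            expand_correlation(C, [1, 1], 5)
        with pytest.raises(ValueError):
            expand_correlation(C, [3, 7], 5)


class TestNearestCorrelation:
    def test_projection_produces_valid_correlation(self):
        rng = np.random.default_rng(0)
        A = rng.normal(size=(6, 6))
        S = A @ A.T
        S[0, 1] = S[1, 0] = 10.0  # force indefiniteness after rescale
        C = nearest_correlation(S)
        assert np.allclose(np.diag(C), 1.0)
        assert np.allclose(C, C.T)
        assert np.linalg.eigvalsh(C).min() >= -1e-10


class TestSimulation:
    def test_marginals_preserved_under_identity_sigma(self):
        margs = [
            CountMarginal("nb", mu=3.0, theta=1.5),
            CountMarginal("zinb", mu=10.0, theta=2.0, pi=0.2),
        ]
        model = GroupCopulaModel(marginals=margs, sigma=np.eye(2))
        Y = simulate_counts(model, 10_000, seed=1)
        for j, m in enumerate(margs):
            se = np.sqrt(m.var() / 10_000)
            assert abs(Y[:, j].mean() - m.mean()) < 3 * se

    def test_simulated_pmf_matches_theory(self):
        """Chi-square goodness of fit of simulated counts vs theoretical pmf."""
        m = CountMarginal("nb", mu=2.714, theta=1.635)
        model = GroupCopulaModel(marginals=[m], sigma=np.eye(1))
        y = simulate_counts(model, 10_000, seed=2)[:, 0]
        kmax = 15
        obs = np.bincount(np.minimum(y, kmax), minlength=kmax + 1)
        pk = np.asarray(m.pmf(np.arange(kmax)))
        probs = np.append(pk, 1.0 - pk.sum())
        res = stats.chisquare(obs, probs * y.size)
        assert res.pvalue > 0.01

    def test_round_trip_distribution_vs_direct_sampling(self):
        """Copula simulation with an expanded Sigma preserves each marginal
        (two-sample test against direct marginal sampling)."""
        margs = [
            CountMarginal("nb", mu=2.0, theta=1.0),
            CountMarginal("poisson", mu=4.0),
            CountMarginal("zinb", mu=8.0, theta=1.5, pi=0.3),
        ]
        sigma = expand_correlation(np.array([[1, 0.6], [0.6, 1]]), [0, 2], 3)
        model = GroupCopulaModel(marginals=margs, sigma=sigma, assoc_index=[0, 2])
        Y = simulate_counts(model, 8000, seed=3)
        for j, m in enumerate(margs):
            direct = m.rvs(8000, random_state=100 + j)
            res = stats.ks_2samp(Y[:, j], direct)
            assert res.pvalue > 0.005

    def test_degenerate_species_emitted_as_zero(self):
        margs = [CountMarginal("zero"), CountMarginal("poisson", mu=2.0)]
        model = GroupCopulaModel(marginals=margs, sigma=np.eye(2))
        Y = simulate_counts(model, 50, seed=4)
        assert np.all(Y[:, 0] == 0)

    def test_model_validation(self):
        margs = [CountMarginal("poisson", mu=1.0), CountMarginal("poisson", mu=2.0)]
        with pytest.raises(ValueError, match="symmetric"):
            GroupCopulaModel(marginals=margs, sigma=np.array([[1, 0.5], [0.2, 1]]))
        with pytest.raises(ValueError, match="outside assoc_index"):
            GroupCopulaModel(
                marginals=margs,
                sigma=np.array([[1, 0.5], [0.5, 1]]),
                assoc_index=[0],
            )


class TestMcem:
    def test_independent_margins_recovered(self):
        margs = [
            CountMarginal("nb", mu=3.0, theta=1.5),
            CountMarginal("poisson", mu=2.0),
            CountMarginal("zinb", mu=6.0, theta=2.0, pi=0.2),
        ]
        model = GroupCopulaModel(marginals=margs, sigma=np.eye(3))
        # sampling noise of a correlation at n=500 is ~0.045, so a single
        # draw can stray near 0.1; the median over seeds must stay well below
        maxima = []
        for s in range(5):
            Y = simulate_counts(model, 500, seed=510 + s)
            sigma, _ = mcem_fit(Y, margs, McemSettings(seed=s))
            maxima.append(np.abs(sigma[~np.eye(3, dtype=bool)]).max())
        assert np.median(maxima) < 0.1

    def test_bivariate_rho_recovery(self, fish_pair, fish_pair_model):
        """Mean rho-hat over seeds is within +/-0.08 of the generating 0.574."""
        mk, ml = fish_pair
        est = []
        for s in range(20):
            Y = simulate_counts(fish_pair_model, 500, seed=300 + s)
            sigma, _ = mcem_fit(Y, [mk, ml], McemSettings(seed=s))
            est.append(sigma[0, 1])
        assert abs(np.mean(est) - 0.574) < 0.08

    def test_every_iterate_is_valid_correlation(self, fish_pair, fish_pair_model):
        mk, ml = fish_pair
        Y = simulate_counts(fish_pair_model, 200, seed=7)
        sigma, diag = mcem_fit(Y, [mk, ml], McemSettings(seed=8))
        assert np.allclose(np.diag(sigma), 1.0)
        assert np.linalg.eigvalsh(sigma).min() >= -1e-10
        assert -1.0 <= sigma[0, 1] <= 1.0

    def test_species_order_invariance(self):
        margs = [
            CountMarginal("nb", mu=3.0, theta=1.5),
            CountMarginal("zinb", mu=8.0, theta=2.0, pi=0.15),
            CountMarginal("poisson", mu=2.5),
        ]
        C = np.array([[1, 0.6, 0.3], [0.6, 1, 0.45], [0.3, 0.45, 1]])
        model = GroupCopulaModel(marginals=margs, sigma=C)
        Y = simulate_counts(model, 800, seed=9)
        perm = np.array([2, 0, 1])
        s1, _ = mcem_fit(Y, margs, McemSettings(seed=10))
        s2, _ = mcem_fit(
            Y[:, perm], [margs[j] for j in perm], McemSettings(seed=10)
        )
        # estimates agree up to the matching permutation, within MC noise
        np.testing.assert_allclose(s2, s1[np.ix_(perm, perm)], atol=0.1)

    def test_degenerate_species_rejected(self):
        margs = [CountMarginal("zero"), CountMarginal("poisson", mu=2.0)]
        Y = np.zeros((20, 2), dtype=int)
        with pytest.raises(ValueError, match="degenerate"):
            mcem_fit(Y, margs, McemSettings(seed=0))

    def test_estimator_interface(self, fish_pair, fish_pair_model):
        mk, ml = fish_pair
        Y = simulate_counts(fish_pair_model, 300, seed=11)
        est = GaussianCopula(marginals=[mk, ml], random_state=12).fit(Y)
        assert est.sigma_.shape == (2, 2)
        assert hasattr(est, "converged_")
        Ysim = est.sample(100, random_state=13)
        assert Ysim.shape == (100, 2)
        assert est.get_params()["n_mc"] == 20


class TestRhoToI:
    def test_identical_marginals_at_rho_one(self):
        m = CountMarginal("nb", mu=3.0, theta=1.5)
        curve = rho_to_I_curve(m, m, rho_grid=[1.0], n_per_dataset=500, n_reps=5,
                               seed=14)
        assert curve["mean"][0] == pytest.approx(1.0)

    def test_monotone_in_rho(self, fish_pair):
        mk, ml = fish_pair
        curve = rho_to_I_curve(
            mk, ml, rho_grid=[-0.8, -0.3, 0.0, 0.3, 0.8],
            n_per_dataset=4000, n_reps=10, seed=15,
        )
        assert np.all(np.diff(curve["mean"]) > 0)

    def test_mean_index_matches_numeric_integration_oracle(self, fish_pair):
        """At rho=0.574 the expected index equals the value obtained by
        deterministic numeric integration of the joint pmf (bivariate-normal
        rectangle probabilities): 0.67568."""
        mk, ml = fish_pair
        curve = rho_to_I_curve(mk, ml, rho_grid=[0.574], n_per_dataset=5000,
                               n_reps=30, seed=16)
        assert curve["mean"][0] == pytest.approx(0.67568, abs=0.01)


class TestSerialization:
    def test_community_model_json_round_trip(self, tmp_path, small_community):
        _, _, truth, _ = small_community
        path = tmp_path / "model.json"
        truth.to_json(path)
        back = CommunityModel.from_json(str(path))
        assert back.species == truth.species
        assert back.sizes == truth.sizes
        for g0, g1 in zip(truth.groups, back.groups):
            np.testing.assert_allclose(g0.sigma, g1.sigma)
            assert [m.to_dict() for m in g0.marginals] == [
                m.to_dict() for m in g1.marginals
            ]
        # simulation from the round-tripped model is reproducible
        Y0, _ = truth.simulate(seed=42)
        Y1, _ = back.simulate(seed=42)
        np.testing.assert_array_equal(Y0, Y1)
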