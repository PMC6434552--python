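"""Count marginal distributions: pmf/cdf/quantile identities, ML fitting,
AICc model selection and rare-species flagging."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from ecocop import (
    CountMarginal,
    MarginalModel,
    fit_marginal,
    fit_marginal_table,
    flag_rare,
    select_marginal,
)
from ecocop.marginals import ParameterError, _aicc


def brute_cdf(m: CountMarginal, y: int) -> float:
    """Independent oracle: cumulative pmf summation."""
    return float(sum(m.pmf(v) for v in range(y + 1)))


ALL_MARGINALS = [
    CountMarginal("poisson", mu=2.5),
    CountMarginal("zip", mu=4.0, pi=0.3),
    CountMarginal("nb", mu=2.714, theta=1.635),
    CountMarginal("zinb", mu=15.375, theta=1.857, pi=0.095),
]


class TestDistribution:
    @pytest.mark.parametrize("m", ALL_MARGINALS, ids=lambda m: m.family)
    def test_pmf_sums_to_one(self, m):
        total = float(np.sum(m.pmf(np.arange(0, 2000))))
        assert total == pytest.approx(1.0, abs=1e-9)

    @pytest.mark.parametrize("m", ALL_MARGINALS, ids=lambda m: m.family)
    def test_cdf_nondecreasing_with_limits(self, m):
        ys = np.arange(-1, 500)
        F = np.asarray(m.cdf(ys))
        assert F[0] == 0.0
        assert np.all(np.diff(F) >= -1e-15)
        assert F[-1] == pytest.approx(1.0, abs=1e-9)

    def test_cdf_matches_brute_force_summation(self):
        m = CountMarginal("poisson", mu=2.5)
        # e^{-2.5} (1 + 2.5 + 2.5^2/2)
        assert m.cdf(2) == pytest.approx(0.5438, abs=5e-5)
        assert m.cdf(-1) == 0.0
        for mm in ALL_MARGINALS:
            assert mm.cdf(7) == pytest.approx(brute_cdf(mm, 7), abs=1e-12)

    def test_zero_inflated_mass_at_zero(self):
        m = CountMarginal("zinb", mu=15.375, theta=1.857, pi=0.095)
        base0 = stats.nbinom(1.857, 1.857 / (1.857 + 15.375)).pmf(0)
        assert m.cdf(0) == pytest.approx(0.095 + (1 - 0.095) * base0, rel=1e-12)

    def test_variance_identities(self):
        nb = CountMarginal("nb", mu=2.714, theta=1.635)
        assert nb.var() == pytest.approx(2.714 + 2.714**2 / 1.635, rel=1e-12)
        po = CountMarginal("poisson", mu=3.3)
        assert po.var() == pytest.approx(3.3, rel=1e-12)

    @pytest.mark.parametrize(
        "m,q,expected",
        [
            (CountMarginal("poisson", mu=2.5), 0.70, 3),
            (CountMarginal("poisson", mu=2.5), 0.0, 0),
            (CountMarginal("zinb", mu=15.375, theta=1.857, pi=0.095), 0.90, 30),
            (CountMarginal("nb", mu=2.714, theta=1.635), 0.75, 4),
        ],
    )
    def test_quantile_values(self, m, q, expected):
        assert m.quantile(q) == expected

    @pytest.mark.parametrize("m", ALL_MARGINALS, ids=lambda m: m.family)
    def test_quantile_cdf_adjunction(self, m):
        # quantile(cdf(y)) == y wherever the cdf is still strictly below 1
        # (beyond that the finite q=1 clamp necessarily breaks the identity)
        ys = np.arange(0, int(m.quantile(1.0 - 1e-9)) + 1)
        assert np.array_equal(m.quantile(m.cdf(ys)), ys)
        qs = np.linspace(0.001, 0.999, 97)
        assert np.all(np.asarray(m.cdf(m.quantile(qs))) >= qs)

    def test_quantile_at_one_is_finite(self):
        for m in ALL_MARGINALS:
            y1 = m.quantile(1.0)
            assert np.isfinite(y1)
            assert 1.0 - m.cdf(y1) < 1e-12

    @given(
        mu=st.floats(0.05, 40.0),
        theta=st.floats(0.2, 10.0),
        pi=st.floats(0.0, 0.8),
        q=st.floats(0.001, 0.999),
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_quantile_is_generalized_inverse_for_any_zinb(self, mu, theta, pi, q):
        m = CountMarginal("zinb", mu=mu, theta=theta, pi=pi)
        y = int(m.quantile(q))
        assert m.cdf(y) >= q
        assert y == 0 or m.cdf(y - 1) < q

    def test_quantile_domain_error(self):
        with pytest.raises(ValueError):
            CountMarginal("poisson", mu=1.0).quantile(1.5)

    def test_zinb_pi_zero_equals_nb(self):
        z = CountMarginal("zinb", mu=5.0, theta=2.0, pi=0.0)
        nb = CountMarginal("nb", mu=5.0, theta=2.0)
        ys = np.arange(0, 60)
        np.testing.assert_allclose(z.pmf(ys), nb.pmf(ys), atol=1e-14)

    def test_nb_large_theta_converges_to_poisson(self):
        nb = CountMarginal("nb", mu=3.0, theta=1e6)
        po = CountMarginal("poisson", mu=3.0)
        ys = np.arange(0, 40)
        np.testing.assert_allclose(nb.pmf(ys), po.pmf(ys), atol=1e-4)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"family": "poisson", "mu": -1.0},
            {"family": "nb", "mu": 2.0, "theta": 0.0},
            {"family": "zinb", "mu": 2.0, "theta": 1.0, "pi": 1.0},
            {"family": "zip", "mu": 2.0, "pi": -0.1},
            {"family": "poisson", "mu": 2.0, "theta": 1.0},
        ],
    )
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ParameterError):
            CountMarginal(**kwargs)

    def test_degenerate_point_mass(self):
        z = CountMarginal("zero")
        assert z.pmf(0) == 1.0 and z.pmf(3) == 0.0
        assert z.cdf(0) == 1.0 and z.quantile(0.99) == 0
        assert np.all(z.rvs(10, random_state=0) == 0)


class TestFitting:
    def test_poisson_mle_is_sample_mean(self):
        y = np.array([0, 2, 3, 5, 1, 1])
        fit = fit_marginal(y, "poisson")
        assert fit.marginal.mu == pytest.approx(y.mean(), rel=1e-12)

    def test_aicc_formula(self):
        y = np.array([0, 2, 3, 5, 1, 1])
        fit = fit_marginal(y, "poisson")
        assert fit.aicc == pytest.approx(_aicc(fit.loglik, 1, 6))
        assert fit.aicc == pytest.approx(-2 * fit.loglik + 2 + 4 / (6 - 2))

    def test_zinb_parameter_recovery(self):
        truth = CountMarginal("zinb", mu=10.0, theta=2.0, pi=0.2)
        y = truth.rvs(2000, random_state=2)
        fit = fit_marginal(y, "zinb")
        assert fit.marginal.mu == pytest.approx(10.0, rel=0.10)
        assert fit.marginal.theta == pytest.approx(2.0, rel=0.15)
        assert fit.marginal.pi == pytest.approx(0.2, abs=0.05)

    @pytest.mark.parametrize(
        "truth",
        [
            CountMarginal("poisson", mu=4.0),
            CountMarginal("zip", mu=6.0, pi=0.25),
            CountMarginal("nb", mu=3.0, theta=1.5),
            CountMarginal("zinb", mu=8.0, theta=2.0, pi=0.2),
        ],
        ids=lambda m: m.family,
    )
    def test_mu_recovery_across_seeds(self, truth):
        """Median absolute relative error of mu-hat stays below 5% at n=2000."""
        errs = []
        for s in range(20):
            y = truth.rvs(2000, random_state=1000 + s)
            fit = fit_marginal(y, truth.family)
            errs.append(abs(fit.marginal.mu - truth.mu) / truth.mu)
        assert np.median(errs) < 0.05

    def test_nb_loglik_dominates_poisson(self):
        y = CountMarginal("nb", mu=3.0, theta=1.0).rvs(300, random_state=5)
        assert fit_marginal(y, "nb").loglik >= fit_marginal(y, "poisson").loglik - 1e-6

    def test_all_zero_counts_yield_degenerate(self):
        for fam in ("poisson", "nb", "zinb"):
            fit = fit_marginal(np.zeros(10, dtype=int), fam)
            assert fit.marginal.is_degenerate
            assert fit.k == 0

    def test_counts_validation(self):
        with pytest.raises(ValueError):
            fit_marginal(np.array([1, -2, 3]), "poisson")
        with pytest.raises(ValueError):
            fit_marginal(np.array([4]), "poisson")


class TestSelection:
    def test_equidispersed_sample_selects_poisson(self):
        y = CountMarginal("poisson", mu=4.0).rvs(1000, random_state=3)
        assert select_marginal(y).family == "poisson"

    def test_overdispersed_zero_inflated_selects_zi_family(self):
        truth = CountMarginal("zinb", mu=15.0, theta=2.0, pi=0.35)
        y = truth.rvs(1500, random_state=4)
        assert select_marginal(y).family == "zinb"

    def test_small_n_excludes_wide_families_with_warning(self):
        y = np.array([1, 0, 2, 1])  # n=4: zinb (k=3) has n <= k+1
        with pytest.warns(RuntimeWarning, match="excluding zinb"):
            fit = select_marginal(y)
        assert fit.family != "zinb"

    def test_empty_family_set_rejected(self):
        with pytest.raises(ValueError):
            select_marginal(np.array([1, 2, 3]), families=())

    def test_estimator_interface(self):
        y = CountMarginal("nb", mu=3.0, theta=1.0).rvs(500, random_state=6)
        est = MarginalModel().fit(y)
        assert est.family_ in ("nb", "zinb")
        assert est.mu_ == pytest.approx(3.0, rel=0.25)
        assert est.get_params()["family"] == "auto"

    def test_marginal_table_per_group_shapes(self, small_community):
        Y, groups, truth, spec = small_community
        report, models = fit_marginal_table(Y, groups)
        assert set(report["group"]) == set(np.unique(groups))
        assert len(models) == 3
        assert all(len(m) == Y.shape[1] for m in models.values())


class TestRareFlagging:
    def test_rules(self):
        N = 56
        Y = np.zeros((N, 4), dtype=int)
        Y[0, 0] = 7  # singleton
        Y[:, 1] = 1  # everywhere
        Y[: int(0.05 * N), 2] = 1  # prevalence 2/56 < 5%
        Y[:3, 3] = 1  # prevalence 3/56 > 5%
        flags = flag_rare(Y, min_prevalence=0.05)
        assert flags.tolist() == [True, False, True, False]

    def test_threshold_is_strict(self):
        Y = np.zeros((20, 1), dtype=int)
        Y[:2, 0] = 1  # prevalence exactly 0.10
        assert not flag_rare(Y, min_prevalence=0.10)[0]
        assert flag_rare(Y, min_prevalence=0.101)[0]

    def test_threshold_validation(self):
        with pytest.raises(ValueError):
            flag_rare(np.ones((5, 2), dtype=int), min_prevalence=0.0)
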