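import numpy as np
import pytest
from scipy import stats

from selfexcite import (
    BaselineSpec,
    ContagionParams,
    SimConfig,
    aic,
    fit_contagion,
    fit_null,
    gap_histogram,
    gap_histogram_aic,
    lrt,
    negbin_negloglik,
    poisson_negloglik,
    profile_ci,
)
from selfexcite.simulate import _contagion_day_counts


@pytest.fixture(scope="module")
def contagion_counts(make_counts_module):
    rng = np.random.default_rng(777)
    return make_counts_module(_contagion_day_counts(
        rng, SimConfig(span_days=2922, n_events_null=232,
                       params=ContagionParams(0.28, 13.0))))


@pytest.fixture(scope="module")
def make_counts_module():
    import datetime as dt
    from selfexcite import DailyCounts

    def _make(counts):
        return DailyCounts(counts=np.asarray(counts), origin=dt.date(2006, 1, 1))
    return _make


class TestPoissonNegloglik:
    def test_hand_values(self):
        assert poisson_negloglik([1.0, 1.0], [1, 0]) == pytest.approx(2.0, abs=1e-12)
        assert poisson_negloglik([2.0], [0]) == pytest.approx(2.0, abs=1e-12)

    def test_matches_independent_poisson_logpmf_sum(self, rng):
        # 10-day toy series: the dropped log k! term is the only difference
        # from the full Poisson log-likelihood.
        from scipy.special import gammaln
        k = rng.poisson(1.5, 10)
        mu = rng.uniform(0.5, 3.0, 10)
        oracle = -stats.poisson.logpmf(k, mu).sum() - gammaln(k + 1.0).sum()
        assert poisson_negloglik(mu, k) == pytest.approx(oracle, abs=1e-10)

    def test_minimised_at_mu_equal_k(self):
        k = np.array([3, 0, 1])
        base = poisson_negloglik(k.astype(float) + 1e-12, k)
        for eps in (0.1, -0.1):
            mu = np.clip(k + eps, 1e-9, None)
            assert poisson_negloglik(mu, k) > base

    def test_impossible_observation_is_penalty_not_exception(self):
        assert poisson_negloglik([0.0, 1.0], [1, 0]) == np.inf


class TestNegbinNegloglik:
    def test_zero_dispersion_recovers_full_poisson(self, rng):
        k = rng.poisson(2.0, 12)
        mu = rng.uniform(0.5, 4.0, 12)
        poisson_full = -stats.poisson.logpmf(k, mu).sum()
        assert negbin_negloglik(mu, k, 0.0) == pytest.approx(poisson_full, abs=1e-8)
        assert negbin_negloglik(mu, k, 1e-12) == pytest.approx(poisson_full, abs=1e-6)

    def test_closed_form_zero_count(self):
        # NB2 pmf at k=0 is (1/(1+alpha mu))^(1/alpha): mu=2, alpha=1 -> 1/3.
        assert negbin_negloglik([2.0], [0], 1.0) == pytest.approx(np.log(3.0), abs=1e-10)

    def test_unimodal_in_count(self):
        vals = [negbin_negloglik([5.0], [k], 0.3) for k in range(0, 20)]
        k_min = int(np.argmin(vals))
        assert 3 <= k_min <= 6
        assert all(np.diff(vals[k_min:]) > 0) and all(np.diff(vals[:k_min + 1]) < 0)

    def test_negative_dispersion_rejected(self):
        with pytest.raises(ValueError):
            negbin_negloglik([1.0], [1], -0.1)


class TestNullFit:
    def test_constant_null_is_rate_times_days(self, make_counts_module):
        counts = np.zeros(100, dtype=int)
        counts[[3, 50, 97]] = 1
        dc = make_counts_module(counts)
        fit = fit_null(dc)
        expected_mu = 3 / 100
        oracle = 100 * expected_mu - 3 * np.log(expected_mu)
        assert fit.negloglik == pytest.approx(oracle, abs=1e-10)
        assert fit.n_params == 0

    def test_zero_events_rejected(self, make_counts_module):
        with pytest.raises(ValueError):
            fit_null(make_counts_module(np.zeros(10, dtype=int)))

    def test_negbin_null_fits_dispersion(self, contagion_counts):
        fit = fit_null(contagion_counts, likelihood="negbin")
        assert fit.n_params == 1
        assert fit.dispersion is not None and fit.dispersion >= 0
        # NB with fitted dispersion can only improve on the Poisson value
        mu = np.full(contagion_counts.n_days,
                     contagion_counts.total / contagion_counts.n_days)
        assert fit.negloglik <= negbin_negloglik(mu, contagion_counts.counts, 0.0) + 1e-9


class TestContagionFit:
    def test_nesting_on_contagion_data(self, contagion_counts):
        null_fit = fit_null(contagion_counts)
        alt_fit = fit_contagion(contagion_counts)
        assert alt_fit.converged
        assert alt_fit.negloglik <= null_fit.negloglik + 1e-9
        assert alt_fit.n_params == 2

    def test_deterministic(self, contagion_counts):
        a = fit_contagion(contagion_counts)
        b = fit_contagion(contagion_counts)
        assert a.params == b.params and a.negloglik == b.negloglik

    def test_null_data_estimate_near_zero_boundary(self, make_counts_module):
        # Median branching-ratio estimate on no-contagion data sits at or
        # near zero; check a handful of Poisson datasets.
        rng = np.random.default_rng(5)
        estimates = []
        for _ in range(9):
            counts = make_counts_module(rng.poisson(232 / 2922, 2922))
            estimates.append(fit_contagion(counts).params.n_secondary)
        assert np.median(estimates) < 0.1

    def test_too_few_events_rejected(self, make_counts_module):
        counts = np.zeros(30, dtype=int)
        counts[4] = 1
        with pytest.raises(ValueError):
            fit_contagion(make_counts_module(counts))

    def test_negbin_fit_nests_poisson_structure(self, contagion_counts):
        fit = fit_contagion(contagion_counts, likelihood="negbin")
        assert fit.n_params == 3
        assert fit.dispersion >= 0
        null_fit = fit_null(contagion_counts, likelihood="negbin")
        assert fit.negloglik <= null_fit.negloglik + 1e-6


class TestProfileCI:
    def test_interval_contains_estimate_and_widens_with_level(self, contagion_counts):
        fit = fit_contagion(contagion_counts)
        ci95 = profile_ci(contagion_counts, None, fit, "n_secondary", level=0.95)
        ci99 = profile_ci(contagion_counts, None, fit, "n_secondary", level=0.99)
        assert ci95.covers(fit.params.n_secondary)
        assert ci99.lower <= ci95.lower and ci99.upper >= ci95.upper

    def test_t_excite_interval(self, contagion_counts):
        fit = fit_contagion(contagion_counts)
        ci = profile_ci(contagion_counts, None, fit, "t_excite", level=0.95)
        assert ci.lower <= fit.params.t_excite <= ci.upper


class TestModelComparison:
    def _result(self, negll, n_params, **kw):
        from selfexcite import FitResult
        defaults = dict(params=None, negloglik=negll, n_params=n_params,
                        converged=True, n_days=100, n_events=10)
        defaults.update(kw)
        return FitResult(**defaults)

    def test_equal_likelihoods_give_p_one(self):
        cmp_ = lrt(self._result(50.0, 0), self._result(50.0, 2))
        assert cmp_.lrt_stat == 0.0
        assert cmp_.p_value == pytest.approx(1.0)

    def test_chi_square_two_df_survival(self):
        # chi2_2 survival is exp(-x/2): delta negll 3 -> stat 6, p = e^-3.
        cmp_ = lrt(self._result(53.0, 0), self._result(50.0, 2))
        assert cmp_.lrt_stat == pytest.approx(6.0)
        assert cmp_.df == 2
        assert cmp_.p_value == pytest.approx(np.exp(-3.0), abs=1e-12)

    def test_mismatched_data_rejected(self):
        with pytest.raises(ValueError, match="same data"):
            lrt(self._result(50.0, 0, n_days=99), self._result(49.0, 2))

    def test_aic_formula(self):
        assert aic(self._result(100.0, 2)) == pytest.approx(204.0)

    def test_aic_preference_matches_lrt_threshold(self):
        # With 2 extra parameters, AIC prefers the alternative iff stat > 4.
        for delta in (1.9, 2.1):
            cmp_ = lrt(self._result(50.0 + delta, 0), self._result(50.0, 2))
            assert (cmp_.aic_alt < cmp_.aic_null) == (cmp_.lrt_stat > 4.0)


class TestGapHistogramAIC:
    def _observed(self):
        rng = np.random.default_rng(8)
        gaps = rng.geometric(0.08, 300) - 1
        return gap_histogram(gaps, d_max=20)

    def test_totals_match_by_construction(self):
        obs = self._observed()
        predicted = obs.all_bins() / obs.total
        result = gap_histogram_aic(obs, predicted, n_params=1)
        assert np.isfinite(result.aic)
        assert result.n_params == 2  # rate-equivalent + fitted dispersion

    def test_matching_shape_never_has_higher_negll(self):
        # Brute force over small 3-bin cases: the prediction proportional to
        # the observation minimises the Poisson/NB negative log-likelihood.
        obs = gap_histogram(np.array([0] * 12 + [1] * 6 + [2] * 2), d_max=1)
        saturated = obs.all_bins() / obs.total
        best = gap_histogram_aic(obs, saturated, n_params=1).negloglik
        grid = np.linspace(0.05, 0.9, 8)
        for p0 in grid:
            for p1 in grid:
                if p0 + p1 >= 0.99:
                    continue
                other = np.array([p0, p1, 1 - p0 - p1])
                assert gap_histogram_aic(obs, other, n_params=1).negloglik >= best - 1e-9

    def test_zero_mass_where_observed_gives_infinite_penalty(self):
        obs = gap_histogram(np.array([0, 0, 1, 5]), d_max=1)
        predicted = np.array([0.5, 0.5, 0.0])
        assert gap_histogram_aic(obs, predicted, n_params=1).aic == np.inf

    def test_unnormalised_prediction_rejected(self):
        obs = self._observed()
        with pytest.raises(ValueError, match="normalised"):
            gap_histogram_aic(obs, np.ones(obs.d_max + 2), n_params=1)
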