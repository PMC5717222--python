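"""Likelihood, priors, conditional and joint samplers, summaries."""

import numpy as np
import pytest
from scipy import stats

import tqkin as tk
from tqkin.inference import IncrementData


def make_curve(P_obs, t_obs, E_T, S_T, omega=1.0):
    cond = tk.ExperimentCondition(E_T=E_T, S_T=S_T, omega=omega,
                                  t_obs=np.asarray(t_obs, dtype=float))
    return tk.ProgressCurve(condition=cond, P_obs=np.asarray(P_obs))


class TestLogLikelihood:
    def test_single_survival_interval(self):
        # n = 0 over one interval: contribution is -lambda dt = -1
        # lambda = k_cat E (S - P)/(K_M + S - P) = 2 * 1 * 1 / 2 = 1
        curve = make_curve([0, 0], [0.0, 1.0], E_T=1.0, S_T=1.0)
        ll = tk.log_likelihood("sQ", tk.MMParams(k_cat=2.0, K_M=1.0), [curve])
        assert ll == pytest.approx(-1.0)

    def test_single_jump_interval(self, simple_curve):
        # lambda = 1*1*2/(2+2) = 0.5, n = 1, dt = 2: log 0.5 - 1
        ll = tk.log_likelihood("sQ", tk.MMParams(1.0, 2.0), [simple_curve])
        assert ll == pytest.approx(np.log(0.5) - 1.0)

    def test_pooling_is_additive(self, simple_curve):
        other = make_curve([0, 1, 2], [0.0, 1.0, 3.0], E_T=2.0, S_T=3.0)
        mm = tk.MMParams(0.7, 1.3)
        lls = [tk.log_likelihood("tQ", mm, [c]) for c in (simple_curve, other)]
        assert tk.log_likelihood("tQ", mm, [simple_curve, other]) == pytest.approx(sum(lls))

    def test_zero_propensity_with_observed_event_is_impossible(self):
        # no enzyme, yet a count appears: log-likelihood -inf
        curve = make_curve([0, 1], [0.0, 1.0], E_T=0.0, S_T=2.0)
        assert tk.log_likelihood("sQ", tk.MMParams(1.0, 2.0), [curve]) == -np.inf

    def test_decreasing_counts_rejected_as_data_error(self, simple_curve):
        simple_curve = tk.ProgressCurve(condition=simple_curve.condition,
                                        P_obs=simple_curve.P_obs.copy())
        simple_curve.P_obs = np.array([1, 0])  # bypass constructor check
        with pytest.raises(ValueError, match="decreasing"):
            IncrementData.from_curves([simple_curve])


class TestPriors:
    @pytest.mark.parametrize("m,shape", [(2.0, 0.2), (10.0, 1.0)])
    def test_moment_identities(self, m, shape):
        p = tk.prior_from_mean(m, 10.0)
        assert p.shape == pytest.approx(shape)
        assert p.rate == pytest.approx(0.1)
        assert p.mean == pytest.approx(m)
        assert p.variance / p.mean == pytest.approx(10.0)

    def test_nonpositive_inputs_rejected(self):
        for bad in [(-1.0, 10.0), (1.0, 0.0)]:
            with pytest.raises(ValueError):
                tk.prior_from_mean(*bad)


class TestKcatConditional:
    def test_matches_conjugate_closed_form(self, test_fx, low_curves, priors):
        prior_k, _ = priors
        data = IncrementData.from_curves(low_curves)
        g = data.g("tQ", 2.0)
        shape = prior_k.shape + data.n.sum()
        rate = prior_k.rate + (g * data.dt).sum()
        d = tk.sample_kcat_conditional(2.0, low_curves, prior_k, 100_000, seed=3)
        se = np.sqrt(shape) / rate / np.sqrt(100_000)
        assert abs(d.k_cat.mean() - shape / rate) < 3 * se

    def test_no_data_returns_the_prior(self, priors):
        prior_k, _ = priors
        d = tk.sample_kcat_conditional(2.0, [], prior_k, 200_000, seed=4)
        assert d.k_cat.mean() == pytest.approx(prior_k.mean, rel=0.05)
        assert d.k_cat.var() == pytest.approx(prior_k.variance, rel=0.1)

    def test_mh_route_agrees_with_exact_gamma(self, low_curves, priors):
        # generic Metropolis-Hastings vs conjugate sampling of the same
        # conditional: distributions agree in Kolmogorov-Smirnov distance
        prior_k, _ = priors
        d1 = tk.sample_kcat_conditional(2.0, low_curves, prior_k, 20_000, seed=5)
        d2 = tk.sample_kcat_mh(2.0, low_curves, prior_k, 20_000, seed=6)
        assert stats.ks_2samp(d1.k_cat, d2.k_cat).statistic < 0.025

    def test_deterministic_under_fixed_seed(self, low_curves, priors):
        a = tk.sample_kcat_conditional(2.0, low_curves, priors[0], 100, seed=9)
        b = tk.sample_kcat_conditional(2.0, low_curves, priors[0], 100, seed=9)
        assert np.array_equal(a.k_cat, b.k_cat)


class TestKmConditional:
    def test_uninformative_data_returns_the_prior(self, priors):
        # enzyme-free curves carry no K_M information: posterior == prior
        _, prior_km = priors
        flat = make_curve([0, 0, 0], [0.0, 1.0, 2.0], E_T=0.0, S_T=2.0)
        d = tk.sample_km_conditional(1.0, [flat], prior_km, 40_000, seed=12)
        ks = stats.kstest(d.K_M, stats.gamma(prior_km.shape,
                                             scale=1 / prior_km.rate).cdf).statistic
        assert ks < 0.05  # autocorrelated draws: generous MC band

    def test_recovers_km_from_tq_simulated_data(self, test_fx, priors):
        # 20 tQ birth-process curves at the low benchmark condition:
        # pooled posterior mean within 20% of the true 2 nM
        _, prior_km = priors
        mm = test_fx.params.mm()
        seeds = tk.child_seeds(55, 20)
        curves = [tk.gillespie_reduced("tQ", mm, test_fx.design_low,
                                       int(s)).progress_curve()
                  for s in seeds]
        d = tk.sample_km_conditional(1.0, curves, prior_km, 20_000, seed=13)
        assert d.K_M.mean() == pytest.approx(2.0, rel=0.2)

    def test_sq_model_overestimates_km_at_high_enzyme(self, test_fx, priors):
        # fitting the Michaelis-Menten law to excess-enzyme data inflates K_M
        _, prior_km = priors
        cond = tk.make_condition(40.0, 0.2, test_fx.omega, mm=test_fx.params.mm())
        curves = tk.generate_datasets(test_fx.params, cond, 10, seed=14)
        d = tk.sample_km_conditional(1.0, curves, prior_km, 10_000, seed=15, model="sQ")
        assert d.K_M.mean() > 2.0


class TestJointSampler:
    def test_pooled_low_high_recovers_both_parameters(self, test_fx, priors, low_curves):
        high = tk.make_condition(40.0, 0.2, test_fx.omega, mm=test_fx.params.mm())
        curves = low_curves + tk.generate_datasets(test_fx.params, high, 20, seed=16)
        d = tk.sample_joint(curves, priors, 10_000, seed=17)
        assert d.k_cat.mean() == pytest.approx(1.0, rel=0.2)
        assert d.K_M.mean() == pytest.approx(2.0, rel=0.2)

    def test_high_enzyme_curve_leaves_km_at_prior_spread(self, test_fx, priors):
        # K_M drops out of the tQ law when E_T >> K_M: its posterior stays
        # about as wide as the prior while k_cat concentrates
        high = tk.make_condition(40.0, 0.2, test_fx.omega, mm=test_fx.params.mm())
        curves = tk.generate_datasets(test_fx.params, high, 1, seed=18)
        d = tk.sample_joint(curves, priors, 10_000, seed=19)
        km_sd_log = np.std(np.log(d.K_M))
        prior_cv_kcat = np.sqrt(priors[0].variance) / priors[0].mean
        assert km_sd_log > 0.5 * priors[1].sd_log
        assert np.std(d.k_cat) / d.k_cat.mean() < 0.2 * prior_cv_kcat

    def test_insensitive_to_chain_initialization(self, test_fx, priors, low_curves):
        # ergodicity check on an identified (pooled) target: starting at
        # the prior means or 10x above lands on the same posterior
        high = tk.make_condition(40.0, 0.2, test_fx.omega, mm=test_fx.params.mm())
        curves = low_curves[:5] + tk.generate_datasets(test_fx.params, high,
                                                       5, seed=90)
        d1 = tk.sample_joint(curves, priors, 20_000, seed=20)
        d2 = tk.sample_joint(curves, priors, 20_000, seed=21,
                             init=(10 * priors[0].mean, 10 * priors[1].mean))
        assert d1.k_cat.mean() == pytest.approx(d2.k_cat.mean(), rel=0.1)
        assert d1.K_M.mean() == pytest.approx(d2.K_M.mean(), rel=0.2)

    def test_posterior_sd_shrinks_with_more_curves(self, test_fx, priors, low_curves):
        # single-parameter estimation: more pooled curves, tighter k_cat
        sds = []
        for k in (1, 5, 20):
            d = tk.sample_kcat_conditional(2.0, low_curves[:k], priors[0],
                                           8_000, seed=22)
            sds.append(d.k_cat.std())
        assert sds[0] > sds[1] > sds[2]

    def test_posterior_cv_below_prior_cv_for_informative_data(self, test_fx, priors, low_curves):
        prior_cv = np.sqrt(priors[0].variance) / priors[0].mean
        d = tk.sample_kcat_conditional(2.0, low_curves, priors[0], 10_000, seed=23)
        assert d.k_cat.std() / d.k_cat.mean() < prior_cv

    def test_sq_and_tq_posteriors_agree_at_low_enzyme(self, test_fx, priors, low_curves):
        # the equivalence regime E_T << S_T + K_M: both reductions give
        # the same k_cat posterior up to Monte-Carlo error
        a = tk.sample_kcat_conditional(2.0, low_curves, priors[0], 50_000,
                                       seed=24, model="tQ")
        b = tk.sample_kcat_conditional(2.0, low_curves, priors[0], 50_000,
                                       seed=25, model="sQ")
        assert a.k_cat.mean() == pytest.approx(b.k_cat.mean(), rel=0.1)

    def test_sq_bias_exceeds_tq_bias_at_high_enzyme(self, test_fx, priors):
        high = tk.make_condition(40.0, 0.2, test_fx.omega, mm=test_fx.params.mm())
        curves = tk.generate_datasets(test_fx.params, high, 10, seed=26)
        err = {}
        for model in ("tQ", "sQ"):
            d = tk.sample_kcat_conditional(2.0, curves, priors[0], 10_000,
                                           seed=27, model=model)
            err[model] = abs(d.k_cat.mean() - 1.0)
        assert err["sQ"] > err["tQ"]

    def test_identical_seed_gives_identical_chains(self, priors, low_curves):
        a = tk.sample_joint(low_curves[:3], priors, 2_000, seed=28)
        b = tk.sample_joint(low_curves[:3], priors, 2_000, seed=28)
        assert np.array_equal(a.k_cat, b.k_cat)
        assert np.array_equal(a.K_M, b.K_M)


class TestSummaries:
    def test_constant_draws(self):
        d = tk.PosteriorDraws(k_cat=np.full(50, 3.0), K_M=None, model="tQ",
                              n_iterations=50, burn_in=0, seed=0,
                              acceptance_rate=1.0, sampler="gamma-exact")
        s = tk.summarize(d)
        assert s["parameters"]["k_cat"]["mean"] == 3.0
        assert s["parameters"]["k_cat"]["cv"] == 0.0

    def test_gamma_cv_identity(self):
        rng = np.random.default_rng(1)
        draws = rng.gamma(10.1, 1 / 10.1, size=100_000)
        d = tk.PosteriorDraws(k_cat=draws, K_M=None, model="tQ",
                              n_iterations=draws.size, burn_in=0, seed=1,
                              acceptance_rate=1.0, sampler="gamma-exact")
        cv = tk.summarize(d)["parameters"]["k_cat"]["cv"]
        assert cv == pytest.approx(1 / np.sqrt(10.1), rel=0.02)

    def test_independent_draws_have_null_log_correlation(self):
        rng = np.random.default_rng(2)
        n = 40_000
        d = tk.PosteriorDraws(k_cat=rng.lognormal(0, 1, n),
                              K_M=rng.lognormal(1, 2, n), model="tQ",
                              n_iterations=n, burn_in=0, seed=2,
                              acceptance_rate=1.0, sampler="gibbs")
        assert abs(tk.summarize(d)["log_correlation"]) < 3 / np.sqrt(n)

    def test_empty_draws_rejected(self):
        d = tk.PosteriorDraws(k_cat=np.empty(0), K_M=None, model="tQ",
                              n_iterations=0, burn_in=0, seed=0,
                              acceptance_rate=0.0, sampler="gamma-exact")
        with pytest.raises(ValueError):
            tk.summarize(d)
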