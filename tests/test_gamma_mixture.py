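"""Gamma fitting: single, mixture, constrained refit, LRT."""

import numpy as np
import pytest
from scipy import stats

from synsites import gamma_mixture as gm
from synsites import synthetic_data as sd

P16_LIKE = sd.GeneratorParams(kappa=0.3, alpha1=16.0, beta1=1.05, alpha2=20.0, beta2=0.5)


def match_to_truth(fit):
    """Return (kappa, mean) of the fitted component closer to the 16.8-pA
    population, and the mean of the other one."""
    m1, m2 = gm.component_means(fit)
    if abs(m1 - 16.8) + abs(m2 - 10.0) <= abs(m2 - 16.8) + abs(m1 - 10.0):
        return fit.kappa, m1, m2
    return 1.0 - fit.kappa, m2, m1


class TestFitSingle:
    def test_recovers_generating_parameters(self):
        x = np.random.default_rng(1).gamma(4.0, 2.5, size=10_000)
        fit = gm.fit_single(x)
        assert 3.8 < fit.component.alpha < 4.2
        assert fit.component.mean == pytest.approx(x.mean(), rel=0.02)
        assert not fit.bound_active

    def test_shape_upper_bound_binds(self):
        # data from a shape-60 gamma: the (0, 40] box pins alpha at 40
        x = np.random.default_rng(2).gamma(60.0, 0.2, size=5_000)
        fit = gm.fit_single(x)
        assert fit.component.alpha == pytest.approx(gm.ALPHA_MAX)
        assert fit.bound_active

    def test_near_degenerate_data_flagged(self):
        x = 10.0 + np.random.default_rng(3).normal(0, 0.01, size=1_000)
        fit = gm.fit_single(x)
        assert fit.bound_active

    def test_nonpositive_amplitudes_rejected(self):
        with pytest.raises(ValueError):
            gm.fit_single(np.array([1.0] * 60 + [-2.0]))

    def test_too_few_events_rejected(self):
        with pytest.raises(ValueError):
            gm.fit_single(np.ones(10))


class TestFitMixture:
    def test_recovers_two_gamma_parameters(self):
        x = sd.sample_amplitudes(P16_LIKE, 5_000, seed=4)
        fit = gm.fit_mixture(x)
        kappa, big_mean, small_mean = match_to_truth(fit)
        assert big_mean == pytest.approx(16.8, rel=0.10)
        assert small_mean == pytest.approx(10.0, rel=0.10)
        assert kappa == pytest.approx(0.3, abs=0.1)

    def test_labeling_rule_orders_shapes(self):
        x = sd.sample_amplitudes(P16_LIKE, 3_000, seed=5)
        fit = gm.fit_mixture(x)
        assert fit.comp1.alpha >= fit.comp2.alpha

    def test_mixture_mean_matches_sample_mean(self):
        x = sd.sample_amplitudes(P16_LIKE, 3_000, seed=6)
        fit = gm.fit_mixture(x)
        assert fit.mixture_mean == pytest.approx(x.mean(), rel=0.02)

    def test_mixture_beats_single_on_bimodal_data(self):
        x = sd.sample_amplitudes(P16_LIKE, 3_000, seed=7)
        single = gm.fit_single(x)
        fit = gm.fit_mixture(x, init_from=single)
        assert fit.loglik > single.loglik

    def test_single_gamma_data_not_strongly_mixture(self):
        # null-model recovery: on unimodal gamma data the LRT should not
        # produce overwhelming evidence for the mixture
        x = np.random.default_rng(8).gamma(9.0, 1.2, size=2_000)
        single = gm.fit_single(x)
        fit = gm.fit_mixture(x, init_from=single)
        lrt = gm.likelihood_ratio_test(single.loglik, fit.loglik)
        assert lrt.p_value > 1e-4

    def test_deterministic_given_data(self):
        x = sd.sample_amplitudes(P16_LIKE, 2_000, seed=9)
        a, b = gm.fit_mixture(x), gm.fit_mixture(x)
        assert a.loglik == b.loglik and a.kappa == b.kappa


class TestConstrainedRefit:
    def test_scale_change_recovered_per_component(self):
        base = sd.sample_amplitudes(P16_LIKE, 5_000, seed=10)
        scaled_params = sd.GeneratorParams(
            kappa=0.3, alpha1=16.0, beta1=1.05 * 1.4, alpha2=20.0, beta2=0.5 * 1.4
        )
        drug = sd.sample_amplitudes(scaled_params, 5_000, seed=11)
        fit = gm.fit_mixture(base)
        refit = gm.fit_mixture_constrained(
            drug, fit.comp1.alpha, fit.comp2.alpha,
            beta1_init=fit.comp1.beta, beta2_init=fit.comp2.beta, kappa_init=fit.kappa,
        )
        assert refit.constrained
        assert refit.comp1.beta / fit.comp1.beta == pytest.approx(1.4, rel=0.1)
        assert refit.comp2.beta / fit.comp2.beta == pytest.approx(1.4, rel=0.1)

    def test_constraint_inactive_at_unconstrained_optimum(self):
        x = sd.sample_amplitudes(P16_LIKE, 4_000, seed=12)
        fit = gm.fit_mixture(x)
        refit = gm.fit_mixture_constrained(
            x, fit.comp1.alpha, fit.comp2.alpha,
            beta1_init=fit.comp1.beta, beta2_init=fit.comp2.beta, kappa_init=fit.kappa,
        )
        assert refit.kappa == pytest.approx(fit.kappa, abs=0.02)
        assert refit.comp1.beta == pytest.approx(fit.comp1.beta, rel=0.02)
        assert refit.comp2.beta == pytest.approx(fit.comp2.beta, rel=0.02)

    def test_constrained_loglik_not_above_unconstrained(self):
        x = sd.sample_amplitudes(P16_LIKE, 4_000, seed=13)
        fit = gm.fit_mixture(x)
        refit = gm.fit_mixture_constrained(
            x, fit.comp1.alpha * 0.9, fit.comp2.alpha * 1.1,
        )
        assert refit.loglik <= fit.loglik + 1e-6

    def test_raised_weight_detected(self):
        # unidling-style generation: component weight raised under the drug
        base = sd.sample_amplitudes(P16_LIKE, 5_000, seed=14)
        drug = sd.sample_amplitudes(
            sd.GeneratorParams(kappa=0.55, alpha1=16.0, beta1=1.05, alpha2=20.0, beta2=0.5),
            5_000, seed=15,
        )
        fit = gm.fit_mixture(base)
        refit = gm.fit_mixture_constrained(
            drug, fit.comp1.alpha, fit.comp2.alpha,
            beta1_init=fit.comp1.beta, beta2_init=fit.comp2.beta, kappa_init=fit.kappa,
        )
        k_base, _, _ = match_to_truth(fit)
        k_drug = refit.kappa if abs(refit.comp1.mean - 16.8) < abs(refit.comp2.mean - 16.8) \
            else 1.0 - refit.kappa
        assert k_drug > k_base


class TestLikelihoodRatio:
    def test_equal_logliks_give_unit_p(self):
        res = gm.likelihood_ratio_test(-100.0, -100.0)
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_chi_square_tail_oracle(self):
        res = gm.likelihood_ratio_test(-110.0, -100.0, df=3)
        assert res.statistic == pytest.approx(20.0)
        assert res.p_value == pytest.approx(stats.chi2.sf(20.0, 3), rel=1e-12)
        assert res.p_value < 0.001

    def test_negative_statistic_raises(self):
        with pytest.raises(gm.ConvergenceError):
            gm.likelihood_ratio_test(-100.0, -101.0)


class TestComponentMeans:
    def test_mean_is_shape_times_scale(self):
        fit = gm.MixtureFit(
            kappa=0.4,
            comp1=gm.GammaComponent(16.0, 1.05),
            comp2=gm.GammaComponent(20.0, 0.5),
            loglik=-1.0,
            n_events=100,
        )
        assert gm.component_means(fit) == (pytest.approx(16.8), pytest.approx(10.0))
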