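"""Spine transmission-site Monte-Carlo: assignment rules, TCM switch,
closed-form expectations and response statistics."""

import numpy as np
import pytest

from synsites import spine_simulator as sp


@pytest.fixture(scope="module")
def pool():
    return sp.UnitResponsePool.generate(seed=0)


class TestUnitResponsePool:
    def test_pool_shape_and_moments(self, pool):
        assert pool.values.shape == (50, 50)
        assert pool.values.mean() == pytest.approx(-4.0, abs=0.15)
        assert pool.values.std() == pytest.approx(1.0, abs=0.1)

    def test_pool_reproducible_per_seed(self):
        a = sp.UnitResponsePool.generate(seed=5)
        b = sp.UnitResponsePool.generate(seed=5)
        np.testing.assert_array_equal(a.values, b.values)


class TestBuildPopulation:
    def test_uniform_all_effective_when_all_unsilenced(self, pool):
        cfg = sp.UniformConfig(
            n_spines=500, p_silent_silenceable=0.0, p_unsilenced_silenceable=1.0,
            p_idled=0.0, p_unidled=0.0,
        )
        popn = sp.build_population(cfg, pool, seed=1)
        assert popn.effective.all()

    def test_uniform_assignment_probabilities(self, pool):
        cfg = sp.UniformConfig(n_spines=10_000)
        popn = sp.build_population(cfg, pool, seed=2)
        # per-spine mode: all sites of a spine share it
        spine_mode = np.full(cfg.n_spines, -1)
        spine_mode[popn.spine_id] = popn.mode
        for mode, p in zip(
            (sp.SILENT, sp.UNSILENCED, sp.IDLED, sp.UNIDLED), cfg.mode_probabilities
        ):
            frac = np.mean(spine_mode == mode)
            sdev = np.sqrt(p * (1 - p) / cfg.n_spines)
            assert abs(frac - p) < 3 * sdev

    def test_uniform_spines_are_homogeneous(self, pool):
        popn = sp.build_population(sp.UniformConfig(n_spines=300), pool, seed=3)
        for s in range(300):
            modes = popn.mode[popn.spine_id == s]
            assert len(np.unique(modes)) == 1

    def test_mixed_every_spine_holds_both_types(self, pool):
        cfg = sp.MixedConfig(n_spines=500)
        popn = sp.build_population(cfg, pool, seed=4)
        for s in range(cfg.n_spines):
            types = popn.site_type[popn.spine_id == s]
            assert (types == 0).any() and (types == 1).any()

    def test_mixed_silenceable_count_range(self, pool):
        cfg = sp.MixedConfig(n_spines=500)
        popn = sp.build_population(cfg, pool, seed=5)
        for s in range(cfg.n_spines):
            n_sil = int((popn.site_type[popn.spine_id == s] == 0).sum())
            assert 1 <= n_sil <= 2

    def test_invalid_probability_vector_rejected(self):
        with pytest.raises(ValueError):
            sp.UniformConfig(p_silent_silenceable=0.5)  # probabilities sum > 1

    def test_bit_reproducible(self, pool):
        cfg = sp.MixedConfig(n_spines=200)
        a = sp.build_population(cfg, pool, seed=6)
        b = sp.build_population(cfg, pool, seed=6)
        np.testing.assert_array_equal(a.mode, b.mode)
        np.testing.assert_array_equal(a.unit_response, b.unit_response)


class TestApplyTcm:
    def test_no_idled_sites_identical_counts(self, pool):
        cfg = sp.UniformConfig(
            n_spines=300, p_silent_silenceable=0.2, p_unsilenced_silenceable=0.5,
            p_idled=0.0, p_unidled=0.3,
        )
        base = sp.build_population(cfg, pool, seed=7)
        tcm = sp.apply_tcm(base)
        np.testing.assert_array_equal(base.n_eff_per_spine(), tcm.n_eff_per_spine())

    def test_per_spine_monotone_and_conserved(self, pool):
        base = sp.build_population(sp.MixedConfig(n_spines=500), pool, seed=8)
        tcm = sp.apply_tcm(base)
        assert np.all(tcm.n_eff_per_spine() >= base.n_eff_per_spine())
        assert tcm.n_sites == base.n_sites
        np.testing.assert_array_equal(tcm.mode, base.mode)

    def test_all_idled_population_fold_undefined(self, pool):
        cfg = sp.UniformConfig(
            n_spines=100, p_silent_silenceable=0.0, p_unsilenced_silenceable=0.0,
            p_idled=1.0, p_unidled=0.0,
        )
        base = sp.build_population(cfg, pool, seed=9)
        summary = sp.summarize([(base, sp.apply_tcm(base))], model="uniform")
        assert np.isnan(summary.folds_n_eff[0])
        assert summary.neff_hist_tcm.sum() == 100  # counts still valid


class TestClosedFormAgreement:
    def test_uniform_effective_totals_match_expectation(self, pool):
        # E[total] = n_spines * E[sites/spine] * P(effective mode)
        cfg = sp.UniformConfig(n_spines=20_000)
        base = sp.build_population(cfg, pool, seed=10)
        tcm = sp.apply_tcm(base)
        e_sites = 4.5
        for popn, p_eff in ((base, 0.35), (tcm, 0.95)):
            total = popn.n_eff_per_spine().sum()
            expected = cfg.n_spines * e_sites * p_eff
            # conservative per-spine variance bound: Var <= E[n^2] * p = 25.5 p
            sdev = np.sqrt(cfg.n_spines * 25.5 * p_eff)
            assert abs(total - expected) < 3 * sdev

    def test_response_fold_tracks_neff_fold(self):
        summary = sp.simulate(sp.MixedConfig(), seed=11)
        assert summary.mean_fold_response == pytest.approx(summary.mean_fold_n_eff, rel=0.05)

    def test_mean_response_tracks_unit_size(self, pool):
        base = sp.build_population(sp.UniformConfig(n_spines=5_000), pool, seed=12)
        resp = base.responses()
        neff = base.n_eff_per_spine()
        responders = neff > 0
        mean_resp = np.abs(resp[responders]).mean()
        assert mean_resp == pytest.approx(4.0 * neff[responders].mean(), rel=0.05)


class TestSpineResponse:
    def test_single_effective_site_response(self):
        popn = sp.SpinePopulation(
            spine_id=np.array([0]), mode=np.array([sp.UNIDLED]),
            unit_response=np.array([-4.0]), n_spines=1,
            effective=np.array([True]),
        )
        assert sp.spine_response(popn, 0) == pytest.approx(-4.0)

    def test_response_is_sum_of_effective_units(self):
        popn = sp.SpinePopulation(
            spine_id=np.array([0, 0, 0, 0]),
            mode=np.array([sp.UNIDLED, sp.UNSILENCED, sp.IDLED, sp.UNIDLED]),
            unit_response=np.array([-3.0, -4.0, -5.0, -6.0]),
            n_spines=1,
            effective=np.array([True, True, False, True]),
        )
        assert sp.spine_response(popn, 0) == pytest.approx(-13.0)


class TestSimulateAndSummarize:
    def test_seeded_runs_identical(self):
        a = sp.simulate(sp.UniformConfig(n_iterations=2, n_spines=300), seed=13)
        b = sp.simulate(sp.UniformConfig(n_iterations=2, n_spines=300), seed=13)
        np.testing.assert_array_equal(a.folds_n_eff, b.folds_n_eff)
        np.testing.assert_array_equal(a.responses_tcm, b.responses_tcm)

    def test_uniform_nonresponders_reflect_silent_fraction(self):
        summary = sp.simulate(sp.UniformConfig(), seed=14)
        # baseline: silent + idled spines do not respond (~65% by assignment)
        assert summary.frac_zero_neff_baseline == pytest.approx(0.65, abs=0.05)
        assert summary.frac_zero_neff_tcm == pytest.approx(0.05, abs=0.02)

    def test_per_spine_frame_shape(self, pool):
        cfg = sp.MixedConfig(n_spines=100)
        base = sp.build_population(cfg, pool, seed=15)
        df = sp.per_spine_frame([(base, sp.apply_tcm(base))])
        assert len(df) == 100
        assert (df["n_eff_tcm"] >= df["n_eff_baseline"]).all()


class TestMultiGaussian:
    def test_single_gaussian_selected(self, rng):
        x = rng.normal(-4.0, 0.5, size=2_000)
        fit = sp.fit_multi_gaussian(x, max_components=4)
        assert fit.n_components == 1

    def test_two_well_separated_peaks(self, rng):
        x = np.concatenate([rng.normal(-4.0, 0.5, 1_000), rng.normal(-8.0, 0.5, 1_000)])
        fit = sp.fit_multi_gaussian(x, max_components=4)
        assert fit.n_components == 2
        assert fit.means[0] == pytest.approx(-8.0, abs=0.3)
        assert fit.means[1] == pytest.approx(-4.0, abs=0.3)

    def test_mixed_model_baseline_multimodal(self):
        # responders of the mixed model stack ~4-pA units: at least three
        # detectable quantal peaks
        summary = sp.simulate(sp.MixedConfig(), seed=16)
        resp = summary.responses_baseline
        resp = resp[np.abs(resp) > sp.RESPONDER_THRESHOLD_PA]
        fit = sp.fit_multi_gaussian(resp, max_components=6)
        assert fit.n_components >= 3
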