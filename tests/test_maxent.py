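"""Unit tests for the K-pairwise model, its samplers and the inverse problem."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from neuromaxent.maxent import (
    BMDivergenceError,
    KPairwiseModel,
    LearningSchedule,
    SamplerConfig,
    bm_fit,
    delta_energy,
    energy,
    enumerate_exact,
    exact_three_point,
    independent_model,
    metropolis_moments,
    predict_three_point,
    random_model,
    sample_raster,
)
from neuromaxent.spike_stats import BinnedRaster, compute_moments


class TestEnergy:
    def test_null_model_has_zero_energy(self):
        m = independent_model(np.zeros(3))
        for sigma in ([1, 1, 1], [-1, 1, -1], [-1, -1, -1]):
            assert energy(m, sigma) == 0.0

    def test_two_spin_hand_value(self):
        m = KPairwiseModel(np.array([1.0, -1.0]),
                           np.array([[0.0, 0.5], [0.5, 0.0]]), np.zeros(3))
        assert energy(m, [1, 1]) == pytest.approx(-0.5)

    def test_synchrony_potential_enters_through_k(self):
        V = np.array([0.0, 0.0, 2.0])
        m = KPairwiseModel(np.array([1.0, -1.0]),
                           np.array([[0.0, 0.5], [0.5, 0.0]]), V)
        assert energy(m, [1, 1]) == pytest.approx(-2.5)

    def test_gauge_and_symmetry_are_enforced(self):
        with pytest.raises(ValueError):
            KPairwiseModel(np.zeros(2), np.zeros((2, 2)), np.array([1.0, 0, 0]))
        with pytest.raises(ValueError):
            KPairwiseModel(np.zeros(2), np.array([[0, 1.0], [0.5, 0]]), np.zeros(3))


class TestDeltaEnergy:
    def test_independent_spin_flip(self):
        m = independent_model(np.array([1.0]))
        assert delta_energy(m, np.array([1.0]), 0) == pytest.approx(2.0)

    @given(st.integers(0, 7), st.integers(0, 2 ** 32 - 1))
    @settings(max_examples=30, deadline=None)
    def test_matches_full_recomputation(self, flip, seed):
        m = random_model(8, seed=seed, v_scale=0.4)
        rng = np.random.default_rng(seed)
        sigma = rng.choice([-1.0, 1.0], 8)
        flipped = sigma.copy()
        flipped[flip] *= -1
        expect = energy(m, flipped) - energy(m, sigma)
        assert delta_energy(m, sigma, flip) == pytest.approx(expect, abs=1e-10)

    def test_flip_up_then_down_cancels(self):
        m = random_model(6, seed=1, v_scale=0.3)
        sigma = np.ones(6)
        d1 = delta_energy(m, sigma, 2)
        sigma[2] *= -1
        d2 = delta_energy(m, sigma, 2)
        assert d1 + d2 == pytest.approx(0.0, abs=1e-12)


class TestEnumeration:
    def test_single_free_spin(self):
        ex = enumerate_exact(independent_model(np.zeros(1)), 1.0)
        assert ex.z == pytest.approx(2.0)
        assert ex.moments.mean_sigma[0] == pytest.approx(0.0)

    def test_isolated_pair_correlation_is_tanh_j(self):
        m = KPairwiseModel(np.zeros(2), np.array([[0, 0.5], [0.5, 0]]), np.zeros(3))
        ex = enumerate_exact(m, 1.0)
        assert ex.moments.pair_sigma[0] == pytest.approx(np.tanh(0.5))

    def test_free_spins_have_binomial_synchrony(self):
        ex = enumerate_exact(independent_model(np.zeros(3)), 1.0)
        from scipy.stats import binom
        np.testing.assert_allclose(ex.moments.pk, binom.pmf(np.arange(4), 3, 0.5),
                                   atol=1e-12)

    def test_independent_spins_at_temperature(self):
        h = np.array([0.7, -0.4])
        for T in (0.5, 2.0):
            ex = enumerate_exact(independent_model(h), T)
            np.testing.assert_allclose(ex.moments.mean_sigma, np.tanh(h / T),
                                       atol=1e-12)

    def test_state_space_guard(self):
        with pytest.raises(ValueError):
            enumerate_exact(independent_model(np.zeros(21)))

    def test_exact_three_point_vanishes_for_independent_spins(self):
        t = exact_three_point(independent_model(np.array([0.3, -0.2, 0.8, 0.1])))
        np.testing.assert_allclose(t, 0.0, atol=1e-12)


class TestMetropolis:
    def test_single_spin_magnetization(self):
        m = independent_model(np.array([1.0]))
        mom, _ = metropolis_moments(m, 1.0, SamplerConfig(n_samples=40_000,
                                                          n_chains=8, seed=0))
        z = abs(mom.mean_sigma[0] - np.tanh(1.0)) / mom.se_mean[0]
        assert z < 3.0

    def test_infinite_temperature_limit(self):
        m = random_model(8, seed=2, v_scale=0.3)
        mom, _ = metropolis_moments(m, 1e3, SamplerConfig(n_samples=60_000,
                                                          n_chains=6, seed=1))
        assert np.all(np.abs(mom.mean_sigma) < 5 * mom.se_mean + 1e-3)
        from scipy.stats import binom
        expect = binom.pmf(np.arange(9), 8, 0.5)
        assert np.all(np.abs(mom.pk - expect) < 5 * mom.se_pk + 1e-3)

    def test_stationary_distribution_of_two_spin_chain(self):
        # empirical state probabilities against the Boltzmann weights
        m = KPairwiseModel(np.array([0.4, -0.3]),
                           np.array([[0, 0.6], [0.6, 0]]),
                           np.array([0.0, -0.4, 0.3]))
        raster = sample_raster(m, 60_000, seed=5, thin=3)
        states = (raster.sigma.T > 0) @ np.array([1, 2])
        emp = np.bincount(states, minlength=4) / states.size
        ex = enumerate_exact(m, 1.0)
        weights = np.zeros(4)
        for code in range(4):
            sigma = np.array([1 if code & 1 else -1, 1 if code & 2 else -1], float)
            weights[code] = np.exp(-energy(m, sigma)) / ex.z
        se = np.sqrt(weights * (1 - weights) / states.size) * 3  # i.i.d. floor
        assert np.all(np.abs(emp - weights) < 10 * se)  # thinned, correlated draws

    def test_sampled_raster_moments_match_enumeration(self):
        m = random_model(10, seed=3, h_scale=0.5, j_scale=0.3, v_scale=0.2)
        raster = sample_raster(m, 200_000, seed=4)
        got = compute_moments(raster)
        ex = enumerate_exact(m, 1.0)
        z = np.abs(got.mean_sigma - ex.moments.mean_sigma) / np.maximum(got.se_mean, 1e-12)
        zp = np.abs(got.pair_sigma - ex.moments.pair_sigma) / np.maximum(got.se_pair, 1e-12)
        assert np.mean(z < 3) > 0.95 and z.max() < 6
        assert np.mean(zp < 3) > 0.95 and zp.max() < 6

    def test_silent_start_heavily_negative_model_stays_silent(self):
        h = np.arctanh(-0.9) * np.ones(6)
        m = independent_model(h)
        raster = sample_raster(m, 100_000, seed=6)
        got = compute_moments(raster)
        ex = enumerate_exact(m, 1.0)
        assert abs(got.pk[0] - ex.moments.pk[0]) < 5 * got.se_pk[0] + 1e-3

    def test_empty_raster_request(self):
        assert sample_raster(independent_model(np.zeros(4)), 0).n_bins == 0


class TestBMFit:
    SCHED = LearningSchedule(theta0=0.3, alpha=0.5, max_iters=1200,
                             mc_samples=20_000, vk_rate_switch_iter=400)

    def test_independent_spins_recovered(self):
        rng = np.random.default_rng(7)
        target = 0.5
        sigma = np.where(rng.random((6, 40_000)) < (1 + target) / 2, 1, -1)
        data = compute_moments(BinnedRaster(sigma.astype(np.int8), 1))
        model, trace = bm_fit(data, self.SCHED,
                              SamplerConfig(n_samples=20_000, n_chains=1, seed=1),
                              seed=2)
        ex = enumerate_exact(model, 1.0)
        np.testing.assert_allclose(ex.moments.mean_sigma, data.mean_sigma, atol=0.02)
        np.testing.assert_allclose(ex.moments.corr, 0.0, atol=0.02)

    def test_gauge_is_preserved_and_unfitted_vk_stay_zero(self, if_fits):
        model, _ = if_fits("crit", 40)
        assert model.V[0] == 0.0
        assert np.all(model.V[~model.fitted_mask] == 0.0)

    def test_too_short_recording_rejected(self):
        from neuromaxent.spike_stats import MomentSet
        bad = MomentSet(3, 100, np.zeros(3), np.zeros(3), np.zeros(3),
                        np.ones(4) / 4)
        with pytest.raises(ValueError):
            bm_fit(bad, self.SCHED)

    def test_divergence_aborts_with_trace(self):
        rng = np.random.default_rng(8)
        sigma = rng.choice([-1, 1], size=(5, 20_000)).astype(np.int8)
        from neuromaxent.spike_stats import BinnedRaster
        data = compute_moments(BinnedRaster(sigma, 1))
        wild = LearningSchedule(theta0=500.0, alpha=0.01, max_iters=400,
                                mc_samples=2_000, vk_rate_switch_iter=10)
        with pytest.raises(BMDivergenceError) as err:
            bm_fit(data, wild, SamplerConfig(n_samples=2_000, n_chains=1, seed=3),
                   seed=4)
        assert len(err.value.trace["max_dmean"]) > 0

    def test_synchrony_constraint_improves_three_point_prediction(self):
        # ground-truth model with genuine synchrony structure: the
        # pairwise-only fit must miss the triplet correlations it creates
        n = 12
        truth = random_model(n, seed=21, h_scale=0.4, j_scale=0.3)
        truth.h -= 0.8
        K = np.arange(n + 1)
        truth.V[:] = (-1.5 * np.exp(-0.5 * ((K - 1.5) / 1.0) ** 2)
                      + 2.0 * np.exp(-0.5 * ((K - 5) / 1.5) ** 2))
        truth.V[0] = 0.0
        data = compute_moments(sample_raster(truth, 150_000, seed=3))
        sched = LearningSchedule(theta0=0.3, alpha=0.5, max_iters=2000,
                                 mc_samples=30_000, vk_rate_switch_iter=600)
        cfg = SamplerConfig(n_samples=30_000, n_chains=1, seed=4)
        with_k, _ = bm_fit(data, sched, cfg, seed=5)
        without_k, _ = bm_fit(data, sched, cfg, seed=5, fit_pk=False)
        t_truth = exact_three_point(truth)
        err_k = np.mean((exact_three_point(with_k) - t_truth) ** 2)
        err_p = np.mean((exact_three_point(without_k) - t_truth) ** 2)
        assert err_k < err_p


class TestPredictThreePoint:
    def test_independent_model_predicts_zero(self):
        m = independent_model(np.full(6, -0.5))
        mean, se = predict_three_point(m, SamplerConfig(n_samples=12_000,
                                                        n_chains=48, seed=5))
        z = np.abs(mean) / np.maximum(se, 1e-12)
        assert np.mean(z < 3) >= 0.95 and z.max() < 6

    def test_matches_enumeration_for_structured_model(self):
        m = random_model(8, seed=11, v_scale=0.3)
        mean, se = predict_three_point(m, SamplerConfig(n_samples=16_000,
                                                        n_chains=40, seed=6))
        truth = exact_three_point(m)
        z = np.abs(mean - truth) / np.maximum(se, 1e-12)
        assert np.mean(z < 3) > 0.95 and z.max() < 6
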