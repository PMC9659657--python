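"""Covariance matrix strategy: init, sampling, adaptation, repair."""

import numpy as np
import pytest

from whaleopt import (CMSState, cms_init, cms_sample, cms_update,
                      make_problem, repair_covariance, run_cms)


def _toy_state(dim=4, n=12, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, dim))
    f = rng.random(n)
    return cms_init(X, f, np.full(dim, -1.0), np.full(dim, 1.0))


class TestInit:
    def test_learning_rate_constants(self):
        state = _toy_state(dim=10, n=20)
        assert state.c1 == pytest.approx(0.02)  # 2 / dim^2
        assert state.mu == 10
        assert state.c_mu == pytest.approx(
            min(state.mu_eff / 100.0, 1.0 - state.c1))

    def test_log_weights_reduce_mu_eff(self):
        state = _toy_state(dim=5, n=10)
        assert np.isclose(state.weights.sum(), 1.0)
        assert np.all(np.diff(state.weights) <= 0)
        assert state.mu_eff == pytest.approx(1.0 / (state.weights ** 2).sum())
        assert state.mu_eff < state.mu  # equal weights would give mu exactly

    def test_degenerate_population_uses_fallback_sigma(self):
        X = np.ones((6, 3))
        f = np.arange(6.0)
        state = cms_init(X, f, np.full(3, -2.0), np.full(3, 2.0))
        assert state.sigma == pytest.approx(0.3 * 4.0)

    def test_mean_starts_at_best(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(8, 3))
        f = rng.random(8)
        state = cms_init(X, f, np.full(3, -1.0), np.full(3, 1.0))
        assert np.array_equal(state.m, X[np.argmin(f)])

    def test_tiny_population_rejected(self):
        with pytest.raises(ValueError):
            cms_init(np.ones((1, 3)), [0.0], np.zeros(3), np.ones(3))

    def test_state_json_round_trip(self):
        state = _toy_state()
        back = CMSState.from_json(state.to_json())
        assert np.allclose(back.C, state.C)
        assert back.sigma == state.sigma


class TestSample:
    def test_zero_sigma_limit_collapses_to_mean(self):
        state = _toy_state()
        state.sigma = 1e-300
        S = cms_sample(state, 5, np.random.default_rng(0))
        assert np.allclose(S, state.m)

    def test_sample_covariance_matches(self):
        state = _toy_state(dim=3)
        state.sigma = 1.0
        state.m = np.zeros(3)
        S = cms_sample(state, 10000, np.random.default_rng(1))
        emp = np.cov(S.T)
        # identity covariance within 3 standard errors (~sqrt(2/n))
        assert np.abs(emp - np.eye(3)).max() < 3 * np.sqrt(2.0 / 10000) + 0.01

    def test_fixed_seed_reproducible(self):
        state = _toy_state()
        a = cms_sample(state, 7, np.random.default_rng(9))
        b = cms_sample(state, 7, np.random.default_rng(9))
        assert np.array_equal(a, b)


class TestUpdate:
    def test_stationary_mean_decays_psigma_and_sigma(self):
        state = _toy_state(dim=4, n=12)
        state.Psigma = np.full(4, 0.5)
        # craft samples whose weighted recombination reproduces the old mean
        samples = np.tile(state.m, (state.mu * 2, 1))
        fits = np.arange(float(state.mu * 2))
        new = cms_update(state, samples, fits)
        assert np.allclose(new.Psigma, (1 - state.c_sigma) * state.Psigma)
        # and with Psigma = 0 sigma contracts by exactly exp(-c_sigma/d_sigma)
        state.Psigma = np.zeros(4)
        new2 = cms_update(state, samples, fits)
        assert new2.sigma == pytest.approx(
            state.sigma * np.exp(-state.c_sigma / state.d_sigma))

    def test_zero_learning_rates_freeze_covariance(self):
        state = _toy_state(dim=3, n=10)
        state.c1 = 0.0
        state.c_mu = 0.0
        rng = np.random.default_rng(2)
        samples = cms_sample(state, 10, rng)
        new = cms_update(state, samples, rng.random(10))
        assert np.allclose(new.C, state.C, atol=1e-12)

    def test_covariance_stays_valid(self):
        state = _toy_state(dim=5, n=12)
        rng = np.random.default_rng(3)
        for _ in range(20):
            samples = cms_sample(state, 12, rng)
            state = cms_update(state, samples, rng.random(12))
            assert np.abs(state.C - state.C.T).max() < 1e-12
            assert np.linalg.eigvalsh(state.C).min() >= 1e-12 * 0.99
            assert state.sigma > 0
            assert np.isclose(state.weights.sum(), 1.0)

    def test_selection_free_update_tracks_sample_mean(self):
        # equal weights + all samples selected: new mean = sample average
        state = _toy_state(dim=3, n=8)
        state.weights = np.full(state.mu, 1.0 / state.mu)
        rng = np.random.default_rng(4)
        samples = rng.normal(size=(state.mu, 3)) + 5.0
        new = cms_update(state, samples, np.zeros(state.mu))
        assert np.allclose(new.m, samples.mean(axis=0))

    def test_nonfinite_fitness_rejected(self):
        state = _toy_state()
        samples = cms_sample(state, 12, np.random.default_rng(0))
        fits = np.zeros(12)
        fits[0] = np.nan
        with pytest.raises(ValueError):
            cms_update(state, samples, fits)


class TestRepair:
    def test_identity_unchanged(self):
        assert np.array_equal(repair_covariance(np.eye(3)), np.eye(3))

    def test_negative_eigenvalue_clipped(self):
        C = np.diag([1.0, -0.1])
        out = repair_covariance(C, floor=1e-12)
        assert np.allclose(np.sort(np.linalg.eigvalsh(out)), [1e-12, 1.0])

    def test_symmetrizes_random_matrix(self):
        rng = np.random.default_rng(5)
        C = rng.normal(size=(6, 6))
        out = repair_covariance(C)
        assert np.abs(out - out.T).max() < 1e-14

    def test_non_square_rejected(self):
        with pytest.raises(ValueError):
            repair_covariance(np.ones((2, 3)))


def test_standalone_cms_converges_quickly():
    """CMS alone is a strong local optimizer on a smooth bowl."""
    prob = make_problem("sphere", 3, seed=8)
    res = run_cms(prob, 20, 6000, seed=0)
    assert res.best_fit < 1e-6
    assert res.fes_used == prob.eval_counter == 6000
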