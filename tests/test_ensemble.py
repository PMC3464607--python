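"""Ensemble operations: initialization, propagation, ESS, resampling."""

import numpy as np
import pytest
from scipy.stats import chisquare

from sbscall.caller import (
    Ensemble,
    advance_ensemble,
    effective_sample_size,
    init_ensemble,
    multinomial_resample,
    posterior_base_distribution,
)
from sbscall.params import CycleParams, ParameterSet, PhasingParams


class TestEffectiveSampleSize:
    def test_uniform_weights(self):
        assert effective_sample_size(np.full(50, 1 / 50)) == pytest.approx(50)

    def test_degenerate_weight(self):
        w = np.zeros(20)
        w[3] = 1.0
        assert effective_sample_size(w) == pytest.approx(1.0)

    def test_two_equal_weights(self):
        w = np.zeros(10)
        w[0] = w[1] = 0.5
        assert effective_sample_size(w) == pytest.approx(2.0)


def uniform_ensemble(N, W=3, t=1, seed=0):
    rng = np.random.default_rng(seed)
    return Ensemble(
        bases=rng.integers(0, 4, size=(N, W)).astype(np.int8),
        lam=np.ones(N),
        log_weights=np.full(N, -np.log(N)),
        t=t,
        l=1,
        r=1,
    )


class TestMultinomialResample:
    def test_degenerate_weight_copies_single_particle(self):
        ens = uniform_ensemble(30)
        lw = np.full(30, -np.inf)
        lw[7] = 0.0
        ens.log_weights = lw
        out = multinomial_resample(ens, np.random.default_rng(0))
        assert np.all(out.bases == ens.bases[7])
        assert out.K_eff == pytest.approx(out.N_p)

    def test_offspring_counts_multinomial(self):
        """Aggregated offspring over many resamplings follow the weights."""
        N = 16
        rng = np.random.default_rng(42)
        w = rng.dirichlet(np.ones(N))
        ens = uniform_ensemble(N)
        ens.log_weights = np.log(w)
        counts = np.zeros(N)
        reps = 10_000
        tag = np.arange(N, dtype=np.int8)
        ens.bases[:, 0] = tag % 4
        ens.lam = tag.astype(float)  # identify parents via lam
        for _ in range(reps):
            out = multinomial_resample(ens, rng)
            counts += np.bincount(out.lam.astype(int), minlength=N)
        _, pvalue = chisquare(counts, reps * N * w)
        assert pvalue > 0.001

    def test_unbiased_statistic(self):
        """Resampling preserves weighted means of particle statistics."""
        rng = np.random.default_rng(3)
        ens = uniform_ensemble(200)
        w = rng.dirichlet(np.ones(200))
        ens.log_weights = np.log(w)
        ens.lam = rng.uniform(0.5, 1.5, 200)
        target = float(w @ ens.lam)
        means = [
            multinomial_resample(ens, np.random.default_rng(s)).lam.mean()
            for s in range(400)
        ]
        assert np.mean(means) == pytest.approx(target, abs=3 * np.std(means) / 20)


def two_window_params(L=12, **kw):
    base = dict(
        d_mean=0.01,
        sigma_mean=0.02,
        alpha=0.1,
        K=np.eye(4),
        Sigma=0.2**2 * np.eye(4),
    )
    base.update(kw)
    cp = CycleParams(**base)
    n_win = -(-L // 5)
    return ParameterSet(PhasingParams(1e-6, 0.003), (cp,) * n_win, 5, L)


class TestInitEnsemble:
    def test_weights_normalized_and_deterministic(self):
        params = two_window_params()
        y1 = np.array([1.0, 0.1, 0.0, 0.0])
        a = init_ensemble(y1, params, 200, np.random.default_rng(5))
        b = init_ensemble(y1, params, 200, np.random.default_rng(5))
        assert np.exp(a.log_weights).sum() == pytest.approx(1.0, abs=1e-10)
        np.testing.assert_array_equal(a.bases, b.bases)
        np.testing.assert_array_equal(a.log_weights, b.log_weights)

    def test_high_weight_particles_have_correct_first_base(self):
        params = two_window_params(Sigma=0.05**2 * np.eye(4))
        y1 = np.array([0.0, 1.0, 0.0, 0.0])  # clean C signal
        ens = init_ensemble(y1, params, 300, np.random.default_rng(1))
        best = np.argsort(ens.log_weights)[-30:]
        assert np.all(ens.bases[best, ens.l] == 1)

    def test_minimum_particles(self):
        params = two_window_params()
        with pytest.raises(ValueError):
            init_ensemble(np.ones(4), params, 1, np.random.default_rng(0))


class TestAdvanceEnsemble:
    def test_flat_likelihood_keeps_weights_uniform(self):
        params = two_window_params(Sigma=1e6 * np.eye(4))
        y1 = np.array([1.0, 0, 0, 0])
        ens = init_ensemble(y1, params, 100, np.random.default_rng(2))
        out = advance_ensemble(ens, np.array([0.5, 0.5, 0, 0]), params, np.random.default_rng(3))
        assert out.t == ens.t + 1
        # the data carry no information; only the mild ||x||^2-dependent
        # normalizer perturbs the weights, so K_eff stays near N_p
        assert out.K_eff > 0.95 * out.N_p

    def test_single_particle_weight_stays_one(self):
        params = two_window_params()
        ens = Ensemble(
            bases=np.array([[0, 1, 2]], dtype=np.int8),
            lam=np.array([1.0]),
            log_weights=np.array([0.0]),
            t=3,
            l=1,
            r=1,
        )
        out = advance_ensemble(ens, np.array([0.1, 0.9, 0.1, 0.0]), params, np.random.default_rng(0))
        assert np.exp(out.log_weights)[0] == pytest.approx(1.0)

    def test_cannot_advance_past_read_end(self):
        params = two_window_params(L=12)
        ens = uniform_ensemble(10, t=12)
        with pytest.raises(ValueError):
            advance_ensemble(ens, np.zeros(4), params, np.random.default_rng(0))


class TestPosteriorBaseDistribution:
    def test_unanimous_center(self):
        ens = uniform_ensemble(40)
        ens.bases[:, 1] = 1  # all C
        np.testing.assert_allclose(posterior_base_distribution(ens), [0, 1, 0, 0])

    def test_two_equal_particles(self):
        ens = Ensemble(
            bases=np.array([[0, 0, 0], [0, 2, 0]], dtype=np.int8),
            lam=np.ones(2),
            log_weights=np.log([0.5, 0.5]),
            t=1,
            l=1,
            r=1,
        )
        np.testing.assert_allclose(
            posterior_base_distribution(ens), [0.5, 0, 0.5, 0]
        )
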