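"""Read-level calling: filters vs exact references, baselines, determinism."""

import numpy as np

import sbscall as sc
from sbscall.caller import enumerate_filtered_posteriors, exact_forward_oracle
from tests.conftest import det_lambda_params, det_lambda_path


class TestExactReferences:
    def test_enumeration_matches_forward_oracle(self):
        """Joint enumeration over all 4^5 templates agrees with the
        forward recursion on the 64-state window chain to 1e-10."""
        params = det_lambda_params(L=5, w=5)
        tile = sc.simulate_tile(3, 5, params, seed=12)
        lam_path = det_lambda_path(params)
        for rd in tile.reads:
            enum = enumerate_filtered_posteriors(rd, params, lam_path)
            fwd = exact_forward_oracle(rd, params, lam_path)
            np.testing.assert_allclose(enum, fwd, atol=1e-10)

    def test_flat_likelihood_gives_uniform_posteriors(self):
        params = det_lambda_params(L=4, w=5)
        cp = params.per_window[0]
        from sbscall.params import CycleParams, ParameterSet

        flat = ParameterSet(
            params.phasing,
            (
                CycleParams(
                    d_mean=cp.d_mean,
                    sigma_mean=0.0,
                    alpha=cp.alpha,
                    K=cp.K,
                    Sigma=1e8 * np.eye(4),
                ),
            ),
            5,
            4,
        )
        rd = sc.simulate_tile(1, 4, params, seed=1).reads[0]
        post = exact_forward_oracle(rd, flat, det_lambda_path(params))
        np.testing.assert_allclose(post, 0.25, atol=1e-9)


class TestPlainFilter:
    def test_two_cycle_posterior_matches_enumeration(self):
        """SISR with N_p = 20,000 is within 0.02 total variation of the
        brute-force posterior on a two-cycle instance."""
        params = det_lambda_params(L=2, w=2)
        tile = sc.simulate_tile(4, 2, params, seed=3)
        lam_path = det_lambda_path(params)
        for rd in tile.reads:
            enum = enumerate_filtered_posteriors(rd, params, lam_path)
            res = sc.call_read(rd, params, N_p=20_000, seed=5, init_lambda_sd=0.0)
            tv = 0.5 * np.abs(enum - res.posteriors).sum(axis=1).max()
            assert tv < 0.02

    def test_posterior_converges_with_particle_count(self):
        """Conditional on a fixed lambda path the Monte Carlo posterior
        approaches the exact filter as N_p grows."""
        params = det_lambda_params(L=10, w=5)
        tile = sc.simulate_tile(10, 10, params, seed=21)
        lam_path = det_lambda_path(params)
        oracles = [exact_forward_oracle(rd, params, lam_path) for rd in tile.reads]
        maes = []
        for N_p in (500, 5_000, 20_000):
            res = sc.call_tile(tile.reads, params, N_p=N_p, seed=9, init_lambda_sd=0.0)
            maes.append(
                np.mean(
                    [np.abs(o - r.posteriors).mean() for o, r in zip(oracles, res)]
                )
            )
        assert maes[0] > maes[1] > maes[2]
        assert maes[2] < 0.02

    def test_beats_naive_caller_on_noisy_preset(self):
        """Modeling phasing/decay/residual beats per-cycle argmax calling."""
        params = sc.default_preset(L=76)
        tile = sc.simulate_tile(120, 76, params, seed=17)
        res = sc.call_tile(tile.reads, params, N_p=400, seed=23)
        pf_err, _ = sc.error_rate([r.calls for r in res], tile.truths)
        naive_err, _ = sc.error_rate(
            [sc.naive_call(rd, params) for rd in tile.reads], tile.truths
        )
        assert pf_err < naive_err

    def test_deterministic_given_seed(self, default_params, default_tile):
        a = sc.call_read(default_tile.reads[0], default_params, N_p=100, seed=4)
        b = sc.call_read(default_tile.reads[0], default_params, N_p=100, seed=4)
        assert a.calls == b.calls
        np.testing.assert_array_equal(a.posteriors, b.posteriors)
        np.testing.assert_array_equal(a.phred, b.phred)

    def test_call_result_invariants(self, default_calls):
        for res in default_calls[:10]:
            np.testing.assert_allclose(res.posteriors.sum(axis=1), 1.0, atol=1e-10)
            idx = res.posteriors.argmax(axis=1)
            assert res.calls == "".join("ACGT"[i] for i in idx)
            assert np.all((res.phred >= 0) & (res.phred <= 60))


class TestRBFilter:
    def test_exact_when_lambda_deterministic(self):
        """With sigma = 0 the RB filter is exact for any particle count."""
        params = det_lambda_params(L=15, w=5)
        tile = sc.simulate_tile(5, 15, params, seed=33)
        lam_path = det_lambda_path(params)
        for N_p in (2, 16):
            for rd in tile.reads:
                oracle = exact_forward_oracle(rd, params, lam_path)
                res = sc.rb_call_read(rd, params, N_p=N_p, seed=2, init_lambda_sd=0.0)
                np.testing.assert_allclose(res.posteriors, oracle, atol=1e-8)

    def test_agrees_with_plain_filter(self):
        """Both filters target the same posterior; on a small noisy
        instance their per-base posteriors agree within Monte Carlo error."""
        params = sc.default_preset(L=8)
        tile = sc.simulate_tile(6, 8, params, seed=2)
        plain = sc.call_tile(tile.reads, params, N_p=20_000, seed=5)
        rb = sc.rb_call_tile(tile.reads, params, N_p=4_000, seed=6)
        mae = np.mean(
            [np.abs(p.posteriors - r.posteriors).mean() for p, r in zip(plain, rb)]
        )
        assert mae < 0.02

    def test_noiseless_error_zero(self, noiseless_params, noiseless_tile):
        res = sc.rb_call_tile(
            noiseless_tile.reads, noiseless_params, N_p=40, seed=3, init_lambda_sd=0.0
        )
        rate, _ = sc.error_rate([r.calls for r in res], noiseless_tile.truths)
        assert rate == 0.0
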