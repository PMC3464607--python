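"""Signal-model kernels: windowed mean, residual correction, densities."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.stats import multivariate_normal, norm

import sbscall as sc
from sbscall.errors import DegenerateTransitionError
from sbscall.params import CycleParams
from sbscall.signal import (
    ABSENT,
    WindowState,
    advance_window_state,
    add_residual,
    density_decay_logdensity,
    observation_logdensity,
    remove_residual,
    windowed_signal_mean,
)


def make_cp(**kw):
    base = dict(
        d_mean=0.0, sigma_mean=0.0, alpha=0.0, K=np.eye(4), Sigma=np.eye(4)
    )
    base.update(kw)
    return CycleParams(**base)


class TestWindowedSignalMean:
    def test_single_column(self):
        st_ = WindowState(bases=np.array([0]), t=1, lam=1.0, l=0, r=0)
        np.testing.assert_allclose(
            windowed_signal_mean(st_, np.array([1.0])), [1, 0, 0, 0]
        )

    def test_weighted_sum(self):
        st_ = WindowState(bases=np.array([0, 1, 2]), t=2, lam=0.5, l=1, r=1)
        x = windowed_signal_mean(st_, np.array([0.1, 0.8, 0.1]))
        np.testing.assert_allclose(x, 0.5 * np.array([0.1, 0.8, 0.1, 0.0]))

    def test_absent_columns_contribute_nothing(self):
        st_ = WindowState(bases=np.array([ABSENT, 1, 2]), t=1, lam=1.0, l=1, r=1)
        x = windowed_signal_mean(st_, np.array([0.3, 0.6, 0.1]))
        np.testing.assert_allclose(x, [0.0, 0.6, 0.1, 0.0])

    @given(st.data())
    def test_matches_dense_matvec(self, data):
        W = data.draw(st.integers(1, 5))
        bases = np.array(
            data.draw(st.lists(st.integers(0, 3), min_size=W, max_size=W)),
            dtype=np.int8,
        )
        h = np.array(
            data.draw(
                st.lists(st.floats(0, 1), min_size=W, max_size=W)
            )
        )
        lam = data.draw(st.floats(0, 3))
        state = WindowState(bases=bases, t=1, lam=lam, l=0, r=W - 1)
        np.testing.assert_allclose(
            windowed_signal_mean(state, h), lam * (state.S_w @ h), atol=1e-12
        )

    def test_negative_lambda_rejected(self):
        with pytest.raises(ValueError):
            WindowState(bases=np.array([0]), t=1, lam=-0.5, l=0, r=0)


class TestResidualCorrection:
    def test_identity_when_alpha_zero(self, noiseless_params):
        y = np.random.default_rng(0).normal(size=(30, 4))
        np.testing.assert_array_equal(remove_residual(y, noiseless_params), y)

    def test_direct_arithmetic(self):
        params = sc.ParameterSet(
            sc.PhasingParams(0, 0),
            (make_cp(alpha=0.5),),
            2,
            2,
        )
        y = np.array([[2.0, 0, 0, 0], [1.0, 1.0, 0, 0]])
        out = remove_residual(y, params)
        np.testing.assert_allclose(out[0], y[0])
        np.testing.assert_allclose(out[1], [0.0, 1.0, 0.0, 0.0])

    def test_round_trip_exact(self):
        params = sc.ParameterSet(
            sc.PhasingParams(0, 0),
            (make_cp(alpha=0.37, d_mean=0.02),) * 2,
            5,
            10,
        )
        y = np.random.default_rng(3).normal(size=(10, 4))
        np.testing.assert_allclose(
            add_residual(remove_residual(y, params), params), y, atol=1e-12
        )


class TestObservationDensity:
    def test_standard_normal_at_mean(self):
        state = WindowState(bases=np.array([0]), t=1, lam=1.0, l=0, r=0)
        ld = observation_logdensity(
            np.array([1.0, 0, 0, 0]), state, np.array([1.0]), make_cp()
        )
        assert ld == pytest.approx(-2.0 * math.log(2 * math.pi))

    def test_matches_scipy_quadratic_form(self):
        rng = np.random.default_rng(11)
        A = rng.normal(size=(4, 4))
        cp = make_cp(K=rng.normal(size=(4, 4)), Sigma=A @ A.T + 0.5 * np.eye(4))
        state = WindowState(
            bases=np.array([2, 0, 3]), t=2, lam=0.8, l=1, r=1
        )
        h = np.array([0.1, 0.7, 0.15])
        y = rng.normal(size=4)
        x = windowed_signal_mean(state, h)
        expected = multivariate_normal.logpdf(
            y, mean=cp.K @ x, cov=float(x @ x) * cp.Sigma
        )
        assert observation_logdensity(y, state, h, cp) == pytest.approx(expected)

    def test_determinant_scaling_with_lambda(self):
        """Doubling lambda doubles the mean and quadruples the covariance
        scale; at the (new) mean the density drops by 4 log 2."""
        cp = make_cp()
        h = np.array([1.0])
        s1 = WindowState(bases=np.array([1]), t=1, lam=1.0, l=0, r=0)
        s2 = WindowState(bases=np.array([1]), t=1, lam=2.0, l=0, r=0)
        at_mean_1 = observation_logdensity(np.array([0, 1.0, 0, 0]), s1, h, cp)
        at_mean_2 = observation_logdensity(np.array([0, 2.0, 0, 0]), s2, h, cp)
        assert at_mean_1 - at_mean_2 == pytest.approx(4 * math.log(2))

    def test_non_positive_definite_sigma_rejected(self):
        cp = make_cp(Sigma=np.zeros((4, 4)))
        from sbscall.signal import GaussianObservation

        with pytest.raises(ValueError):
            GaussianObservation(cp)


class TestDensityDecay:
    def test_standard_normal_value(self):
        cp = make_cp(sigma_mean=1.0)
        assert density_decay_logdensity(1.0, 1.0, cp) == pytest.approx(
            -0.5 * math.log(2 * math.pi)
        )

    def test_scaling_of_one_minus_d(self):
        """Halving (1-d) halves mean and s.d.; density at mean rises log 2."""
        cp_a = make_cp(d_mean=0.0, sigma_mean=0.3)
        cp_b = make_cp(d_mean=0.5, sigma_mean=0.3)
        at_mean_a = density_decay_logdensity(1.0, 1.0, cp_a)
        at_mean_b = density_decay_logdensity(0.5, 1.0, cp_b)
        assert at_mean_b - at_mean_a == pytest.approx(math.log(2))

    @given(
        lam_prev=st.floats(0.1, 3),
        lam_t=st.floats(-1, 3),
        d=st.floats(0, 0.9),
        sg=st.floats(0.01, 1),
    )
    def test_matches_scalar_gaussian(self, lam_prev, lam_t, d, sg):
        cp = make_cp(d_mean=d, sigma_mean=sg)
        mean = (1 - d) * lam_prev
        sd = (1 - d) * lam_prev * sg
        assert density_decay_logdensity(lam_t, lam_prev, cp) == pytest.approx(
            norm.logpdf(lam_t, mean, sd), rel=1e-9
        )

    @pytest.mark.parametrize("d,lam_prev,sg", [(1.0, 1.0, 0.5), (0.0, 0.0, 0.5), (0.0, 1.0, 0.0)])
    def test_degenerate_transition_rejected(self, d, lam_prev, sg):
        cp = make_cp(d_mean=d, sigma_mean=sg)
        with pytest.raises(DegenerateTransitionError):
            density_decay_logdensity(1.0, lam_prev, cp)


class TestAdvanceWindowState:
    def test_overlap_carried_deterministically(self):
        cp = make_cp(sigma_mean=0.1)
        for seed in range(20):
            rng = np.random.default_rng(seed)
            s0 = WindowState(bases=np.array([1, 2, 3]), t=5, lam=1.0, l=1, r=1)
            s1 = advance_window_state(s0, rng, cp, L=20)
            np.testing.assert_array_equal(s1.bases[:2], s0.bases[1:])
            assert s1.t == 6

    def test_new_column_uniform(self):
        cp = make_cp()
        rng = np.random.default_rng(1)
        s0 = WindowState(bases=np.array([0, 0, 0]), t=3, lam=1.0, l=1, r=1)
        counts = np.zeros(4)
        n = 10_000
        for _ in range(n):
            counts[advance_window_state(s0, rng, cp, L=100).bases[-1]] += 1
        # each frequency within 4 binomial sigmas of 1/4
        sd = math.sqrt(0.25 * 0.75 / n)
        assert np.all(np.abs(counts / n - 0.25) < 4 * sd)

    def test_noiseless_decay_exact(self):
        cp = make_cp(d_mean=0.1, sigma_mean=0.0)
        s0 = WindowState(bases=np.array([0, 1, 2]), t=2, lam=0.8, l=1, r=1)
        s1 = advance_window_state(s0, np.random.default_rng(0), cp, L=10)
        assert s1.lam == pytest.approx(0.9 * 0.8)

    def test_absent_beyond_template_end(self):
        cp = make_cp()
        s0 = WindowState(bases=np.array([0, 1, 2]), t=9, lam=1.0, l=1, r=1)
        s1 = advance_window_state(s0, np.random.default_rng(0), cp, L=10)
        assert s1.bases[-1] == ABSENT

    def test_cannot_advance_past_end(self):
        cp = make_cp()
        s0 = WindowState(bases=np.array([0, 1, ABSENT]), t=10, lam=1.0, l=1, r=1)
        with pytest.raises(ValueError):
            advance_window_state(s0, np.random.default_rng(0), cp, L=10)
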