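"""Signal-model kernels: windowed mean, residual correction, densities.

The hidden state of the base-calling HMM at cycle t is the pair
(S_t^w, lambda_t): the 4 x (l+r+1) window of template columns centred at
position t, and the per-cluster density.  The windowed signal mean is

    x_t^w = lambda_t * sum_{i=-l..r} s_{t+i} H[t+i, t],

the observation density is a 4-d Gaussian

    y''_t | S_t^w, lambda_t  ~  N(K_t x_t^w, ||x_t^w||_2^2 Sigma_t),

and the density transition is the scalar Gaussian

    lambda_t | lambda_{t-1} ~ N((1-d_t) lambda_{t-1},
                                (1-d_t)^2 lambda_{t-1}^2 sigma_t^2).

When ||x_t^w||^2 falls below ``COV_FLOOR`` the covariance scale is clamped
there so the observation density stays proper for lambda near 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from scipy.linalg import cho_solve, cholesky

from .errors import DegenerateTransitionError
from .params import CycleParams, ParameterSet

__all__ = [
    "COV_FLOOR",
    "WindowState",
    "windowed_signal_mean",
    "remove_residual",
    "add_residual",
    "observation_logdensity",
    "density_decay_logdensity",
    "advance_window_state",
    "GaussianObservation",
]

#: Floor on the squared signal norm scaling the observation covariance.
COV_FLOOR = 1e-8

_LOG_2PI = math.log(2.0 * math.pi)

#: Sentinel for a window slot whose template position falls outside 1..L.
ABSENT = -1


@dataclass
class WindowState:
    """Hidden state (S_t^w, lambda_t) at a cycle.

    ``bases`` holds the l+r+1 window columns as channel indices 0..3, with
    ``ABSENT`` (-1) marking columns whose template position lies outside
    1..L (they contribute zero signal).  Slot k corresponds to template
    position t - l + k.
    """

    bases: np.ndarray
    t: int
    lam: float
    l: int
    r: int

    def __post_init__(self) -> None:
        bases = np.asarray(self.bases, dtype=np.int8)
        if bases.shape != (self.l + self.r + 1,):
            raise ValueError("window width must equal l + r + 1")
        if bases.max(initial=-1) > 3 or bases.min(initial=0) < ABSENT:
            raise ValueError("window entries must be 0..3 or ABSENT")
        if self.lam < 0:
            raise ValueError("lambda must be non-negative")
        self.bases = bases

    @property
    def S_w(self) -> np.ndarray:
        """Dense 4 x (l+r+1) indicator matrix (absent columns all-zero)."""
        W = self.l + self.r + 1
        S = np.zeros((4, W))
        for k, b in enumerate(self.bases):
            if b != ABSENT:
                S[b, k] = 1.0
        return S


def windowed_signal_mean(state: WindowState, h_w: np.ndarray) -> np.ndarray:
    """Windowed signal mean x_t^w = lambda_t * sum_k s_k * h_w[k].

    Absent window columns are skipped (their profile slots carry no mass).
    """
    h_w = np.asarray(h_w, dtype=float)
    if h_w.shape != state.bases.shape:
        raise ValueError("profile window and state window sizes differ")
    if state.lam < 0:
        raise ValueError("lambda must be non-negative")
    x = np.zeros(4)
    for k, b in enumerate(state.bases):
        if b != ABSENT:
            x[b] += h_w[k]
    return state.lam * x


def remove_residual(y: np.ndarray, params: ParameterSet) -> np.ndarray:
    """Residual correction y''_t = y_t - alpha_t (1 - d_t) y_{t-1}.

    Row 1 is unchanged (y_0 = 0).  Uses the central decay value d_mean of
    each cycle's window.  Exactly inverted by :func:`add_residual`.
    """
    y = np.asarray(y, dtype=float)
    out = y.copy()
    for t in range(2, y.shape[0] + 1):
        cp = params.cycle(t)
        out[t - 1] = y[t - 1] - cp.alpha * (1.0 - cp.d) * y[t - 2]
    return out


def add_residual(y_corr: np.ndarray, params: ParameterSet) -> np.ndarray:
    """Inverse of :func:`remove_residual` (forward reconstruction)."""
    y_corr = np.asarray(y_corr, dtype=float)
    out = y_corr.copy()
    for t in range(2, y_corr.shape[0] + 1):
        cp = params.cycle(t)
        out[t - 1] = y_corr[t - 1] + cp.alpha * (1.0 - cp.d) * out[t - 2]
    return out


class GaussianObservation:
    """Precomputed pieces of the observation density for one CycleParams.

    Evaluates log N(y; K x, c Sigma) with c = max(||x||^2, COV_FLOOR) for
    batches of signal means x, sharing one Cholesky factor of Sigma.
    """

    def __init__(self, cp: CycleParams):
        Sigma = cp.Sigma
        try:
            self._chol = cholesky(Sigma, lower=True)
        except np.linalg.LinAlgError as exc:
            raise ValueError("Sigma must be positive definite") from exc
        if not np.all(np.diag(self._chol) > 0):
            raise ValueError("Sigma must be positive definite")
        self._logdet = 2.0 * float(np.log(np.diag(self._chol)).sum())
        self._cho = (self._chol, True)
        self.K = cp.K
        self.Sigma_inv = cho_solve(self._cho, np.eye(4))

    @property
    def logdet(self) -> float:
        """log det Sigma."""
        return self._logdet

    def loglik(self, y: np.ndarray, x: np.ndarray) -> np.ndarray:
        """Log-density of observation(s) y at signal mean(s) x.

        ``x`` has shape (..., 4); ``y`` is a 4-vector (broadcast) or
        matches x's shape.  Returns shape (...,).
        """
        x = np.asarray(x, dtype=float)
        c = np.maximum((x * x).sum(axis=-1), COV_FLOOR)
        mu = x @ self.K.T
        diff = np.asarray(y, dtype=float) - mu
        # Sigma^{-1} via the shared Cholesky factor
        sol = cho_solve(self._cho, diff.reshape(-1, 4).T).T.reshape(diff.shape)
        quad = (diff * sol).sum(axis=-1) / c
        return -0.5 * (4.0 * _LOG_2PI + 4.0 * np.log(c) + self._logdet + quad)


def observation_logdensity(
    y_corr_t: np.ndarray,
    state: WindowState,
    h_w: np.ndarray,
    cp: CycleParams,
) -> float:
    """Log observation density g(y''_t | S_t^w, lambda_t)."""
    x = windowed_signal_mean(state, h_w)
    return float(GaussianObservation(cp).loglik(np.asarray(y_corr_t, float), x))


def density_decay_logdensity(
    lambda_t: float, lambda_prev: float, cp: CycleParams
) -> float:
    """Log-density of the lambda transition N((1-d)l', (1-d)^2 l'^2 s^2).

    Uses the central values d = d_mean, sigma = sigma_mean.  A zero
    transition variance (d = 1, lambda_prev = 0 or sigma = 0) is rejected.
    """
    one_minus_d = 1.0 - cp.d
    sd = abs(one_minus_d * lambda_prev) * cp.sigma
    if sd <= 0.0:
        raise DegenerateTransitionError(
            "lambda transition has zero variance "
            f"(d={cp.d}, sigma={cp.sigma}, lambda_prev={lambda_prev})"
        )
    mean = one_minus_d * lambda_prev
    z = (lambda_t - mean) / sd
    return -0.5 * (_LOG_2PI + z * z) - math.log(sd)


def advance_window_state(
    state: WindowState,
    rng: np.random.Generator,
    cp: CycleParams,
    L: int,
) -> WindowState:
    """Propagate the hidden state one cycle via the HMM transition.

    The window columns shift left by one (the overlapping columns are
    carried over deterministically); the new rightmost column is drawn
    uniformly from the four bases, or marked absent when its template
    position t+1+r exceeds L.  lambda advances by the decay transition
    with per-cycle d and sigma drawn from their uniform hyper-intervals.
    """
    t = state.t
    if t >= L:
        raise ValueError(f"cannot advance past the final cycle (t={t}, L={L})")
    bases = np.empty_like(state.bases)
    bases[:-1] = state.bases[1:]
    new_pos = t + 1 + state.r
    bases[-1] = rng.integers(0, 4) if new_pos <= L else ABSENT
    d_lo, d_hi = cp.d_interval()
    s_lo, s_hi = cp.sigma_interval()
    d = rng.uniform(d_lo, d_hi) if d_hi > d_lo else d_lo
    sigma = rng.uniform(s_lo, s_hi) if s_hi > s_lo else s_lo
    eps = sigma * rng.standard_normal()
    lam = max((1.0 - d) * state.lam * (1.0 + eps), 0.0)
    return WindowState(bases=bases, t=t + 1, lam=lam, l=state.l, r=state.r)
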