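"""Domain types and parameter containers for the sequencing signal model.

The model describes per-cluster, per-cycle four-channel fluorescence
intensities produced by a sequencing-by-synthesis instrument.  A length-L
template is a 4xL matrix ``S`` of unit indicator columns (component 1 = A,
2 = C, 3 = G, 4 = T).  The signal a cluster emits at cycle ``t`` is governed
by

* phasing/pre-phasing probabilities ``p``/``q`` (a strand fails to extend,
  or extends by more than one base, in a cycle),
* a per-cluster density ``lambda_t`` that decays stochastically with
  per-cycle decay ``d_t`` and innovation s.d. ``sigma_t``,
* a 4x4 crosstalk matrix ``K_t`` mixing the dye channels,
* a residual coefficient ``alpha_t`` carrying a fraction of the previous
  cycle's measured intensity into the current one, and
* a 4x4 observation-noise covariance ``Sigma_t``.

``d_t`` and ``sigma_t`` are treated as uniformly distributed hidden
quantities; only their means and variances are carried as parameters.
Cycle-dependent parameters are held constant within short windows of ``w``
cycles; :class:`ParameterSet` stores one :class:`CycleParams` per window and
resolves per-cycle lookups.  Cycle indices are 1-based at every interface.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "BASES",
    "base_vector",
    "sequence_to_indices",
    "indices_to_sequence",
    "TemplateSequence",
    "PhasingParams",
    "CycleParams",
    "ParameterSet",
    "IntensityRead",
    "uniform_interval",
]

#: Channel/base order used everywhere: index 0=A, 1=C, 2=G, 3=T.
BASES = "ACGT"

_BASE_INDEX = {b: i for i, b in enumerate(BASES)}


def base_vector(base: int | str) -> np.ndarray:
    """Unit indicator 4-vector e_A, e_C, e_G or e_T for a base.

    Accepts a base letter or its 0-based channel index.
    """
    if isinstance(base, str):
        base = _BASE_INDEX[base.upper()]
    if not 0 <= base < 4:
        raise ValueError(f"base index out of range: {base}")
    e = np.zeros(4)
    e[base] = 1.0
    return e


def sequence_to_indices(seq: str) -> np.ndarray:
    """Base string -> int array of channel indices (A=0, C=1, G=2, T=3)."""
    try:
        return np.array([_BASE_INDEX[b] for b in seq.upper()], dtype=np.int8)
    except KeyError as exc:  # pragma: no cover - message only
        raise ValueError(f"invalid base {exc} in sequence") from exc


def indices_to_sequence(idx: np.ndarray) -> str:
    return "".join(BASES[i] for i in np.asarray(idx, dtype=int))


@dataclass(frozen=True)
class TemplateSequence:
    """A template DNA sequence of length L, stored as channel indices.

    The dense 4xL indicator matrix ``S`` is available as a property.
    """

    indices: np.ndarray

    def __post_init__(self) -> None:
        idx = np.asarray(self.indices, dtype=np.int8)
        if idx.ndim != 1 or idx.size < 1:
            raise ValueError("template must be a non-empty 1-d index array")
        if idx.min() < 0 or idx.max() > 3:
            raise ValueError("template indices must lie in 0..3")
        object.__setattr__(self, "indices", idx)

    @classmethod
    def from_string(cls, seq: str) -> "TemplateSequence":
        return cls(sequence_to_indices(seq))

    @property
    def L(self) -> int:
        return int(self.indices.size)

    @property
    def S(self) -> np.ndarray:
        """Dense 4xL indicator matrix (each column a unit base vector)."""
        S = np.zeros((4, self.L))
        S[self.indices, np.arange(self.L)] = 1.0
        return S

    def __str__(self) -> str:
        return indices_to_sequence(self.indices)


@dataclass(frozen=True)
class PhasingParams:
    """Phasing probability ``p`` and pre-phasing probability ``q``."""

    p: float
    q: float

    def __post_init__(self) -> None:
        if self.p < 0 or self.q < 0:
            raise ValueError("phasing probabilities must be non-negative")
        if self.p + self.q > 1:
            raise ValueError(f"p + q must not exceed 1 (got {self.p + self.q})")


def uniform_interval(
    mean: float,
    var: float,
    lo: float = -math.inf,
    hi: float = math.inf,
    name: str = "parameter",
) -> tuple[float, float]:
    """Endpoints of the uniform distribution with the given moments.

    A Uniform(a, b) with mean m and variance v has half-width sqrt(3 v);
    this is the unique uniform matching the two moments.  Endpoints falling
    outside [lo, hi] are clipped (with a warning, since clipping perturbs
    the moments).
    """
    if var < 0:
        raise ValueError("variance must be non-negative")
    h = math.sqrt(3.0 * var)
    a, b = mean - h, mean + h
    if a < lo or b > hi:
        warnings.warn(
            f"uniform interval for {name} [{a:.3g}, {b:.3g}] clipped to "
            f"[{max(a, lo):.3g}, {min(b, hi):.3g}]",
            stacklevel=2,
        )
        a, b = max(a, lo), min(b, hi)
    return a, b


@dataclass(frozen=True)
class CycleParams:
    """Per-window cycle parameters (decay, residual, crosstalk, noise).

    ``d_mean``/``d_var`` and ``sigma_mean``/``sigma_var`` are the moments of
    the uniform hyper-distributions of the per-cycle decay d_t and the
    lambda-innovation s.d. sigma_t.  ``d`` and ``sigma`` expose the central
    (mean) values for use where a point value is required (e.g. residual
    correction).
    """

    d_mean: float
    sigma_mean: float
    alpha: float
    K: np.ndarray
    Sigma: np.ndarray
    d_var: float = 0.0
    sigma_var: float = 0.0

    def __post_init__(self) -> None:
        K = np.asarray(self.K, dtype=float)
        Sigma = np.asarray(self.Sigma, dtype=float)
        if K.shape != (4, 4) or Sigma.shape != (4, 4):
            raise ValueError("K and Sigma must be 4x4")
        if not np.allclose(Sigma, Sigma.T, atol=1e-10):
            raise ValueError("Sigma must be symmetric")
        if np.linalg.eigvalsh(Sigma).min() < 0:
            raise ValueError("Sigma must be positive semi-definite")
        if not 0.0 <= self.d_mean <= 1.0:
            raise ValueError("d must lie in [0, 1]")
        if not 0.0 <= self.alpha < 1.0:
            raise ValueError("alpha must lie in [0, 1)")
        if self.sigma_mean < 0 or self.d_var < 0 or self.sigma_var < 0:
            raise ValueError("sigma_mean and variances must be non-negative")
        object.__setattr__(self, "K", K)
        object.__setattr__(self, "Sigma", 0.5 * (Sigma + Sigma.T))

    @property
    def d(self) -> float:
        return self.d_mean

    @property
    def sigma(self) -> float:
        return self.sigma_mean

    def d_interval(self) -> tuple[float, float]:
        """Uniform hyper-interval of d_t, clipped to [0, 1]."""
        return uniform_interval(self.d_mean, self.d_var, 0.0, 1.0, name="d")

    def sigma_interval(self) -> tuple[float, float]:
        """Uniform hyper-interval of sigma_t, clipped to [0, inf)."""
        return uniform_interval(
            self.sigma_mean, self.sigma_var, 0.0, math.inf, name="sigma"
        )


@dataclass(frozen=True)
class ParameterSet:
    """Full parameter collection: phasing plus one CycleParams per window.

    Window m (1-based) covers cycles (m-1)*w + 1 .. m*w, except the last
    window which absorbs any remainder; there are ceil(L / w) windows.
    """

    phasing: PhasingParams
    per_window: tuple[CycleParams, ...]
    window_length: int
    L: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "per_window", tuple(self.per_window))
        if self.window_length < 1 or self.L < 1:
            raise ValueError("window_length and L must be positive")
        expected = self.n_windows
        if len(self.per_window) != expected:
            raise ValueError(
                f"need ceil(L/w) = {expected} windows, got {len(self.per_window)}"
            )

    @property
    def n_windows(self) -> int:
        return -(-self.L // self.window_length)

    def window_of(self, t: int) -> int:
        """0-based window index of 1-based cycle t (last window absorbs)."""
        if not 1 <= t <= self.L:
            raise ValueError(f"cycle {t} outside 1..{self.L}")
        return min((t - 1) // self.window_length, self.n_windows - 1)

    def cycle(self, t: int) -> CycleParams:
        """CycleParams governing 1-based cycle t."""
        return self.per_window[self.window_of(t)]

    def window_cycles(self, m: int) -> range:
        """1-based cycles covered by 0-based window m."""
        if not 0 <= m < self.n_windows:
            raise ValueError(f"window {m} outside 0..{self.n_windows - 1}")
        start = m * self.window_length + 1
        stop = self.L if m == self.n_windows - 1 else (m + 1) * self.window_length
        return range(start, stop + 1)

    def replace_window(self, m: int, cp: CycleParams) -> "ParameterSet":
        pw = list(self.per_window)
        pw[m] = cp
        return ParameterSet(self.phasing, tuple(pw), self.window_length, self.L)


@dataclass
class IntensityRead:
    """One cluster's L x 4 observed channel intensities.

    ``corrected(params)`` returns the residual-corrected intensities
    y''_t = y_t - alpha_t (1 - d_t) y_{t-1} (with y_0 = 0) used as the
    observations of the hidden Markov model.
    """

    y: np.ndarray
    cluster_id: str = "read"
    _corrected_cache: tuple | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        y = np.asarray(self.y, dtype=float)
        if y.ndim != 2 or y.shape[1] != 4 or y.shape[0] < 1:
            raise ValueError("intensities must be an L x 4 array, L >= 1")
        self.y = y

    @property
    def L(self) -> int:
        return int(self.y.shape[0])

    def corrected(self, params: ParameterSet) -> np.ndarray:
        """Residual-corrected intensities y'' (cached per parameter set)."""
        from .signal import remove_residual  # local import avoids a cycle

        if self._corrected_cache is None or self._corrected_cache[0] is not params:
            self._corrected_cache = (params, remove_residual(self.y, params))
        return self._corrected_cache[1]
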