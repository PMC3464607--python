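"""Phasing/pre-phasing transition matrix and strand-length profile.

In each chemistry cycle a strand either fails to extend (probability p,
"phasing"), extends by exactly one base (probability 1 - p - q), or extends
by two ("pre-phasing", probability q).  Tracking the strand-length state
i in {0, .., L} gives an (L+1) x (L+1) transition matrix P; its powers
yield the profile matrix H with

    H[i, j] = [P^j]_{1, i+1}   (1-based),

the probability that a synthesized strand has length i after j cycles.
Column t of H weights how much each template position contributes to the
cycle-t signal.  Because p and q are small, h_t is dominated by the l+r+1
entries around position t; :func:`window_profile` extracts that window.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import PhasingParams

__all__ = [
    "build_transition_matrix",
    "build_phasing_profile",
    "window_profile",
    "PhasingProfile",
]


def build_transition_matrix(phasing: PhasingParams, L: int) -> np.ndarray:
    """(L+1) x (L+1) strand-length transition matrix.

    Entry (i, j) (0-based state = strand length) is p for j = i, 1 - p - q
    for j = i + 1 and q for j = i + 2.  Near the boundary, transitions that
    would overshoot length L deposit their mass on state L, which is
    absorbing, so every row remains stochastic.
    """
    if L < 1:
        raise ValueError("L must be >= 1")
    p, q = phasing.p, phasing.q
    P = np.zeros((L + 1, L + 1))
    for i in range(L + 1):
        P[i, i] += p
        if i + 1 <= L:
            P[i, i + 1] += 1.0 - p - q
        else:
            P[i, i] += 1.0 - p - q
        if i + 2 <= L:
            P[i, i + 2] += q
        else:
            P[i, L] += q
    return P


@dataclass(frozen=True)
class PhasingProfile:
    """Transition matrix P, profile matrix H and window radii (l, r)."""

    P: np.ndarray
    H: np.ndarray
    l: int
    r: int

    def __post_init__(self) -> None:
        if self.l < 0 or self.r < 0:
            raise ValueError("window radii must be non-negative")
        if self.H.shape[0] != self.H.shape[1]:
            raise ValueError("H must be square")

    @property
    def L(self) -> int:
        return int(self.H.shape[0])

    @property
    def width(self) -> int:
        return self.l + self.r + 1

    def windowed_columns(self) -> tuple[np.ndarray, np.ndarray]:
        """Windowed profile values and validity masks for every cycle.

        Returns ``(hw, valid)``, each of shape (L, l+r+1); row t-1 holds
        the window for cycle t.  Slot k corresponds to template position
        t - l + k; out-of-range positions are invalid and carry value 0.
        """
        L, l, r = self.L, self.l, self.r
        W = self.width
        hw = np.zeros((L, W))
        valid = np.zeros((L, W), dtype=bool)
        for t in range(1, L + 1):
            v, m = window_profile(self, t)
            hw[t - 1] = v
            valid[t - 1] = m
        return hw, valid


def build_phasing_profile(
    P: np.ndarray, L: int, l: int = 1, r: int = 1
) -> PhasingProfile:
    """Profile matrix H from the transition matrix by repeated products.

    H[i-1, j-1] = [P^j]_{1, i+1} (1-based i, j in 1..L): the probability a
    strand has length i after j cycles, starting from length 0.
    """
    if P.shape != (L + 1, L + 1):
        raise ValueError(f"P must be (L+1) x (L+1) = {(L + 1, L + 1)}, got {P.shape}")
    H = np.empty((L, L))
    row = np.zeros(L + 1)
    row[0] = 1.0  # strand length 0 before any cycle
    for j in range(L):
        row = row @ P
        H[:, j] = row[1 : L + 1]
    return PhasingProfile(P=P, H=H, l=l, r=r)


def window_profile(profile: PhasingProfile, t: int) -> tuple[np.ndarray, np.ndarray]:
    """Windowed profile column h_t^w for 1-based cycle t.

    Returns ``(values, valid)`` of length l+r+1: slot k holds
    H[t-l+k, t] for template positions inside 1..L; positions outside the
    sequence are flagged invalid and contribute zero signal (edge windows
    simply have fewer terms).
    """
    L, l, r = profile.L, profile.l, profile.r
    if not 1 <= t <= L:
        raise ValueError(f"cycle {t} outside 1..{L}")
    W = profile.width
    values = np.zeros(W)
    valid = np.zeros(W, dtype=bool)
    for k in range(W):
        pos = t - l + k  # 1-based template position
        if 1 <= pos <= L:
            values[k] = profile.H[pos - 1, t - 1]
            valid[k] = True
    return values, valid
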