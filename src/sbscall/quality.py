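"""Phred quality scores, error rates and discrimination curves.

The filtered posterior gives the probability of a calling error directly:
P(called base wrong at cycle t) = 1 - p(s_t = called | y''_{1:t}), and the
phred score is Q = -10 log10 of that error probability, rounded and capped
at ``Q_MAX`` (a posterior of exactly 1 would give an infinite score; 60
corresponds to an error probability of 1e-6, beyond the resolution of the
particle approximation).

With simulated ground truth available, error rates are plain mismatch
fractions against the true templates; no reference alignment is involved.
The discrimination score D(eps) is the fraction of *all* called bases that
are both correct and have predicted error probability below eps.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Q_MAX",
    "phred_score",
    "phred_from_posteriors",
    "error_rate",
    "predicted_error_probs",
    "discrimination_score",
    "discrimination_curve",
    "calibration_table",
    "DEFAULT_CALIBRATION_EDGES",
    "QualityReport",
]

#: Cap on phred scores (error probability floor 1e-6).
Q_MAX = 60


def phred_score(posterior_row: np.ndarray, call: int) -> int:
    """Phred score of a called base from its posterior row.

    ``call`` is the 0-based channel index of the called base.  The error
    probability is 1 minus the posterior mass on the call; the score is
    rounded to the nearest integer and clipped to [0, Q_MAX].
    """
    err = 1.0 - float(np.asarray(posterior_row, dtype=float)[call])
    if err <= 10.0 ** (-Q_MAX / 10.0):
        return Q_MAX
    return int(min(max(round(-10.0 * np.log10(err)), 0), Q_MAX))


def phred_from_posteriors(posteriors: np.ndarray, calls_idx: np.ndarray) -> np.ndarray:
    """Vectorized phred scores for an L x 4 posterior matrix."""
    post = np.asarray(posteriors, dtype=float)
    err = 1.0 - post[np.arange(post.shape[0]), np.asarray(calls_idx, dtype=int)]
    err = np.clip(err, 10.0 ** (-Q_MAX / 10.0), 1.0)
    return np.clip(np.rint(-10.0 * np.log10(err)), 0, Q_MAX).astype(int)


def _as_strings(seqs: Iterable) -> list[str]:
    return [str(s) for s in seqs]


def error_rate(
    calls: Sequence[str], truths: Sequence
) -> tuple[float, np.ndarray]:
    """Overall and per-cycle mismatch fractions against known truths."""
    calls = _as_strings(calls)
    truths = _as_strings(truths)
    if len(calls) != len(truths):
        raise ValueError("calls and truths must have the same read count")
    lengths = {len(c) for c in calls} | {len(t) for t in truths}
    if len(lengths) != 1:
        raise ValueError("all calls and truths must share one length")
    L = lengths.pop()
    mism = np.zeros(L)
    for c, t in zip(calls, truths):
        mism += np.frombuffer(c.encode(), dtype=np.uint8) != np.frombuffer(
            t.encode(), dtype=np.uint8
        )
    per_cycle = mism / len(calls)
    return float(mism.sum() / (L * len(calls))), per_cycle


def predicted_error_probs(result) -> np.ndarray:
    """Per-base predicted error probabilities 1 - p(called | y'')."""
    post = np.asarray(result.posteriors, dtype=float)
    idx = np.array([("ACGT").index(b) for b in result.calls])
    return 1.0 - post[np.arange(post.shape[0]), idx]


def _flatten(results: Sequence, truths: Sequence) -> tuple[np.ndarray, np.ndarray]:
    """(predicted error prob, correctness) over all bases of all reads."""
    errs, correct = [], []
    for res, truth in zip(results, truths):
        errs.append(predicted_error_probs(res))
        t = str(truth)
        correct.append(np.array([c == tb for c, tb in zip(res.calls, t)]))
    return np.concatenate(errs), np.concatenate(correct)


def discrimination_score(results: Sequence, truths: Sequence, epsilon: float) -> float:
    """D(eps): fraction of all bases both correct and confidently called.

    Counts bases that are correct *and* have predicted error probability
    strictly below eps, over all called bases.
    """
    if not 0.0 < epsilon < 1.0:
        raise ValueError("epsilon must lie in (0, 1)")
    errs, correct = _flatten(results, truths)
    return float((correct & (errs < epsilon)).sum() / errs.size)


def discrimination_curve(
    results: Sequence, truths: Sequence, eps_grid: np.ndarray
) -> list[tuple[float, float]]:
    """(eps, D(eps)) pairs over a tolerance grid; monotone by construction."""
    errs, correct = _flatten(results, truths)
    curve = []
    for eps in np.asarray(eps_grid, dtype=float):
        curve.append((float(eps), float((correct & (errs < eps)).sum() / errs.size)))
    return curve


def discrimination_from_phred(
    calls: Sequence[str],
    phreds: Sequence[np.ndarray],
    truths: Sequence,
    eps_grid: np.ndarray,
) -> list[tuple[float, float]]:
    """D(eps) curve from phred scores alone (e.g. parsed from FASTQ).

    The predicted error probability is recovered as 10^(-Q/10); due to
    integer rounding of Q this is a slightly coarsened version of
    :func:`discrimination_curve`.
    """
    errs = np.concatenate([10.0 ** (-np.asarray(q, float) / 10.0) for q in phreds])
    correct = np.concatenate(
        [
            np.array([c == tb for c, tb in zip(cs, str(t))])
            for cs, t in zip(calls, truths)
        ]
    )
    return [
        (float(e), float((correct & (errs < e)).sum() / errs.size))
        for e in np.asarray(eps_grid, dtype=float)
    ]


#: Half-decade log-spaced bin edges used for calibration checks.  Bins
#: below ~1/N_p cannot be resolved by an N_p-particle posterior.
DEFAULT_CALIBRATION_EDGES = np.array(
    [0.0, 1e-3, 10**-2.5, 1e-2, 10**-1.5, 1e-1, 10**-0.5, 1.0]
)


def calibration_table(
    results: Sequence,
    truths: Sequence,
    edges: np.ndarray = DEFAULT_CALIBRATION_EDGES,
) -> pd.DataFrame:
    """Bin bases by predicted error probability; compare with observed.

    Returns one row per bin with the base count, the mean predicted error
    probability and the empirical mismatch frequency.  A well-calibrated
    caller has empirical ~ predicted in every populated bin.
    """
    errs, correct = _flatten(results, truths)
    idx = np.digitize(errs, edges[1:-1], right=False)
    rows = []
    for b in range(len(edges) - 1):
        sel = idx == b
        n = int(sel.sum())
        rows.append(
            {
                "bin_lo": edges[b],
                "bin_hi": edges[b + 1],
                "n": n,
                "mean_predicted": float(errs[sel].mean()) if n else np.nan,
                "empirical": float(1.0 - correct[sel].mean()) if n else np.nan,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class QualityReport:
    """Tile-level quality summary.

    ``per_base_error_prob``/``phred`` are per-cycle means of the predicted
    error probability and the corresponding phred score;
    ``per_cycle_error`` is the empirical per-cycle mismatch rate and
    ``discrimination`` the (eps, D(eps)) curve, which must be
    non-decreasing in eps.
    """

    per_base_error_prob: np.ndarray
    phred: np.ndarray
    per_cycle_error: np.ndarray
    discrimination: list[tuple[float, float]]

    def __post_init__(self) -> None:
        if np.any(self.per_base_error_prob < 0) or np.any(self.per_base_error_prob > 1):
            raise ValueError("error probabilities must lie in [0, 1]")
        d = [v for _, v in self.discrimination]
        if any(b < a - 1e-12 for a, b in zip(d, d[1:])):
            raise ValueError("D(eps) must be non-decreasing in eps")

    @classmethod
    def from_results(
        cls,
        results: Sequence,
        truths: Sequence,
        eps_grid: np.ndarray | None = None,
    ) -> "QualityReport":
        if eps_grid is None:
            eps_grid = np.logspace(-6, -0.05, 24)
        pred = np.stack([predicted_error_probs(r) for r in results])
        mean_pred = pred.mean(axis=0)
        phred = phred_from_posteriors(
            np.stack([1.0 - mean_pred, mean_pred], axis=1), np.zeros(len(mean_pred), int)
        )
        _, per_cycle = error_rate([r.calls for r in results], truths)
        curve = discrimination_curve(results, truths, eps_grid)
        return cls(mean_pred, phred, per_cycle, curve)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cycle": np.arange(1, len(self.per_base_error_prob) + 1),
                "mean_predicted_error": self.per_base_error_prob,
                "phred_of_mean": self.phred,
                "empirical_error": self.per_cycle_error,
            }
        )
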