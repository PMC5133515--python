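"""Threshold-maximized Bernoulli likelihood ratio statistic.

A gene's per-sample burden scores are dichotomized at a threshold ``t``:
``T_A`` cases and ``T_U`` controls have scores strictly exceeding ``t``.
The statistic compares the product of the two group-wise Bernoulli
likelihoods (alternative) against the pooled Bernoulli likelihood (null),

    Lambda = log [ pA^TA (1-pA)^(m-TA) pU^TU (1-pU)^(l-TU) ]
           - log [ p^T (1-p)^(m+l-T) ]

with ``pA = TA/m``, ``pU = TU/l``, ``p = T/(m+l)`` the maximum-likelihood
proportions.  The *direction-adjusted* variant swaps ``pA`` and ``pU`` in
the numerator whenever ``pA <= pU``, penalizing control-side enrichment
instead of rewarding it; it is the form used with direction- and
annotation-weighted burden scores.  The statistic is maximized over the
grid of observed score values, and its null distribution is obtained by
gene-specific label permutation (see :mod:`burdenlrt.permutation`), so the
logarithm base is inert; natural log is used throughout.  All zero
probabilities follow the convention ``0 * log 0 = 0``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import xlogy

__all__ = [
    "ThresholdedCounts",
    "LRTResult",
    "lrt_at_threshold",
    "maximize_lrt",
]

#: branch tags
EQ_PLAIN = "EQ2"
EQ_SWAPPED = "EQ4"

_MODES = ("plain", "direction-adjusted", "symmetric")


@dataclass(frozen=True)
class ThresholdedCounts:
    """Exceedance counts of burden scores above a threshold ``t``."""

    t: float
    t_a: int
    t_u: int
    m: int
    l: int

    def __post_init__(self) -> None:
        if not (0 <= self.t_a <= self.m and 0 <= self.t_u <= self.l):
            raise ValueError(
                f"inconsistent counts: T_A={self.t_a} (m={self.m}), "
                f"T_U={self.t_u} (l={self.l})"
            )

    @property
    def t_total(self) -> int:
        return self.t_a + self.t_u

    @property
    def p_a(self) -> float:
        return self.t_a / self.m

    @property
    def p_u(self) -> float:
        return self.t_u / self.l

    @property
    def p_pooled(self) -> float:
        return self.t_total / (self.m + self.l)


@dataclass(frozen=True)
class LRTResult:
    """Maximized LRT statistic with the winning threshold and counts."""

    statistic: float
    t_star: float
    counts: ThresholdedCounts
    branch: str
    degenerate: bool = False


def _lambda_terms(t_a, t_u, m, l, mode):
    """Vectorized log-likelihood-ratio evaluation.

    ``t_a``/``t_u`` may be arrays (broadcast together); ``m``, ``l`` are
    scalars.  Returns (lam, swapped_mask).
    """
    t_a = np.asarray(t_a, dtype=float)
    t_u = np.asarray(t_u, dtype=float)
    p_a = t_a / m
    p_u = t_u / l
    t = t_a + t_u
    n = m + l
    p = t / n

    denom = xlogy(t, p) + xlogy(n - t, 1.0 - p)
    # group the two Bernoulli factors per sample group before adding, so
    # that swapping the case/control roles permutes identical addends and
    # the label-swap symmetry holds exactly in floating point
    num_plain = (xlogy(t_a, p_a) + xlogy(m - t_a, 1.0 - p_a)) + (
        xlogy(t_u, p_u) + xlogy(l - t_u, 1.0 - p_u)
    )
    if mode in ("plain", "symmetric"):
        return num_plain - denom, np.zeros_like(num_plain, dtype=bool)

    # direction-adjusted: swap the group estimates when pA <= pU; a strictly
    # positive count against a zero swapped estimate legitimately gives -inf
    # (such grid points exist but never win the maximization).
    with np.errstate(divide="ignore", invalid="ignore"):
        num_swap = (xlogy(t_a, p_u) + xlogy(m - t_a, 1.0 - p_u)) + (
            xlogy(t_u, p_a) + xlogy(l - t_u, 1.0 - p_a)
        )
    swapped = p_a <= p_u
    lam = np.where(swapped, num_swap - denom, num_plain - denom)
    return lam, swapped


def lrt_at_threshold(counts: ThresholdedCounts, mode: str = "plain"):
    """Evaluate the LRT statistic at one set of exceedance counts.

    Parameters
    ----------
    counts
        Exceedance counts at a fixed threshold.
    mode
        ``"plain"`` (or ``"symmetric"``) always uses the unswapped form;
        ``"direction-adjusted"`` swaps the group estimates when
        ``p_A <= p_U``.

    Returns
    -------
    (lam, branch)
        The statistic (natural log) and which branch produced it.
    """
    if mode not in _MODES:
        raise ValueError(f"unknown mode {mode!r}; expected one of {_MODES}")
    if counts.m < 1 or counts.l < 1:
        raise ValueError("need at least one case and one control")
    if counts.t_total > counts.m + counts.l:
        raise ValueError("inconsistent counts: T > m + l")
    lam, swapped = _lambda_terms(counts.t_a, counts.t_u, counts.m, counts.l, mode)
    branch = EQ_SWAPPED if (mode == "direction-adjusted" and bool(swapped)) else EQ_PLAIN
    return float(lam), branch


# ---------------------------------------------------------------------------
# threshold maximization


def _grid_fixed(scores: np.ndarray):
    """Precompute the threshold grid machinery for a fixed score vector.

    Returns (grid, order_desc, k) where ``grid`` is the ascending unique
    score values, ``order_desc`` sorts samples by descending score, and
    ``k[g]`` is the total number of samples with score > grid[g].
    """
    scores = np.asarray(scores, dtype=float)
    grid = np.unique(scores)
    order_desc = np.argsort(-scores, kind="stable")
    asc = scores[order_desc][::-1]
    k = scores.size - np.searchsorted(asc, grid, side="right")
    return grid, order_desc, k


def _exceed_case_counts(case_ind: np.ndarray, order_desc, k):
    """T_A per threshold for each row of a (B, n) case-indicator matrix."""
    cs = np.cumsum(case_ind[:, order_desc], axis=1)
    padded = np.concatenate([np.zeros((cs.shape[0], 1), dtype=cs.dtype), cs], axis=1)
    return padded[:, k]


def max_lambda_fixed_scores(scores, case_ind, mode):
    """Max-over-threshold statistic for fixed scores, batched over labelings.

    ``case_ind`` is a (B, n) 0/1 matrix of case indicators; returns the
    (B,) vector of maximized statistics.  This is the permutation-engine
    fast path for methods whose weights do not depend on the labels.
    """
    grid, order_desc, k = _grid_fixed(scores)
    case_ind = np.atleast_2d(np.asarray(case_ind))
    m = int(case_ind[0].sum())
    l = case_ind.shape[1] - m
    t_a = _exceed_case_counts(case_ind, order_desc, k)
    lam, _ = _lambda_terms(t_a, k[np.newaxis, :] - t_a, m, l, mode)
    return lam.max(axis=1)


def maximize_lrt(scores, status, mode: str = "plain") -> LRTResult:
    """Maximize the LRT statistic over the grid of observed score values.

    The grid is the sorted unique scores; "exceed" is strict (score > t),
    so any threshold between consecutive unique values is equivalent to a
    grid member, and the all-exceed point (t below the minimum) always
    yields Lambda = 0.  Ties in the maximum are broken toward the smallest
    threshold for determinism.
    """
    if mode not in _MODES:
        raise ValueError(f"unknown mode {mode!r}; expected one of {_MODES}")
    scores = np.asarray(scores, dtype=float)
    status = np.asarray(status)
    if scores.shape != status.shape:
        raise ValueError("scores and phenotype status have different lengths")
    m = int(status.sum())
    l = status.size - m
    if m < 1 or l < 1:
        raise ValueError("need at least one case and one control")

    grid, order_desc, k = _grid_fixed(scores)
    t_a = _exceed_case_counts(status[np.newaxis, :].astype(np.int64), order_desc, k)[0]
    t_u = k - t_a
    lam, _ = _lambda_terms(t_a, t_u, m, l, mode)

    best = lam.max()
    g = int(np.argmax(lam >= best - 1e-12))  # smallest threshold attaining max
    counts = ThresholdedCounts(
        t=float(grid[g]), t_a=int(t_a[g]), t_u=int(t_u[g]), m=m, l=l
    )
    stat, branch = lrt_at_threshold(counts, mode=mode)
    return LRTResult(
        statistic=float(stat),
        t_star=float(grid[g]),
        counts=counts,
        branch=branch,
        degenerate=bool(grid.size == 1),
    )
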