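"""CMC and C-alpha baseline tests under the shared permutation engine.

Both comparators are driven by the same two-stage label-permutation
machinery (and the same per-gene seed streams) as the LRT methods, so
per-gene p-values are comparable replicate-for-replicate.

CMC (combined multivariate and collapsing): variants with minor-allele
frequency below a collapsing cutoff are pooled into a single carrier
indicator; commoner variants keep individual dosage columns.  The
statistic is Hotelling's T^2 between the case and control mean vectors
of that design (constant columns dropped), with a permutation p-value in
place of the original's asymptotic reference.

C-alpha: with ``n_i`` minor-allele copies of variant i overall, ``y_i``
of them in cases, and null case share ``p0 = m/(m+l)``,

    T = sum_i [ (y_i - n_i p0)^2 - n_i p0 (1 - p0) ]

tests the *variance* of the case/control allele split — sensitive to
mixed-direction effects that cancel in a burden sum.  The binomial
variance normalizer c and Z = T/sqrt(c) are reported; the primary
p-value is permutation-based (recomputing y_i each replicate), with the
one-sided normal approximation alongside for reference.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .permutation import PermutationResult, _exact, _two_stage

__all__ = ["cmc_design", "cmc_test", "calpha_components", "calpha_test"]


# ---------------------------------------------------------------------------
# CMC


def cmc_design(unit, maf_cut: float = 0.01) -> np.ndarray:
    """Collapsed design matrix: rare-carrier indicator + common dosage columns.

    A variant is "rare" when its sample minor-allele frequency is below
    ``maf_cut``.  Constant columns are dropped; the result may be empty.
    """
    if not (0.0 <= maf_cut <= 0.5):
        raise ValueError("maf_cut must lie in [0, 0.5]")
    x = np.asarray(unit.dosages, dtype=float)
    maf = x.sum(axis=0) / (2.0 * x.shape[0])
    rare = maf < maf_cut
    cols = []
    if rare.any():
        cols.append((x[:, rare].sum(axis=1) > 0).astype(float))
    if (~rare).any():
        cols.extend(x[:, j] for j in np.flatnonzero(~rare))
    if not cols:
        return np.empty((x.shape[0], 0))
    design = np.column_stack(cols)
    keep = np.ptp(design, axis=0) > 0
    return design[:, keep]


def _hotelling_batch(design: np.ndarray, status: np.ndarray):
    """Batched Hotelling's T^2 over permuted case indicators."""
    n, p = design.shape
    m = int(status.sum())
    l = n - m
    total_sum = design.sum(axis=0)
    cross = design.T @ design  # fixed second moment
    factor = m * l / n

    def batch(perms: np.ndarray) -> np.ndarray:
        c = status[perms].astype(float)  # (B, n)
        case_mean = (c @ design) / m  # (B, p)
        ctrl_mean = (total_sum[np.newaxis, :] - c @ design) / l
        d = case_mean - ctrl_mean
        # pooled within-group covariance from the fixed total second moment
        s = (
            cross[np.newaxis, :, :]
            - m * case_mean[:, :, np.newaxis] * case_mean[:, np.newaxis, :]
            - l * ctrl_mean[:, :, np.newaxis] * ctrl_mean[:, np.newaxis, :]
        ) / max(n - 2, 1)
        sinv = np.linalg.pinv(s)
        sol = np.einsum("bij,bj->bi", sinv, d)
        t2 = factor * np.einsum("bi,bi->b", d, sol)
        # a mean difference outside the column space of a singular pooled
        # covariance (perfect separation) is infinitely significant
        resid = np.einsum("bij,bj->bi", s, sol) - d
        dnorm = np.linalg.norm(d, axis=1)
        bad = np.linalg.norm(resid, axis=1) > 1e-8 * (dnorm + 1e-30)
        t2[bad & (dnorm > 0)] = np.inf
        return t2

    return batch


def cmc_test(unit, ph, maf_cut: float = 0.01, b1: int = 1000, b2: int = 10000,
             gate: float = 0.1, seed: int = 0, exact: bool = False) -> PermutationResult:
    """CMC collapsing test with a two-stage permutation p-value."""
    status = ph.status.astype(np.int64)
    design = cmc_design(unit, maf_cut)
    if design.shape[1] == 0:
        return PermutationResult(1.0, 0, 1, 0.0, seed, None, degenerate=True)
    batch = _hotelling_batch(design, status)
    observed = float(batch(np.arange(status.size)[np.newaxis, :])[0])
    if exact:
        p, total = _exact(batch, observed, status)
        return PermutationResult(p, total, 1, observed, seed, exact=True)
    rng = np.random.default_rng(seed)
    p, b, stage = _two_stage(batch, observed, rng, status.size, b1, b2, gate)
    return PermutationResult(p, b, stage, observed, seed)


# ---------------------------------------------------------------------------
# C-alpha


def calpha_components(unit, ph):
    """(n_i, y_i, p0, T, c, Z) for the observed labeling.

    ``c`` sums, over the distinct copy-totals n, the count of variants
    with that total times the binomial variance of the per-variant term:
    ``sum_u [ (u - n p0)^2 - n p0 (1-p0) ]^2 Binom(u; n, p0)``.
    """
    status = ph.status.astype(float)
    x = np.asarray(unit.dosages, dtype=float)
    n_i = x.sum(axis=0)
    y_i = status @ x
    p0 = ph.m / (ph.m + ph.l)
    q0 = 1.0 - p0
    t_stat = float(np.sum((y_i - n_i * p0) ** 2 - n_i * p0 * q0))
    c = 0.0
    poly = n_i[n_i >= 1].astype(int)
    for n, count in zip(*np.unique(poly, return_counts=True)):
        u = np.arange(n + 1)
        term = (u - n * p0) ** 2 - n * p0 * q0
        c += count * float(np.sum(term**2 * stats.binom.pmf(u, n, p0)))
    z = t_stat / np.sqrt(c) if c > 0 else 0.0
    return n_i, y_i, p0, t_stat, c, z


def calpha_test(unit, ph, b1: int = 1000, b2: int = 10000, gate: float = 0.1,
                seed: int = 0, exact: bool = False) -> PermutationResult:
    """C-alpha dispersion test with a two-stage permutation p-value.

    The permutation p is primary; the one-sided normal approximation
    ``P(Z > z)`` is attached under ``extra["p_normal"]`` for reference
    only, never for ranking.
    """
    status = ph.status.astype(np.int64)
    x = np.asarray(unit.dosages, dtype=float)
    n_i, y_i, p0, t_obs, c, z = calpha_components(unit, ph)
    if not np.any(n_i >= 1):
        return PermutationResult(1.0, 0, 1, 0.0, seed, None, degenerate=True)
    center = n_i * p0
    var0 = n_i * p0 * (1.0 - p0)

    def batch(perms: np.ndarray) -> np.ndarray:
        cmat = status[perms].astype(float)
        y = cmat @ x  # (B, v)
        return np.sum((y - center[np.newaxis, :]) ** 2 - var0[np.newaxis, :], axis=1)

    extra = {"p_normal": float(stats.norm.sf(z)), "z": float(z), "c": float(c)}
    if exact:
        p, total = _exact(batch, t_obs, status)
        return PermutationResult(p, total, 1, t_obs, seed, exact=True, extra=extra)
    rng = np.random.default_rng(seed)
    p, b, stage = _two_stage(batch, t_obs, rng, status.size, b1, b2, gate)
    return PermutationResult(p, b, stage, t_obs, seed, extra=extra)
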