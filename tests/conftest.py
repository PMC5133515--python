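"""Shared fixtures and independent oracles for the test suite.

The oracle functions here deliberately re-derive every quantity by naive
direct substitution (plain Python floats, explicit loops, exhaustive
enumeration) so that they share no code path with the package
implementation they check.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
import pytest

from burdenlrt.io import GeneUnit, PhenotypeVector


def make_unit(dosages, gene="G", categories=None, explicit=None, positions=None):
    dosages = np.asarray(dosages, dtype=float)
    n, v = dosages.shape
    if categories is None:
        categories = np.full(v, "OTHER", dtype=object)
    if explicit is None:
        explicit = np.full(v, np.nan)
    if positions is None:
        positions = np.arange(1, v + 1) * 100
    return GeneUnit(
        gene=gene,
        dosages=dosages,
        variant_ids=[f"{gene}:v{i}" for i in range(v)],
        positions=np.asarray(positions),
        categories=np.asarray(categories, dtype=object),
        explicit_weights=np.asarray(explicit, dtype=float),
    )


def make_pheno(status):
    status = np.asarray(status, dtype=np.int8)
    return PhenotypeVector([f"S{i}" for i in range(status.size)], status)


# ---------------------------------------------------------------------------
# independent statistic oracles


def oracle_lambda(ta, tu, m, l, swapped=False):
    """Direct substitution of the Bernoulli likelihood ratio, term by term."""

    def powlog(k, p):
        if k == 0:
            return 0.0  # 0 * log 0 = 0 convention
        if p <= 0.0:
            return float("-inf")
        return k * math.log(p)

    pa, pu, p = ta / m, tu / l, (ta + tu) / (m + l)
    if swapped:
        num = (
            powlog(ta, pu) + powlog(m - ta, 1 - pu)
            + powlog(tu, pa) + powlog(l - tu, 1 - pa)
        )
    else:
        num = (
            powlog(ta, pa) + powlog(m - ta, 1 - pa)
            + powlog(tu, pu) + powlog(l - tu, 1 - pu)
        )
    den = powlog(ta + tu, p) + powlog(m + l - ta - tu, 1 - p)
    return num - den


def oracle_max_lambda(scores, status, mode="plain"):
    """Naive loop-over-thresholds maximization using :func:`oracle_lambda`."""
    scores = list(map(float, scores))
    status = list(map(int, status))
    m = sum(status)
    l = len(status) - m
    best = float("-inf")
    for t in sorted(set(scores)):
        ta = sum(1 for s, y in zip(scores, status) if y == 1 and s > t)
        tu = sum(1 for s, y in zip(scores, status) if y == 0 and s > t)
        if mode == "direction-adjusted" and ta / m <= tu / l:
            lam = oracle_lambda(ta, tu, m, l, swapped=True)
        else:
            lam = oracle_lambda(ta, tu, m, l)
        best = max(best, lam)
    return best


def oracle_calpha_t(dosages, status, p0):
    """Direct evaluation of the dispersion statistic T."""
    t = 0.0
    for i in range(dosages.shape[1]):
        n_i = float(dosages[:, i].sum())
        y_i = float(dosages[status == 1, i].sum())
        t += (y_i - n_i * p0) ** 2 - n_i * p0 * (1 - p0)
    return t


def enumerate_assignments(n, m):
    """All distinct case/control labelings with m cases over n samples."""
    for cases in itertools.combinations(range(n), m):
        status = np.zeros(n, dtype=np.int8)
        status[list(cases)] = 1
        yield status


def oracle_exhaustive_p(stat_fn, dosages, status, tie_eps=1e-9):
    """Exhaustive permutation p: share of labelings with stat >= observed."""
    observed = stat_fn(dosages, status)
    n, m = status.size, int(status.sum())
    count = total = 0
    for assign in enumerate_assignments(n, m):
        total += 1
        count += stat_fn(dosages, assign) >= observed - tie_eps
    return count / total


@pytest.fixture
def rng():
    return np.random.default_rng(20160)
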