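"""Gene-specific permutation p-values with two-stage early stopping.

Case/control labels are permuted over all samples (equivalently, sample
rows are permuted), which preserves the genotype correlation structure
within the gene, so the null distribution is valid under arbitrary
linkage between variants.  For every replicate the *full* pipeline of the
chosen method is re-run on the permuted labels: in particular the
effect-direction sign weights of LRT-DIR are recomputed from the permuted
labels each time — freezing them at their observed values would be
anti-conservative.  Threshold maximization is redone every replicate.

The two-stage scheme runs ``b1`` replicates, and continues to ``b2``
total replicates only if the interim empirical p-value is below the gate
(default 0.1).  P-values use the add-one estimator
``p = (1 + #{permuted >= observed}) / (1 + B)``, which is valid for any
B; ties count toward the numerator.  Stage-1 replicates are the prefix of
the stage-2 stream, so a gene that passes the gate gets exactly the
single-stage p-value at ``b2``.
"""

from __future__ import annotations

import hashlib
import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .burden import annotation_weights, burden_scores, unit_weights
from .lrt import max_lambda_fixed_scores, maximize_lrt

logger = logging.getLogger(__name__)

__all__ = ["PermutationResult", "permute_gene", "permute_scores", "run_all_genes",
           "gene_seed"]

_TIE_EPS = 1e-9  # float slop under which a permuted statistic ties the observed
_CHUNK = 256

METHODS = ("lrt", "lrt-dir", "lrt-bs")


@dataclass
class PermutationResult:
    """Empirical p-value for one gene under one method."""

    p_value: float
    b_used: int
    stage: int
    statistic: float
    seed: int
    t_star: float | None = None
    degenerate: bool = False
    exact: bool = False
    extra: dict | None = None


def gene_seed(master_seed: int, gene: str) -> int:
    """Reproducible per-gene seed, independent of gene processing order."""
    digest = hashlib.blake2b(f"{master_seed}:{gene}".encode(), digest_size=4).digest()
    return int.from_bytes(digest, "big") % (2**31)


def _perm_batches(rng, n: int, total: int, chunk: int = _CHUNK):
    """Yield (nb, n) permutation index matrices drawn sequentially from rng."""
    done = 0
    base = np.arange(n)
    while done < total:
        nb = min(chunk, total - done)
        yield rng.permuted(np.tile(base, (nb, 1)), axis=1)
        done += nb


def _two_stage(batch_stats, observed: float, rng, n: int,
               b1: int, b2: int, gate: float):
    """Core adaptive loop; returns (p, b_used, stage)."""
    if not (b1 >= 1 and b2 >= b1):
        raise ValueError("need b1 >= 1 and b2 >= b1")
    if not (0.0 < gate < 1.0):
        raise ValueError("gate must lie in (0, 1)")
    count = 0
    b = 0
    for perms in _perm_batches(rng, n, b1):
        count += int(np.sum(batch_stats(perms) >= observed - _TIE_EPS))
        b += perms.shape[0]
    p = (1 + count) / (1 + b)
    if p >= gate or b2 == b1:
        return p, b, 1
    for perms in _perm_batches(rng, n, b2 - b1):
        count += int(np.sum(batch_stats(perms) >= observed - _TIE_EPS))
        b += perms.shape[0]
    return (1 + count) / (1 + b), b, 2


def _exact(batch_stats, observed: float, status: np.ndarray):
    """Exhaustive p over all distinct case/control label assignments."""
    n = status.size
    m = int(status.sum())
    count = 0
    total = 0
    combos = itertools.combinations(range(n), m)
    while True:
        block = list(itertools.islice(combos, _CHUNK))
        if not block:
            break
        order = np.argsort(-status, kind="stable")  # observed cases first
        perms = np.empty((len(block), n), dtype=np.intp)
        for r, cases in enumerate(block):
            rest = [i for i in range(n) if i not in cases]
            # place observed case indices at the chosen case positions, so
            # status[perm] is the indicator of the chosen assignment
            perm = np.empty(n, dtype=np.intp)
            perm[list(cases)] = order[:m]
            perm[rest] = order[m:]
            perms[r] = perm
        count += int(np.sum(batch_stats(perms) >= observed - _TIE_EPS))
        total += len(block)
    return count / total, total


# ---------------------------------------------------------------------------
# method statistic constructors


def _fixed_score_method(scores: np.ndarray, status: np.ndarray, mode: str):
    """Batch statistic for methods whose weights ignore the labels."""

    def batch(perms: np.ndarray) -> np.ndarray:
        return max_lambda_fixed_scores(scores, status[perms], mode)

    return batch


def _lrt_dir_method(unit, status: np.ndarray, mode: str):
    """Batch statistic recomputing direction sign weights per replicate."""
    x = unit.dosages
    m = int(status.sum())
    l = status.size - m
    col_tot = x.sum(axis=0)

    def batch(perms: np.ndarray) -> np.ndarray:
        c = status[perms].astype(float)  # (B, n)
        case_counts = c @ x  # (B, v)
        f_case = case_counts / (2.0 * m)
        f_ctrl = (col_tot[np.newaxis, :] - case_counts) / (2.0 * l)
        signs = np.where(f_case <= f_ctrl, 1.0, -1.0)
        scores = signs @ x.T  # (B, n)
        out = np.empty(perms.shape[0])
        for r in range(perms.shape[0]):
            out[r] = max_lambda_fixed_scores(scores[r], c[r : r + 1], mode)[0]
        return out

    return batch


def _method_machinery(unit, ph, method: str, scheme, mode: str | None,
                      bs_combine_direction: bool):
    """Return (batch_stats, observe_fn) for one of the LRT methods."""
    status = ph.status.astype(np.int64)
    if mode is None:
        mode = "plain" if method == "lrt" else "symmetric"
    if method == "lrt":
        scores = burden_scores(unit, unit_weights(unit))
        return _fixed_score_method(scores, status, mode), scores
    if method == "lrt-dir":
        return _lrt_dir_method(unit, status, mode), None
    if method == "lrt-bs":
        w = annotation_weights(unit, scheme if scheme is not None else "bs-10-5-1")
        if bs_combine_direction:
            # optional mode: magnitude times per-replicate direction sign
            scaled = unit.dosages * w.values[np.newaxis, :]

            class _Scaled:
                dosages = scaled

            return _lrt_dir_method(_Scaled, status, mode), None
        scores = burden_scores(unit, w)
        return _fixed_score_method(scores, status, mode), scores
    raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")


def permute_scores(scores, status, mode: str, b1: int = 1000, b2: int = 10000,
                   gate: float = 0.1, seed: int = 0,
                   exact: bool = False) -> PermutationResult:
    """Permutation p-value for a *fixed* score vector (weights frozen).

    This is the building block for label-independent weightings; note that
    running LRT-DIR through this path (weights computed once from the
    observed labels) is statistically invalid — use
    :func:`permute_gene` with ``method="lrt-dir"`` instead.
    """
    scores = np.asarray(scores, dtype=float)
    status = np.asarray(status, dtype=np.int64)
    res = maximize_lrt(scores, status, mode)
    batch = _fixed_score_method(scores, status, mode)
    observed = float(max_lambda_fixed_scores(scores, status[np.newaxis, :], mode)[0])
    if exact:
        p, total = _exact(batch, observed, status)
        return PermutationResult(p, total, 1, observed, seed, res.t_star,
                                 res.degenerate, exact=True)
    rng = np.random.default_rng(seed)
    p, b, stage = _two_stage(batch, observed, rng, status.size, b1, b2, gate)
    return PermutationResult(p, b, stage, observed, seed, res.t_star, res.degenerate)


def permute_gene(unit, ph, method: str = "lrt", b1: int = 1000, b2: int = 10000,
                 gate: float = 0.1, seed: int = 0, scheme=None, mode: str | None = None,
                 bs_combine_direction: bool = False,
                 exact: bool = False) -> PermutationResult:
    """Two-stage permutation p-value for one gene under one LRT method.

    ``method`` is ``"lrt"`` (plain statistic on unit weights),
    ``"lrt-dir"`` (per-replicate direction sign weights) or ``"lrt-bs"``
    (fixed annotation weights).  The weighted methods default to the
    label-symmetric statistic (``mode="symmetric"``), which scores
    unevenness in either direction; ``mode="direction-adjusted"``
    selects the swapped-estimate adjustment instead, which penalizes
    control-side enrichment (see :mod:`burdenlrt.lrt`).  With ``exact=True``
    the p-value is computed by exhaustive enumeration of all distinct
    label assignments instead of random sampling (small cohorts only).
    """
    status = ph.status.astype(np.int64)
    if unit.dosages.shape[0] != status.size:
        raise ValueError("gene unit and phenotypes have different sample counts")

    # degenerate gene: constant scores under every labeling
    if np.all(unit.dosages == unit.dosages[0:1, :]):
        logger.info("gene %s: constant dosages, degenerate result", unit.gene)
        return PermutationResult(1.0, 0, 1, 0.0, seed, None, degenerate=True)

    batch, _ = _method_machinery(unit, ph, method, scheme, mode, bs_combine_direction)
    identity = np.arange(status.size)[np.newaxis, :]
    observed = float(batch(identity)[0])

    # threshold/degeneracy bookkeeping from the observed labeling
    if method == "lrt-dir" or bs_combine_direction:
        from .burden import direction_weights

        w = direction_weights(unit, status)
        vals = w.values
        if method == "lrt-bs" or bs_combine_direction:
            vals = vals * annotation_weights(unit, scheme or "bs-10-5-1").values
        obs_scores = unit.dosages @ vals
    elif method == "lrt-bs":
        obs_scores = burden_scores(unit, annotation_weights(unit, scheme or "bs-10-5-1"))
    else:
        obs_scores = burden_scores(unit, unit_weights(unit))
    eff_mode = mode or ("plain" if method == "lrt" else "symmetric")
    res = maximize_lrt(obs_scores, status, eff_mode)

    if exact:
        p, total = _exact(batch, observed, status)
        return PermutationResult(p, total, 1, observed, seed, res.t_star,
                                 res.degenerate, exact=True)
    rng = np.random.default_rng(seed)
    p, b, stage = _two_stage(batch, observed, rng, status.size, b1, b2, gate)
    return PermutationResult(p, b, stage, observed, seed, res.t_star, res.degenerate)


def run_all_genes(units, ph, method: str = "lrt", b1: int = 1000, b2: int = 10000,
                  gate: float = 0.1, seed: int = 0, scheme=None,
                  mode: str | None = None, maf_cut: float = 0.01,
                  progress: bool = False) -> pd.DataFrame:
    """Run one method over all gene units; deterministic given ``seed``.

    Per-gene seeds are derived from the master seed and the gene symbol,
    so results do not depend on processing order, and every method
    (including the CMC and C-alpha comparators) consumes the identical
    per-gene permutation stream.
    """
    from . import comparators

    rows = []
    for unit in units:
        gseed = gene_seed(seed, unit.gene)
        if method in METHODS:
            r = permute_gene(unit, ph, method, b1, b2, gate, gseed, scheme, mode)
        elif method == "cmc":
            r = comparators.cmc_test(unit, ph, maf_cut, b1, b2, gate, gseed)
        elif method == "calpha":
            r = comparators.calpha_test(unit, ph, b1, b2, gate, gseed)
        else:
            raise ValueError(f"unknown method {method!r}")
        if progress:
            logger.info("%s %s: p=%.4g (B=%d)", method, unit.gene, r.p_value, r.b_used)
        rows.append(
            {
                "gene": unit.gene,
                "method": method,
                "statistic": r.statistic,
                "p_value": r.p_value,
                "stage": r.stage,
                "b_used": r.b_used,
                "t_star": np.nan if r.t_star is None else r.t_star,
                "n_variants": unit.n_variants,
                "degenerate": r.degenerate,
            }
        )
    cols = ["gene", "method", "statistic", "p_value", "stage", "b_used",
            "t_star", "n_variants", "degenerate"]
    return pd.DataFrame(rows, columns=cols)
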