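"""Synthetic exome case-control cohorts and the weight-scheme power harness.

The generator emulates a modest exome association cohort: a few thousand
unrelated samples, genes carrying a handful to dozens of rare variants,
and a binary phenotype from a logistic liability model.  Per variant a
minor-allele frequency is drawn from a truncated Beta rare-variant
spectrum, dosages are Binomial(2, MAF) (Hardy-Weinberg, linkage
equilibrium), and disease status is Bernoulli with

    logit P(case) = intercept + sum_causal beta_i x_i.

Three effect archetypes mirror qualitatively distinct gene mechanisms —
strong protective, weak, and strong deleterious effects — plus a null
archetype for type-I-error studies.  To emulate incomplete functional
annotation, only the first ``n_annotated`` causal variants (by position)
are marked ``functional`` in the emitted annotation table; every other
variant is ``rest``.  The weight-scheme grid pairs functional weights
{2, 5, 10} with rest weights {1, -1} (six combinations), alongside an
unweighted baseline.
"""

from __future__ import annotations

import hashlib
import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit

from .io import AnnotationTable, GenotypeMatrix, PhenotypeVector, build_gene_units, variant_key
from .permutation import METHODS, permute_gene

__all__ = [
    "GeneSpec",
    "SimConfig",
    "ARCHETYPE_EFFECTS",
    "archetype_gene",
    "simulate_cohort",
    "weight_scheme_grid",
    "power_study",
]

#: per-causal-variant log-odds effects by archetype
ARCHETYPE_EFFECTS = {
    "protective-strong": -math.log(3.0),
    "weak": math.log(1.3),
    "deleterious-strong": math.log(3.0),
    "null": 0.0,
}


@dataclass(frozen=True)
class GeneSpec:
    """Architecture of one simulated gene."""

    name: str
    n_variants: int = 30
    n_causal: int = 10
    beta: float = 0.0  # per-causal log-odds effect; sign = direction
    betas: tuple[float, ...] | None = None  # explicit per-causal effects
    archetype: str = "null"
    maf_alpha: float = 0.5
    maf_beta: float = 8.0
    maf_min: float = 0.001
    maf_max: float = 0.05

    def __post_init__(self) -> None:
        if self.n_causal > self.n_variants:
            raise ValueError("causal count exceeds variant count")
        if self.betas is not None and len(self.betas) != self.n_causal:
            raise ValueError("betas length must equal n_causal")
        if not (0.0 <= self.maf_min < self.maf_max <= 0.5):
            raise ValueError("MAF truncation bounds must satisfy 0 <= min < max <= 0.5")

    def effect_vector(self) -> np.ndarray:
        if self.betas is not None:
            return np.asarray(self.betas, dtype=float)
        return np.full(self.n_causal, self.beta, dtype=float)


def archetype_gene(name: str, archetype: str, n_variants: int = 30,
                   n_causal: int = 10) -> GeneSpec:
    """A GeneSpec with the archetype's default effect size."""
    if archetype not in ARCHETYPE_EFFECTS:
        raise ValueError(f"unknown archetype {archetype!r}")
    if archetype == "null":
        n_causal = 0
    return GeneSpec(name=name, n_variants=n_variants, n_causal=n_causal,
                    beta=ARCHETYPE_EFFECTS[archetype], archetype=archetype)


@dataclass(frozen=True)
class SimConfig:
    """Cohort-level simulation settings.

    The default intercept of -1.56 puts the baseline case fraction near
    17%, echoing the case/control imbalance of hypertension exome
    cohorts; 2,000 samples is the default desk-scale cohort.
    """

    genes: tuple[GeneSpec, ...]
    n_samples: int = 2000
    intercept: float = -1.56
    n_annotated: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "genes", tuple(self.genes))


def _sub_seed(*parts) -> int:
    digest = hashlib.blake2b(":".join(map(str, parts)).encode(), digest_size=4).digest()
    return int.from_bytes(digest, "big") % (2**31)


def _truncated_maf(rng, spec: GeneSpec, size: int) -> np.ndarray:
    out = np.empty(size)
    filled = 0
    for _ in range(1000):
        draw = rng.beta(spec.maf_alpha, spec.maf_beta, size=4 * size)
        ok = draw[(draw > spec.maf_min) & (draw < spec.maf_max)]
        take = min(ok.size, size - filled)
        out[filled : filled + take] = ok[:take]
        filled += take
        if filled == size:
            return out
    raise ValueError("MAF distribution places almost no mass inside the truncation bounds")


def simulate_cohort(cfg: SimConfig, replicate: int = 0):
    """One synthetic cohort; deterministic in ``(cfg, replicate)``.

    Returns ``(GenotypeMatrix, PhenotypeVector, AnnotationTable)`` ready
    for :func:`burdenlrt.io.build_gene_units`.
    """
    rng = np.random.default_rng(_sub_seed("cohort", cfg.seed, replicate))
    n = cfg.n_samples
    sample_ids = [f"S{i:05d}" for i in range(n)]

    blocks, meta_rows, ann_rows = [], [], []
    logit = np.full(n, cfg.intercept)
    for g, spec in enumerate(cfg.genes):
        mafs = _truncated_maf(rng, spec, spec.n_variants)
        x = rng.binomial(2, mafs[np.newaxis, :], size=(n, spec.n_variants))
        causal = np.sort(rng.choice(spec.n_variants, size=spec.n_causal, replace=False))
        if spec.n_causal:
            logit += x[:, causal] @ spec.effect_vector()
        annotated = set(causal[: cfg.n_annotated].tolist())
        base = (g + 1) * 1_000_000
        for i in range(spec.n_variants):
            pos = base + 100 * i
            meta_rows.append(
                {
                    "variant_id": variant_key("1", pos, "A", "G"),
                    "chrom": "1",
                    "pos": pos,
                    "ref": "A",
                    "alt": "G",
                    "gene": spec.name,
                }
            )
            ann_rows.append(
                {
                    "chrom": "1",
                    "pos": pos,
                    "ref": "A",
                    "alt": "G",
                    "category": "functional" if i in annotated else "rest",
                }
            )
        blocks.append(x)

    status = rng.binomial(1, expit(logit))
    for _ in range(100):
        if 0 < status.sum() < n:
            break
        status = rng.binomial(1, expit(logit))
    gm = GenotypeMatrix(
        sample_ids,
        np.concatenate(blocks, axis=1).astype(np.int16),
        pd.DataFrame(meta_rows),
        {"missing": 0, "flipped": [], "source": "simulated"},
    )
    ph = PhenotypeVector(sample_ids, status.astype(np.int8))
    ann = AnnotationTable(pd.DataFrame(ann_rows))
    return gm, ph, ann


def weight_scheme_grid(include_baseline: bool = True) -> dict[str, dict[str, float]]:
    """The six (functional, rest) weight pairs {2,5,10} x {1,-1}.

    Keys are ``f<w>_r<w>``; with ``include_baseline`` an ``unweighted``
    all-ones scheme is appended for comparison.
    """
    grid = {
        f"f{f}_r{r}": {"functional": float(f), "rest": float(r)}
        for f, r in itertools.product((2, 5, 10), (1, -1))
    }
    if include_baseline:
        grid["unweighted"] = {"functional": 1.0, "rest": 1.0}
    return grid


def power_study(cfg: SimConfig, methods=("lrt",), schemes=None, alpha: float = 0.05,
                reps: int = 100, b1: int = 200, b2: int = 999, gate: float = 0.1,
                seed: int = 0, maf_cut: float = 0.01,
                missing_policy: str = "as-ref") -> pd.DataFrame:
    """Monte-Carlo power (or, for null genes, type-I error) estimation.

    For each replicate a fresh cohort is simulated from ``cfg`` and each
    gene is tested by each method (and, for ``lrt-bs``, each scheme in
    ``schemes``) with the two-stage permutation engine; rejection is
    ``p <= alpha``.  Returns one row per (gene, method, scheme) with the
    estimated power and its binomial Monte-Carlo standard error.
    """
    if schemes is None:
        # the robust same-sign, large-contrast scheme on the simulator's categories
        schemes = {"f10_r1": {"functional": 10.0, "rest": 1.0}}
    arch = {spec.name: spec.archetype for spec in cfg.genes}
    hits: dict[tuple, int] = {}
    for r in range(reps):
        gm, ph, ann = simulate_cohort(cfg, r)
        units = build_gene_units(gm, ph, ann, missing_policy=missing_policy)
        for unit in units:
            for method in methods:
                runs = schemes.items() if method == "lrt-bs" else [("-", None)]
                for sname, scheme in runs:
                    sub = _sub_seed(seed, r, unit.gene, method, sname)
                    if method in METHODS:
                        res = permute_gene(unit, ph, method, b1, b2, gate, sub,
                                           scheme=scheme)
                    else:
                        from . import comparators

                        if method == "cmc":
                            res = comparators.cmc_test(unit, ph, maf_cut, b1, b2,
                                                       gate, sub)
                        elif method == "calpha":
                            res = comparators.calpha_test(unit, ph, b1, b2, gate, sub)
                        else:
                            raise ValueError(f"unknown method {method!r}")
                    key = (unit.gene, method, sname)
                    hits[key] = hits.get(key, 0) + (res.p_value <= alpha)
    rows = []
    for (gene, method, sname), k in hits.items():
        power = k / reps
        rows.append(
            {
                "gene": gene,
                "archetype": arch.get(gene, "?"),
                "method": method,
                "scheme": sname,
                "alpha": alpha,
                "power": power,
                "mc_se": math.sqrt(power * (1.0 - power) / reps),
                "replicates": reps,
            }
        )
    return pd.DataFrame(rows)
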