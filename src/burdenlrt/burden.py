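"""Weighted burden scores for a gene's variants.

The burden score of sample ``k`` in a gene with variants ``i = 1..n_j`` is
``S_k = sum_i s_i * x_ik`` where ``x_ik`` is the minor-allele dosage and
``s_i`` a per-variant weight.  Three weightings are supported:

* UNIT: ``s_i = 1`` — the plain collapsed genotype count;
* DIRECTION: ``s_i = +1`` if the variant's minor-allele frequency in cases
  is at most its frequency in controls, ``-1`` otherwise, so opposite
  genetic effects no longer cancel in the sum;
* ANNOTATION: categorical magnitudes from a weight scheme, by default
  10 for nsSNVs on a predicted protein-binding site, 5 for other nsSNVs,
  and 1 for everything else.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

__all__ = [
    "WeightVector",
    "NAMED_SCHEMES",
    "resolve_scheme",
    "burden_scores",
    "unit_weights",
    "direction_weights",
    "annotation_weights",
]

#: built-in named weight schemes (category -> multiplier)
NAMED_SCHEMES: dict[str, dict[str, float]] = {
    "bs-10-5-1": {"BS": 10.0, "NSSNV_NONBS": 5.0, "OTHER": 1.0},
}


@dataclass(frozen=True)
class WeightVector:
    """Per-variant multipliers aligned to one gene unit's variant order."""

    values: np.ndarray
    provenance: str  # UNIT | DIRECTION | ANNOTATION

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if not np.all(np.isfinite(self.values)):
            raise ValueError("weights must be finite")
        if self.provenance == "DIRECTION" and not np.all(np.isin(self.values, (-1.0, 1.0))):
            raise ValueError("DIRECTION weights must be in {-1, +1}")

    def __len__(self) -> int:
        return self.values.size


def resolve_scheme(scheme) -> dict[str, float]:
    """Turn a scheme name or category->value mapping into a plain dict."""
    if isinstance(scheme, str):
        try:
            return dict(NAMED_SCHEMES[scheme])
        except KeyError:
            raise ValueError(
                f"unknown named weight scheme {scheme!r}; "
                f"built-ins: {sorted(NAMED_SCHEMES)}"
            ) from None
    if isinstance(scheme, Mapping):
        return {str(k): float(v) for k, v in scheme.items()}
    raise TypeError("scheme must be a name or a category->value mapping")


def burden_scores(unit, w: WeightVector) -> np.ndarray:
    """Per-sample weighted burden scores ``S_k = sum_i s_i x_ik``."""
    if len(w) != unit.n_variants:
        raise ValueError(
            f"weight length {len(w)} does not match the gene's "
            f"{unit.n_variants} variants"
        )
    return unit.dosages @ w.values


def unit_weights(unit) -> WeightVector:
    """All-ones weights: the plain collapsed burden score."""
    return WeightVector(np.ones(unit.n_variants), "UNIT")


def direction_weights(unit, status) -> WeightVector:
    """Effect-direction sign weights from case/control allele frequencies.

    For each variant, ``s_i = +1`` if the minor-allele frequency among
    cases is <= that among controls, else ``-1``.  Ties (including
    monomorphic variants) fall in the ``+1`` branch.  When used inside a
    permutation test these signs must be recomputed from the permuted
    labels in every replicate; the permutation engine does so.
    """
    status = np.asarray(status)
    m = int(status.sum())
    l = status.size - m
    if m < 1 or l < 1:
        raise ValueError("need at least one case and one control")
    case_counts = status.astype(float) @ unit.dosages
    total_counts = unit.dosages.sum(axis=0)
    f_case = case_counts / (2.0 * m)
    f_ctrl = (total_counts - case_counts) / (2.0 * l)
    signs = np.where(f_case <= f_ctrl, 1.0, -1.0)
    return WeightVector(signs, "DIRECTION")


def annotation_weights(unit, scheme="bs-10-5-1") -> WeightVector:
    """Categorical annotation weights; explicit per-variant weights override.

    ``scheme`` is a built-in name or a category->value map, e.g.
    ``{"functional": 10, "rest": 1}``.  A variant whose category is absent
    from the scheme (and which carries no explicit weight) is an error.
    """
    mapping = resolve_scheme(scheme)
    values = np.empty(unit.n_variants, dtype=float)
    for i, cat in enumerate(unit.categories):
        explicit = unit.explicit_weights[i]
        if np.isfinite(explicit):
            values[i] = explicit
        elif cat in mapping:
            values[i] = mapping[cat]
        else:
            raise ValueError(
                f"variant {unit.variant_ids[i]} has category {cat!r} with no "
                f"weight in scheme {sorted(mapping)} and no explicit weight"
            )
    return WeightVector(values, "ANNOTATION")
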