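"""Genomic inflation, QQ coordinates, top-gene selection, cross-method tables.

The genomic inflation factor λ is computed by the median-χ²₁ definition:
each p-value is transformed to a one-degree-of-freedom χ² quantile and
the median of those is divided by the null χ²₁ median (≈ 0.4549);
λ ≈ 1 indicates calibrated p-values.  Tied p-values — common under
permutation discreteness — share the minimum rank, so several genes can
all be rank 1.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "genomic_inflation",
    "qq_coordinates",
    "add_ranks",
    "top_genes",
    "cross_method_table",
    "qq_plot",
]

_CHI2_MEDIAN = float(stats.chi2.ppf(0.5, df=1))


def genomic_inflation(pvalues, zero_floor: float | None = None) -> float:
    """Median-based genomic inflation factor λ of a set of p-values.

    Any exact zero (impossible under the add-one permutation estimator,
    but possible in external input) is mapped to ``zero_floor`` — by
    default half the smallest positive p present — and logged.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("need at least one p-value")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if np.any(p == 0):
        if zero_floor is None:
            pos = p[p > 0]
            if pos.size == 0:
                raise ValueError("all p-values are zero")
            zero_floor = float(pos.min()) / 2.0
        logger.warning("mapped %d zero p-values to %g", int((p == 0).sum()), zero_floor)
        p = np.where(p == 0, zero_floor, p)
    chisq = stats.chi2.isf(p, df=1)
    return float(np.median(chisq) / _CHI2_MEDIAN)


def qq_coordinates(pvalues) -> pd.DataFrame:
    """(-log10 expected, -log10 observed) pairs for a QQ plot.

    Expected quantiles are ``(i - 0.5) / G`` against the sorted observed
    p-values; rows are ordered by ascending observed p-value.
    """
    p = np.sort(np.asarray(pvalues, dtype=float))
    if p.size == 0:
        raise ValueError("need at least one p-value")
    g = p.size
    expected = (np.arange(1, g + 1) - 0.5) / g
    return pd.DataFrame(
        {
            "expected": -np.log10(expected),
            "observed": -np.log10(p),
        }
    )


def add_ranks(results: pd.DataFrame, p_col: str = "p_value") -> pd.DataFrame:
    """Attach competition ranks (1 = smallest p; ties share the minimum rank)."""
    out = results.copy()
    out["rank"] = out[p_col].rank(method="min").astype(int)
    return out


def top_genes(results: pd.DataFrame, cutoff: float = 1.55e-4) -> list[str]:
    """Genes with p <= cutoff, ordered by p then symbol."""
    if not (0.0 < cutoff <= 1.0):
        raise ValueError("cutoff must lie in (0, 1]")
    sub = results[results["p_value"] <= cutoff]
    sub = sub.sort_values(["p_value", "gene"])
    return sub["gene"].tolist()


def cross_method_table(results_by_method: dict[str, pd.DataFrame],
                       cutoff: float = 1.55e-4) -> pd.DataFrame:
    """Merged table over the union of each method's top genes.

    One row per gene in the union; per method, columns ``p_<method>``
    and ``rank_<method>`` carry that gene's (possibly non-top) p-value
    and min-tie rank under the method.
    """
    union: list[str] = []
    ranked = {}
    for method, df in results_by_method.items():
        ranked[method] = add_ranks(df).set_index("gene")
        for gene in top_genes(df, cutoff):
            if gene not in union:
                union.append(gene)
    rows = []
    for gene in union:
        row: dict = {"gene": gene}
        for method, df in ranked.items():
            if gene in df.index:
                row[f"p_{method}"] = float(df.loc[gene, "p_value"])
                row[f"rank_{method}"] = int(df.loc[gene, "rank"])
            else:
                row[f"p_{method}"] = np.nan
                row[f"rank_{method}"] = pd.NA
        rows.append(row)
    cols = ["gene"] + [f"{pre}_{m}" for m in results_by_method for pre in ("p", "rank")]
    return pd.DataFrame(rows, columns=cols)


def qq_plot(pvalues_by_method: dict[str, np.ndarray], path, cutoff: float | None = None):
    """Render QQ plots (one panel overlay) to SVG/PNG via matplotlib."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    lim = 0.0
    for method, p in pvalues_by_method.items():
        coords = qq_coordinates(p)
        ax.plot(coords["expected"], coords["observed"], ".", ms=4,
                label=f"{method} (λ={genomic_inflation(p):.2f})")
        lim = max(lim, coords["expected"].max(), coords["observed"].max())
    ax.plot([0, lim], [0, lim], "k--", lw=0.8)
    if cutoff is not None:
        ax.axhline(-np.log10(cutoff), color="grey", lw=0.8, ls=":")
    ax.set_xlabel(r"$-\log_{10} P_{expected}$")
    ax.set_ylabel(r"$-\log_{10} P_{observed}$")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
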