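"""Cohort input/output and per-gene analysis units.

Genotypes are held as a samples x variants matrix of minor-allele dosages
(0/1/2, with -1 marking a missing genotype) plus per-variant metadata
(chromosome, 1-based position, ref, alt, gene symbol).  Two on-disk
formats are read: VCF v4.x (GT fields only; multi-allelic records are
split into one column per alternate allele) and a simple TSV matrix
dialect with header ``variant_id chrom pos ref alt gene s1 s2 ...`` and
cells in ``{0, 1, 2, .}``.

Dosages always count the *minor* allele: if an alt allele's sample
frequency exceeds 0.5 the column is flipped (``x -> 2 - x``) on read and
the flip recorded in the load log.  Gene assignment is consumed as input
(a column, an INFO tag, or an external map) — it is never computed here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MISSING = -1  # in-memory missing-dosage marker

__all__ = [
    "GenotypeMatrix",
    "PhenotypeVector",
    "AnnotationTable",
    "GeneUnit",
    "read_genotypes",
    "write_genotypes",
    "read_phenotypes",
    "read_annotation",
    "align_cohort",
    "build_gene_units",
]

_META_COLS = ["variant_id", "chrom", "pos", "ref", "alt", "gene"]


def variant_key(chrom, pos, ref, alt) -> str:
    return f"{chrom}:{pos}:{ref}:{alt}"


@dataclass
class GenotypeMatrix:
    """Minor-allele dosages for samples x variants, with variant metadata."""

    sample_ids: list[str]
    dosages: np.ndarray  # (n_samples, n_variants) int16, MISSING = -1
    variant_meta: pd.DataFrame  # columns: variant_id, chrom, pos, ref, alt, gene
    log: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=np.int16)
        if self.dosages.shape != (len(self.sample_ids), len(self.variant_meta)):
            raise ValueError("dosage matrix shape does not match sample/variant lists")
        ok = np.isin(self.dosages, (0, 1, 2, MISSING))
        if not ok.all():
            bad = self.dosages[~ok].ravel()[0]
            raise ValueError(f"invalid dosage value {bad}; expected 0/1/2 or missing")
        vids = self.variant_meta["variant_id"]
        if vids.duplicated().any():
            dup = vids[vids.duplicated()].iloc[0]
            raise ValueError(f"duplicate variant_id {dup!r}")

    @property
    def variant_ids(self) -> list[str]:
        return self.variant_meta["variant_id"].tolist()

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_variants(self) -> int:
        return len(self.variant_meta)

    def subset_samples(self, sample_ids) -> "GenotypeMatrix":
        index = {s: i for i, s in enumerate(self.sample_ids)}
        rows = [index[s] for s in sample_ids]
        return GenotypeMatrix(
            list(sample_ids), self.dosages[rows], self.variant_meta.copy(), dict(self.log)
        )


@dataclass
class PhenotypeVector:
    """Binary case/control labels aligned to a GenotypeMatrix's samples."""

    sample_ids: list[str]
    status: np.ndarray  # 1 = case, 0 = control

    def __post_init__(self) -> None:
        self.status = np.asarray(self.status, dtype=np.int8)
        if self.status.size != len(self.sample_ids):
            raise ValueError("status length does not match sample_ids")
        if not np.isin(self.status, (0, 1)).all():
            raise ValueError("status must be 0/1")
        if self.m < 1 or self.l < 1:
            raise ValueError(
                f"need at least one case and one control (got m={self.m}, l={self.l})"
            )

    @property
    def m(self) -> int:
        """Number of cases."""
        return int(self.status.sum())

    @property
    def l(self) -> int:
        """Number of controls."""
        return int(self.status.size - self.status.sum())


class AnnotationTable:
    """Per-variant annotation categories and optional explicit weights.

    Keyed by ``chrom:pos:ref:alt``; an explicit numeric weight, when
    present, overrides the category's scheme weight downstream.
    """

    def __init__(self, frame: pd.DataFrame):
        frame = frame.copy()
        if "key" not in frame.columns:
            frame["key"] = [
                variant_key(c, p, r, a)
                for c, p, r, a in zip(frame["chrom"], frame["pos"], frame["ref"], frame["alt"])
            ]
        if frame["key"].duplicated().any():
            dup = frame["key"][frame["key"].duplicated()].iloc[0]
            raise ValueError(f"variant {dup!r} annotated more than once")
        if "weight" not in frame.columns:
            frame["weight"] = np.nan
        self.frame = frame.set_index("key")

    def _row(self, keys):
        for k in keys:
            if k in self.frame.index:
                return self.frame.loc[k]
        return None

    def category(self, *keys, default: str = "OTHER") -> str:
        row = self._row(keys)
        return default if row is None else str(row["category"])

    def weight(self, *keys) -> float:
        row = self._row(keys)
        return float("nan") if row is None else float(row["weight"])

    def __len__(self) -> int:
        return len(self.frame)


@dataclass
class GeneUnit:
    """One gene's dosage sub-matrix with aligned annotation slots.

    ``dosages`` has missing genotypes already resolved (see
    :func:`build_gene_units`), so downstream tests see a complete matrix.
    """

    gene: str
    dosages: np.ndarray  # (n_samples, n_variants) float
    variant_ids: list[str]
    positions: np.ndarray
    categories: np.ndarray  # per-variant category strings
    explicit_weights: np.ndarray  # per-variant explicit weight, NaN if none
    n_missing: int = 0

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]


# ---------------------------------------------------------------------------
# readers / writers


def _flip_to_minor(dosages: np.ndarray, meta: pd.DataFrame, log: dict) -> None:
    """Flip columns whose alt-allele frequency exceeds 0.5 (in place)."""
    flipped = []
    for j in range(dosages.shape[1]):
        col = dosages[:, j]
        obs = col[col != MISSING]
        if obs.size and obs.mean() / 2.0 > 0.5:
            col[col != MISSING] = 2 - col[col != MISSING]
            flipped.append(meta["variant_id"].iloc[j])
    if flipped:
        logger.info("flipped %d columns to minor-allele orientation", len(flipped))
    log["flipped"] = flipped


def _read_tsv_matrix(path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing_cols = [c for c in _META_COLS if c not in df.columns]
    if missing_cols:
        raise ValueError(f"tsv-matrix {path} lacks columns {missing_cols}")
    sample_ids = [c for c in df.columns if c not in _META_COLS]
    if not sample_ids:
        raise ValueError(f"tsv-matrix {path} has no sample columns")
    meta = df[_META_COLS].copy()
    meta["pos"] = meta["pos"].astype(int)
    cells = df[sample_ids].to_numpy()
    dosages = np.empty(cells.shape, dtype=np.int16)
    n_missing = 0
    for (i, j), v in np.ndenumerate(cells):
        if v == ".":
            dosages[i, j] = MISSING
            n_missing += 1
        elif v in ("0", "1", "2"):
            dosages[i, j] = int(v)
        else:
            raise ValueError(
                f"malformed cell {v!r} at variant row {i + 2} of {path} "
                "(expected 0, 1, 2 or .)"
            )
    log = {"missing": n_missing, "source": str(path)}
    dosages = dosages.T.copy()  # file is variants x samples
    _flip_to_minor(dosages, meta, log)
    if n_missing:
        logger.info("%s: %d missing genotype cells", path, n_missing)
    return GenotypeMatrix(sample_ids, dosages, meta.reset_index(drop=True), log)


def _read_vcf(path, gene_map=None, gene_info_tag: str = "GENE") -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    sample_ids = list(vcf.samples)
    if not sample_ids:
        raise ValueError(f"VCF {path} contains no samples")
    columns, records = [], []
    n_missing = 0
    for var in vcf:
        genos = var.genotypes  # [[a1, a2, phased], ...]
        for ai, alt in enumerate(var.ALT, start=1):
            col = np.empty(len(sample_ids), dtype=np.int16)
            for s, g in enumerate(genos):
                alleles = [a for a in g[:-1] if a is not None]
                if any(a < 0 for a in alleles) or not alleles:
                    col[s] = MISSING
                    n_missing += 1
                else:
                    col[s] = sum(a == ai for a in alleles)
            key = variant_key(var.CHROM, var.POS, var.REF, alt)
            gene = ""
            if gene_map is not None:
                gene = gene_map.get(key, "")
            elif gene_info_tag:
                tag = var.INFO.get(gene_info_tag)
                if tag is not None:
                    gene = str(tag)
            columns.append(col)
            records.append(
                {
                    "variant_id": key,
                    "chrom": str(var.CHROM),
                    "pos": int(var.POS),
                    "ref": var.REF,
                    "alt": alt,
                    "gene": gene,
                }
            )
    if not records:
        raise ValueError(f"VCF {path} contains no variant records")
    meta = pd.DataFrame.from_records(records)
    dosages = np.column_stack(columns)
    log = {"missing": n_missing, "source": str(path)}
    _flip_to_minor(dosages, meta, log)
    if n_missing:
        logger.info("%s: %d missing genotypes", path, n_missing)
    return GenotypeMatrix(sample_ids, dosages, meta, log)


def read_genotypes(path, format: str | None = None, gene_map=None,
                   gene_info_tag: str = "GENE") -> GenotypeMatrix:
    """Read a genotype matrix from VCF or the TSV matrix dialect.

    ``format`` is ``"vcf"`` or ``"tsv-matrix"``; when omitted it is
    guessed from the file extension.  ``gene_map`` (variant key -> gene
    symbol) overrides the VCF INFO tag lookup.
    """
    if format is None:
        s = str(path)
        format = "vcf" if s.endswith((".vcf", ".vcf.gz")) else "tsv-matrix"
    if format == "vcf":
        return _read_vcf(path, gene_map=gene_map, gene_info_tag=gene_info_tag)
    if format == "tsv-matrix":
        return _read_tsv_matrix(path)
    raise ValueError(f"unknown genotype format {format!r}")


def write_genotypes(gm: GenotypeMatrix, path) -> None:
    """Write a GenotypeMatrix in the TSV matrix dialect (round-trip safe)."""
    cells = gm.dosages.T.astype(object)
    cells[cells == MISSING] = "."
    out = pd.concat(
        [gm.variant_meta.reset_index(drop=True),
         pd.DataFrame(cells, columns=gm.sample_ids)],
        axis=1,
    )
    out.to_csv(path, sep="\t", index=False)


def read_phenotypes(path, sample_ids=None, derive_from_bp: bool = False) -> PhenotypeVector:
    """Read a binary phenotype TSV (``sample_id status``).

    With ``derive_from_bp`` the file instead carries ``sample_id SBP DBP``
    and hypertension status is derived as SBP >= 140 or DBP >= 90 (the
    American Heart Association cutoffs).  If ``sample_ids`` is given the
    phenotypes are reordered to it; samples present on only one side are
    dropped with a logged count.
    """
    df = pd.read_csv(path, sep="\t")
    if derive_from_bp:
        for c in ("sample_id", "SBP", "DBP"):
            if c not in df.columns:
                raise ValueError(f"phenotype file {path} lacks column {c!r}")
        status = ((df["SBP"] >= 140) | (df["DBP"] >= 90)).astype(int)
    else:
        if "status" not in df.columns or "sample_id" not in df.columns:
            raise ValueError(f"phenotype file {path} needs sample_id and status columns")
        status = df["status"].astype(int)
        if not status.isin((0, 1)).all():
            raise ValueError("status column must be 0/1")
    pheno = dict(zip(df["sample_id"].astype(str), status))
    if sample_ids is not None:
        kept = [s for s in sample_ids if s in pheno]
        dropped = len(sample_ids) - len(kept) + len(pheno) - len(kept)
        if dropped:
            logger.warning("dropped %d samples absent from genotypes or phenotypes", dropped)
        pheno = {s: pheno[s] for s in kept}
    if not pheno:
        raise ValueError("no samples shared between genotypes and phenotypes")
    return PhenotypeVector(list(pheno), np.fromiter(pheno.values(), dtype=np.int8))


def read_annotation(path) -> AnnotationTable:
    """Read an annotation TSV: ``chrom pos ref alt category [weight]``."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    for c in ("chrom", "pos", "ref", "alt", "category"):
        if c not in df.columns:
            raise ValueError(f"annotation file {path} lacks column {c!r}")
    return AnnotationTable(df)


def align_cohort(gm: GenotypeMatrix, ph: PhenotypeVector):
    """Restrict genotypes and phenotypes to their shared samples, in genotype order."""
    shared = [s for s in gm.sample_ids if s in set(ph.sample_ids)]
    if len(shared) < gm.n_samples or len(shared) < len(ph.sample_ids):
        logger.warning(
            "alignment dropped %d genotype and %d phenotype samples",
            gm.n_samples - len(shared), len(ph.sample_ids) - len(shared),
        )
    index = {s: i for i, s in enumerate(ph.sample_ids)}
    status = ph.status[[index[s] for s in shared]]
    return gm.subset_samples(shared), PhenotypeVector(shared, status)


def build_gene_units(gm: GenotypeMatrix, ph: PhenotypeVector,
                     ann: AnnotationTable | None = None,
                     missing_policy: str = "as-ref") -> list[GeneUnit]:
    """Group variant columns into per-gene analysis units.

    Missing dosages are resolved here: policy ``"as-ref"`` (default) sets
    them to 0 minor alleles — conservative for burden scores and keeps
    unit-weight scores integer-valued; ``"mean-impute"`` substitutes the
    per-variant mean of observed dosages.  Variants lacking an annotation
    row get category ``OTHER``.  Genes with all-constant columns are
    retained (tests return a degenerate result downstream, not an error).
    """
    if gm.sample_ids != ph.sample_ids:
        raise ValueError("genotypes and phenotypes are not aligned; call align_cohort")
    if missing_policy not in ("as-ref", "mean-impute"):
        raise ValueError(f"unknown missing policy {missing_policy!r}")
    units = []
    meta = gm.variant_meta
    for gene in meta["gene"].loc[meta["gene"] != ""].unique():
        idx = np.flatnonzero((meta["gene"] == gene).to_numpy())
        sub = gm.dosages[:, idx].astype(float)
        miss = sub == MISSING
        n_missing = int(miss.sum())
        if n_missing:
            if missing_policy == "as-ref":
                sub[miss] = 0.0
            else:
                for j in range(sub.shape[1]):
                    col = sub[:, j]
                    obs = col[~miss[:, j]]
                    col[miss[:, j]] = obs.mean() if obs.size else 0.0
            logger.info("gene %s: resolved %d missing dosages (%s)",
                        gene, n_missing, missing_policy)
        keys = meta["variant_id"].iloc[idx].tolist()
        full_keys = [
            variant_key(meta["chrom"].iloc[j], meta["pos"].iloc[j],
                        meta["ref"].iloc[j], meta["alt"].iloc[j])
            for j in idx
        ]
        if ann is not None:
            cats = np.array([ann.category(fk, k) for fk, k in zip(full_keys, keys)])
            expw = np.array([ann.weight(fk, k) for fk, k in zip(full_keys, keys)])
        else:
            cats = np.full(len(keys), "OTHER", dtype=object)
            expw = np.full(len(keys), np.nan)
        units.append(
            GeneUnit(
                gene=str(gene),
                dosages=sub,
                variant_ids=keys,
                positions=meta["pos"].iloc[idx].to_numpy(),
                categories=cats,
                explicit_weights=expw,
                n_missing=n_missing,
            )
        )
    return units
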