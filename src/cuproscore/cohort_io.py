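"""Expression/clinical/gene-set I/O, unit conversion, cohort merging and
clinical baseline summaries.

All tabular formats are plain TSV (UTF-8, ``.`` decimal): expression matrices
are written genes-as-rows with a header row of sample ids; clinical tables are
one row per sample. Gene sets use the MSigDB GMT convention
(``name<TAB>description<TAB>gene1<TAB>gene2...``). Writers preserve input
row/column order so outputs are deterministic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

VALID_UNITS = ("FPKM", "TPM", "log2TPM1")

REQUIRED_CLINICAL = ("time", "event")


@dataclass
class ExpressionMatrix:
    """Gene-by-sample expression matrix with a declared unit scale.

    Parameters
    ----------
    values
        DataFrame with gene ids as index and sample ids as columns.
    unit
        One of ``FPKM``, ``TPM`` or ``log2TPM1`` (log2(TPM+1)).
    batch
        Optional per-sample batch labels (indexed by sample id).
    """

    values: pd.DataFrame
    unit: str
    batch: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.unit not in VALID_UNITS:
            raise ValueError(f"unknown unit {self.unit!r}; expected one of {VALID_UNITS}")
        idx = self.values.index
        if idx.has_duplicates:
            dups = idx[idx.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene ids: {dups}")
        cols = self.values.columns
        if cols.has_duplicates:
            dups = cols[cols.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dups}")
        arr = self.values.to_numpy()
        if not np.isfinite(arr).all():
            raise ValueError("expression values must be finite")
        if self.batch is not None:
            self.batch = pd.Series(self.batch).reindex(cols)
            if self.batch.isna().any():
                missing = self.batch.index[self.batch.isna()].tolist()
                raise ValueError(f"batch label missing for samples: {missing}")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def subset_genes(self, genes) -> "ExpressionMatrix":
        missing = [g for g in genes if g not in self.values.index]
        if missing:
            raise KeyError(f"genes absent from matrix: {missing}")
        return ExpressionMatrix(self.values.loc[list(genes)], self.unit, self.batch)


@dataclass
class ClinicalTable:
    """Per-sample survival and categorical covariates.

    ``data`` is indexed by sample id and must contain ``time`` (days, > 0)
    and ``event`` (0 = censored, 1 = event). Any further columns are treated
    as categorical covariates (grade, T/N/M, stage, batch, ...).
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dups}")
        for col in REQUIRED_CLINICAL:
            if col not in self.data.columns:
                raise ValueError(f"clinical table missing required column {col!r}")
        time = pd.to_numeric(self.data["time"])
        if (time <= 0).any():
            bad = self.data.index[time <= 0].tolist()
            raise ValueError(f"non-positive survival times for samples: {bad}")
        event = self.data["event"]
        if not event.isin([0, 1]).all():
            raise ValueError("event flag must be 0 or 1")

    @property
    def samples(self) -> list[str]:
        return list(self.data.index)

    @property
    def time(self) -> np.ndarray:
        return self.data["time"].to_numpy(dtype=float)

    @property
    def event(self) -> np.ndarray:
        return self.data["event"].to_numpy(dtype=int)


@dataclass
class GeneSetCollection:
    """Named gene sets with optional descriptions."""

    sets: dict[str, list[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if len(genes) == 0:
                raise ValueError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]

    def items(self):
        return self.sets.items()


def read_expression(path, unit: str = "log2TPM1") -> ExpressionMatrix:
    """Read a genes-as-rows TSV expression matrix.

    First column holds gene ids, header row holds sample ids.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate gene ids in {path}: {dups}")
    try:
        values = df.astype(float)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"non-numeric expression value in {path}: {exc}") from exc
    return ExpressionMatrix(values, unit)


def write_expression(matrix: ExpressionMatrix, path) -> None:
    matrix.values.to_csv(path, sep="\t", index_label="gene")


def read_clinical(path) -> ClinicalTable:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return ClinicalTable(df)


def write_clinical(clinical: ClinicalTable, path) -> None:
    clinical.data.to_csv(path, sep="\t", index_label="sample")


def fpkm_to_tpm(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Convert FPKM to TPM: per sample, TPM_g = FPKM_g / sum(FPKM) * 1e6.

    Every column of the result sums to 1e6.
    """
    if matrix.unit != "FPKM":
        raise ValueError(f"expected FPKM input, got {matrix.unit}")
    colsum = matrix.values.sum(axis=0)
    zero = colsum.index[colsum <= 0].tolist()
    if zero:
        raise ValueError(f"samples with non-positive FPKM sum: {zero}")
    tpm = matrix.values.div(colsum, axis=1) * 1e6
    return ExpressionMatrix(tpm, "TPM", matrix.batch)


def log_transform(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """log2(TPM + 1). The 1e6 column-sum invariant is *not* preserved."""
    if matrix.unit != "TPM":
        raise ValueError(f"expected TPM input, got {matrix.unit}")
    if (matrix.values.to_numpy() < 0).any():
        raise ValueError("negative values are not valid TPM")
    return ExpressionMatrix(np.log2(matrix.values + 1.0), "log2TPM1", matrix.batch)


def merge_cohorts(
    cohorts: list[tuple[ExpressionMatrix, ClinicalTable]],
) -> tuple[ExpressionMatrix, ClinicalTable]:
    """Merge cohorts on the intersection of their gene universes.

    Samples lacking survival time or event are dropped (count logged); the
    batch label of each retained sample is set to its cohort index. Sample
    ids must be globally unique across cohorts.
    """
    if len(cohorts) < 2:
        raise ValueError("need at least 2 cohorts to merge")
    units = {m.unit for m, _ in cohorts}
    if len(units) > 1:
        raise ValueError(f"incompatible unit tags: {sorted(units)}")
    genes = None
    for m, _ in cohorts:
        genes = set(m.genes) if genes is None else genes & set(m.genes)
    if not genes:
        raise ValueError("empty gene intersection across cohorts")
    # keep gene order of the first cohort
    gene_order = [g for g in cohorts[0][0].genes if g in genes]

    seen: set[str] = set()
    expr_parts, clin_parts, batch_parts = [], [], []
    n_excluded = 0
    for i, (m, c) in enumerate(cohorts):
        collide = seen & set(m.samples)
        if collide:
            raise ValueError(f"sample id collision across cohorts: {sorted(collide)}")
        seen |= set(m.samples)
        clin = c.data.reindex(m.samples)
        ok = clin["time"].notna() & clin["event"].notna()
        n_excluded += int((~ok).sum())
        kept = clin.index[ok]
        expr_parts.append(m.values.loc[gene_order, kept])
        clin_kept = clin.loc[kept].copy()
        clin_kept["batch"] = i
        clin_parts.append(clin_kept)
        batch_parts.append(pd.Series(i, index=kept))
    if n_excluded:
        logger.info("%d sample%s excluded for incomplete survival data",
                    n_excluded, "" if n_excluded == 1 else "s")
    values = pd.concat(expr_parts, axis=1)
    batch = pd.concat(batch_parts)
    merged_unit = cohorts[0][0].unit
    return (
        ExpressionMatrix(values, merged_unit, batch),
        ClinicalTable(pd.concat(clin_parts, axis=0)),
    )


def summarize_clinical(clinical: ClinicalTable, covariates: list[str]) -> dict[str, pd.DataFrame]:
    """Baseline table: per covariate, category counts and percentages.

    Percentages are computed over non-missing samples only and rounded to
    one decimal, so each covariate's percentages sum to 100 up to rounding.
    """
    out: dict[str, pd.DataFrame] = {}
    for cov in covariates:
        if cov not in clinical.data.columns:
            raise KeyError(f"unknown covariate {cov!r}")
        col = clinical.data[cov].dropna()
        counts = col.value_counts(sort=False)
        pct = (counts / counts.sum() * 100).round(1)
        out[cov] = pd.DataFrame({"count": counts, "percent": pct})
    return out


def baseline_percentages(counts: list[int]) -> list[float]:
    """Percentages (1-decimal) for a vector of category counts."""
    total = sum(counts)
    if total <= 0:
        raise ValueError("counts must sum to a positive total")
    return [round(c / total * 100, 1) for c in counts]


def read_gmt(path) -> GeneSetCollection:
    """Read gene sets in MSigDB GMT format."""
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line needs >= 3 fields")
            name, desc, *genes = fields
            genes = [g for g in genes if g]
            if not genes:
                raise ValueError(f"{path}:{lineno}: gene set {name!r} has no genes")
            if name in sets:
                raise ValueError(f"{path}:{lineno}: duplicate set name {name!r}")
            sets[name] = genes
            descriptions[name] = desc
    return GeneSetCollection(sets, descriptions)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name, genes in collection.items():
            desc = collection.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *genes]) + "\n")
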