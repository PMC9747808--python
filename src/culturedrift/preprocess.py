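"""Bulk expression preprocessing: loading, normalization, filtering, harmonization.

Expression matrices are genes x samples tables on either the TPM scale or the
log2(TPM + 1) scale.  The preprocessing contract is:

1. log2(TPM + 1) transform, averaging duplicate gene rows after the transform;
2. drop genes with zeros in >= 80% of samples, then drop the 20% lowest-variance
   survivors (both fractions configurable);
3. harmonize the tumor and cell-line cohorts to their shared gene set and shared
   disease codes before any cross-cohort statistics are computed.

Sample-level subsetting (non-silent mutation carriers, arbitrary sample panels)
operates on the harmonized matrix.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

TPM = "tpm"
LOG2_TPM1 = "log2_tpm1"

# MAF variant classifications we recognise; anything not "Silent" counts as
# non-silent for mutation subsetting.
VARIANT_CLASSIFICATIONS = frozenset(
    {
        "Silent",
        "Missense_Mutation",
        "Nonsense_Mutation",
        "Nonstop_Mutation",
        "Frame_Shift_Del",
        "Frame_Shift_Ins",
        "In_Frame_Del",
        "In_Frame_Ins",
        "Splice_Site",
        "Translation_Start_Site",
    }
)


class PreprocessError(ValueError):
    """Raised when an expression matrix violates a preprocessing contract."""


@dataclass
class ExpressionMatrix:
    """Genes x samples expression values with an explicit scale flag.

    Parameters
    ----------
    values
        DataFrame indexed by gene id with one column per sample id.
    scale
        Either ``"tpm"`` (raw, nonnegative) or ``"log2_tpm1"``.
    metadata
        Optional per-sample metadata (indexed by sample id) carrying at least
        ``cohort`` and ``disease_code`` columns.
    """

    values: pd.DataFrame
    scale: str = TPM
    metadata: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.scale not in (TPM, LOG2_TPM1):
            raise PreprocessError(f"unknown scale {self.scale!r}")
        if not np.isfinite(self.values.to_numpy(dtype=float)).all():
            raise PreprocessError("expression values must be finite")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def sample_meta(self) -> pd.DataFrame:
        if self.metadata is None:
            raise PreprocessError("matrix carries no sample metadata")
        return self.metadata.loc[self.sample_ids]


@dataclass
class FilterReport:
    n_input: int
    n_zero_removed: int
    n_lowvar_removed: int

    @property
    def n_output(self) -> int:
        return self.n_input - self.n_zero_removed - self.n_lowvar_removed


@dataclass
class HarmonizeReport:
    n_genes_dropped_tumor: int
    n_genes_dropped_cellline: int
    n_samples_dropped: int
    diseases: list[str] = field(default_factory=list)


@dataclass
class BiotypePartition:
    coding: set[str]
    lncRNA: set[str]
    unannotated: set[str]


def normalize_expression(raw: ExpressionMatrix) -> ExpressionMatrix:
    """log2(TPM + 1) transform followed by duplicate-gene averaging.

    Duplicate rows (same gene id) are averaged *after* the log transform, so a
    gene measured twice contributes the mean of its log-scale profiles.
    """
    if raw.scale != TPM:
        raise PreprocessError(f"expected scale {TPM!r}, got {raw.scale!r}")
    if raw.values.size == 0:
        raise PreprocessError("empty expression matrix")
    arr = raw.values.to_numpy(dtype=float)
    if (arr < 0).any():
        g, s = np.argwhere(arr < 0)[0]
        raise PreprocessError(
            f"negative TPM value at gene {raw.values.index[g]!r}, "
            f"sample {raw.values.columns[s]!r}"
        )
    logged = pd.DataFrame(
        np.log2(arr + 1.0), index=raw.values.index, columns=raw.values.columns
    )
    if logged.index.has_duplicates:
        logged = logged.groupby(level=0, sort=False).mean()
    return ExpressionMatrix(values=logged, scale=LOG2_TPM1, metadata=raw.metadata)


def filter_genes(
    m: ExpressionMatrix,
    zero_frac_remove: float = 0.8,
    low_var_frac: float = 0.2,
) -> tuple[ExpressionMatrix, FilterReport]:
    """Two-stage gene filter: zero-fraction removal, then low-variance removal.

    Stage 1 removes every gene whose fraction of exactly-zero samples is
    ``>= zero_frac_remove`` (inclusive).  Stage 2 ranks the survivors by
    variance and removes the ``floor(low_var_frac * n_survivors)`` lowest,
    breaking variance ties by gene id so the result is deterministic.
    """
    if m.scale != LOG2_TPM1:
        raise PreprocessError(f"expected scale {LOG2_TPM1!r}, got {m.scale!r}")
    for name, frac in (("zero_frac_remove", zero_frac_remove), ("low_var_frac", low_var_frac)):
        if not 0.0 <= frac <= 1.0:
            raise PreprocessError(f"{name} must lie in [0, 1], got {frac}")

    n_input = m.values.shape[0]
    zero_frac = (m.values == 0).mean(axis=1)
    keep = m.values.loc[zero_frac < zero_frac_remove]
    n_zero_removed = n_input - keep.shape[0]

    n_drop = math.floor(low_var_frac * keep.shape[0])
    if n_drop > 0:
        variance = keep.var(axis=1, ddof=1)
        order = sorted(keep.index, key=lambda g: (variance[g], g))
        dropped = set(order[:n_drop])
        keep = keep.loc[[g for g in keep.index if g not in dropped]]
    report = FilterReport(n_input, n_zero_removed, n_drop)
    return ExpressionMatrix(keep, scale=LOG2_TPM1, metadata=m.metadata), report


def harmonize_cohorts(
    tumor: ExpressionMatrix,
    cellline: ExpressionMatrix,
    meta: pd.DataFrame,
) -> tuple[ExpressionMatrix, pd.Series, HarmonizeReport]:
    """Merge the two cohorts on shared genes and shared disease codes.

    ``meta`` is indexed by sample id with ``cohort`` in {"tumor", "cell_line"}
    and a ``disease_code`` column.  The merged matrix keeps the sorted gene
    intersection; samples are restricted to disease codes present in both
    cohorts.  Returns the merged matrix, a binary cohort label per sample
    ("tumor"/"cell_line"), and a report of what was dropped.
    """
    for m, name in ((tumor, "tumor"), (cellline, "cellline")):
        if m.scale != LOG2_TPM1:
            raise PreprocessError(f"{name} matrix not on {LOG2_TPM1!r} scale")
    genes = sorted(set(tumor.gene_ids) & set(cellline.gene_ids))
    if not genes:
        raise PreprocessError("no genes shared between cohorts")

    missing = [s for s in tumor.sample_ids + cellline.sample_ids if s not in meta.index]
    if missing:
        raise PreprocessError(f"samples missing from metadata: {missing[:5]}")
    t_dis = set(meta.loc[tumor.sample_ids, "disease_code"])
    c_dis = set(meta.loc[cellline.sample_ids, "disease_code"])
    shared = sorted(t_dis & c_dis)
    if not shared:
        raise PreprocessError(
            f"no diseases shared between cohorts (tumor: {sorted(t_dis)}, "
            f"cell line: {sorted(c_dis)})"
        )
    keep_t = [s for s in tumor.sample_ids if meta.at[s, "disease_code"] in shared]
    keep_c = [s for s in cellline.sample_ids if meta.at[s, "disease_code"] in shared]
    merged = pd.concat(
        [tumor.values.loc[genes, keep_t], cellline.values.loc[genes, keep_c]], axis=1
    )
    if merged.columns.has_duplicates:
        raise PreprocessError("cohorts share sample ids")
    labels = pd.Series(
        ["tumor"] * len(keep_t) + ["cell_line"] * len(keep_c),
        index=merged.columns,
        name="cohort",
    )
    report = HarmonizeReport(
        n_genes_dropped_tumor=len(tumor.gene_ids) - len(genes),
        n_genes_dropped_cellline=len(cellline.gene_ids) - len(genes),
        n_samples_dropped=(len(tumor.sample_ids) - len(keep_t))
        + (len(cellline.sample_ids) - len(keep_c)),
        diseases=shared,
    )
    out = ExpressionMatrix(merged, scale=LOG2_TPM1, metadata=meta.loc[merged.columns])
    return out, labels, report


def subset_by_mutation(
    m: ExpressionMatrix, mutations: pd.DataFrame, gene_symbol: str
) -> ExpressionMatrix:
    """Keep samples carrying at least one non-silent variant in ``gene_symbol``.

    ``mutations`` is a MAF-like table with columns ``Tumor_Sample_Barcode``,
    ``Hugo_Symbol`` and ``Variant_Classification``.  Samples absent from the
    table are treated as wild-type (MAF files only list variants).
    """
    hits = mutations[
        (mutations["Hugo_Symbol"] == gene_symbol)
        & (mutations["Variant_Classification"] != "Silent")
    ]
    if gene_symbol not in set(mutations["Hugo_Symbol"]):
        warnings.warn(f"gene {gene_symbol!r} absent from mutation table", stacklevel=2)
    carriers = set(hits["Tumor_Sample_Barcode"])
    keep = [s for s in m.sample_ids if s in carriers]
    meta = m.metadata.loc[keep] if m.metadata is not None else None
    return replace(m, values=m.values[keep], metadata=meta)


def partition_by_biotype(genes, annotation: pd.DataFrame) -> BiotypePartition:
    """Split a gene set into coding and lncRNA per the annotation table.

    ``annotation`` is indexed by gene id with a ``biotype`` column holding
    "coding" or "lncRNA".  Unannotated genes are excluded with a warning.
    """
    genes = set(genes)
    known = genes & set(annotation.index)
    unannotated = genes - known
    if unannotated:
        warnings.warn(
            f"{len(unannotated)} gene(s) lack a biotype annotation and were excluded",
            stacklevel=2,
        )
    biotype = annotation.loc[sorted(known), "biotype"]
    bad = set(biotype) - {"coding", "lncRNA"}
    if bad:
        raise PreprocessError(f"unknown biotype value(s): {sorted(bad)}")
    return BiotypePartition(
        coding=set(biotype.index[biotype == "coding"]),
        lncRNA=set(biotype.index[biotype == "lncRNA"]),
        unannotated=unannotated,
    )


# ---------------------------------------------------------------------------
# File formats


def read_expression_tsv(path, scale: str = TPM) -> ExpressionMatrix:
    """Read a Xena-style expression TSV (first column gene id, header = samples).

    A GCT header (``#1.2`` version line plus a dimensions line) is tolerated
    and skipped, as is a GCT ``Description`` column.
    """
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("#1.2"):
            fh.readline()  # dimensions line
            df = pd.read_csv(fh, sep="\t", index_col=0)
            if "Description" in df.columns:
                df = df.drop(columns="Description")
        else:
            fh.seek(0)
            df = pd.read_csv(fh, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.index.name = None
    return ExpressionMatrix(df.astype(float), scale=scale)


def write_expression_tsv(m: ExpressionMatrix, path) -> None:
    m.values.to_csv(path, sep="\t", index_label="gene_id")


def read_sample_sheet(path) -> pd.DataFrame:
    """Read per-sample metadata TSV indexed by its first (sample id) column."""
    meta = pd.read_csv(path, sep="\t", index_col=0)
    if meta.index.has_duplicates:
        raise PreprocessError("duplicate sample ids in sample sheet")
    return meta


def read_mutation_table(path) -> pd.DataFrame:
    """Read a MAF-like tab-separated mutation table (``#`` comments skipped)."""
    maf = pd.read_csv(path, sep="\t", comment="#")
    required = {"Tumor_Sample_Barcode", "Hugo_Symbol", "Variant_Classification"}
    missing = required - set(maf.columns)
    if missing:
        raise PreprocessError(f"mutation table missing columns: {sorted(missing)}")
    return maf


def read_gene_annotation(path) -> pd.DataFrame:
    ann = pd.read_csv(path, sep="\t", index_col=0)
    if ann.index.has_duplicates:
        raise PreprocessError("duplicate gene ids in annotation")
    return ann
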