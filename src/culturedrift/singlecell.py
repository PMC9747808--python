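"""Single-cell comparison stage: QC, clustering/typing, marker detection.

The workflow mirrors the standard droplet scRNA-seq toolkit path on an
AnnData of raw integer counts (cells x genes): QC removes cells detecting too
many genes or too many mitochondrial genes, counts are depth-normalized to
the median library size and log1p-transformed, cells are embedded with PCA,
connected in a nearest-neighbor graph and partitioned with Leiden community
detection, and each cluster is typed by the marker signature with the highest
mean scaled expression.  Tumor-versus-cell-line marker genes come from a
one-sided Wilcoxon rank-sum test, and per-sample top gene lists are scored
against molecular-subtype signatures with the hypergeometric upper tail.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scanpy as sc
from anndata import AnnData
from scipy import stats

from .enrichment import hypergeom_pvalue


class SingleCellError(ValueError):
    pass


@dataclass
class SignatureSet:
    """Named gene signatures (cell-type markers or molecular subtypes)."""

    signatures: dict[str, frozenset[str]]

    def __post_init__(self) -> None:
        self.signatures = {k: frozenset(v) for k, v in self.signatures.items()}
        for name, genes in self.signatures.items():
            if not genes:
                raise SingleCellError(f"signature {name!r} is empty")

    def __len__(self) -> int:
        return len(self.signatures)

    def names(self) -> list[str]:
        return sorted(self.signatures)


@dataclass
class QCReport:
    n_input: int
    n_removed_genes: int  # cells over the detected-genes ceiling
    n_removed_mito: int  # cells over the mitochondrial ceiling
    n_kept: int


def qc_filter_cells(
    adata: AnnData,
    max_genes: float = 5000,
    mito_threshold: float = 30,
    mito_metric: str = "n_genes",
) -> tuple[AnnData, QCReport]:
    """Remove cells detecting too many genes and/or too much mitochondrial signal.

    A cell is removed when its number of detected (nonzero) genes exceeds
    ``max_genes`` OR its mitochondrial metric exceeds ``mito_threshold``.
    ``mito_metric`` is either ``"n_genes"`` (count of distinct mitochondrial
    genes detected) or ``"percent_counts"`` (percent of counts assigned to
    mitochondrial genes).  Mitochondrial genes are flagged by the boolean
    ``adata.var["mito"]`` column.
    """
    if mito_metric not in ("n_genes", "percent_counts"):
        raise SingleCellError(f"unknown mito_metric {mito_metric!r}")
    X = _dense(adata)
    n_detected = (X > 0).sum(axis=1)
    mito_filtering = np.isfinite(mito_threshold)
    if "mito" in adata.var.columns:
        mito_mask = adata.var["mito"].to_numpy(dtype=bool)
    else:
        mito_mask = np.zeros(adata.n_vars, dtype=bool)
    if mito_filtering and not mito_mask.any():
        raise SingleCellError(
            "mitochondrial filtering requested but no genes are flagged mito"
        )
    if mito_metric == "n_genes":
        mito_values = (X[:, mito_mask] > 0).sum(axis=1) if mito_mask.any() else np.zeros(adata.n_obs)
    else:
        total = X.sum(axis=1)
        total[total == 0] = 1.0
        mito_values = 100.0 * X[:, mito_mask].sum(axis=1) / total

    over_genes = n_detected > max_genes
    over_mito = mito_values > mito_threshold if mito_filtering else np.zeros(adata.n_obs, dtype=bool)
    keep = ~(over_genes | over_mito)
    if not keep.any():
        warnings.warn("QC removed every cell", stacklevel=2)
    out = adata[keep].copy()
    out.obs["n_genes_detected"] = n_detected[keep]
    out.obs["mito_metric"] = mito_values[keep]
    report = QCReport(
        n_input=adata.n_obs,
        n_removed_genes=int(over_genes.sum()),
        n_removed_mito=int(over_mito.sum()),
        n_kept=int(keep.sum()),
    )
    return out, report


def normalize_log(adata: AnnData) -> AnnData:
    """Depth-normalize to the median library size, then log1p (in place)."""
    sc.pp.normalize_total(adata, target_sum=None)
    sc.pp.log1p(adata)
    return adata


def cluster_and_type(
    adata: AnnData,
    markers: SignatureSet,
    n_pcs: int = 40,
    resolution: float = 1.0,
    n_neighbors: int = 15,
    seed: int = 0,
) -> AnnData:
    """Leiden clustering on a PCA embedding, then marker-based cluster typing.

    Counts are normalized and log-transformed internally (raw counts kept in
    a layer).  Each cluster receives the label of the marker set with the
    highest mean z-scaled expression over its cells, ties broken by name.
    Writes ``obs["cluster"]`` (contiguous string categories from 0) and
    ``obs["cell_type"]``.
    """
    adata = adata.copy()
    adata.layers["counts"] = adata.X.copy()
    normalize_log(adata)
    n_pcs_eff = min(n_pcs, adata.n_obs - 1, adata.n_vars - 1)
    if n_pcs_eff < n_pcs:
        warnings.warn(f"reducing n_pcs from {n_pcs} to {n_pcs_eff}", stacklevel=2)
    sc.pp.pca(adata, n_comps=n_pcs_eff, random_state=seed)
    sc.pp.neighbors(adata, n_neighbors=n_neighbors, n_pcs=n_pcs_eff, random_state=seed)
    sc.tl.leiden(
        adata,
        resolution=resolution,
        random_state=seed,
        key_added="cluster",
        flavor="leidenalg",
    )

    # z-scale genes on the log-normalized data for marker scoring
    X = _dense(adata)
    mu = X.mean(axis=0, keepdims=True)
    sd = X.std(axis=0, keepdims=True)
    sd[sd == 0] = 1.0
    Z = (X - mu) / sd
    gene_pos = {g: i for i, g in enumerate(adata.var_names)}

    labels = {}
    for cluster in adata.obs["cluster"].cat.categories:
        cells = (adata.obs["cluster"] == cluster).to_numpy()
        scores = {}
        for name in markers.names():
            cols = [gene_pos[g] for g in markers.signatures[name] if g in gene_pos]
            scores[name] = Z[np.ix_(cells, cols)].mean() if cols else -np.inf
        # highest score wins; ties resolved toward the lexicographically
        # smallest signature name
        labels[cluster] = min(markers.names(), key=lambda s: (-scores[s], s))
    adata.obs["cell_type"] = adata.obs["cluster"].map(labels).astype("category")
    return adata


def rank_sum_top_genes(
    values_a: pd.DataFrame | np.ndarray,
    values_b: pd.DataFrame | np.ndarray,
    gene_names=None,
    top_n: int = 100,
) -> pd.DataFrame:
    """One-sided Wilcoxon rank-sum scan for genes up in group A versus group B.

    Inputs are cells x genes matrices of normalized log counts.  Genes are
    ranked by p-value ascending, ties broken by effect size (difference of
    group means, descending) then by gene name; the ``top_n`` head of the
    ranking is returned with BH-adjusted q-values computed over all genes.
    """
    A = np.asarray(values_a, dtype=float)
    B = np.asarray(values_b, dtype=float)
    if gene_names is None:
        if isinstance(values_a, pd.DataFrame):
            gene_names = list(values_a.columns)
        else:
            raise SingleCellError("gene_names required for array input")
    if A.shape[0] < 3 or B.shape[0] < 3:
        raise SingleCellError("both groups need >= 3 cells")
    if A.shape[1] != B.shape[1]:
        raise SingleCellError("gene dimensions differ between groups")

    exact = A.shape[0] <= 5 and B.shape[0] <= 5
    res = stats.mannwhitneyu(
        A, B, alternative="greater", axis=0,
        method="exact" if exact else "asymptotic",
    )
    pvals = np.atleast_1d(res.pvalue)
    effect = A.mean(axis=0) - B.mean(axis=0)
    from statsmodels.stats.multitest import multipletests

    _, qvals, _, _ = multipletests(pvals, method="fdr_bh")
    table = pd.DataFrame(
        {"gene": gene_names, "p": pvals, "q": qvals, "effect": effect}
    )
    table = table.sort_values(
        ["p", "effect", "gene"], ascending=[True, False, True]
    ).reset_index(drop=True)
    return table.head(top_n)


def signature_enrichment(
    top_genes_per_sample: dict[str, list[str] | frozenset[str]],
    signatures: SignatureSet,
    universe,
) -> pd.DataFrame:
    """Hypergeometric -log10 p matrix of per-sample top genes vs signatures.

    Rows are samples, columns signature names; each entry is -log10 of the
    upper-tail p-value for the overlap of the sample's top gene list with the
    signature, both intersected with the universe.
    """
    universe = frozenset(universe)
    if not universe:
        raise SingleCellError("empty universe")
    rows = {}
    for sample in sorted(top_genes_per_sample):
        query = frozenset(top_genes_per_sample[sample]) & universe
        row = {}
        for name in signatures.names():
            sig = signatures.signatures[name] & universe
            p = hypergeom_pvalue(len(query & sig), len(query), len(sig), len(universe))
            row[name] = float(-np.log10(p)) + 0.0 if p > 0 else np.inf
        rows[sample] = row
    return pd.DataFrame.from_dict(rows, orient="index")[signatures.names()]


def _dense(adata: AnnData) -> np.ndarray:
    X = adata.X
    return np.asarray(X.todense()) if hasattr(X, "todense") else np.asarray(X)


# ---------------------------------------------------------------------------
# I/O


def read_signatures_gmt(path) -> SignatureSet:
    """Read signatures from GMT (name, description, member genes)."""
    sigs: dict[str, frozenset[str]] = {}
    with open(path) as fh:
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            if len(fields) >= 3:
                sigs[fields[0]] = frozenset(g for g in fields[2:] if g)
    return SignatureSet(sigs)


def read_counts(path_or_dir, mito_prefix: str = "MT-") -> AnnData:
    """Read a counts matrix from an MTX directory or a dense TSV.

    MTX directories follow the CellRanger layout (``matrix.mtx``,
    ``barcodes.tsv``, ``features.tsv`` or ``genes.tsv``); dense TSVs are
    genes x cells with gene ids in the first column.  Genes whose symbol
    starts with ``mito_prefix`` are flagged in ``var["mito"]``.
    """
    import os

    if os.path.isdir(path_or_dir):
        adata = sc.read_10x_mtx(path_or_dir)
    else:
        df = pd.read_csv(path_or_dir, sep="\t", index_col=0)
        adata = AnnData(
            X=df.to_numpy(dtype=float).T,
            obs=pd.DataFrame(index=df.columns.astype(str)),
            var=pd.DataFrame(index=df.index.astype(str)),
        )
    adata.var["mito"] = [g.startswith(mito_prefix) for g in adata.var_names]
    return adata
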