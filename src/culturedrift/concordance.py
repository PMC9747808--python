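"""Group-difference and tumor/cell-line concordance statistics.

Protein (or any feature-level) group comparisons use the two-sided
Mann-Whitney U test, exact when the product of group sizes is small enough to
enumerate and the data are tie-free, otherwise the normal approximation with
tie correction.  Pathway-level concordance is the distribution of pairwise
Spearman correlations between every tumor sample and every cell-line sample
within a disease, computed over the pathway's genes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


class ConcordanceError(ValueError):
    pass


@dataclass
class GroupComparison:
    feature: str
    n_x: int
    n_y: int
    u_statistic: float  # U of the first group
    p_value: float
    direction: str  # "x", "y" or "tie": which group has the higher median
    stars: str = ""


@dataclass
class ConcordanceResult:
    disease: str
    pathway: str
    correlations: np.ndarray  # one rho per (tumor sample, cell-line sample) pair
    mean_rho: float = field(init=False)

    def __post_init__(self) -> None:
        self.mean_rho = float(np.mean(self.correlations))


def _significance_stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def mannwhitney_compare(
    x, y, feature: str = "", exact_max_product: int = 400
) -> GroupComparison:
    """Two-sided Mann-Whitney U comparison of two groups.

    The exact null distribution is used when ``n_x * n_y <= exact_max_product``
    and the pooled data are tie-free; otherwise the normal approximation with
    tie correction applies.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ConcordanceError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < pooled.size
    method = "exact" if (x.size * y.size <= exact_max_product and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    mx, my = np.median(x), np.median(y)
    direction = "x" if mx > my else ("y" if my > mx else "tie")
    p = min(float(res.pvalue), 1.0)
    return GroupComparison(
        feature=feature,
        n_x=int(x.size),
        n_y=int(y.size),
        u_statistic=float(res.statistic),
        p_value=p,
        direction=direction,
        stars=_significance_stars(p),
    )


def pairwise_pathway_correlation(
    tumor_values: pd.DataFrame,
    cellline_values: pd.DataFrame,
    pathway_genes,
    tumor_disease: pd.Series,
    cellline_disease: pd.Series,
    pathway_name: str = "",
) -> list[ConcordanceResult]:
    """Per-disease pairwise Spearman correlations over a pathway's genes.

    For each disease present in both cohorts, every (tumor sample, cell-line
    sample) pair contributes one Spearman rho computed on the shared pathway
    genes.  Results are sorted by mean rho descending (ties by disease code).
    """
    shared = sorted(
        frozenset(pathway_genes) & set(tumor_values.index) & set(cellline_values.index)
    )
    n_missing = len(frozenset(pathway_genes)) - len(shared)
    if n_missing:
        warnings.warn(f"{n_missing} pathway gene(s) missing from a matrix", stacklevel=2)
    if len(shared) < 3:
        raise ConcordanceError(
            f"need >= 3 shared pathway genes, got {len(shared)}"
        )
    diseases = sorted(set(tumor_disease) & set(cellline_disease))
    results = []
    for disease in diseases:
        t_cols = tumor_disease.index[tumor_disease == disease]
        c_cols = cellline_disease.index[cellline_disease == disease]
        # Spearman = Pearson on ranks; ranking each sample's gene vector once
        # lets all pairs be computed as a single matrix product.
        t_ranks = tumor_values.loc[shared, t_cols].rank(axis=0).to_numpy()
        c_ranks = cellline_values.loc[shared, c_cols].rank(axis=0).to_numpy()

        def _standardize(r):
            r = r - r.mean(axis=0, keepdims=True)
            denom = np.sqrt((r**2).sum(axis=0, keepdims=True))
            denom[denom == 0] = np.nan
            return r / denom

        rho = _standardize(t_ranks).T @ _standardize(c_ranks)
        results.append(
            ConcordanceResult(
                disease=disease, pathway=pathway_name, correlations=rho.ravel()
            )
        )
    results.sort(key=lambda r: (-r.mean_rho, r.disease))
    return results


def mutation_frequency(
    mutations: pd.DataFrame, sample_disease: pd.Series, gene_symbol: str
) -> pd.Series:
    """Fraction of each disease's samples with >= 1 non-silent variant in a gene."""
    hits = mutations[
        (mutations["Hugo_Symbol"] == gene_symbol)
        & (mutations["Variant_Classification"] != "Silent")
    ]
    carriers = set(hits["Tumor_Sample_Barcode"])
    freq = {}
    for disease in sorted(set(sample_disease)):
        samples = sample_disease.index[sample_disease == disease]
        freq[disease] = float(np.mean([s in carriers for s in samples]))
    return pd.Series(freq, name=f"{gene_symbol}_freq")


def burden_vs_concordance(
    burden: pd.Series, mean_rho: pd.Series
) -> tuple[float, float]:
    """Spearman correlation of per-disease mutation burden vs mean concordance."""
    if set(burden.index) != set(mean_rho.index):
        raise ConcordanceError("disease sets of the two vectors differ")
    if len(burden) < 3:
        raise ConcordanceError("need >= 3 diseases")
    diseases = sorted(burden.index)
    rho, p = stats.spearmanr(burden.loc[diseases], mean_rho.loc[diseases])
    return float(rho), float(p)


def comparisons_to_frame(comparisons: list[GroupComparison]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "feature": [c.feature for c in comparisons],
            "n_x": [c.n_x for c in comparisons],
            "n_y": [c.n_y for c in comparisons],
            "U": [c.u_statistic for c in comparisons],
            "p": [c.p_value for c in comparisons],
            "direction": [c.direction for c in comparisons],
            "stars": [c.stars for c in comparisons],
        }
    )
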