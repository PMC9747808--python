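"""Feature-stability selection with a resampled linear margin classifier.

A linear SVM separating tumor from cell-line samples is refit on many random
stratified 80/20 splits; on each split genes are ranked by the magnitude of
their weight-vector coefficients |w|, and the top fraction from every split is
combined (intersection by default, union optionally) into a stable feature
set.  A two-pass protocol removes an immune blocklist between passes: the
first-pass set is tested for pathway over-representation, all genes of the
significantly enriched immune pathways are pooled into a blocklist, and the
selection is repeated with those genes excluded.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import train_test_split
from sklearn.preprocessing import StandardScaler
from sklearn.svm import LinearSVC

from .enrichment import EnrichmentResult, PathwayCollection, enrich_collection


class SelectionError(ValueError):
    pass


@dataclass
class FeatureRanking:
    """Per-split gene ranking by |w| with the held-out accuracy of the split."""

    seed: int
    weights: pd.Series  # |w| per gene
    ranks: pd.Series  # 1 = largest |w|; ties broken by gene id
    accuracy: float

    def top(self, k: int) -> frozenset[str]:
        return frozenset(self.ranks.index[self.ranks <= k])


@dataclass
class StableFeatureSet:
    genes: frozenset[str]
    n_splits: int
    top_frac: float
    merge_rule: str
    master_seed: int
    accuracies: list[float] = field(default_factory=list)
    split_seeds: list[int] = field(default_factory=list)
    n_top_per_split: int = 0
    support_counts: pd.Series | None = None  # per gene: splits with rank <= k
    mean_weights: pd.Series | None = None  # per gene: mean |w| across splits

    def sorted_genes(self) -> list[str]:
        return sorted(self.genes)


@dataclass
class Blocklist:
    genes: frozenset[str]
    provenance: list[str] = field(default_factory=list)


@dataclass
class TwoPassResult:
    first_pass: StableFeatureSet
    first_pass_enrichment: list[EnrichmentResult]
    blocklist: Blocklist
    final: StableFeatureSet


def _split_seeds(master_seed: int, n_splits: int) -> list[int]:
    # Sequential draws so that the first m seeds of an n-split run (m < n)
    # equal the seeds of an m-split run: nested resampling sequences.
    rng = np.random.default_rng(master_seed)
    return [int(rng.integers(0, 2**31 - 1)) for _ in range(n_splits)]


def rank_features_single_split(
    values: pd.DataFrame,
    labels: pd.Series,
    seed: int,
    test_size: float = 0.2,
    C: float = 1.0,
    class_weight: str | None = "balanced",
    standardize: bool = True,
) -> FeatureRanking:
    """Fit one seeded stratified split and rank genes by |w|.

    ``values`` is genes x samples on the log scale; ``labels`` holds the
    two-class cohort label per sample.  Standardization (per-gene mean/SD) is
    fit on the training portion only, so |w| magnitudes are comparable across
    genes without leaking the held-out samples.
    """
    classes = sorted(set(labels))
    if len(classes) != 2:
        raise SelectionError(f"need exactly 2 classes, got {classes}")
    X = values.to_numpy(dtype=float).T  # samples x genes
    y = (labels.loc[values.columns] == classes[1]).to_numpy()
    X_tr, X_te, y_tr, y_te = train_test_split(
        X, y, test_size=test_size, stratify=y, random_state=seed
    )
    if len(set(y_tr)) < 2:  # pragma: no cover - stratification prevents this
        raise SelectionError("a class is absent from the training split")
    if standardize:
        scaler = StandardScaler().fit(X_tr)
        X_tr, X_te = scaler.transform(X_tr), scaler.transform(X_te)
    clf = LinearSVC(C=C, class_weight=class_weight, random_state=seed, max_iter=5000)
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*converge.*")
        clf.fit(X_tr, y_tr)
    w = pd.Series(np.abs(clf.coef_[0]), index=values.index, name="abs_weight")
    order = sorted(values.index, key=lambda g: (-w[g], g))
    ranks = pd.Series(
        np.arange(1, len(order) + 1), index=order, name="rank"
    ).loc[values.index]
    accuracy = float(clf.score(X_te, y_te))
    return FeatureRanking(seed=seed, weights=w, ranks=ranks, accuracy=accuracy)


def stable_feature_set(
    values: pd.DataFrame,
    labels: pd.Series,
    n_splits: int = 50,
    top_frac: float = 0.10,
    merge_rule: str = "intersection",
    master_seed: int = 0,
    **fit_kwargs,
) -> StableFeatureSet:
    """Combine per-split top-fraction gene sets over ``n_splits`` resamples.

    Each split keeps its top ``k = ceil(top_frac * n_genes)`` genes by |w|;
    the per-split sets are intersected (default) or unioned.  Split seeds are
    derived deterministically from ``master_seed``.
    """
    if n_splits < 1:
        raise SelectionError("n_splits must be >= 1")
    if not 0 < top_frac <= 1:
        raise SelectionError("top_frac must lie in (0, 1]")
    if merge_rule not in ("intersection", "union"):
        raise SelectionError(f"unknown merge_rule {merge_rule!r}")

    k = math.ceil(top_frac * values.shape[0])
    seeds = _split_seeds(master_seed, n_splits)
    top_sets, accuracies = [], []
    support: pd.Series = pd.Series(0, index=values.index, dtype=int)
    weight_sum = pd.Series(0.0, index=values.index)
    for seed in seeds:
        ranking = rank_features_single_split(values, labels, seed, **fit_kwargs)
        top = ranking.top(k)
        top_sets.append(top)
        accuracies.append(ranking.accuracy)
        support.loc[sorted(top)] += 1
        weight_sum += ranking.weights

    if merge_rule == "intersection":
        genes = frozenset.intersection(*top_sets)
        if not genes:
            warnings.warn("intersection of per-split top sets is empty", stacklevel=2)
    else:
        genes = frozenset.union(*top_sets)
    return StableFeatureSet(
        genes=genes,
        n_splits=n_splits,
        top_frac=top_frac,
        merge_rule=merge_rule,
        master_seed=master_seed,
        accuracies=accuracies,
        split_seeds=seeds,
        n_top_per_split=k,
        support_counts=support,
        mean_weights=weight_sum / n_splits,
    )


def build_immune_blocklist(
    enrichments: list[EnrichmentResult],
    collection: PathwayCollection,
    dataset_genes,
    alpha: float = 0.05,
    top_n: int = 100,
) -> Blocklist:
    """Pool the genes of enriched immune pathways into a removal blocklist.

    Among the ``top_n`` pathways by p-value, every pathway with q < ``alpha``
    and category "immune" contributes all of its member genes (restricted to
    the dataset's genes).
    """
    dataset_genes = frozenset(dataset_genes)
    window = sorted(enrichments, key=lambda r: (r.p_value, r.pathway))[:top_n]
    immune = [r for r in window if r.significant and r.q_value < alpha and r.category == "immune"]
    if not immune:
        warnings.warn("no immune pathway enriched; blocklist is empty", stacklevel=2)
        return Blocklist(genes=frozenset())
    pooled: set[str] = set()
    for r in immune:
        pooled |= collection.sets[r.pathway]
    return Blocklist(
        genes=frozenset(pooled) & dataset_genes,
        provenance=sorted(r.pathway for r in immune),
    )


def two_pass_selection(
    values: pd.DataFrame,
    labels: pd.Series,
    collection: PathwayCollection,
    n_splits: int = 50,
    top_frac: float = 0.10,
    merge_rule: str = "intersection",
    master_seed: int = 0,
    alpha: float = 0.05,
    blocklist_top_n: int = 100,
    universe=None,
    **fit_kwargs,
) -> TwoPassResult:
    """Full two-pass protocol: select, blocklist immune programs, re-select.

    Pass 1 runs the stability selection on all genes; its stable set is tested
    for pathway over-representation (universe defaults to the dataset's gene
    list) and the enriched immune pathways define the blocklist.  Pass 2 reruns
    the selection with blocklisted genes removed, guaranteeing the final set is
    disjoint from the blocklist.
    """
    params = dict(
        n_splits=n_splits,
        top_frac=top_frac,
        merge_rule=merge_rule,
        master_seed=master_seed,
        **fit_kwargs,
    )
    first = stable_feature_set(values, labels, **params)
    if universe is None:
        universe = frozenset(values.index)
    enr = enrich_collection(first.genes, collection, universe, alpha=alpha)
    blocklist = build_immune_blocklist(
        enr, collection, values.index, alpha=alpha, top_n=blocklist_top_n
    )
    keep = [g for g in values.index if g not in blocklist.genes]
    if not keep:
        raise SelectionError("blocklist covers every gene in the dataset")
    final = stable_feature_set(values.loc[keep], labels, **params)
    return TwoPassResult(
        first_pass=first, first_pass_enrichment=enr, blocklist=blocklist, final=final
    )


def selection_to_frame(result: StableFeatureSet) -> pd.DataFrame:
    """Per-gene summary table: support across splits and final membership."""
    if result.support_counts is None:
        raise SelectionError("selection carries no support counts")
    return pd.DataFrame(
        {
            "gene_id": result.support_counts.index,
            "mean_abs_weight": result.mean_weights.to_numpy(),
            "n_splits_in_top": result.support_counts.to_numpy(),
            "selected": [g in result.genes for g in result.support_counts.index],
        }
    )
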