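"""Hypergeometric over-representation analysis against GMT pathway collections.

For a query gene list of size n drawn from a universe of N genes, a pathway
with K members in the universe, and an observed overlap k, the enrichment
p-value is the upper tail P(X >= k) of the hypergeometric distribution
Hypergeom(N, K, n).  Benjamini-Hochberg q-values are computed over all tested
pathways, and a pathway is significant when q < alpha.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln
from statsmodels.stats.multitest import multipletests

PATHWAY_CATEGORIES = (
    "cellular response",
    "development",
    "cancer driver",
    "metabolism",
    "blood",
    "immune",
    "other",
)


class EnrichmentError(ValueError):
    pass


@dataclass
class PathwayCollection:
    """Named gene sets with one category label per pathway."""

    sets: dict[str, frozenset[str]]
    categories: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.sets = {name: frozenset(genes) for name, genes in self.sets.items()}
        for name, genes in self.sets.items():
            if not genes:
                raise EnrichmentError(f"pathway {name!r} is empty")
        for name, cat in self.categories.items():
            if cat not in PATHWAY_CATEGORIES:
                raise EnrichmentError(f"unknown category {cat!r} for pathway {name!r}")

    def __len__(self) -> int:
        return len(self.sets)

    def category(self, name: str) -> str:
        return self.categories.get(name, "other")

    def genes(self) -> frozenset[str]:
        out: set[str] = set()
        for genes in self.sets.values():
            out |= genes
        return frozenset(out)


@dataclass
class EnrichmentResult:
    pathway: str
    category: str
    universe_size: int  # N
    pathway_size: int  # K, after intersecting with the universe
    query_size: int  # n
    overlap: int  # k
    p_value: float
    q_value: float = float("nan")
    significant: bool = False
    overlap_genes: frozenset[str] = frozenset()


# cached log-factorial table; grown on demand
_LOG_FACT = np.zeros(1)


def _log_fact(m: int) -> np.ndarray:
    global _LOG_FACT
    if m >= _LOG_FACT.size:
        _LOG_FACT = gammaln(np.arange(max(m + 1, 2 * _LOG_FACT.size)) + 1.0)
    return _LOG_FACT


def hypergeom_pvalue(k: int, n: int, K: int, N: int) -> float:
    """Upper-tail hypergeometric p-value P(X >= k).

    ``N`` universe size, ``K`` pathway size, ``n`` query size, ``k`` overlap.
    The tail is accumulated from log-space PMF terms (log-factorials plus a
    log-sum-exp), so tiny probabilities keep full relative precision.
    """
    if not (0 <= K <= N and 0 <= n <= N):
        raise EnrichmentError(f"invalid parameters K={K}, n={n}, N={N}")
    if not 0 <= k <= min(n, K):
        raise EnrichmentError(f"overlap k={k} outside [0, min(n={n}, K={K})]")
    if k == 0:
        return 1.0
    lf = _log_fact(N)
    j = np.arange(max(k, n + K - N), min(n, K) + 1)
    log_terms = (
        lf[K] - lf[j] - lf[K - j]
        + lf[N - K] - lf[n - j] - lf[N - K - n + j]
        - (lf[N] - lf[n] - lf[N - n])
    )
    peak = log_terms.max()
    return float(min(np.exp(peak + np.log(np.exp(log_terms - peak).sum())), 1.0))


def enrich_collection(
    query,
    collection: PathwayCollection,
    universe,
    alpha: float = 0.05,
) -> list[EnrichmentResult]:
    """Test every pathway for over-representation of ``query`` in ``universe``.

    Query genes outside the universe are dropped with a warning count folded
    into the returned sizes; pathway sets are intersected with the universe.
    Results carry BH q-values over all tested pathways and come back sorted by
    (p-value, pathway name).
    """
    universe = frozenset(universe)
    if not universe:
        raise EnrichmentError("empty universe")
    query = frozenset(query) & universe
    N, n = len(universe), len(query)

    results = []
    for name in sorted(collection.sets):
        members = collection.sets[name] & universe
        overlap = query & members
        p = hypergeom_pvalue(len(overlap), n, len(members), N) if members else 1.0
        results.append(
            EnrichmentResult(
                pathway=name,
                category=collection.category(name),
                universe_size=N,
                pathway_size=len(members),
                query_size=n,
                overlap=len(overlap),
                p_value=p,
                overlap_genes=overlap,
            )
        )
    if results:
        reject, q, _, _ = multipletests(
            [r.p_value for r in results], alpha=alpha, method="fdr_bh"
        )
        for r, rej, qv in zip(results, reject, q):
            r.q_value = float(qv)
            r.significant = bool(qv < alpha)
    results.sort(key=lambda r: (r.p_value, r.pathway))
    return results


def overlap_enrichments(
    res_a: list[EnrichmentResult], res_b: list[EnrichmentResult], collection: PathwayCollection
) -> tuple[dict[str, str], Counter]:
    """Shared significant pathways of two analyses, with per-category counts.

    Both result lists must have been computed against the same collection.
    Returns ``(shared pathway -> category, Counter of categories)``.
    """
    names_a = {r.pathway for r in res_a}
    names_b = {r.pathway for r in res_b}
    if names_a != set(collection.sets) or names_b != set(collection.sets):
        raise EnrichmentError("result lists do not match the pathway collection")
    sig_a = {r.pathway for r in res_a if r.significant}
    sig_b = {r.pathway for r in res_b if r.significant}
    shared = {name: collection.category(name) for name in sorted(sig_a & sig_b)}
    return shared, Counter(shared.values())


def results_to_frame(results: list[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "pathway": [r.pathway for r in results],
            "category": [r.category for r in results],
            "N": [r.universe_size for r in results],
            "K": [r.pathway_size for r in results],
            "n": [r.query_size for r in results],
            "k": [r.overlap for r in results],
            "p": [r.p_value for r in results],
            "q": [r.q_value for r in results],
            "significant": [r.significant for r in results],
        }
    )


# ---------------------------------------------------------------------------
# GMT I/O


def read_gmt(path, categories: dict[str, str] | None = None) -> PathwayCollection:
    """Read a GMT file (pathway name, description, tab-separated member genes).

    The description field is used as the category label when it names one of
    the recognised categories and no explicit mapping is supplied.
    """
    sets: dict[str, frozenset[str]] = {}
    cats: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise EnrichmentError(f"malformed GMT line: {line[:60]!r}")
            name, desc, genes = fields[0], fields[1], fields[2:]
            if name in sets:
                raise EnrichmentError(f"duplicate pathway name {name!r}")
            sets[name] = frozenset(g for g in genes if g)
            if desc in PATHWAY_CATEGORIES:
                cats[name] = desc
    if categories:
        cats.update(categories)
    return PathwayCollection(sets=sets, categories=cats)


def write_gmt(collection: PathwayCollection, path) -> None:
    with open(path, "w") as fh:
        for name in sorted(collection.sets):
            genes = "\t".join(sorted(collection.sets[name]))
            fh.write(f"{name}\t{collection.category(name)}\t{genes}\n")
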