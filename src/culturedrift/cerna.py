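"""ceRNA ("sponge") network bridging: lncRNA -> miRNA -> pathway genes.

Under the competing-endogenous-RNA model, a lncRNA sequesters miRNAs that
would otherwise repress their mRNA targets.  Given curated lncRNA-miRNA and
miRNA-gene interaction tables, a miRNA *bridges* a differentially expressed
lncRNA set to a pathway gene set when it interacts with at least one member of
each.  The bridged network is exported as a SIF edge file plus a node
attribute table (id, type, log fold change).
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import pandas as pd

from .enrichment import hypergeom_pvalue

LNC_MIRNA = "lnc_mirna"
MIRNA_GENE = "mirna_gene"
EDGE_TYPES = (LNC_MIRNA, MIRNA_GENE)
NODE_TYPES = ("lncRNA", "miRNA", "coding")

_SPECIES_PREFIX = re.compile(r"^[a-z]{3}-(?=(mir|let|miR))", re.IGNORECASE)


class NetworkError(ValueError):
    pass


def normalize_mirna_id(name: str, alias_map: dict[str, str] | None = None) -> str:
    """Canonicalise a miRNA identifier.

    Lowercases, strips a three-letter species prefix (``hsa-`` etc.), resolves
    aliases, and preserves arm suffixes (-5p/-3p) since the two arms are
    distinct mature miRNAs.
    """
    s = _SPECIES_PREFIX.sub("", name.strip()).lower()
    if alias_map:
        s = alias_map.get(s, s)
    return s


@dataclass
class InteractionTable:
    """Deduplicated typed interaction edges (lnc-miRNA and miRNA-gene)."""

    edges: pd.DataFrame  # columns: source, target, type

    def __post_init__(self) -> None:
        required = {"source", "target", "type"}
        if not required <= set(self.edges.columns):
            raise NetworkError(f"interaction table needs columns {sorted(required)}")
        bad = set(self.edges["type"]) - set(EDGE_TYPES)
        if bad:
            raise NetworkError(f"unknown edge type(s): {sorted(bad)}")
        if (self.edges["source"] == self.edges["target"]).any():
            raise NetworkError("self-edges are not allowed")
        self.edges = (
            self.edges.drop_duplicates(subset=["source", "target", "type"])
            .sort_values(["type", "source", "target"])
            .reset_index(drop=True)
        )

    def of_type(self, edge_type: str) -> pd.DataFrame:
        return self.edges[self.edges["type"] == edge_type]

    def normalize_mirna(self, alias_map: dict[str, str] | None = None) -> "InteractionTable":
        edges = self.edges.copy()
        lnc = edges["type"] == LNC_MIRNA
        mir = edges["type"] == MIRNA_GENE
        edges.loc[lnc, "target"] = edges.loc[lnc, "target"].map(
            lambda s: normalize_mirna_id(s, alias_map)
        )
        edges.loc[mir, "source"] = edges.loc[mir, "source"].map(
            lambda s: normalize_mirna_id(s, alias_map)
        )
        return InteractionTable(edges)


@dataclass
class BridgeResult:
    mirnas: frozenset[str]
    lncrnas: frozenset[str]  # lncRNAs incident to a kept miRNA
    genes: frozenset[str]  # pathway genes targeted by a kept miRNA


@dataclass
class CeRNANetwork:
    nodes: pd.DataFrame  # columns: id, type, lfc (may be NaN)
    edges: pd.DataFrame  # columns: source, target, type

    def __post_init__(self) -> None:
        if self.nodes["id"].duplicated().any():
            raise NetworkError("duplicate node ids")
        bad = set(self.nodes["type"]) - set(NODE_TYPES)
        if bad:
            raise NetworkError(f"unknown node type(s): {sorted(bad)}")
        ids = set(self.nodes["id"])
        dangling = (~self.edges["source"].isin(ids)) | (~self.edges["target"].isin(ids))
        if dangling.any():
            raise NetworkError("edge endpoints missing from the node table")
        self.nodes = self.nodes.sort_values("id").reset_index(drop=True)
        self.edges = (
            self.edges.sort_values(["type", "source", "target"]).reset_index(drop=True)
        )


def bridge_mirna(
    lnc_set, pathway_genes, table: InteractionTable
) -> BridgeResult:
    """miRNAs interacting with both the lncRNA set and the pathway gene set.

    A miRNA is kept iff it has >= 1 lnc-miRNA edge whose lncRNA lies in
    ``lnc_set`` and >= 1 miRNA-gene edge whose gene lies in ``pathway_genes``.
    Also returns the lncRNAs and genes incident to the kept miRNAs.
    """
    lnc_set, pathway_genes = frozenset(lnc_set), frozenset(pathway_genes)
    if table.edges.empty:
        warnings.warn("empty interaction table", stacklevel=2)
        return BridgeResult(frozenset(), frozenset(), frozenset())
    lnc_edges = table.of_type(LNC_MIRNA)
    lnc_edges = lnc_edges[lnc_edges["source"].isin(lnc_set)]
    gene_edges = table.of_type(MIRNA_GENE)
    gene_edges = gene_edges[gene_edges["target"].isin(pathway_genes)]
    kept = frozenset(lnc_edges["target"]) & frozenset(gene_edges["source"])
    return BridgeResult(
        mirnas=kept,
        lncrnas=frozenset(lnc_edges.loc[lnc_edges["target"].isin(kept), "source"]),
        genes=frozenset(gene_edges.loc[gene_edges["source"].isin(kept), "target"]),
    )


def target_overlap_test(
    mirna_set, candidate_genes, universe, table: InteractionTable
) -> tuple[frozenset[str], float]:
    """Are the candidate genes over-represented among the miRNA set's targets?

    ``targeted`` = candidates with >= 1 incoming edge from ``mirna_set``;
    the p-value is the hypergeometric upper tail with K = all universe genes
    targeted by the miRNA set and N = the universe size.
    """
    mirna_set, universe = frozenset(mirna_set), frozenset(universe)
    candidate_genes = frozenset(candidate_genes)
    if not candidate_genes <= universe:
        raise NetworkError("candidate genes must lie inside the universe")
    gene_edges = table.of_type(MIRNA_GENE)
    hit = frozenset(gene_edges.loc[gene_edges["source"].isin(mirna_set), "target"])
    targeted = candidate_genes & hit
    K = len(hit & universe)
    p = hypergeom_pvalue(len(targeted), len(candidate_genes), K, len(universe))
    return targeted, p


def build_network(
    bridge: BridgeResult, table: InteractionTable, lfc: pd.Series | None = None
) -> CeRNANetwork:
    """Assemble the typed network induced by a bridging result.

    Keeps lnc-miRNA edges between bridge lncRNAs and bridge miRNAs, and
    miRNA-gene edges between bridge miRNAs and bridge genes.  ``lfc`` is an
    optional per-node log fold change carried as a node attribute.
    """
    lnc_edges = table.of_type(LNC_MIRNA)
    lnc_edges = lnc_edges[
        lnc_edges["source"].isin(bridge.lncrnas) & lnc_edges["target"].isin(bridge.mirnas)
    ]
    gene_edges = table.of_type(MIRNA_GENE)
    gene_edges = gene_edges[
        gene_edges["source"].isin(bridge.mirnas) & gene_edges["target"].isin(bridge.genes)
    ]
    nodes = pd.DataFrame(
        {
            "id": sorted(bridge.lncrnas) + sorted(bridge.mirnas) + sorted(bridge.genes),
            "type": ["lncRNA"] * len(bridge.lncrnas)
            + ["miRNA"] * len(bridge.mirnas)
            + ["coding"] * len(bridge.genes),
        }
    )
    nodes["lfc"] = [float(lfc[i]) if lfc is not None and i in lfc.index else float("nan")
                    for i in nodes["id"]]
    return CeRNANetwork(nodes=nodes, edges=pd.concat([lnc_edges, gene_edges]))


# ---------------------------------------------------------------------------
# SIF / node-attribute export


def export_network(net: CeRNANetwork, sif_path, nodes_path) -> None:
    """Write a SIF edge file and a node attribute TSV.

    Both files are written in sorted order, so repeated exports of the same
    network are byte-identical.
    """
    with open(sif_path, "w") as fh:
        for row in net.edges.itertuples(index=False):
            fh.write(f"{row.source}\t{row.type}\t{row.target}\n")
    with open(nodes_path, "w") as fh:
        fh.write("id\ttype\tlfc\n")
        for row in net.nodes.itertuples(index=False):
            lfc = "" if pd.isna(row.lfc) else repr(float(row.lfc))
            fh.write(f"{row.id}\t{row.type}\t{lfc}\n")


def import_network(sif_path, nodes_path) -> CeRNANetwork:
    nodes = pd.read_csv(nodes_path, sep="\t", dtype={"id": str, "type": str})
    nodes["lfc"] = pd.to_numeric(nodes.get("lfc"), errors="coerce")
    try:
        edges = pd.read_csv(
            sif_path, sep="\t", names=["source", "type", "target"], dtype=str
        )[["source", "target", "type"]]
    except pd.errors.EmptyDataError:
        edges = pd.DataFrame(columns=["source", "target", "type"])
    return CeRNANetwork(nodes=nodes, edges=edges)


def export_graphml(net: CeRNANetwork, path) -> None:
    """Optional GraphML mirror of the SIF export (for graph tooling)."""
    import networkx as nx

    g = nx.DiGraph()
    for row in net.nodes.itertuples(index=False):
        attrs = {"type": row.type}
        if not pd.isna(row.lfc):
            attrs["lfc"] = float(row.lfc)
        g.add_node(row.id, **attrs)
    for row in net.edges.itertuples(index=False):
        g.add_edge(row.source, row.target, interaction=row.type)
    nx.write_graphml(g, path)


def read_interaction_table(path, alias_map: dict[str, str] | None = None) -> InteractionTable:
    edges = pd.read_csv(path, sep="\t", dtype=str)
    return InteractionTable(edges).normalize_mirna(alias_map)


def write_interaction_table(table: InteractionTable, path) -> None:
    table.edges.to_csv(path, sep="\t", index=False)
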