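"""Synthetic two-cohort multi-omic data with planted, machine-readable truth.

Three generators emit every input the pipeline consumes, each with a ground
truth object describing what was planted:

* ``generate_bulk_cohort`` — tumor and cell-line bulk expression (TPM scale)
  with four planted "cancer driver" pathways shifted down in cell lines, an
  immune program expressed in tumors only, a non-differential control
  pathway, differentially expressed lncRNAs, decoy pathways, gene
  annotation, a pathway collection and a MAF-like mutation table.
* ``generate_sponge_system`` — a lncRNA-miRNA-gene interaction table plus a
  pair of miRNA matrices (two platforms with divergent naming conventions)
  carrying a planted batch shift/scale and direction-consistent sponge
  effects: lncRNA down in cell lines, most bridging miRNA up, targets down.
* ``generate_sc_cohort`` — negative-binomial single-cell counts for two
  tumor samples (mixing malignant subtype programs S2/S3 with normal
  infiltrate) and one cell-line sample drawn purely from the invasive
  S1-like program, with QC outlier cells injected at configured rates.

Bulk expression is Gaussian on the log2 scale and single-cell counts are
negative binomial — the minimal noise models matching each platform.
Identical config and seed reproduce identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from anndata import AnnData

from .cerna import LNC_MIRNA, MIRNA_GENE, InteractionTable
from .enrichment import PathwayCollection
from .mirna import MiRNAMatrix
from .preprocess import TPM, ExpressionMatrix
from .singlecell import SignatureSet


class SyntheticError(ValueError):
    pass


@dataclass
class SyntheticConfig:
    """Study conditions for all three generators (sizes chosen for desk runs)."""

    # bulk cohort
    n_coding: int = 2000
    n_lnc: int = 20
    n_tumor: int = 200
    n_cellline: int = 60
    n_diseases: int = 6
    delta: float = 1.5  # planted shift, log2 units
    sigma: float = 1.0  # per-gene noise SD, log2 units
    n_driver_pathways: int = 4
    driver_pathway_size: int = 25
    immune_size: int = 50
    control_size: int = 25
    n_silent: int = 50  # mostly-zero genes exercising the zero filter
    n_decoy_pathways: int = 10
    decoy_size: int = 25
    # sponge system
    n_mirna: int = 60
    n_bridging: int = 40
    consistency: float = 0.9  # fraction of bridging miRNA shifted up
    batch_shift: float = 5.0
    batch_scale: float = 2.0
    mirna_sigma: float = 1.0
    n_mirna_tumor: int = 60
    n_mirna_cellline: int = 60
    n_platform_b_missing: int = 8
    # single-cell cohort
    sc_n_genes: int = 900
    sc_n_mito: int = 20
    sc_cells_per_sample: int = 1000
    sc_marker_size: int = 15
    sc_subtype_size: int = 40
    sc_tumor_up_size: int = 50
    sc_base_rate: float = 0.2
    sc_dispersion: float = 2.0
    sc_program_fold: float = 10.0
    sc_tumor_up_fold: float = 8.0
    sc_n_outlier_high: int = 10
    sc_n_outlier_mito: int = 10
    sc_max_genes: int = 600
    sc_mito_threshold: int = 15
    sc_infiltrate_frac: float = 0.3  # fraction of tumor cells that are normal infiltrate

    def __post_init__(self) -> None:
        planted = (
            self.n_driver_pathways * self.driver_pathway_size
            + self.immune_size
            + self.control_size
            + self.n_silent
        )
        if planted > self.n_coding:
            raise SyntheticError("planted programs exceed n_coding")
        if not 0.0 <= self.consistency <= 1.0:
            raise SyntheticError("consistency must lie in [0, 1]")
        if self.sigma <= 0:
            raise SyntheticError("sigma must be positive")
        if self.n_bridging > self.n_mirna:
            raise SyntheticError("n_bridging exceeds n_mirna")


@dataclass
class GroundTruth:
    """Planted structure, serialized alongside every generated dataset."""

    planted_de: dict[str, str] = field(default_factory=dict)  # gene -> direction
    immune_genes: list[str] = field(default_factory=list)
    lnc_genes: list[str] = field(default_factory=list)  # planted down in cell lines
    driver_pathways: list[str] = field(default_factory=list)
    control_pathway: str = ""
    decoy_pathways: list[str] = field(default_factory=list)
    mutation_carriers: dict[str, list[str]] = field(default_factory=dict)
    bridging_mirna: list[str] = field(default_factory=list)
    bridging_up: list[str] = field(default_factory=list)
    bridging_down: list[str] = field(default_factory=list)
    decoy_mirna: list[str] = field(default_factory=list)
    sponge_targets: list[str] = field(default_factory=list)
    cell_populations: dict[str, str] = field(default_factory=dict)  # cell -> population
    outlier_cells: list[str] = field(default_factory=list)
    subtype_programs: dict[str, list[str]] = field(default_factory=dict)
    tumor_up_genes: list[str] = field(default_factory=list)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            return cls(**json.load(fh))


# ---------------------------------------------------------------------------
# Gene namespace shared by the bulk and sponge generators


def _coding_ids(cfg: SyntheticConfig) -> list[str]:
    return [f"GENE{i:04d}" for i in range(cfg.n_coding)]


def _lnc_ids(cfg: SyntheticConfig) -> list[str]:
    return [f"LNC{i:03d}" for i in range(cfg.n_lnc)]


def gene_roles(cfg: SyntheticConfig) -> dict[str, list[str]]:
    """Deterministic partition of the coding namespace into planted programs."""
    coding = _coding_ids(cfg)
    n_driver = cfg.n_driver_pathways * cfg.driver_pathway_size
    cut1 = n_driver
    cut2 = cut1 + cfg.immune_size
    cut3 = cut2 + cfg.control_size
    cut4 = cut3 + cfg.n_silent
    return {
        "driver": coding[:cut1],
        "immune": coding[cut1:cut2],
        "control": coding[cut2:cut3],
        "silent": coding[cut3:cut4],
        "null": coding[cut4:],
    }


@dataclass
class BulkCohort:
    tumor: ExpressionMatrix
    cellline: ExpressionMatrix
    metadata: pd.DataFrame
    annotation: pd.DataFrame
    collection: PathwayCollection
    mutations: pd.DataFrame
    truth: GroundTruth


def generate_bulk_cohort(cfg: SyntheticConfig, seed: int) -> BulkCohort:
    """Two-cohort bulk expression with planted pathway-level shifts.

    Baseline log2 expression is Normal(mu_g, sigma) per gene.  Driver-pathway
    genes and lncRNAs are shifted down by delta in cell lines; immune-program
    genes are expressed in tumors only; control-pathway, decoy and null genes
    are identically distributed in both cohorts.  Matrices are emitted on the
    TPM scale (2**x - 1) so the preprocessing stage is exercised end to end.
    """
    rng = np.random.default_rng(seed)
    roles = gene_roles(cfg)
    lnc = _lnc_ids(cfg)
    genes = _coding_ids(cfg) + lnc
    n_genes = len(genes)
    pos = {g: i for i, g in enumerate(genes)}

    mu = rng.uniform(2.0, 8.0, size=n_genes)
    t_log = rng.normal(mu[:, None], cfg.sigma, size=(n_genes, cfg.n_tumor))
    c_log = rng.normal(mu[:, None], cfg.sigma, size=(n_genes, cfg.n_cellline))

    down = [pos[g] for g in roles["driver"] + lnc]
    c_log[down, :] -= cfg.delta

    immune_rows = [pos[g] for g in roles["immune"]]
    t_log[immune_rows, :] = rng.normal(
        rng.uniform(4.0, 8.0, size=(len(immune_rows), 1)), cfg.sigma,
        size=(len(immune_rows), cfg.n_tumor),
    )
    c_log[immune_rows, :] = 0.0  # tumor-only immune program

    silent_rows = [pos[g] for g in roles["silent"]]
    for block in (t_log, c_log):
        expressed = rng.random((len(silent_rows), block.shape[1])) < 0.1
        block[silent_rows, :] = np.where(
            expressed, np.abs(rng.normal(1.0, 0.2, expressed.shape)), 0.0
        )

    t_log = np.clip(t_log, 0.0, None)
    c_log = np.clip(c_log, 0.0, None)

    t_ids = [f"T{i:04d}" for i in range(cfg.n_tumor)]
    c_ids = [f"C{i:04d}" for i in range(cfg.n_cellline)]
    diseases = [f"D{i + 1:02d}" for i in range(cfg.n_diseases)]
    meta = pd.DataFrame(
        {
            "cohort": ["tumor"] * cfg.n_tumor + ["cell_line"] * cfg.n_cellline,
            "disease_code": [diseases[i % cfg.n_diseases] for i in range(cfg.n_tumor)]
            + [diseases[i % cfg.n_diseases] for i in range(cfg.n_cellline)],
        },
        index=t_ids + c_ids,
    )

    tumor = ExpressionMatrix(
        pd.DataFrame(2.0**t_log - 1.0, index=genes, columns=t_ids),
        scale=TPM, metadata=meta.loc[t_ids],
    )
    cellline = ExpressionMatrix(
        pd.DataFrame(2.0**c_log - 1.0, index=genes, columns=c_ids),
        scale=TPM, metadata=meta.loc[c_ids],
    )

    annotation = pd.DataFrame(
        {
            "symbol": genes,
            "biotype": ["coding"] * cfg.n_coding + ["lncRNA"] * cfg.n_lnc,
            "immune_program": [g in set(roles["immune"]) for g in genes],
            "mito": False,
        },
        index=pd.Index(genes, name="gene_id"),
    )

    sets: dict[str, frozenset] = {}
    categories: dict[str, str] = {}
    driver_names = []
    for j in range(cfg.n_driver_pathways):
        name = f"DRIVER_PW_{j + 1}"
        lo = j * cfg.driver_pathway_size
        sets[name] = frozenset(roles["driver"][lo : lo + cfg.driver_pathway_size])
        categories[name] = "cancer driver"
        driver_names.append(name)
    sets["IMMUNE_PROGRAM"] = frozenset(roles["immune"])
    categories["IMMUNE_PROGRAM"] = "immune"
    sets["CONTROL_PW"] = frozenset(roles["control"])
    categories["CONTROL_PW"] = "cancer driver"  # the non-DE driver-class control
    decoy_names = []
    for j in range(cfg.n_decoy_pathways):
        name = f"DECOY_PW_{j + 1:02d}"
        sets[name] = frozenset(rng.choice(roles["null"], cfg.decoy_size, replace=False))
        categories[name] = "other"
        decoy_names.append(name)
    collection = PathwayCollection(sets=sets, categories=categories)

    mutations, carriers = _generate_mutations(cfg, rng, meta)

    truth = GroundTruth(
        planted_de={g: "down" for g in roles["driver"]},
        immune_genes=list(roles["immune"]),
        lnc_genes=list(lnc),
        driver_pathways=driver_names,
        control_pathway="CONTROL_PW",
        decoy_pathways=decoy_names,
        mutation_carriers=carriers,
    )
    return BulkCohort(tumor, cellline, meta, annotation, collection, mutations, truth)


def _generate_mutations(cfg, rng, meta) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    """MAF-like table: per-disease non-silent rates for KRAS/TP53 plus
    silent decoy records."""
    rows = []
    carriers: dict[str, list[str]] = {}
    diseases = sorted(set(meta["disease_code"]))
    for gene in ("KRAS", "TP53"):
        rate = {d: rng.uniform(0.1, 0.6) for d in diseases}
        carriers[gene] = []
        for sample, row in meta.iterrows():
            if rng.random() < rate[row["disease_code"]]:
                cls = "Missense_Mutation" if rng.random() < 0.8 else "Nonsense_Mutation"
                rows.append((sample, gene, cls))
                carriers[gene].append(sample)
            elif rng.random() < 0.1:
                rows.append((sample, gene, "Silent"))
    maf = pd.DataFrame(
        rows, columns=["Tumor_Sample_Barcode", "Hugo_Symbol", "Variant_Classification"]
    )
    return maf, carriers


# ---------------------------------------------------------------------------
# Sponge system


@dataclass
class SpongeSystem:
    interactions: InteractionTable
    matrix_a: MiRNAMatrix  # platform A (miRNA-seq-style ids, "hsa-" prefixed)
    matrix_b: MiRNAMatrix  # platform B (probe-style ids, needs the alias map)
    alias_map: dict[str, str]
    truth: GroundTruth


def generate_sponge_system(cfg: SyntheticConfig, seed: int) -> SpongeSystem:
    """Planted ceRNA system: interactions, batched miRNA matrices, truth.

    Bridging miRNAs interact with >= 1 planted lncRNA and >= 1 driver-pathway
    gene; decoys have only one kind of edge.  In cell lines a ``consistency``
    fraction of bridging miRNAs is shifted up by delta (the rest down); decoys
    carry no cohort effect.  Samples of both cohorts are split across two
    platforms/batches ("A" additive-neutral, "B" with additive shift and
    multiplicative scale), and the two emitted matrices use divergent naming
    conventions resolved by the emitted alias map.
    """
    rng = np.random.default_rng(seed)
    roles = gene_roles(cfg)
    lnc = _lnc_ids(cfg)
    mirna = [f"mir-{100 + i}" for i in range(cfg.n_mirna)]
    bridging, decoys = mirna[: cfg.n_bridging], mirna[cfg.n_bridging :]

    edges = []
    for m in bridging:
        for l in rng.choice(lnc, rng.integers(1, 4), replace=False):
            edges.append((l, m, LNC_MIRNA))
        for g in rng.choice(roles["driver"], rng.integers(2, 5), replace=False):
            edges.append((m, g, MIRNA_GENE))
    for i, m in enumerate(decoys):
        if i % 2 == 0:
            edges.append((rng.choice(lnc), m, LNC_MIRNA))
        else:
            edges.append((m, rng.choice(roles["driver"]), MIRNA_GENE))
    interactions = InteractionTable(
        pd.DataFrame(edges, columns=["source", "target", "type"])
    )
    targets = sorted(set(
        interactions.of_type(MIRNA_GENE)
        .loc[lambda d: d["source"].isin(bridging), "target"]
    ))

    n_up = math.ceil(cfg.consistency * cfg.n_bridging)
    shuffled = list(rng.permutation(bridging))
    up, down_mir = sorted(shuffled[:n_up]), sorted(shuffled[n_up:])

    t_ids = [f"MT{i:03d}" for i in range(cfg.n_mirna_tumor)]
    c_ids = [f"MC{i:03d}" for i in range(cfg.n_mirna_cellline)]
    samples = pd.DataFrame(
        {
            "batch": [("A", "B")[i % 2] for i in range(len(t_ids))]
            + [("A", "B")[i % 2] for i in range(len(c_ids))],
            "cohort": ["tumor"] * len(t_ids) + ["cell_line"] * len(c_ids),
        },
        index=t_ids + c_ids,
    )

    mu = rng.uniform(3.0, 9.0, size=cfg.n_mirna)
    shift = np.zeros(cfg.n_mirna)
    idx = {m: i for i, m in enumerate(mirna)}
    shift[[idx[m] for m in up]] = cfg.delta
    shift[[idx[m] for m in down_mir]] = -cfg.delta

    log_vals = np.empty((cfg.n_mirna, len(samples)))
    for j, sample in enumerate(samples.index):
        eff = mu + (shift if samples.at[sample, "cohort"] == "cell_line" else 0.0)
        noise = rng.normal(0.0, cfg.mirna_sigma, cfg.n_mirna)
        if samples.at[sample, "batch"] == "B":
            log_vals[:, j] = eff + cfg.batch_shift + cfg.batch_scale * noise
        else:
            log_vals[:, j] = eff + noise
    counts = np.clip(2.0**log_vals - 1.0, 0.0, None)

    in_a = samples["batch"] == "A"
    b_missing = sorted(rng.choice(mirna, cfg.n_platform_b_missing, replace=False))
    b_rows = [m for m in mirna if m not in set(b_missing)]
    values = pd.DataFrame(counts, index=mirna, columns=samples.index)

    mat_a = MiRNAMatrix(
        values.loc[:, in_a].set_axis([f"hsa-{m}" for m in mirna], axis=0),
        samples.loc[in_a],
    )
    mat_b = MiRNAMatrix(
        values.loc[b_rows, ~in_a].set_axis(
            [m.replace("mir-", "MIR").upper() for m in b_rows], axis=0
        ),
        samples.loc[~in_a],
    )
    alias_map = {m.replace("mir-", "mir"): m for m in mirna}

    truth = GroundTruth(
        lnc_genes=list(lnc),
        bridging_mirna=sorted(bridging),
        bridging_up=up,
        bridging_down=down_mir,
        decoy_mirna=sorted(decoys),
        sponge_targets=targets,
    )
    return SpongeSystem(interactions, mat_a, mat_b, alias_map, truth)


# ---------------------------------------------------------------------------
# Single-cell cohort


@dataclass
class SCCohort:
    adata: AnnData
    markers: SignatureSet  # cell-type markers
    subtypes: SignatureSet  # molecular subtype signatures S1/S2/S3
    truth: GroundTruth


def _sc_gene_programs(cfg: SyntheticConfig) -> tuple[list[str], dict[str, list[str]]]:
    mito = [f"MT-SC{i:02d}" for i in range(cfg.sc_n_mito)]
    n_rest = cfg.sc_n_genes - cfg.sc_n_mito
    rest = [f"SCG{i:04d}" for i in range(n_rest)]
    cuts = np.cumsum(
        [cfg.sc_marker_size] * 3 + [cfg.sc_subtype_size] * 3 + [cfg.sc_tumor_up_size]
    )
    if cuts[-1] > n_rest:
        raise SyntheticError("single-cell programs exceed sc_n_genes")
    programs = {
        "malignant": rest[: cuts[0]],
        "tcell": rest[cuts[0] : cuts[1]],
        "macrophage": rest[cuts[1] : cuts[2]],
        "S1": rest[cuts[2] : cuts[3]],
        "S2": rest[cuts[3] : cuts[4]],
        "S3": rest[cuts[4] : cuts[5]],
        "tumor_up": rest[cuts[5] : cuts[6]],
    }
    return mito + rest, programs


# population -> (sample origin, active programs)
_SC_POPULATIONS = {
    "malignant_S2": ("tumor", ("malignant", "S2")),
    "malignant_S3": ("tumor", ("malignant", "S3")),
    "tcell": ("tumor", ("tcell",)),
    "macrophage": ("tumor", ("macrophage",)),
    "cellline_S1": ("cell_line", ("malignant", "S1")),
}


def _sc_tumor_mix(cfg: SyntheticConfig) -> tuple[tuple[str, float], ...]:
    inf = cfg.sc_infiltrate_frac
    return (
        ("malignant_S2", (1.0 - inf) / 2),
        ("malignant_S3", (1.0 - inf) / 2),
        ("tcell", inf * 2 / 3),
        ("macrophage", inf / 3),
    )


def generate_sc_cohort(cfg: SyntheticConfig, seed: int) -> SCCohort:
    """Negative-binomial single-cell counts for two tumor samples and one
    cell-line sample.

    Tumor samples mix malignant populations expressing subtype programs S2/S3
    with T-cell and macrophage infiltrate; the cell-line sample draws only an
    S1-like malignant population.  A tumor-up program is active in every
    tumor cell.  QC outliers (over-detected cells and mitochondria-rich
    cells) are injected into the first tumor sample at configured rates.
    """
    rng = np.random.default_rng(seed)
    genes, programs = _sc_gene_programs(cfg)
    gene_pos = {g: i for i, g in enumerate(genes)}
    base = rng.lognormal(np.log(cfg.sc_base_rate), 0.5, size=len(genes))

    def population_means(population: str, sample_cohort: str) -> np.ndarray:
        m = base.copy()
        for prog in _SC_POPULATIONS[population][1]:
            m[[gene_pos[g] for g in programs[prog]]] *= cfg.sc_program_fold
        if sample_cohort == "tumor":
            m[[gene_pos[g] for g in programs["tumor_up"]]] *= cfg.sc_tumor_up_fold
        return m

    cells, rows, pops, samples_col = [], [], [], []
    for sample in ("tumor_1", "tumor_2", "cell_line"):
        cohort = "tumor" if sample.startswith("tumor") else "cell_line"
        if cohort == "tumor":
            mix = _sc_tumor_mix(cfg)
            names = [p for p, _ in mix]
            probs = np.array([w for _, w in mix])
            assignment = rng.choice(names, size=cfg.sc_cells_per_sample, p=probs)
        else:
            assignment = np.repeat("cellline_S1", cfg.sc_cells_per_sample)
        for i, population in enumerate(assignment):
            m = population_means(population, cohort) * rng.uniform(0.8, 1.2)
            r = cfg.sc_dispersion
            rows.append(rng.negative_binomial(r, r / (r + m)))
            cells.append(f"{sample}_c{i:04d}")
            pops.append(population)
            samples_col.append(sample)

    outliers = []
    mito_rows = [gene_pos[g] for g in genes if g.startswith("MT-")]
    for i in range(cfg.sc_n_outlier_high):
        m = population_means("malignant_S2", "tumor") * 25.0
        r = cfg.sc_dispersion
        rows.append(rng.negative_binomial(r, r / (r + m)))
        name = f"tumor_1_high{i:02d}"
        cells.append(name), pops.append("outlier_high"), samples_col.append("tumor_1")
        outliers.append(name)
    for i in range(cfg.sc_n_outlier_mito):
        m = population_means("malignant_S2", "tumor")
        m[mito_rows] = 10.0
        r = cfg.sc_dispersion
        rows.append(rng.negative_binomial(r, r / (r + m)))
        name = f"tumor_1_mito{i:02d}"
        cells.append(name), pops.append("outlier_mito"), samples_col.append("tumor_1")
        outliers.append(name)

    X = np.vstack(rows).astype(np.int64)
    obs = pd.DataFrame(
        {"sample": samples_col, "true_population": pops}, index=cells
    )
    var = pd.DataFrame(
        {"mito": [g.startswith("MT-") for g in genes]}, index=genes
    )
    adata = AnnData(X=X.astype(np.float64), obs=obs, var=var)

    markers = SignatureSet(
        {k: frozenset(programs[k]) for k in ("malignant", "tcell", "macrophage")}
    )
    subtypes = SignatureSet({k: frozenset(programs[k]) for k in ("S1", "S2", "S3")})
    truth = GroundTruth(
        cell_populations=dict(zip(cells, pops)),
        outlier_cells=outliers,
        subtype_programs={k: list(programs[k]) for k in ("S1", "S2", "S3")},
        tumor_up_genes=list(programs["tumor_up"]),
    )
    return SCCohort(adata, markers, subtypes, truth)


def generate_two_population_sc(
    cfg: SyntheticConfig, seed: int, n_cells: int = 300
) -> tuple[AnnData, pd.Series]:
    """Two well-separated cell populations (disjoint expression programs).

    A reduced fixture for clustering checks: half the cells activate the
    malignant program, half the T-cell program, no outliers, one sample.
    Returns the counts and the planted population label per cell.
    """
    rng = np.random.default_rng(seed)
    genes, programs = _sc_gene_programs(cfg)
    gene_pos = {g: i for i, g in enumerate(genes)}
    base = rng.lognormal(np.log(cfg.sc_base_rate), 0.5, size=len(genes))
    rows, labels = [], []
    for i in range(n_cells):
        population = "malignant" if i < n_cells // 2 else "tcell"
        m = base.copy()
        m[[gene_pos[g] for g in programs[population]]] *= cfg.sc_program_fold
        r = cfg.sc_dispersion
        rows.append(rng.negative_binomial(r, r / (r + m)))
        labels.append(population)
    cells = [f"cell{i:04d}" for i in range(n_cells)]
    adata = AnnData(
        X=np.vstack(rows).astype(np.float64),
        obs=pd.DataFrame(index=cells),
        var=pd.DataFrame({"mito": [g.startswith("MT-") for g in genes]}, index=genes),
    )
    return adata, pd.Series(labels, index=cells, name="true_population")
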