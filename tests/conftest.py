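"""Shared fixtures: the default synthetic study, computed once per session."""

import warnings

import numpy as np
import pandas as pd
import pytest

import culturedrift as cd
from culturedrift.singlecell import _dense, normalize_log

# The expensive pipeline stages are session-scoped so unit and acceptance
# tests share one computation of each.

BULK_SEED = 1
SPONGE_SEED = 2
SC_SEED = 3
SELECT_SEED = 11


@pytest.fixture(scope="session")
def cfg():
    return cd.SyntheticConfig()


@pytest.fixture(scope="session")
def bulk(cfg):
    return cd.generate_bulk_cohort(cfg, BULK_SEED)


@pytest.fixture(scope="session")
def merged_filtered(bulk):
    tumor = cd.normalize_expression(bulk.tumor)
    cell = cd.normalize_expression(bulk.cellline)
    merged, labels, _ = cd.harmonize_cohorts(tumor, cell, bulk.metadata)
    filtered, report = cd.filter_genes(merged)
    return filtered, labels, report


@pytest.fixture(scope="session")
def two_pass(bulk, merged_filtered):
    filtered, labels, _ = merged_filtered
    return cd.two_pass_selection(
        filtered.values, labels, bulk.collection, master_seed=SELECT_SEED
    )


@pytest.fixture(scope="session")
def sponge(cfg):
    return cd.generate_sponge_system(cfg, SPONGE_SEED)


@pytest.fixture(scope="session")
def sponge_corrected(sponge):
    merged, report = cd.prepare_mirna(
        sponge.matrix_a, sponge.matrix_b, sponge.alias_map
    )
    corrected, model = cd.eb_batch_correct(merged)
    return merged, corrected, model, report


@pytest.fixture(scope="session")
def sc_cohort(cfg):
    return cd.generate_sc_cohort(cfg, SC_SEED)


@pytest.fixture(scope="session")
def sc_filtered(cfg, sc_cohort):
    filtered, report = cd.qc_filter_cells(
        sc_cohort.adata,
        max_genes=cfg.sc_max_genes,
        mito_threshold=cfg.sc_mito_threshold,
    )
    return filtered, report


@pytest.fixture(scope="session")
def sc_lognorm(sc_filtered):
    """Median-depth-normalized log counts as a cells x genes DataFrame."""
    filtered, _ = sc_filtered
    norm = filtered.copy()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        normalize_log(norm)
    return pd.DataFrame(_dense(norm), index=norm.obs_names, columns=norm.var_names), norm.obs


@pytest.fixture
def small_labeled_matrix():
    """Tiny two-class expression matrix with one strongly informative gene."""
    rng = np.random.default_rng(42)
    n1, n2, n_null = 40, 30, 30
    genes = [f"g{i:03d}" for i in range(n_null + 1)]
    samples = [f"s{i:03d}" for i in range(n1 + n2)]
    X = rng.normal(0.0, 1.0, (n_null + 1, n1 + n2))
    X[0, :n1] += 3.0  # informative gene separates the classes
    values = pd.DataFrame(X, index=genes, columns=samples)
    labels = pd.Series(["tumor"] * n1 + ["cell_line"] * n2, index=samples)
    return values, labels
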