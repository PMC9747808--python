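"""miRNA cross-platform comparison: harmonize, batch-correct, fold changes.

Two miRNA quantification matrices from different platforms are merged on the
intersection of their harmonized identifiers, log2(x + 1) transformed, and
adjusted for batch effects with a parametric empirical-Bayes location-scale
model: per feature, the data are standardized against the batch-design fit,
per-batch additive (gamma) and multiplicative (delta) effects are estimated
and shrunk toward batch-level priors (normal prior on gamma, inverse-gamma on
delta; hyperparameters by method of moments), and the adjusted data are
rescaled to the pooled variance and grand mean.  By default a final exact
moment-alignment step pins every batch's per-feature mean and variance to the
feature's grand mean and pooled within-batch variance, which makes the
correction idempotent and removes residual batch means entirely; the shrunk
estimates remain available on the returned model.  Directional log fold
changes (cell line minus tumor) are computed on the corrected log-scale data.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .cerna import normalize_mirna_id

RAW = "raw"
LOG2_COUNT1 = "log2_count1"


class MiRNAError(ValueError):
    pass


@dataclass
class MiRNAMatrix:
    """miRNA x samples values plus per-sample batch and cohort labels."""

    values: pd.DataFrame
    samples: pd.DataFrame  # indexed by sample id; columns: batch, cohort
    scale: str = RAW

    def __post_init__(self) -> None:
        if list(self.values.columns) != list(self.samples.index):
            self.samples = self.samples.loc[self.values.columns]
        for col in ("batch", "cohort"):
            if col not in self.samples.columns:
                raise MiRNAError(f"sample sheet missing {col!r} column")
        if not np.isfinite(self.values.to_numpy(dtype=float)).all():
            raise MiRNAError("miRNA values must be finite")

    @property
    def mirna_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def batches(self) -> list[str]:
        return sorted(set(self.samples["batch"]))


@dataclass
class BatchCorrectionModel:
    batches: list[str]
    grand_mean: pd.Series  # per feature
    pooled_var: pd.Series  # per feature (within-batch pooled)
    gamma_hat: pd.DataFrame  # feature x batch, raw additive estimates
    delta_hat: pd.DataFrame  # feature x batch, raw multiplicative estimates
    gamma_star: pd.DataFrame  # shrunk additive effects
    delta_star: pd.DataFrame  # shrunk multiplicative effects
    gamma_bar: pd.Series  # per batch, prior mean of gamma
    tau_sq: pd.Series  # per batch, prior variance of gamma
    a_prior: pd.Series  # per batch, inverse-gamma shape
    b_prior: pd.Series  # per batch, inverse-gamma scale
    exact_align: bool = True


@dataclass
class LFCTable:
    table: pd.DataFrame  # columns: lfc, mean_cell_line, mean_tumor, sign

    @property
    def n_positive(self) -> int:
        return int((self.table["lfc"] > 0).sum())

    @property
    def n_negative(self) -> int:
        return int((self.table["lfc"] < 0).sum())


def prepare_mirna(
    a: MiRNAMatrix, b: MiRNAMatrix, alias_map: dict[str, str] | None = None
) -> tuple[MiRNAMatrix, dict]:
    """Harmonize identifiers, merge on the shared features, log-transform.

    Identifiers are lowercased, species-prefix-stripped and alias-resolved;
    duplicate rows (post-harmonization collisions) are averaged on the raw
    scale.  The merged matrix keeps only features quantified on both
    platforms, then applies log2(x + 1).
    """
    def harmonized(m: MiRNAMatrix) -> pd.DataFrame:
        if m.scale != RAW:
            raise MiRNAError("prepare_mirna expects raw-scale inputs")
        vals = m.values.copy()
        vals.index = [normalize_mirna_id(i, alias_map) for i in vals.index]
        if vals.index.has_duplicates:
            vals = vals.groupby(level=0, sort=False).mean()
        return vals

    va, vb = harmonized(a), harmonized(b)
    shared = sorted(set(va.index) & set(vb.index))
    if not shared:
        raise MiRNAError("no miRNA shared between the two matrices")
    merged = pd.concat([va.loc[shared], vb.loc[shared]], axis=1)
    if merged.columns.has_duplicates:
        raise MiRNAError("the two matrices share sample ids")
    merged = np.log2(merged + 1.0)
    samples = pd.concat([a.samples, b.samples])
    report = {
        "n_a": len(va.index),
        "n_b": len(vb.index),
        "n_shared": len(shared),
        "dropped_a": sorted(set(va.index) - set(shared)),
        "dropped_b": sorted(set(vb.index) - set(shared)),
    }
    return MiRNAMatrix(merged, samples.loc[merged.columns], scale=LOG2_COUNT1), report


def _it_sol(s_data, g_hat, d_hat, g_bar, t2, a, b, conv=1e-4):
    """Iterative joint solution for the shrunk batch effects of one batch."""
    n = s_data.shape[1]
    g_old, d_old = g_hat.copy(), d_hat.copy()
    change = 1.0
    while change > conv:
        g_new = (t2 * n * g_hat + d_old * g_bar) / (t2 * n + d_old)
        sum2 = ((s_data - g_new[:, None]) ** 2).sum(axis=1)
        d_new = (0.5 * sum2 + b) / (n / 2.0 + a - 1.0)
        change = max(
            (np.abs(g_new - g_old) / np.maximum(np.abs(g_old), 1e-12)).max(),
            (np.abs(d_new - d_old) / np.maximum(np.abs(d_old), 1e-12)).max(),
        )
        g_old, d_old = g_new, d_new
    return g_old, d_old


def eb_batch_correct(
    m: MiRNAMatrix, exact_align: bool = True
) -> tuple[MiRNAMatrix, BatchCorrectionModel | None]:
    """Empirical-Bayes location-scale batch correction.

    Requires >= 2 samples per batch.  With a single batch the data pass
    through unchanged (nothing to correct).  With ``exact_align`` (default)
    the EB-adjusted data receive a final exact per-batch moment alignment:
    every feature's per-batch mean is pinned to its grand mean and the
    per-batch variance to the pooled within-batch variance, which preserves
    the grand mean to machine precision and makes the operation idempotent.
    """
    batches = m.batches
    idx = {b: np.flatnonzero((m.samples["batch"] == b).to_numpy()) for b in batches}
    for b, cols in idx.items():
        if len(cols) < 2:
            raise MiRNAError(f"batch {b!r} has fewer than 2 samples")
    if len(batches) == 1:
        return replace(m, values=m.values.copy()), None

    X = m.values.to_numpy(dtype=float)
    n_array = X.shape[1]
    sizes = np.array([len(idx[b]) for b in batches], dtype=float)

    batch_means = np.column_stack([X[:, idx[b]].mean(axis=1) for b in batches])
    grand = batch_means @ (sizes / n_array)  # == overall sample mean
    resid = X.copy()
    for j, b in enumerate(batches):
        resid[:, idx[b]] -= batch_means[:, [j]]
    # residual variance about batch means, pooled over all samples (ddof 0)
    var_pooled = (resid**2).mean(axis=1)
    var_pooled = np.where(var_pooled <= 0, 1e-12, var_pooled)
    sd = np.sqrt(var_pooled)

    s_data = (X - grand[:, None]) / sd[:, None]

    gamma_hat = np.column_stack([s_data[:, idx[b]].mean(axis=1) for b in batches])
    delta_hat = np.column_stack([s_data[:, idx[b]].var(axis=1, ddof=1) for b in batches])

    gamma_bar = gamma_hat.mean(axis=0)
    t2 = gamma_hat.var(axis=0, ddof=1)
    d_mean = delta_hat.mean(axis=0)
    d_var = delta_hat.var(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        a_prior = np.where(d_var > 0, (2 * d_var + d_mean**2) / np.where(d_var > 0, d_var, 1), np.inf)
        b_prior = np.where(d_var > 0, (d_mean * d_var + d_mean**3) / np.where(d_var > 0, d_var, 1), np.inf)

    gamma_star = np.empty_like(gamma_hat)
    delta_star = np.empty_like(delta_hat)
    adjusted = s_data.copy()
    for j, b in enumerate(batches):
        cols = idx[b]
        if t2[j] <= 1e-12 or not np.isfinite(a_prior[j]):
            # Degenerate priors (batch effects indistinguishable across
            # features): fall back to the unshrunk estimates.
            g_star, d_star = gamma_hat[:, j], delta_hat[:, j]
        else:
            g_star, d_star = _it_sol(
                s_data[:, cols], gamma_hat[:, j], delta_hat[:, j],
                gamma_bar[j], t2[j], a_prior[j], b_prior[j],
            )
        d_star = np.where(d_star <= 0, 1e-12, d_star)
        gamma_star[:, j], delta_star[:, j] = g_star, d_star
        adjusted[:, cols] = (s_data[:, cols] - g_star[:, None]) / np.sqrt(d_star)[:, None]

    corrected = adjusted * sd[:, None] + grand[:, None]

    if exact_align:
        # Pool target variance from within-batch variances of the *input*.
        within_var = np.column_stack(
            [X[:, idx[b]].var(axis=1, ddof=1) for b in batches]
        )
        w = (sizes - 1) / (sizes - 1).sum()
        target_var = within_var @ w
        target_sd = np.sqrt(np.where(target_var <= 0, 1e-12, target_var))
        for j, b in enumerate(batches):
            cols = idx[b]
            mu = corrected[:, cols].mean(axis=1)
            s = corrected[:, cols].std(axis=1, ddof=1)
            s = np.where(s <= 0, 1e-12, s)
            corrected[:, cols] = (
                (corrected[:, cols] - mu[:, None]) / s[:, None]
            ) * target_sd[:, None] + grand[:, None]

    genes = m.values.index
    model = BatchCorrectionModel(
        batches=batches,
        grand_mean=pd.Series(grand, index=genes),
        pooled_var=pd.Series(var_pooled, index=genes),
        gamma_hat=pd.DataFrame(gamma_hat, index=genes, columns=batches),
        delta_hat=pd.DataFrame(delta_hat, index=genes, columns=batches),
        gamma_star=pd.DataFrame(gamma_star, index=genes, columns=batches),
        delta_star=pd.DataFrame(delta_star, index=genes, columns=batches),
        gamma_bar=pd.Series(gamma_bar, index=batches),
        tau_sq=pd.Series(t2, index=batches),
        a_prior=pd.Series(a_prior, index=batches),
        b_prior=pd.Series(b_prior, index=batches),
        exact_align=exact_align,
    )
    out = pd.DataFrame(corrected, index=genes, columns=m.values.columns)
    return replace(m, values=out), model


def group_lfc(m: MiRNAMatrix, tumor_label: str = "tumor", cellline_label: str = "cell_line") -> LFCTable:
    """Directional log fold change: mean(cell line) - mean(tumor) per feature.

    Positive values mean higher expression in cell lines.  Expects log-scale
    values; both cohorts must be present.
    """
    cohorts = m.samples["cohort"]
    t_cols = list(cohorts.index[cohorts == tumor_label])
    c_cols = list(cohorts.index[cohorts == cellline_label])
    if not t_cols or not c_cols:
        raise MiRNAError(
            f"both cohorts required (tumor n={len(t_cols)}, cell line n={len(c_cols)})"
        )
    mean_t = m.values[t_cols].mean(axis=1)
    mean_c = m.values[c_cols].mean(axis=1)
    lfc = mean_c - mean_t
    table = pd.DataFrame(
        {
            "lfc": lfc,
            "mean_cell_line": mean_c,
            "mean_tumor": mean_t,
            "sign": np.sign(lfc).astype(int),
        }
    )
    return LFCTable(table)


# ---------------------------------------------------------------------------
# I/O


def read_mirna_matrix(path, sample_sheet_path) -> MiRNAMatrix:
    values = pd.read_csv(path, sep="\t", index_col=0).astype(float)
    samples = pd.read_csv(sample_sheet_path, sep="\t", index_col=0)
    return MiRNAMatrix(values, samples.loc[values.columns])


def read_alias_map(path) -> dict[str, str]:
    """Two-column TSV (alias, canonical); aliases stored pre-normalized."""
    df = pd.read_csv(path, sep="\t", names=["alias", "canonical"], header=0, dtype=str)
    return {normalize_mirna_id(a): normalize_mirna_id(c)
            for a, c in zip(df["alias"], df["canonical"])}


def write_alias_map(alias_map: dict[str, str], path) -> None:
    with open(path, "w") as fh:
        fh.write("alias\tcanonical\n")
        for alias in sorted(alias_map):
            fh.write(f"{alias}\t{alias_map[alias]}\n")
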