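"""Expression preprocessing: normalization, filtering, harmonization, subsetting."""

import numpy as np
import pandas as pd
import pytest

from culturedrift.preprocess import (
    LOG2_TPM1,
    TPM,
    ExpressionMatrix,
    PreprocessError,
    filter_genes,
    harmonize_cohorts,
    normalize_expression,
    partition_by_biotype,
    read_expression_tsv,
    read_mutation_table,
    subset_by_mutation,
    write_expression_tsv,
)


def _em(values, genes, samples, scale=TPM, meta=None):
    return ExpressionMatrix(
        pd.DataFrame(values, index=genes, columns=samples), scale=scale, metadata=meta
    )


class TestNormalize:
    def test_log2_closed_form(self):
        m = _em([[0.0, 1.0, 3.0]], ["g1"], ["a", "b", "c"])
        out = normalize_expression(m)
        assert out.scale == LOG2_TPM1
        np.testing.assert_allclose(out.values.loc["g1"], [0.0, 1.0, 2.0])

    def test_duplicate_rows_averaged_after_log(self):
        # TPM rows (1,3) and (3,1) -> log rows (1,2),(2,1) -> mean (1.5,1.5)
        m = _em([[1.0, 3.0], [3.0, 1.0]], ["g", "g"], ["a", "b"])
        out = normalize_expression(m)
        assert list(out.gene_ids) == ["g"]
        np.testing.assert_allclose(out.values.loc["g"], [1.5, 1.5])

    def test_unique_genes_untouched_as_set(self):
        m = _em([[1.0], [3.0]], ["g1", "g2"], ["a"])
        out = normalize_expression(m)
        assert out.gene_ids == ["g1", "g2"]

    def test_rejects_negative_with_coordinates(self):
        m = _em([[1.0, -0.5]], ["g1"], ["a", "b"])
        with pytest.raises(PreprocessError, match="g1.*b"):
            normalize_expression(m)

    def test_rejects_empty(self):
        m = ExpressionMatrix(pd.DataFrame(), scale=TPM)
        with pytest.raises(PreprocessError, match="empty"):
            normalize_expression(m)


class TestFilterGenes:
    def _toy(self):
        rng = np.random.default_rng(0)
        X = rng.normal(3, 1, (6, 10))
        X[0, :8] = 0.0  # zero in exactly 8 of 10 samples
        genes = [f"g{i}" for i in range(6)]
        return _em(X, genes, [f"s{i}" for i in range(10)], scale=LOG2_TPM1)

    def test_zero_fraction_boundary_inclusive(self):
        out, report = filter_genes(self._toy(), zero_frac_remove=0.8, low_var_frac=0.0)
        assert "g0" not in out.gene_ids
        assert report.n_zero_removed == 1 and report.n_lowvar_removed == 0

    def test_low_variance_floor_removes_exactly_one_of_five(self):
        # 5 genes with hand-ordered variances: floor(0.2 * 5) = 1 removed
        X = np.array(
            [
                [1.0, 1.0, 1.0, 1.1],  # var 0.0025 -> lowest, removed
                [1.0, 2.0, 1.0, 2.0],
                [0.0, 3.0, 0.0, 3.0],
                [1.0, 5.0, 1.0, 5.0],
                [0.0, 9.0, 0.0, 9.0],
            ]
        )
        m = _em(X, [f"g{i}" for i in range(5)], list("abcd"), scale=LOG2_TPM1)
        out, report = filter_genes(m, zero_frac_remove=1.0, low_var_frac=0.2)
        assert report.n_lowvar_removed == 1
        assert "g0" not in out.gene_ids and len(out.gene_ids) == 4

    def test_noop_configuration_is_identity(self):
        m = self._toy()
        out, report = filter_genes(m, zero_frac_remove=1.0, low_var_frac=0.0)
        pd.testing.assert_frame_equal(out.values, m.values)
        assert report.n_zero_removed == report.n_lowvar_removed == 0

    @pytest.mark.parametrize("bad", [{"zero_frac_remove": 1.2}, {"low_var_frac": -0.1}])
    def test_rejects_thresholds_outside_unit_interval(self, bad):
        with pytest.raises(PreprocessError, match="must lie"):
            filter_genes(self._toy(), **bad)

    def test_removal_counts_partition_the_input(self):
        rng = np.random.default_rng(7)
        X = rng.normal(2, 1, (40, 12))
        X[rng.random((40, 12)) < 0.4] = 0.0
        m = _em(X, [f"g{i:02d}" for i in range(40)], [f"s{i}" for i in range(12)],
                scale=LOG2_TPM1)
        out, report = filter_genes(m, zero_frac_remove=0.5, low_var_frac=0.25)
        assert set(out.gene_ids) <= set(m.gene_ids)
        assert report.n_zero_removed + report.n_lowvar_removed == (
            len(m.gene_ids) - len(out.gene_ids)
        )


class TestHarmonize:
    def _cohorts(self, t_dis=("BRCA", "GBM"), c_dis=("GBM", "OV")):
        t = _em([[1.0, 2.0], [3.0, 4.0], [5.0, 6.0]], ["a", "b", "c"],
                ["t1", "t2"], scale=LOG2_TPM1)
        c = _em([[1.0, 2.0], [3.0, 4.0], [5.0, 6.0]], ["b", "c", "d"],
                ["c1", "c2"], scale=LOG2_TPM1)
        meta = pd.DataFrame(
            {
                "cohort": ["tumor", "tumor", "cell_line", "cell_line"],
                "disease_code": list(t_dis) + list(c_dis),
            },
            index=["t1", "t2", "c1", "c2"],
        )
        return t, c, meta

    def test_gene_and_disease_intersection(self):
        t, c, meta = self._cohorts()
        merged, labels, report = harmonize_cohorts(t, c, meta)
        assert merged.gene_ids == ["b", "c"]
        # only the shared disease GBM survives: t2 and c1
        assert merged.sample_ids == ["t2", "c1"]
        assert list(labels) == ["tumor", "cell_line"]
        assert report.diseases == ["GBM"]

    def test_gene_intersection_symmetric(self):
        t, c, meta = self._cohorts(("GBM", "GBM"), ("GBM", "GBM"))
        ab, _, _ = harmonize_cohorts(t, c, meta)
        # swapping cohort roles requires swapped metadata labels too
        meta2 = meta.copy()
        ba, _, _ = harmonize_cohorts(c, t, meta2)
        assert ab.gene_ids == ba.gene_ids

    def test_identical_structure_keeps_all_samples(self):
        t, c, meta = self._cohorts(("GBM", "GBM"), ("GBM", "GBM"))
        merged, labels, _ = harmonize_cohorts(t, c, meta)
        assert merged.shape[1] == 4

    def test_rejects_empty_intersections(self):
        t, c, meta = self._cohorts(("BRCA", "BRCA"), ("OV", "OV"))
        with pytest.raises(PreprocessError, match="diseases"):
            harmonize_cohorts(t, c, meta)
        t2 = _em([[1.0, 2.0]], ["zzz"], ["t1", "t2"], scale=LOG2_TPM1)
        with pytest.raises(PreprocessError, match="genes"):
            harmonize_cohorts(t2, c, meta)


class TestMutationSubset:
    MAF = pd.DataFrame(
        {
            "Tumor_Sample_Barcode": ["s1", "s2", "s3", "s4", "s2"],
            "Hugo_Symbol": ["KRAS", "KRAS", "KRAS", "KRAS", "TP53"],
            "Variant_Classification": [
                "Missense_Mutation", "Silent", "Nonsense_Mutation",
                "Frame_Shift_Del", "Missense_Mutation",
            ],
        }
    )

    def _matrix(self):
        return _em(
            np.arange(10.0).reshape(2, 5), ["g1", "g2"],
            ["s1", "s2", "s3", "s4", "s5"], scale=LOG2_TPM1,
        )

    def test_keeps_nonsilent_carriers_only(self):
        out = subset_by_mutation(self._matrix(), self.MAF, "KRAS")
        # s1, s3, s4 carry non-silent KRAS; s2 only Silent; s5 absent (wild-type)
        assert out.sample_ids == ["s1", "s3", "s4"]

    def test_subset_and_complement_partition_samples(self):
        m = self._matrix()
        kept = set(subset_by_mutation(m, self.MAF, "KRAS").sample_ids)
        complement = set(m.sample_ids) - kept
        assert kept | complement == set(m.sample_ids) and not kept & complement

    def test_absent_gene_warns_and_returns_empty(self):
        with pytest.warns(UserWarning, match="BRAF"):
            out = subset_by_mutation(self._matrix(), self.MAF, "BRAF")
        assert out.sample_ids == []


class TestBiotypePartition:
    ANN = pd.DataFrame(
        {"biotype": ["coding", "lncRNA", "coding"]}, index=["g1", "g2", "g3"]
    )

    def test_partition(self):
        part = partition_by_biotype({"g1", "g2", "g3"}, self.ANN)
        assert part.coding == {"g1", "g3"} and part.lncRNA == {"g2"}

    def test_all_coding_gives_empty_lnc(self):
        part = partition_by_biotype({"g1", "g3"}, self.ANN)
        assert part.lncRNA == set()

    def test_unannotated_excluded_with_warning(self):
        with pytest.warns(UserWarning, match="1 gene"):
            part = partition_by_biotype({"g1", "gX"}, self.ANN)
        assert part.unannotated == {"gX"}
        assert part.coding | part.lncRNA == {"g1"}


class TestIO:
    def test_expression_tsv_round_trip(self, tmp_path):
        m = _em([[1.5, 2.5], [0.0, 3.0]], ["g1", "g2"], ["s1", "s2"])
        path = tmp_path / "expr.tsv"
        write_expression_tsv(m, path)
        back = read_expression_tsv(path)
        pd.testing.assert_frame_equal(back.values, m.values)

    def test_gct_header_tolerated(self, tmp_path):
        path = tmp_path / "expr.gct"
        path.write_text(
            "#1.2\n2\t2\nName\tDescription\ts1\ts2\n"
            "g1\tfoo\t1.0\t2.0\ng2\tbar\t3.0\t4.0\n"
        )
        m = read_expression_tsv(path)
        assert m.gene_ids == ["g1", "g2"] and m.sample_ids == ["s1", "s2"]

    def test_maf_requires_standard_columns(self, tmp_path):
        path = tmp_path / "bad.maf"
        path.write_text("Hugo_Symbol\tfoo\nKRAS\t1\n")
        with pytest.raises(PreprocessError, match="missing columns"):
            read_mutation_table(path)
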