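"""Resampled linear-SVM feature-stability selection and the two-pass protocol."""

import numpy as np
import pandas as pd
import pytest

import culturedrift.select as sel
from culturedrift.enrichment import EnrichmentResult, PathwayCollection
from culturedrift.select import (
    Blocklist,
    SelectionError,
    build_immune_blocklist,
    rank_features_single_split,
    stable_feature_set,
    two_pass_selection,
)


def _margin_objective_grid(X, y, C=1.0):
    """Brute-force grid search of the 2-feature soft-margin objective.

    Independent check of the fitted weight ordering: minimizes
    0.5 * ||w||^2 + C * sum(hinge) over a coarse (w1, w2, b) grid.
    """
    ys = np.where(y, 1.0, -1.0)
    best, best_w = np.inf, None
    for w1 in np.arange(-3, 3.01, 0.1):
        for w2 in np.arange(-1.5, 1.51, 0.1):
            margins = ys * (X[:, 0] * w1 + X[:, 1] * w2)
            for b in np.arange(-1.0, 1.01, 0.1):
                loss = 0.5 * (w1**2 + w2**2) + C * np.maximum(
                    0.0, 1.0 - (margins + ys * b)
                ).sum()
                if loss < best:
                    best, best_w = loss, (w1, w2)
    return best_w


class TestSingleSplit:
    def test_informative_gene_ranked_first(self):
        rng = np.random.default_rng(0)
        n = 100
        y = np.array([False] * 50 + [True] * 50)
        X = np.column_stack(
            [np.where(y, 2.0, -2.0) + rng.normal(0, 0.2, n), rng.normal(0, 1, n)]
        )
        values = pd.DataFrame(X.T, index=["A", "B"], columns=[f"s{i}" for i in range(n)])
        labels = pd.Series(np.where(y, "tumor", "cell_line"), index=values.columns)
        ranking = rank_features_single_split(values, labels, seed=3)
        assert ranking.ranks["A"] == 1
        assert ranking.weights["A"] > ranking.weights["B"]
        # independent brute-force check of the weight ordering on scaled data
        Xs = (X - X.mean(0)) / X.std(0)
        w = _margin_objective_grid(Xs, y)
        assert abs(w[0]) > abs(w[1])

    def test_permuted_labels_give_chance_accuracy(self, small_labeled_matrix):
        values, labels = small_labeled_matrix
        rng = np.random.default_rng(1)
        majority = max(labels.value_counts()) / len(labels)
        accs = []
        for seed in range(20):
            permuted = pd.Series(
                rng.permutation(labels.to_numpy()), index=labels.index
            )
            accs.append(
                rank_features_single_split(values, permuted, seed=seed).accuracy
            )
        assert abs(np.mean(accs) - majority) < 0.1

    def test_duplicated_feature_gets_adjacent_rank_and_equal_weight(
        self, small_labeled_matrix
    ):
        values, labels = small_labeled_matrix
        dup = values.loc[["g000"]].rename(index={"g000": "g000_copy"})
        ranking = rank_features_single_split(pd.concat([values, dup]), labels, seed=5)
        r1, r2 = ranking.ranks["g000"], ranking.ranks["g000_copy"]
        assert abs(r1 - r2) == 1
        assert ranking.weights["g000"] == pytest.approx(
            ranking.weights["g000_copy"], rel=1e-3
        )

    def test_requires_two_classes(self, small_labeled_matrix):
        values, labels = small_labeled_matrix
        with pytest.raises(SelectionError, match="classes"):
            rank_features_single_split(
                values, pd.Series("tumor", index=labels.index), seed=0
            )


class TestStableSet:
    def test_identical_rankings_intersect_to_exactly_k(
        self, small_labeled_matrix, monkeypatch
    ):
        values, labels = small_labeled_matrix
        fixed = rank_features_single_split(values, labels, seed=0)
        monkeypatch.setattr(
            sel, "rank_features_single_split", lambda *a, **k: fixed
        )
        result = stable_feature_set(values, labels, n_splits=2, top_frac=0.1)
        assert len(result.genes) == int(np.ceil(0.1 * values.shape[0]))

    def test_union_of_disjoint_top_sets_has_size_2k(
        self, small_labeled_matrix, monkeypatch
    ):
        values, labels = small_labeled_matrix
        k = int(np.ceil(0.1 * values.shape[0]))
        base = rank_features_single_split(values, labels, seed=0)
        flipped = sel.FeatureRanking(
            seed=1,
            weights=base.weights,
            ranks=pd.Series(
                len(base.ranks) + 1 - base.ranks.to_numpy(), index=base.ranks.index
            ),
            accuracy=base.accuracy,
        )
        rankings = iter([base, flipped])
        monkeypatch.setattr(
            sel, "rank_features_single_split", lambda *a, **kw: next(rankings)
        )
        result = stable_feature_set(
            values, labels, n_splits=2, top_frac=0.1, merge_rule="union"
        )
        assert len(result.genes) == 2 * k

    def test_deterministic_for_fixed_master_seed(self, small_labeled_matrix):
        values, labels = small_labeled_matrix
        a = stable_feature_set(values, labels, n_splits=4, master_seed=9)
        b = stable_feature_set(values, labels, n_splits=4, master_seed=9)
        assert a.genes == b.genes and a.split_seeds == b.split_seeds
        assert a.accuracies == b.accuracies

    def test_intersection_non_increasing_for_nested_seed_sequences(
        self, small_labeled_matrix
    ):
        values, labels = small_labeled_matrix
        sizes, seeds = [], []
        for n_splits in (2, 4, 6):
            r = stable_feature_set(values, labels, n_splits=n_splits, master_seed=3)
            sizes.append(len(r.genes))
            seeds.append(r.split_seeds)
        assert seeds[0] == seeds[1][:2] and seeds[1] == seeds[2][:4]
        assert sizes[0] >= sizes[1] >= sizes[2]

    def test_parameter_validation(self, small_labeled_matrix):
        values, labels = small_labeled_matrix
        with pytest.raises(SelectionError):
            stable_feature_set(values, labels, n_splits=0)
        with pytest.raises(SelectionError):
            stable_feature_set(values, labels, top_frac=0.0)
        with pytest.raises(SelectionError):
            stable_feature_set(values, labels, merge_rule="xor")


def _enr(pathway, category, q):
    return EnrichmentResult(
        pathway=pathway, category=category, universe_size=100, pathway_size=10,
        query_size=10, overlap=5, p_value=q / 2, q_value=q, significant=q < 0.05,
    )


class TestBlocklist:
    COLL = PathwayCollection(
        sets={
            "imm1": frozenset({"a", "b"}),
            "imm2": frozenset({"b", "c", "offdata"}),
            "other1": frozenset({"d"}),
        },
        categories={"imm1": "immune", "imm2": "immune", "other1": "metabolism"},
    )

    def test_union_of_enriched_immune_pathways(self):
        enr = [_enr("imm1", "immune", 0.01), _enr("imm2", "immune", 0.02),
               _enr("other1", "metabolism", 0.001)]
        bl = build_immune_blocklist(enr, self.COLL, {"a", "b", "c", "d"})
        assert bl.genes == {"a", "b", "c"}
        assert bl.provenance == ["imm1", "imm2"]

    def test_no_immune_enriched_gives_empty_with_notice(self):
        enr = [_enr("other1", "metabolism", 0.001), _enr("imm1", "immune", 0.9)]
        with pytest.warns(UserWarning, match="no immune"):
            bl = build_immune_blocklist(enr, self.COLL, {"a", "b"})
        assert bl.genes == frozenset()

    def test_restricted_to_dataset_genes(self):
        enr = [_enr("imm2", "immune", 0.01)]
        bl = build_immune_blocklist(enr, self.COLL, {"b", "c", "zzz"})
        assert bl.genes == {"b", "c"}  # "offdata" not in the dataset


class TestTwoPass:
    def test_empty_blocklist_equals_single_pass(self, small_labeled_matrix):
        values, labels = small_labeled_matrix
        coll = PathwayCollection(sets={"pw": frozenset({"g001", "g002"})})
        with pytest.warns(UserWarning, match="no immune"):
            result = two_pass_selection(
                values, labels, coll, n_splits=3, master_seed=2
            )
        single = stable_feature_set(values, labels, n_splits=3, master_seed=2)
        assert result.final.genes == single.genes
        assert result.blocklist.genes == frozenset()

    def test_final_set_disjoint_from_blocklist(self, two_pass):
        assert not (two_pass.final.genes & two_pass.blocklist.genes)

    def test_blocklist_covering_all_genes_rejected(self, small_labeled_matrix):
        values, labels = small_labeled_matrix
        coll = PathwayCollection(
            sets={"imm_all": frozenset(values.index)},
            categories={"imm_all": "immune"},
        )
        # alpha > 1 forces every pathway significant, so the blocklist is total
        with pytest.raises(SelectionError, match="blocklist"):
            two_pass_selection(
                values, labels, coll, n_splits=2, master_seed=0, alpha=1.5
            )
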