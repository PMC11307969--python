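
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import pdxkit as pk
from pdxkit.knn import ConstantExpressionError, NeighborRanking

from conftest import random_integer_cohort
from oracles import brute_rank_neighbors, brute_vote, closed_form_spearman


def make_ranking(labels_best_to_worst, rhos=None):
    """Build a ranking directly from an ordered label list."""
    n = len(labels_best_to_worst)
    rhos = rhos or [1.0 - i / n for i in range(n)]
    sample_ids = [f"r{i:02d}" for i in range(n)]
    ranking = NeighborRanking("q", list(zip(sample_ids, rhos)))
    labels = pd.Series(labels_best_to_worst, index=sample_ids)
    return ranking, labels


class TestSpearmanRho:
    def test_identity_and_antisymmetry(self):
        x = np.array([3.0, 1.0, 4.0, 1.5])
        assert pk.spearman_rho(x, x) == pytest.approx(1.0)
        order = np.argsort(x)
        reverse = np.empty_like(x)
        reverse[order] = x[order[::-1]]
        assert pk.spearman_rho(x, reverse) == pytest.approx(-1.0)

    def test_hand_derived_value(self):
        assert pk.spearman_rho([1, 2, 3, 4], [1, 3, 2, 4]) == pytest.approx(0.8)

    def test_constant_vector_is_an_error_not_zero(self):
        with pytest.raises(ConstantExpressionError):
            pk.spearman_rho([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_ties_use_average_ranks(self):
        # ranks x = (1, 2.5, 2.5, 4), ranks y = (3, 1, 2, 4): rho = 1/sqrt(10)
        rho = pk.spearman_rho([1.0, 2.0, 2.0, 4.0], [3.0, 1.0, 2.0, 4.0])
        assert rho == pytest.approx(1.0 / np.sqrt(10.0))

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(st.permutations(range(5)))
    def test_matches_closed_form_on_distinct_values(self, perm):
        x = np.arange(5, dtype=float)
        y = np.array(perm, dtype=float)
        assert pk.spearman_rho(x, y) == pytest.approx(closed_form_spearman(x, y))


class TestRankNeighbors:
    def _cohort(self, reference, labels):
        return pk.ReferenceCohort(pk.ExpressionMatrix(reference, unit="rpkm"), labels)

    def test_identical_sample_ranks_first_with_rho_one(self):
        ref = pd.DataFrame(
            {"a": [1.0, 5.0, 2.0], "b": [9.0, 1.0, 4.0], "c": [2.0, 3.0, 8.0]},
            index=["g1", "g2", "g3"],
        )
        labels = pd.Series({"a": "X", "b": "Y", "c": "Z"})
        query = ref["b"].rename("q")
        ranking = pk.rank_neighbors(query, self._cohort(ref, labels))
        assert len(ranking.neighbors) == 3
        assert ranking.neighbors[0] == ("b", pytest.approx(1.0))

    def test_ordering_matches_pairwise_oracle(self):
        rng = np.random.default_rng(42)
        ref = pd.DataFrame(
            rng.integers(0, 6, size=(5, 4)).astype(float),
            index=[f"g{i}" for i in range(5)],
            columns=["r0", "r1", "r2", "r3"],
        )
        query = pd.Series(rng.integers(0, 6, 5).astype(float), index=ref.index, name="q")
        labels = pd.Series("X", index=ref.columns)
        ranking = pk.rank_neighbors(query, self._cohort(ref, labels))
        expected = brute_rank_neighbors(query, ref)
        assert [s for s, _ in ranking.neighbors] == [s for s, _ in expected]
        np.testing.assert_allclose(
            [r for _, r in ranking.neighbors], [r for _, r in expected], atol=1e-12
        )

    def test_constant_reference_excluded_with_warning(self, caplog):
        ref = pd.DataFrame(
            {"a": [1.0, 2.0, 3.0], "flat": [2.0, 2.0, 2.0]}, index=["g1", "g2", "g3"]
        )
        labels = pd.Series({"a": "X", "flat": "Y"})
        query = pd.Series([3.0, 1.0, 2.0], index=ref.index, name="q")
        with caplog.at_level("WARNING", logger="pdxkit.knn"):
            ranking = pk.rank_neighbors(query, self._cohort(ref, labels))
        assert [s for s, _ in ranking.neighbors] == ["a"]
        assert "constant reference" in caplog.text

    def test_monotone_transform_leaves_ranking_unchanged(self):
        rng = np.random.default_rng(3)
        ref = pd.DataFrame(
            rng.random((6, 5)) * 100, index=[f"g{i}" for i in range(6)],
            columns=[f"r{i}" for i in range(5)],
        )
        labels = pd.Series("X", index=ref.columns)
        query = pd.Series(rng.random(6) * 100, index=ref.index, name="q")
        base = pk.rank_neighbors(query, self._cohort(ref, labels))
        transformed = pk.rank_neighbors(
            np.exp(query / 20.0).rename("q"), self._cohort(ref, labels)
        )
        assert [s for s, _ in base.neighbors] == [s for s, _ in transformed.neighbors]

    def test_gene_and_sample_permutation_invariance(self):
        rng = np.random.default_rng(5)
        ref = pd.DataFrame(
            rng.random((6, 5)), index=[f"g{i}" for i in range(6)],
            columns=[f"r{i}" for i in range(5)],
        )
        labels = pd.Series(["A", "B", "A", "B", "A"], index=ref.columns)
        query = pd.Series(rng.random(6), index=ref.index, name="q")
        base = pk.classify_knn(
            pk.rank_neighbors(query, self._cohort(ref, labels)), labels, k=3
        )
        gene_perm = rng.permutation(ref.index)
        sample_perm = rng.permutation(ref.columns)
        shuffled = pk.classify_knn(
            pk.rank_neighbors(
                query.loc[gene_perm],
                self._cohort(ref.loc[gene_perm, sample_perm], labels),
            ),
            labels, k=3,
        )
        assert base.predicted_label == shuffled.predicted_label
        assert base.agreement == shuffled.agreement


class TestClassifyKnn:
    def test_k1_takes_top_neighbor(self):
        ranking, labels = make_ranking(["A", "B", "B"])
        result = pk.classify_knn(ranking, labels, k=1)
        assert result.predicted_label == "A"
        assert result.removed_for_tiebreak == 0

    def test_tie_drops_worst_and_revotes(self):
        # (A,A,B,B,A,B) at k=6: 3-3 tie; dropping the worst B gives A the vote
        ranking, labels = make_ranking(["A", "A", "B", "B", "A", "B"])
        result = pk.classify_knn(ranking, labels, k=6)
        assert result.predicted_label == "A"
        assert result.removed_for_tiebreak == 1

    def test_alternating_tie_needs_repeated_removal(self):
        # (A,B,A,B): 2-2, drop -> (A,B,A) resolves; removed once
        ranking, labels = make_ranking(["A", "B", "A", "B"])
        result = pk.classify_knn(ranking, labels, k=4)
        assert result.predicted_label == "A"
        assert result.removed_for_tiebreak == 1

    def test_single_class_cohort_always_that_label(self):
        ranking, labels = make_ranking(["Z"] * 5)
        for k in range(1, 6):
            assert pk.classify_knn(ranking, labels, k=k).predicted_label == "Z"

    def test_k_out_of_range_rejected(self):
        ranking, labels = make_ranking(["A", "B"])
        with pytest.raises(ValueError):
            pk.classify_knn(ranking, labels, k=0)
        with pytest.raises(ValueError):
            pk.classify_knn(ranking, labels, k=3)

    def test_matches_bruteforce_on_random_small_cohorts(self):
        for seed in range(100):
            query, reference, labels, k = random_integer_cohort(seed)
            cohort = pk.ReferenceCohort(
                pk.ExpressionMatrix(reference, unit="rpkm"), labels
            )
            try:
                ranking = pk.rank_neighbors(query, cohort)
            except ConstantExpressionError:
                continue
            result = pk.classify_knn(ranking, labels, k=min(k, len(ranking.neighbors)))
            ordered = brute_rank_neighbors(query, reference)
            expected_label, expected_removed = brute_vote(
                [labels[s] for s, _ in ordered], min(k, len(ordered))
            )
            assert result.predicted_label == expected_label
            assert result.removed_for_tiebreak == expected_removed


class TestAgreementScore:
    @pytest.mark.parametrize(
        "labels, predicted, expected",
        [
            (["A"] * 10, "A", 1.0),
            (["B"] * 10, "A", 0.0),
            (["A"] * 7 + ["B"] * 3, "A", 0.7),
        ],
    )
    def test_top10_fraction(self, labels, predicted, expected):
        ranking, label_map = make_ranking(labels + ["B", "A"])  # 12 neighbors
        assert pk.agreement_score(ranking, label_map, predicted) == pytest.approx(expected)

    def test_short_ranking_uses_all_neighbors(self):
        ranking, labels = make_ranking(["A", "A", "B"])
        assert pk.agreement_score(ranking, labels, "A") == pytest.approx(2 / 3)

    def test_agreement_on_tenths_grid(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            labels = list(rng.choice(["A", "B", "C"], size=12))
            ranking, label_map = make_ranking(labels)
            score = pk.agreement_score(ranking, label_map, "A")
            assert round(score * 10) == pytest.approx(score * 10)


class TestLoocv:
    def test_singleton_grid_chooses_that_k(self, separable_cohort):
        cohort, _ = separable_cohort
        report = pk.loocv_select_k(cohort, ["tumor_type"], [6])
        assert report.chosen_k == 6

    def test_separable_cohort_is_perfect_below_class_size(self, separable_cohort):
        cohort, _ = separable_cohort
        smallest = cohort.labels.value_counts().min()
        report = pk.loocv_select_k(
            cohort, ["tumor_type"], list(range(1, smallest))
        )
        for k in report.k_grid:
            assert report.accuracy[("tumor_type", k)] == 1.0

    def test_shuffled_labels_fall_to_chance(self, separable_cohort):
        cohort, _ = separable_cohort
        rng = np.random.default_rng(2024)
        shuffled = pd.Series(
            rng.permutation(cohort.labels.to_numpy()), index=cohort.labels.index
        )
        null_cohort = pk.ReferenceCohort(
            cohort.expression, shuffled, metadata={"tumor_type": shuffled}
        )
        report = pk.loocv_select_k(null_cohort, ["tumor_type"], [6])
        n = len(shuffled)
        p = 1.0 / shuffled.nunique()
        se = np.sqrt(p * (1 - p) / n)
        assert abs(report.accuracy[("tumor_type", 6)] - p) <= 3 * se

    def test_empty_inputs_rejected(self, separable_cohort):
        cohort, _ = separable_cohort
        with pytest.raises(ValueError):
            pk.loocv_select_k(cohort, [], [6])
        with pytest.raises(ValueError):
            pk.loocv_select_k(cohort, ["tumor_type"], [])

    def test_ties_choose_smallest_k(self, separable_cohort):
        cohort, _ = separable_cohort
        report = pk.loocv_select_k(cohort, ["tumor_type"], [3, 5, 7])
        assert report.chosen_k == 3  # all perfect; smallest wins


class TestClassifyCohort:
    def test_duplicated_reference_sample_self_matches(self, separable_cohort):
        cohort, _ = separable_cohort
        sample_id = cohort.expression.sample_ids[0]
        queries = pk.ExpressionMatrix(
            cohort.expression.data[[sample_id]].rename(columns={sample_id: "q"}),
            unit="rpkm",
        )
        results, errors = pk.classify_cohort(queries, cohort, k=1)
        assert not errors
        assert results[0].predicted_label == cohort.labels[sample_id]

    def test_empty_batch_gives_empty_results(self, separable_cohort):
        cohort, _ = separable_cohort
        queries = pk.ExpressionMatrix(
            pd.DataFrame(index=cohort.expression.data.index), unit="rpkm"
        )
        results, errors = pk.classify_cohort(queries, cohort, k=6)
        assert results == [] and errors == {}

    def test_constant_query_reported_not_fatal(self, separable_cohort):
        cohort, _ = separable_cohort
        genes = cohort.expression.data.index
        data = pd.DataFrame(
            {"flat": np.ones(len(genes)),
             "ok": cohort.expression.data.iloc[:, 0].to_numpy()},
            index=genes,
        )
        results, errors = pk.classify_cohort(
            pk.ExpressionMatrix(data, unit="rpkm"), cohort, k=6
        )
        assert [r.query_id for r in results] == ["ok"]
        assert "flat" in errors
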