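import numpy as np
import pandas as pd
import pytest

from difreg import ExpressionMatrix, condition_means, rank_tfs, rif_scores

from conftest import make_matrix, pearson_oracle


def rif_oracle(tf_row_a, tf_row_b, deg_rows_a, deg_rows_b):
    """Per-term loop over DEGs, independent of the vectorised implementation."""
    terms = []
    for deg_a, deg_b in zip(deg_rows_a, deg_rows_b):
        e1, e2 = np.mean(deg_a), np.mean(deg_b)
        r1 = pearson_oracle(tf_row_a, deg_a)
        r2 = pearson_oracle(tf_row_b, deg_b)
        if np.isnan(r1) or np.isnan(r2):
            terms.append(0.0)
        else:
            terms.append((e1 * r1) ** 2 - (e2 * r2) ** 2)
    return float(np.mean(terms))


class TestConditionMeans:
    def test_simple_means(self):
        matrix = make_matrix([[1, 3, 2, 2, 2]], n_a=2, n_b=3)
        means = condition_means(matrix, ["g1"])
        assert means.loc["g1", "e1"] == pytest.approx(2.0)
        assert means.loc["g1", "e2"] == pytest.approx(2.0)

    def test_constant_gene(self):
        matrix = make_matrix([[4, 4, 4, 4, 4, 4]], n_a=3, n_b=3)
        means = condition_means(matrix)
        assert means.loc["g1", "e1"] == means.loc["g1", "e2"] == 4.0

    def test_unknown_gene_rejected(self, random_matrix):
        with pytest.raises(KeyError):
            condition_means(random_matrix, ["missing"])

    def test_matches_loop_oracle(self):
        rng = np.random.default_rng(31)
        matrix = make_matrix(rng.normal(size=(20, 10)), n_a=4, n_b=6)
        means = condition_means(matrix)
        for gene in matrix.gene_ids:
            row = matrix.data.loc[gene]
            assert abs(means.loc[gene, "e1"] - row[:4].mean()) < 1e-12
            assert abs(means.loc[gene, "e2"] - row[4:].mean()) < 1e-12


class TestRifScores:
    def test_cancellation_case_scores_zero(self):
        # DEG1: e1 = 2, e2 = 1, r1 = 1, r2 = 0; DEG2: e1 = 1, e2 = 2,
        # r1 = 0, r2 = 1 -> terms (2*1)^2 - 0 and 0 - (2*1)^2 cancel.
        matrix = make_matrix(
            [[1, 2, 3, 1, 2, 3],          # TF
             [1, 2, 3, 0.5, 2, 0.5],      # DEG1
             [0.5, 2, 0.5, 1, 2, 3]],     # DEG2
            gene_ids=["TF", "D1", "D2"], n_a=3, n_b=3)
        means = condition_means(matrix, ["D1", "D2"])
        assert means.loc["D1", "e1"] == pytest.approx(2.0)
        assert means.loc["D1", "e2"] == pytest.approx(1.0)
        scores = rif_scores(["TF"], ["D1", "D2"], means, matrix)
        assert scores.loc[0, "rif"] == pytest.approx(0.0, abs=1e-12)

    def test_single_deg_worked_case(self):
        # e1 = 3, e2 = 1, r1 = r2 = 0.5 -> RIF = 1.5^2 - 0.5^2 = 2.0
        matrix = make_matrix(
            [[1, 2, 3, 1, 2, 3],   # TF
             [3, 2, 4, 1, 0, 2]],  # DEG: corr 0.5 with TF in both conditions
            gene_ids=["TF", "D1"], n_a=3, n_b=3)
        means = condition_means(matrix, ["D1"])
        assert means.loc["D1", "e1"] == pytest.approx(3.0)
        assert means.loc["D1", "e2"] == pytest.approx(1.0)
        scores = rif_scores(["TF"], ["D1"], means, matrix)
        assert scores.loc[0, "rif"] == pytest.approx(2.0, abs=1e-12)

    def test_duplicated_conditions_force_zero(self):
        rng = np.random.default_rng(12)
        half = rng.normal(size=(10, 5))
        matrix = make_matrix(np.hstack([half, half]), n_a=5, n_b=5)
        genes = matrix.gene_ids
        scores = rif_scores(genes[:3], genes[3:], condition_means(matrix), matrix)
        np.testing.assert_allclose(scores["rif"], 0.0, atol=1e-12)

    def test_matches_per_term_loop_oracle(self):
        rng = np.random.default_rng(77)
        matrix = make_matrix(rng.normal(size=(15, 12)) + 5, n_a=5, n_b=7)
        tfs, degs = matrix.gene_ids[:4], matrix.gene_ids[4:]
        scores = rif_scores(tfs, degs, condition_means(matrix, degs), matrix)
        a = matrix.data[matrix.samples_in("A")].to_numpy()
        b = matrix.data[matrix.samples_in("B")].to_numpy()
        for i, tf in enumerate(tfs):
            expected = rif_oracle(a[i], b[i], a[4:], b[4:])
            assert abs(scores.loc[i, "rif"] - expected) < 1e-10

    def test_condition_swap_negates_scores(self):
        rng = np.random.default_rng(78)
        matrix = make_matrix(rng.normal(size=(10, 12)) + 3, n_a=6, n_b=6)
        tfs, degs = matrix.gene_ids[:2], matrix.gene_ids[2:]
        scores = rif_scores(tfs, degs, condition_means(matrix, degs), matrix)
        swapped = ExpressionMatrix(matrix.data,
                                   matrix.conditions.map({"A": "B", "B": "A"}))
        flipped = rif_scores(tfs, degs, condition_means(swapped, degs), swapped)
        np.testing.assert_allclose(flipped["rif"], -scores["rif"], atol=1e-12)

    def test_scaling_condition_a_scales_positive_part(self):
        # multiplying all condition-A values of the DEGs by c scales e1 by c
        # while correlations are scale invariant
        rng = np.random.default_rng(79)
        values = rng.normal(size=(3, 10)) + 4
        matrix = make_matrix(values, gene_ids=["TF", "D1", "D2"], n_a=5, n_b=5)
        degs = ["D1", "D2"]
        base = rif_scores(["TF"], degs, condition_means(matrix, degs), matrix)
        scaled_values = values.copy()
        scaled_values[1:, :5] *= 3.0
        scaled = make_matrix(scaled_values, gene_ids=["TF", "D1", "D2"],
                             n_a=5, n_b=5)
        got = rif_scores(["TF"], degs, condition_means(scaled, degs), scaled)
        # recompute directly: positive parts scale by 9, negative unchanged
        a = values[:, :5]
        b = values[:, 5:]
        pos = np.mean([(a[j].mean() * pearson_oracle(a[0], a[j])) ** 2
                       for j in (1, 2)])
        neg = np.mean([(b[j].mean() * pearson_oracle(b[0], b[j])) ** 2
                       for j in (1, 2)])
        assert got.loc[0, "rif"] == pytest.approx(9 * pos - neg, abs=1e-10)
        assert base.loc[0, "rif"] == pytest.approx(pos - neg, abs=1e-10)

    def test_undefined_correlations_contribute_zero_and_are_tallied(self):
        matrix = make_matrix(
            [[1, 2, 3, 1, 2, 3],
             [5, 5, 5, 5, 5, 5],   # constant DEG: undefined correlation
             [3, 2, 4, 1, 0, 2]],
            gene_ids=["TF", "D0", "D1"], n_a=3, n_b=3)
        degs = ["D0", "D1"]
        scores = rif_scores(["TF"], degs, condition_means(matrix, degs), matrix)
        assert scores.loc[0, "n_excluded_pairs"] == 1
        assert scores.loc[0, "n_de"] == 2
        assert scores.loc[0, "rif"] == pytest.approx(2.0 / 2, abs=1e-12)

    def test_empty_deg_list_rejected(self, random_matrix):
        means = condition_means(random_matrix)
        with pytest.raises(ValueError, match="n_de"):
            rif_scores(["g1"], [], means, random_matrix)

    def test_missing_tf_named_in_error(self, random_matrix):
        means = condition_means(random_matrix)
        with pytest.raises(KeyError, match="ghost"):
            rif_scores(["ghost"], ["g1"], means, random_matrix)


class TestRankTfs:
    def test_ties_broken_by_tf_id(self):
        scores = pd.DataFrame({"tf_id": ["T2", "T1", "T3"],
                               "rif": [3.3, 3.6, 3.6],
                               "n_de": 5, "n_excluded_pairs": 0})
        ranked = rank_tfs(scores)
        assert list(ranked["tf_id"]) == ["T1", "T3", "T2"]
        assert list(ranked["rank"]) == [1, 2, 3]

    def test_single_tf_gets_rank_one(self):
        ranked = rank_tfs(pd.DataFrame({"tf_id": ["T"], "rif": [0.5]}))
        assert list(ranked["rank"]) == [1]

    def test_printed_score_table_ranking(self):
        # eleven published impact scores; ranking by value descending must
        # reproduce the published order
        published = [
            ("HAND1", 3.675835, 1), ("PTK7", 3.646741, 2),
            ("NFKB1", 3.341134, 3), ("ZIC3", 3.321142, 4),
            ("STAT6", 3.301687, 5), ("E2F1", 3.206273, 6),
            ("PELP1", 3.051003, 7), ("USF2", 3.037221, 8),
            ("CBFB", 2.996446, 9), ("SOX9", 2.968472, 10),
            ("FOXO4", 2.837118, 11),
        ]
        shuffled = pd.DataFrame(
            {"tf_id": [t for t, _, _ in published][::-1],
             "rif": [s for _, s, _ in published][::-1]})
        ranked = rank_tfs(shuffled)
        got = dict(zip(ranked["tf_id"], ranked["rank"]))
        assert got == {t: r for t, _, r in published}
        assert got["HAND1"] == 1
        assert got["NFKB1"] == 3

    def test_rank_by_abs(self):
        scores = pd.DataFrame({"tf_id": ["T1", "T2"], "rif": [-5.0, 1.0]})
        assert list(rank_tfs(scores, "abs")["tf_id"]) == ["T1", "T2"]
        assert list(rank_tfs(scores, "value")["tf_id"]) == ["T2", "T1"]

    def test_invalid_rank_key_rejected(self):
        with pytest.raises(ValueError):
            rank_tfs(pd.DataFrame({"tf_id": ["T"], "rif": [1.0]}), "bogus")
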