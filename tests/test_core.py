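"""The scoring algorithm: normalization factors, rank weights, pathway
scores, and their invariances, checked against a brute-force oracle."""

import numpy as np
import pytest
import scipy.sparse as sp
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import naive_score_pathway, random_case
from sipsic import (
    CPM,
    DENOM_WEIGHTED_MEAN,
    ExpressionMatrix,
    GeneSet,
    GeneSetCollection,
    normalization_factor,
    normalization_factors,
    normalize_genes,
    rank_weights,
    score_collection,
    score_pathway,
    top_tau_count,
)
from sipsic.errors import CoverageError, EmptyResultError, ParameterError


class TestTopTauCount:
    @pytest.mark.parametrize("n,tau,expected", [
        (100, 5, 5),      # 5% of 100
        (3, 5, 1),        # floor at one cell
        (1000, 2, 20),
        (7, 50, 4),       # ceil(3.5)
        (1, 100, 1),
    ])
    def test_ceil_with_floor_of_one(self, n, tau, expected):
        assert top_tau_count(n, tau) == expected

    @pytest.mark.parametrize("tau", [0, -1, 101])
    def test_tau_out_of_range(self, tau):
        with pytest.raises(ParameterError):
            top_tau_count(100, tau)


class TestNormalizationFactor:
    def test_median_of_top_window(self):
        values = np.zeros(100)
        values[:5] = [1, 2, 3, 4, 5]
        assert normalization_factor(values, tau=5) == 3.0

    def test_all_zero_gene_yields_zero(self):
        assert normalization_factor(np.zeros(50), tau=5) == 0.0

    def test_zero_median_falls_back_to_max(self):
        # top-5 window = {7, 0, 0, 0, 0}: median 0, so NF = max = 7
        values = np.zeros(100)
        values[0] = 7.0
        assert normalization_factor(values, tau=5) == 7.0

    def test_sparse_rows_agree_with_dense(self, rng):
        x = rng.random((30, 60))
        x[x < 0.8] = 0
        m_dense = ExpressionMatrix(x, [f"g{i}" for i in range(30)],
                                   [f"c{j}" for j in range(60)], CPM)
        m_sparse = ExpressionMatrix(sp.csr_matrix(x), m_dense.gene_ids,
                                    m_dense.cell_ids, CPM)
        nf_d = normalization_factors(m_dense, tau=5).factors
        nf_s = normalization_factors(m_sparse, tau=5).factors
        np.testing.assert_allclose(nf_d, nf_s, atol=1e-15)


class TestNormalizeGenes:
    def test_elementwise_division(self):
        m = ExpressionMatrix(np.array([[1.0, 2.0, 3.0]]), ["g"],
                             ["a", "b", "c"], CPM)
        nf = normalization_factors(m, tau=100)  # median of all 3 = 2... use direct
        s = normalize_genes(m, nf)
        np.testing.assert_allclose(np.asarray(s), [[0.5, 1.0, 1.5]])

    def test_all_zero_gene_row_stays_zero_without_nan(self):
        m = ExpressionMatrix(np.zeros((1, 4)), ["g"], list("abcd"), CPM)
        s = normalize_genes(m, normalization_factors(m, tau=5))
        assert np.all(np.asarray(s) == 0.0)
        assert np.isfinite(np.asarray(s)).all()

    def test_per_gene_scale_invariance(self, rng):
        x = rng.random((4, 10)) * 50
        m = ExpressionMatrix(x, [f"g{i}" for i in range(4)],
                             [f"c{j}" for j in range(10)], CPM)
        s1 = np.asarray(normalize_genes(m, normalization_factors(m, 5)))
        x2 = x.copy()
        x2[2, :] *= 13.0
        m2 = ExpressionMatrix(x2, m.gene_ids, m.cell_ids, CPM)
        s2 = np.asarray(normalize_genes(m2, normalization_factors(m2, 5)))
        np.testing.assert_allclose(s1, s2, rtol=1e-12)


class TestRankWeights:
    def test_ascending_with_total_expression(self):
        m = ExpressionMatrix(np.array([[1.0, 2.0, 3.0], [0.0, 1.0, 6.0]]),
                             ["A", "B"], ["c1", "c2", "c3"], CPM)
        rw = rank_weights(m, GeneSet("S", ["A", "B"]))
        assert dict(zip(rw.gene_ids, rw.ranks)) == {"A": 1.0, "B": 2.0}

    def test_ties_get_midranks(self):
        m = ExpressionMatrix(np.array([[3.0, 3.0], [2.0, 4.0]]),
                             ["A", "B"], ["c1", "c2"], CPM)
        rw = rank_weights(m, GeneSet("S", ["A", "B"]))
        np.testing.assert_allclose(rw.ranks, [1.5, 1.5])

    def test_rank_sum_is_triangular_number(self, rng):
        for _ in range(20):
            m, gs = random_case(rng)
            rw = rank_weights(m, gs)
            assert rw.ranks.sum() == pytest.approx(rw.n_set * (rw.n_set + 1) / 2)

    def test_missing_genes_recorded(self):
        m = ExpressionMatrix(np.ones((1, 2)), ["A"], ["c1", "c2"], CPM)
        rw = rank_weights(m, GeneSet("S", ["A", "ZZZ"]))
        assert rw.genes_missing == ["ZZZ"] and rw.n_set == 1

    def test_zero_overlap_raises_coverage_error(self):
        m = ExpressionMatrix(np.ones((1, 2)), ["A"], ["c1", "c2"], CPM)
        with pytest.raises(CoverageError, match="S"):
            rank_weights(m, GeneSet("S", ["X", "Y"]))


class TestScorePathway:
    def test_worked_example(self, worked_matrix):
        scores = score_pathway(worked_matrix, GeneSet("S", ["A", "B"]), tau=5)
        np.testing.assert_allclose(scores, [1 / 12, 1 / 4, 3 / 4], atol=1e-15)

    def test_single_gene_constant_expression_scores_one(self):
        m = ExpressionMatrix(np.full((1, 5), 4.2), ["g"],
                             [f"c{j}" for j in range(5)], CPM)
        np.testing.assert_allclose(score_pathway(m, GeneSet("S", ["g"])), 1.0)

    def test_weighted_mean_denominator_is_constant_rescale(self, worked_matrix):
        gs = GeneSet("S", ["A", "B"])
        default = score_pathway(worked_matrix, gs)
        wmean = score_pathway(worked_matrix, gs,
                              weight_denominator=DENOM_WEIGHTED_MEAN)
        # n_P = 2: denominators 4 vs 3
        np.testing.assert_allclose(wmean, default * 4.0 / 3.0, rtol=1e-12)

    def test_oracle_equivalence_random_cases(self, rng):
        for _ in range(50):
            m, gs = random_case(rng)
            tau = float(rng.choice([2.0, 5.0, 10.0, 50.0]))
            got = score_pathway(m, gs, tau=tau)
            rows = [list(m.values[m.gene_index()[g], :]) for g in gs.genes]
            want = naive_score_pathway(rows, tau)
            np.testing.assert_allclose(got, want, atol=1e-12)

    def test_sparse_dense_agreement(self, rng):
        for _ in range(20):
            m, gs = random_case(rng)
            m_sp = ExpressionMatrix(sp.csr_matrix(m.values), m.gene_ids,
                                    m.cell_ids, CPM)
            np.testing.assert_allclose(score_pathway(m, gs),
                                       score_pathway(m_sp, gs), atol=1e-12)

    def test_monotone_dominance(self, rng):
        """If one cell dominates another elementwise on set genes, its score
        is at least as large."""
        for _ in range(20):
            m, gs = random_case(rng)
            rows = np.array([m.gene_index()[g] for g in gs.genes])
            sub = m.values[rows, :]
            scores = score_pathway(m, gs)
            for j in range(m.n_cells):
                for k in range(m.n_cells):
                    if np.all(sub[:, j] >= sub[:, k]):
                        assert scores[j] >= scores[k] - 1e-12

    @settings(max_examples=30, deadline=None)
    @given(st.integers(0, 2**32 - 1))
    def test_nonnegative_and_finite(self, seed):
        m, gs = random_case(np.random.default_rng(seed))
        scores = score_pathway(m, gs)
        assert np.isfinite(scores).all()
        assert (scores >= 0).all()

    @settings(max_examples=30, deadline=None)
    @given(st.integers(0, 2**32 - 1))
    def test_cell_permutation_equivariance(self, seed):
        case_rng = np.random.default_rng(seed)
        m, gs = random_case(case_rng)
        perm = case_rng.permutation(m.n_cells)
        m_perm = ExpressionMatrix(m.values[:, perm], m.gene_ids,
                                  m.cell_ids[perm], CPM)
        np.testing.assert_allclose(score_pathway(m_perm, gs),
                                   score_pathway(m, gs)[perm], atol=1e-12)


class TestScoreCollection:
    def test_zero_coverage_set_skipped_not_dropped_silently(self, worked_matrix):
        coll = GeneSetCollection([GeneSet("GOOD", ["A", "B"]),
                                  GeneSet("ABSENT", ["X", "Y"])])
        result = score_collection(worked_matrix, coll)
        assert result.pathways == ["GOOD"]
        assert [name for name, _ in result.skipped] == ["ABSENT"]

    def test_batch_equals_per_set_loop(self, rng):
        m, _ = random_case(rng, max_genes=15, max_cells=8)
        sets = []
        for i in range(4):
            size = rng.integers(1, 5)
            sets.append(GeneSet(f"S{i}", list(rng.choice(m.gene_ids, size=size,
                                                         replace=False))))
        coll = GeneSetCollection(sets)
        batch = score_collection(m, coll)
        for s in sets:
            np.testing.assert_allclose(batch.frame.loc[s.name].to_numpy(),
                                       score_pathway(m, s), atol=1e-15)

    def test_all_sets_skipped_raises(self, worked_matrix):
        coll = GeneSetCollection([GeneSet("NOPE", ["Q"])])
        with pytest.raises(EmptyResultError):
            score_collection(worked_matrix, coll)

    def test_metadata_records_coverage(self, worked_matrix):
        coll = GeneSetCollection([GeneSet("S", ["A", "B", "MISSING"])])
        result = score_collection(worked_matrix, coll)
        info = result.info["S"]
        assert info.n_set == 2 and info.genes_missing == ["MISSING"]
        assert info.coverage == pytest.approx(2 / 3)
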