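import numpy as np
import pytest

from tripath import (
    AssociationMatrix,
    EntityIndex,
    PathParams,
    ScoreMatrix,
    SimilarityMatrix,
    assemble_three_layer,
    fdecay,
    integrate_scores,
    predict,
    two_layer_path_scores,
)

from _oracles import (
    exhaustive_two_layer,
    loop_integrate,
    random_normalized_association,
    random_similarity,
)


def _random_instance(rng, max_n=8):
    p, q, r = (int(x) for x in rng.integers(2, max_n + 1, size=3))
    idx_m = EntityIndex([f"m{i}" for i in range(p)], "mirna")
    idx_b = EntityIndex([f"b{i}" for i in range(q)], "drug")
    idx_d = EntityIndex([f"d{i}" for i in range(r)], "disease")
    S1 = SimilarityMatrix(random_similarity(rng, p), idx_m)
    S2 = SimilarityMatrix(random_similarity(rng, q), idx_b)
    S3 = SimilarityMatrix(random_similarity(rng, r), idx_d)
    A1 = AssociationMatrix((rng.random((p, r)) < 0.4).astype(float), idx_m, idx_d)
    A2 = AssociationMatrix((rng.random((p, q)) < 0.4).astype(float), idx_m, idx_b)
    A3 = AssociationMatrix((rng.random((q, r)) < 0.4).astype(float), idx_b, idx_d)
    return S1, S2, S3, A1, A2, A3


class TestFdecay:
    @pytest.mark.parametrize(
        "length, beta, expected", [(2, 7.0, 14.0), (1, 7.0, 7.0), (2, 1.0, 2.0)]
    )
    def test_values(self, length, beta, expected):
        assert fdecay(length, beta) == expected

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            fdecay(0, 7.0)
        with pytest.raises(ValueError):
            fdecay(2, 0.0)


class TestTwoLayerPathScores:
    def test_similarity_then_association_path(self, toy_two_layer):
        _, _, S_row, S_col, A = toy_two_layer
        W = two_layer_path_scores(S_row, S_col, A, PathParams(beta=7.0))
        assert W.values[1, 0] == pytest.approx(0.9**14)
        assert W.values[0, 0] == pytest.approx(1.0)  # direct term unpenalized

    def test_association_then_similarity_path(self, toy_two_layer):
        idx_m, idx_d, S_row, _, A = toy_two_layer
        S_col = SimilarityMatrix(np.array([[1.0, 0.8], [0.8, 1.0]]), idx_d)
        W = two_layer_path_scores(S_row, S_col, A, PathParams(beta=7.0))
        assert W.values[0, 1] == pytest.approx(0.8**14)

    def test_no_similarity_edges_gives_direct_only(self):
        rng = np.random.default_rng(5)
        idx_m = EntityIndex(["m0", "m1", "m2"], "mirna")
        idx_d = EntityIndex(["d0", "d1"], "disease")
        A = AssociationMatrix(
            random_normalized_association(rng, 3, 2), idx_m, idx_d, stage="normalized"
        )
        W = two_layer_path_scores(
            SimilarityMatrix(np.eye(3), idx_m),
            SimilarityMatrix(np.eye(2), idx_d),
            A,
            PathParams(),
        )
        np.testing.assert_array_equal(W.values, A.values)

    @pytest.mark.parametrize("seed", range(15))
    def test_dfs_matches_exhaustive_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        p, r = (int(x) for x in rng.integers(2, 16, size=2))
        idx_m = EntityIndex([f"m{i}" for i in range(p)], "mirna")
        idx_d = EntityIndex([f"d{i}" for i in range(r)], "disease")
        Sr = SimilarityMatrix(random_similarity(rng, p), idx_m)
        Sc = SimilarityMatrix(random_similarity(rng, r), idx_d)
        A = AssociationMatrix(
            random_normalized_association(rng, p, r), idx_m, idx_d, stage="normalized"
        )
        beta = float(rng.uniform(1.0, 8.0))
        W = two_layer_path_scores(Sr, Sc, A, PathParams(beta=beta))
        expected = exhaustive_two_layer(Sr.values, Sc.values, A.values, beta)
        np.testing.assert_allclose(W.values, expected, atol=1e-12)

    def test_unsupported_length_rejected(self, toy_two_layer):
        _, _, S_row, S_col, A = toy_two_layer
        with pytest.raises(ValueError, match="L = 2"):
            two_layer_path_scores(S_row, S_col, A, PathParams(L=3))


class TestIntegrateScores:
    def _scores(self, values, rows, cols):
        return ScoreMatrix(np.asarray(values, dtype=float), rows, cols)

    def test_hand_worked_single_drug(self):
        idx_m = EntityIndex(["a"], "mirna")
        idx_b = EntityIndex(["b"], "drug")
        idx_d = EntityIndex(["c"], "disease")
        out = integrate_scores(
            self._scores([[0.5]], idx_m, idx_d),
            self._scores([[0.9]], idx_m, idx_b),
            self._scores([[0.8]], idx_b, idx_d),
            PathParams(beta=7.0, rescale_mediated=False),
        )
        assert out.values[0, 0] == pytest.approx(0.5 + 0.72**14)

    def test_zero_drug_weights_leave_w1(self):
        idx_m = EntityIndex(["a"], "mirna")
        idx_b = EntityIndex(["b1", "b2"], "drug")
        idx_d = EntityIndex(["c"], "disease")
        out = integrate_scores(
            self._scores([[0.3]], idx_m, idx_d),
            self._scores([[0.0, 0.0]], idx_m, idx_b),
            self._scores([[0.4], [0.1]], idx_b, idx_d),
            PathParams(),
        )
        assert out.values[0, 0] == pytest.approx(0.3)

    def test_mediators_add_up(self):
        idx_m = EntityIndex(["a"], "mirna")
        idx_b = EntityIndex(["b1", "b2"], "drug")
        idx_d = EntityIndex(["c"], "disease")
        params = PathParams(beta=2.0, rescale_mediated=False)
        w1 = self._scores([[0.1]], idx_m, idx_d)
        w2 = self._scores([[0.6, 0.5]], idx_m, idx_b)
        w3 = self._scores([[0.7], [0.4]], idx_b, idx_d)
        out = integrate_scores(w1, w2, w3, params)
        assert out.values[0, 0] - 0.1 == pytest.approx((0.6 * 0.7) ** 4 + (0.5 * 0.4) ** 4)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_loop_oracle(self, seed):
        rng = np.random.default_rng(seed)
        S1, S2, S3, A1, A2, A3 = _random_instance(rng)
        w1 = ScoreMatrix(random_normalized_association(rng, *A1.shape), A1.row_index, A1.col_index)
        w2 = ScoreMatrix(random_normalized_association(rng, *A2.shape), A2.row_index, A2.col_index)
        w3 = ScoreMatrix(random_normalized_association(rng, *A3.shape), A3.row_index, A3.col_index)
        params = PathParams(beta=float(rng.uniform(1, 8)))
        out = integrate_scores(w1, w2, w3, params)
        expected = loop_integrate(w1.values, w2.values, w3.values, params.beta)
        np.testing.assert_allclose(out.values, expected, atol=1e-12)


class TestAssemble:
    def test_index_mismatch_named(self):
        rng = np.random.default_rng(0)
        S1, S2, S3, A1, A2, A3 = _random_instance(rng)
        from tripath import normalize_global_max, reconstruct_bipartite

        A1n = normalize_global_max(reconstruct_bipartite(S1, S3, A1))
        A2n = normalize_global_max(reconstruct_bipartite(S1, S2, A2))
        A3n = normalize_global_max(reconstruct_bipartite(S2, S3, A3))
        assemble_three_layer(S1, S2, S3, A1n, A2n, A3n)  # consistent: no error
        with pytest.raises(ValueError, match="A1n columns"):
            assemble_three_layer(S1, S2, S2, A1n, A2n, A3n)

    def test_empty_layer_impossible(self):
        # a three-layer network requires all layers; an empty entity set is
        # refused at index construction already
        with pytest.raises(ValueError):
            EntityIndex([], "drug")


class TestPredict:
    def test_identity_similarities_reproduce_associations(self):
        # no similarity propagation and no drug-mediated chains: the output
        # is exactly the raw miRNA-disease matrix
        rng = np.random.default_rng(7)
        S1, S2, S3, A1, A2, A3 = _random_instance(rng)
        eye = lambda idx: SimilarityMatrix(np.eye(len(idx)), idx)
        A2_empty = AssociationMatrix(
            np.zeros(A2.shape), A2.row_index, A2.col_index
        )
        scores = predict(
            eye(S1.index), eye(S2.index), eye(S3.index), A1, A2_empty, A3, PathParams()
        )
        np.testing.assert_array_equal(scores.values, A1.values)

    def test_identity_similarities_make_w1_direct(self):
        # even with drug chains present, the direct slice stays untouched
        rng = np.random.default_rng(8)
        S1, S2, S3, A1, A2, A3 = _random_instance(rng)
        eye = lambda idx: SimilarityMatrix(np.eye(len(idx)), idx)
        _, stages = predict(
            eye(S1.index), eye(S2.index), eye(S3.index), A1, A2, A3,
            PathParams(), return_stages=True,
        )
        np.testing.assert_array_equal(stages["W1"].values, A1.values)

    @pytest.mark.parametrize("seed", range(10))
    def test_monotone_stacking(self, seed):
        # each stage only adds nonnegative evidence: Score >= W1 >= A1''
        rng = np.random.default_rng(seed)
        S1, S2, S3, A1, A2, A3 = _random_instance(rng)
        scores, stages = predict(S1, S2, S3, A1, A2, A3, PathParams(), return_stages=True)
        assert (scores.values >= stages["W1"].values - 1e-12).all()
        assert (stages["W1"].values >= stages["A1n"].values - 1e-12).all()

    def test_large_beta_recovers_direct_term(self):
        # as beta grows every path product strictly below 1 is crushed to
        # zero; cells fed by a product at (or numerically near) 1 are exempt
        from _oracles import max_path_products

        rng = np.random.default_rng(11)
        S1, S2, S3, A1, A2, A3 = _random_instance(rng)
        scores, stages = predict(
            S1, S2, S3, A1, A2, A3, PathParams(beta=500.0), return_stages=True
        )
        contracting = max_path_products(stages) < 0.97
        gap = np.abs(scores.values - stages["A1n"].values)
        assert contracting.any()
        assert (gap[contracting] < 1e-9).all()

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(13)
        S1, S2, S3, A1, A2, A3 = _random_instance(rng)
        base = predict(S1, S2, S3, A1, A2, A3, PathParams()).values

        pm = rng.permutation(len(S1.index))
        pd_ = rng.permutation(len(S3.index))
        idx_m = EntityIndex([S1.index[i] for i in pm], "mirna")
        idx_d = EntityIndex([S3.index[i] for i in pd_], "disease")
        S1p = SimilarityMatrix(S1.values[np.ix_(pm, pm)], idx_m)
        S3p = SimilarityMatrix(S3.values[np.ix_(pd_, pd_)], idx_d)
        A1p = AssociationMatrix(A1.values[np.ix_(pm, pd_)], idx_m, idx_d)
        A2p = AssociationMatrix(A2.values[pm], idx_m, A2.col_index)
        A3p = AssociationMatrix(A3.values[:, pd_], A3.row_index, idx_d)
        permuted = predict(S1p, S2, S3p, A1p, A2p, A3p, PathParams()).values
        np.testing.assert_allclose(permuted, base[np.ix_(pm, pd_)], atol=1e-12)

    def test_bit_identical_determinism(self):
        rng = np.random.default_rng(17)
        S1, S2, S3, A1, A2, A3 = _random_instance(rng)
        first = predict(S1, S2, S3, A1, A2, A3, PathParams()).values
        second = predict(S1, S2, S3, A1, A2, A3, PathParams()).values
        assert np.array_equal(first, second)
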