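import numpy as np
import pytest

from dcsnet.errors import AlignmentError, ConsistencyError, ParameterError
from dcsnet.hetnet import shortest_path_matrix
from dcsnet.io_tables import DISEASE, LNCRNA
from dcsnet.scoring import (
    association_degree,
    build_dccm,
    distance_correlation_coefficient,
    extract_c13,
    final_scores,
    prediction_block,
)
from dcsnet.similarity import SimilarityMatrix, identity_similarity

from conftest import fad_brute_oracle, random_network


class TestCoefficient:
    def test_distance_one_r6(self):
        assert distance_correlation_coefficient(1, 6) == pytest.approx(6 / 7)

    @pytest.mark.parametrize("r", [1, 2, 4, 6])
    def test_boundary(self, r):
        assert distance_correlation_coefficient(r, r) == pytest.approx(1 / (r + 1))

    def test_zero_entry(self):
        assert distance_correlation_coefficient(0, 6) == 0.0

    def test_out_of_range(self):
        with pytest.raises(ParameterError):
            distance_correlation_coefficient(7, 6)


class TestDccm:
    def test_empty_graph(self, rng):
        net = random_network(rng, 2, 2, 2, p=0.0)
        net.am[:] = 0
        dccm = build_dccm(shortest_path_matrix(net, 3))
        assert np.array_equal(dccm.values, np.eye(6) * 0.75)

    def test_path_r2_values(self, path_network):
        dccm = build_dccm(shortest_path_matrix(path_network, 2)).values
        assert dccm[0, 1] == pytest.approx(2 / 3)
        assert dccm[1, 2] == pytest.approx(2 / 3)
        assert dccm[0, 2] == pytest.approx(1 / 3)
        assert np.allclose(np.diag(dccm), 2 / 3)

    def test_codomain(self, rng):
        r = 4
        net = random_network(rng, 4, 4, 4, p=0.3)
        dccm = build_dccm(shortest_path_matrix(net, r)).values
        allowed = {0.0, r / (r + 1)} | {1 - k / (r + 1) for k in range(1, r + 1)}
        for v in np.unique(dccm):
            assert any(abs(v - a) < 1e-12 for a in allowed)

    def test_symmetry(self, rng):
        net = random_network(rng, 5, 5, 5, p=0.3)
        dccm = build_dccm(shortest_path_matrix(net, 6)).values
        assert np.array_equal(dccm, dccm.T)


class TestAssociationDegree:
    def test_path_hand_trace(self, path_network):
        # rowsums (5/3, 2, 5/3); AD(d1, l1) = (5/3 + 5/3) / 3 = 10/9
        dccm = build_dccm(shortest_path_matrix(path_network, 2))
        ad = association_degree(dccm, node_names=path_network.node_names)
        assert ad.values[0, 2] == 10 / 9
        assert ad.values[0, 1] == pytest.approx((5 / 3 + 2) / 3)

    def test_diagonal_only_dccm(self, rng):
        r = 3
        net = random_network(rng, 2, 2, 2, p=0.0)
        net.am[:] = 0
        ad = association_degree(build_dccm(shortest_path_matrix(net, r)))
        expected = 2 * (r / (r + 1)) / 6
        assert np.allclose(ad.values, expected)

    def test_symmetry(self, rng):
        net = random_network(rng, 4, 5, 3, p=0.3)
        ad = association_degree(build_dccm(shortest_path_matrix(net, 6)))
        np.testing.assert_allclose(ad.values, ad.values.T, atol=1e-14)


class TestExtractC13:
    def test_path_is_one_by_one(self, path_network):
        dccm = build_dccm(shortest_path_matrix(path_network, 2))
        ad = association_degree(dccm, node_names=path_network.node_names)
        c13 = extract_c13(ad, path_network)
        assert c13.values.shape == (1, 1)
        assert c13.values[0, 0] == 10 / 9
        assert c13.row_names == ("d1",) and c13.col_names == ("l1",)

    def test_block_indexing_random(self, rng):
        net = random_network(rng, 3, 4, 5, p=0.4)
        ad = association_degree(
            build_dccm(shortest_path_matrix(net, 3)), node_names=net.node_names
        )
        c13 = extract_c13(ad, net)
        D, M = net.n_diseases, net.n_mirnas
        for i in range(net.n_diseases):
            for j in range(net.n_lncrnas):
                assert c13.values[i, j] == ad.values[i, D + M + j]

    def test_dimension_mismatch(self, rng, path_network):
        other = random_network(rng, 2, 2, 2, p=0.5)
        ad = association_degree(build_dccm(shortest_path_matrix(other, 2)))
        with pytest.raises(ConsistencyError):
            extract_c13(ad, path_network)


class TestFinalScores:
    def test_identity_similarities_bit_identical(self, rng):
        net = random_network(rng, 4, 3, 5, p=0.4)
        c13 = prediction_block(net, 6)
        fad = final_scores(
            c13,
            identity_similarity(c13.row_names, DISEASE),
            identity_similarity(c13.col_names, LNCRNA),
        )
        assert np.array_equal(fad.values, c13.values)

    def test_similarity_off_returns_c13(self, rng):
        net = random_network(rng, 3, 3, 3, p=0.5)
        c13 = prediction_block(net, 4)
        fad = final_scores(c13, use_similarity=False)
        assert np.array_equal(fad.values, c13.values)
        assert fad.kind == "FAD"

    def test_triple_product_oracle(self, rng):
        for _ in range(5):
            D, L = 4, 5
            c13_vals = rng.random((D, L))
            fsd_vals = rng.random((D, D))
            fsd_vals = (fsd_vals + fsd_vals.T) / 2
            fsl_vals = rng.random((L, L))
            fsl_vals = (fsl_vals + fsl_vals.T) / 2
            from dcsnet.scoring import C13, ScoreMatrix

            dn = tuple(f"d{i}" for i in range(D))
            ln = tuple(f"l{i}" for i in range(L))
            c13 = ScoreMatrix(C13, dn, ln, c13_vals)
            fad = final_scores(
                c13,
                SimilarityMatrix(dn, fsd_vals, DISEASE),
                SimilarityMatrix(ln, fsl_vals, LNCRNA),
            )
            oracle = np.zeros((D, L))
            for i in range(D):
                for j in range(L):
                    for a in range(D):
                        for b in range(L):
                            oracle[i, j] += fsd_vals[i, a] * c13_vals[a, b] * fsl_vals[b, j]
            np.testing.assert_allclose(fad.values, oracle, atol=1e-10, rtol=0)

    def test_name_order_mismatch_raises(self, rng):
        net = random_network(rng, 3, 3, 3, p=0.5)
        c13 = prediction_block(net, 4)
        wrong = identity_similarity(tuple(reversed(c13.row_names)), DISEASE)
        with pytest.raises(AlignmentError):
            final_scores(c13, wrong, identity_similarity(c13.col_names, LNCRNA))

    def test_scalar_rescaling_scales_fad(self, rng):
        net = random_network(rng, 3, 4, 5, p=0.4)
        c13 = prediction_block(net, 6)
        fsd = identity_similarity(c13.row_names, DISEASE)
        fsl = identity_similarity(c13.col_names, LNCRNA)
        fad1 = final_scores(c13, fsd, fsl)
        fsd2 = SimilarityMatrix(fsd.entity_names, fsd.values * 3.5, DISEASE)
        fad2 = final_scores(c13, fsd2, fsl)
        np.testing.assert_allclose(fad2.values, 3.5 * fad1.values, rtol=1e-12)


class TestFullPipelineOracle:
    def test_matches_brute_force(self, rng):
        for _ in range(10):
            D = int(rng.integers(2, 5))
            M = int(rng.integers(2, 5))
            L = int(rng.integers(2, 5))
            net = random_network(rng, D, M, L, p=float(rng.uniform(0.2, 0.6)))
            r = int(rng.integers(2, 7))
            fsd_vals = rng.random((D, D))
            fsd_vals = (fsd_vals + fsd_vals.T) / 2
            fsl_vals = rng.random((L, L))
            fsl_vals = (fsl_vals + fsl_vals.T) / 2
            c13 = prediction_block(net, r)
            fad = final_scores(
                c13,
                SimilarityMatrix(net.diseases, fsd_vals, DISEASE),
                SimilarityMatrix(net.lncrnas, fsl_vals, LNCRNA),
            )
            oracle = fad_brute_oracle(net.am, D, M, L, r, fsd_vals, fsl_vals)
            np.testing.assert_allclose(fad.values, oracle, atol=1e-10, rtol=0)

    def test_edge_addition_never_decreases_ad(self, rng):
        for _ in range(10):
            net = random_network(rng, 3, 4, 4, p=0.25)
            r = 4
            ad1 = association_degree(build_dccm(shortest_path_matrix(net, r))).values
            D, M, L = net.n_diseases, net.n_mirnas, net.n_lncrnas
            am2 = net.am.copy()
            while True:
                m = D + int(rng.integers(M))
                other = int(rng.integers(D + L))
                o = other if other < D else D + M + (other - D)
                if am2[m, o] == 0:
                    am2[m, o] = am2[o, m] = 1
                    break
            net2 = type(net)(net.diseases, net.mirnas, net.lncrnas, am2)
            ad2 = association_degree(build_dccm(shortest_path_matrix(net2, r))).values
            assert np.all(ad2 >= ad1 - 1e-12)
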