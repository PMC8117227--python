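"""Relationship-matrix tests against brute-force oracles and closed forms."""

import numpy as np
import pytest
import scipy.sparse as sp

from gwasim import kinship

from conftest import kinship_oracle, make_pedigree, random_pedigree


@pytest.fixture
def sib_pedigree():
    # founders 0,1; full sibs 2,3; their inbred offspring 4
    return make_pedigree(sire=[-1, -1, 0, 0, 2], dam=[-1, -1, 1, 1, 3])


class TestPedigreeA:
    def test_unrelated_founders_identity(self):
        ped = make_pedigree(sire=[-1, -1], dam=[-1, -1], sex=["M", "F"])
        np.testing.assert_allclose(kinship.build_A(ped), np.eye(2))

    def test_parent_offspring_and_fullsib_inbreeding(self, sib_pedigree):
        A = kinship.build_A(sib_pedigree)
        assert A[0, 2] == pytest.approx(0.5)
        assert A[2, 3] == pytest.approx(0.5)
        assert A[4, 4] == pytest.approx(1.25)  # full-sib mating offspring

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_recursive_oracle(self, seed):
        rng = np.random.default_rng(seed)
        ped = random_pedigree(n=20, n_founders=6, rng=rng)
        A = kinship.build_A(ped)
        np.testing.assert_allclose(A, kinship_oracle(ped.sire, ped.dam), atol=1e-12)

    def test_inbreeding_equals_A_diagonal(self):
        rng = np.random.default_rng(9)
        ped = random_pedigree(n=200, n_founders=10, rng=rng)
        F = kinship.inbreeding(ped)
        np.testing.assert_allclose(F, np.diag(kinship.build_A(ped)) - 1.0, atol=1e-10)

    def test_sparse_inverse_matches_dense(self):
        rng = np.random.default_rng(4)
        ped = random_pedigree(n=60, n_founders=8, rng=rng)
        A = kinship.build_A(ped)
        Ainv = kinship.build_A_inverse(ped).toarray()
        np.testing.assert_allclose(Ainv, np.linalg.inv(A), atol=1e-8)

    def test_large_pedigree_block_extraction_matches_tabular(self):
        # exceeds the dense threshold, so the triangular-solve path runs
        rng = np.random.default_rng(5)
        ped = random_pedigree(n=3200, n_founders=50, rng=rng)
        idx = rng.choice(3200, 25, replace=False)
        A = kinship.build_A(ped)
        np.testing.assert_allclose(
            kinship.A22_from_pedigree(ped, idx), A[np.ix_(idx, idx)], atol=1e-8
        )
        rows = rng.choice(3200, 10, replace=False)
        cols = rng.choice(3200, 15, replace=False)
        np.testing.assert_allclose(
            kinship.relationship_block(ped, rows, cols),
            A[np.ix_(rows, cols)],
            atol=1e-8,
        )

    def test_subset_A22_contracts(self):
        A = np.array([[1.0, 0.2, 0.3], [0.2, 1.1, 0.4], [0.3, 0.4, 1.2]])
        np.testing.assert_allclose(kinship.subset_A22(A, [2]), [[1.2]])
        perm = kinship.subset_A22(A, [2, 0])
        np.testing.assert_allclose(perm, [[1.2, 0.3], [0.3, 1.0]])
        with pytest.raises(ValueError, match="empty"):
            kinship.subset_A22(A, [])


class TestGenomicG:
    def test_vanraden_opposite_homozygotes(self):
        G = kinship.build_G_vanraden(np.array([[0], [2]]))
        np.testing.assert_allclose(G, [[2.0, -2.0], [-2.0, 2.0]])

    def test_vanraden_heterozygote_zero_diagonal(self):
        dos = np.array([[1, 1, 1], [0, 0, 0], [2, 2, 2]])
        G = kinship.build_G_vanraden(dos)
        assert G[0, 0] == pytest.approx(0.0)  # centered row is all-zero

    def test_vanraden_duplicate_animal(self):
        rng = np.random.default_rng(0)
        dos = rng.integers(0, 3, (5, 40))
        dos[4] = dos[0]
        G = kinship.build_G_vanraden(dos)
        np.testing.assert_allclose(G[0], G[4])

    def test_vanraden_monomorphic_aborts(self):
        with pytest.raises(ValueError, match="monomorphic"):
            kinship.build_G_vanraden(np.ones((4, 3)) * 2)

    def test_vanraden_mean_diagonal_near_one_under_hwe(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(0.1, 0.9, 2000)
        dos = rng.binomial(2, p, size=(500, 2000))
        G = kinship.build_G_vanraden(dos)
        assert np.mean(np.diag(G)) == pytest.approx(1.0, abs=0.05)

    def test_gemma_single_locus(self):
        G = kinship.build_G_gemma(np.array([[0], [2]]))
        np.testing.assert_allclose(G, [[1.0, -1.0], [-1.0, 1.0]])

    def test_gemma_identical_animals_zero(self):
        G = kinship.build_G_gemma(np.ones((3, 10)))
        np.testing.assert_allclose(G, 0.0)

    def test_gemma_vs_vanraden_scalar_ratio(self):
        rng = np.random.default_rng(2)
        dos = rng.integers(0, 3, (20, 100))
        p = dos.mean(axis=0) / 2
        spq = 2 * np.sum(p * (1 - p))
        np.testing.assert_allclose(
            kinship.build_G_gemma(dos) * dos.shape[1],
            kinship.build_G_vanraden(dos) * spq,
            atol=1e-10,
        )


class TestBlendTune:
    def test_blend_identity_cases(self):
        G0 = np.eye(3)
        np.testing.assert_allclose(kinship.blend_G(G0, 0.95, 0.05), G0)
        np.testing.assert_allclose(kinship.blend_G(G0 * 2, 1.0, 0.0), G0 * 2)

    def test_blend_lifts_singular_matrix(self):
        dos = np.array([[0, 2, 1], [0, 2, 1], [2, 0, 1]])  # duplicate animals
        G0 = kinship.build_G_vanraden(dos)
        G = kinship.blend_G(G0)
        assert np.linalg.eigvalsh(G).min() >= 0.05 - 1e-12

    def test_tune_recovers_half_scale(self):
        rng = np.random.default_rng(3)
        M = rng.standard_normal((6, 6))
        A22 = M @ M.T / 6 + np.diag(rng.uniform(0.5, 1.0, 6))
        G = 2.0 * A22
        tuned, a, b = kinship.tune_G_to_A22(G, A22)
        assert b == pytest.approx(0.5)
        assert a == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(tuned, A22)

    def test_tune_matches_means_and_is_idempotent(self):
        rng = np.random.default_rng(4)
        dos = rng.integers(0, 3, (10, 60))
        G = kinship.blend_G(kinship.build_G_vanraden(dos))
        A22 = np.eye(10) * 1.02 + 0.01
        tuned, _, _ = kinship.tune_G_to_A22(G, A22)
        assert np.mean(np.diag(tuned)) == pytest.approx(np.mean(np.diag(A22)))
        off = ~np.eye(10, dtype=bool)
        assert tuned[off].mean() == pytest.approx(A22[off].mean())
        again, a2, b2 = kinship.tune_G_to_A22(tuned, A22)
        assert (a2, b2) == (pytest.approx(0.0, abs=1e-12), pytest.approx(1.0))

    def test_tune_degenerate_aborts(self):
        with pytest.raises(ValueError, match="degenerate"):
            kinship.tune_G_to_A22(np.ones((3, 3)), np.eye(3))


class TestDelta:
    def test_matched_sums_give_one(self):
        A22 = np.eye(4)
        assert kinship.compute_delta(A22, A22) == pytest.approx(1.0)

    def test_two_animal_example(self):
        A22 = np.array([[2.0, 1.0], [1.0, 2.0]])  # sum 6
        G = np.array([[1.5, 0.5], [0.5, 1.5]])  # sum 4
        assert kinship.compute_delta(A22, G) == pytest.approx(0.75)

    def test_sign_when_G_exceeds_A22(self):
        assert kinship.compute_delta(np.eye(2), np.eye(2) * 2) > 1.0


class TestHinv:
    def test_no_genotyped_animals_returns_Ainv(self):
        Ainv = np.eye(4) * 1.5
        H = kinship.build_Hinv(Ainv, np.empty((0, 0)), np.empty((0, 0)), np.array([], int))
        np.testing.assert_allclose(H, Ainv)

    def test_all_genotyped_with_G_equal_A_cancels(self):
        rng = np.random.default_rng(5)
        ped = random_pedigree(n=8, n_founders=4, rng=rng)
        A = kinship.build_A(ped)
        Ainv = np.linalg.inv(A)
        idx = np.arange(8)
        H = kinship.build_Hinv(Ainv, Ainv, Ainv, idx)
        np.testing.assert_allclose(H, Ainv, atol=1e-10)

    def test_correction_confined_to_genotyped_block(self):
        rng = np.random.default_rng(6)
        ped = random_pedigree(n=10, n_founders=5, rng=rng)
        Ainv = np.linalg.inv(kinship.build_A(ped))
        idx = np.array([6, 8, 9])
        G = np.eye(3) * 1.3
        A22inv = np.linalg.inv(kinship.build_A(ped)[np.ix_(idx, idx)])
        H = kinship.build_Hinv(Ainv, A22inv, np.linalg.inv(G), idx)
        diff = H - Ainv
        mask = np.zeros((10, 10), bool)
        mask[np.ix_(idx, idx)] = True
        assert np.all(diff[~mask] == 0.0)

    def test_matches_partitioned_H_oracle(self):
        # assemble H from its partitioned definition and invert directly
        rng = np.random.default_rng(7)
        ped = random_pedigree(n=12, n_founders=5, rng=rng)
        A = kinship.build_A(ped)
        idx = np.array([7, 9, 10, 11])
        rest = np.setdiff1d(np.arange(12), idx)
        A22 = A[np.ix_(idx, idx)]
        dos = rng.integers(0, 3, (4, 50))
        G = kinship.blend_G(kinship.build_G_vanraden(dos))
        G, _, _ = kinship.tune_G_to_A22(G, A22)

        A22i = np.linalg.inv(A22)
        A12 = A[np.ix_(rest, idx)]
        H = np.zeros((12, 12))
        H[np.ix_(idx, idx)] = G
        H[np.ix_(rest, idx)] = A12 @ A22i @ G
        H[np.ix_(idx, rest)] = H[np.ix_(rest, idx)].T
        H[np.ix_(rest, rest)] = (
            A[np.ix_(rest, rest)] - A12 @ A22i @ A12.T + A12 @ A22i @ G @ A22i @ A12.T
        )
        Hinv = kinship.build_Hinv(np.linalg.inv(A), A22i, np.linalg.inv(G), idx)
        np.testing.assert_allclose(Hinv, np.linalg.inv(H), atol=1e-8)

    def test_sparse_input_stays_sparse(self):
        Ainv = sp.identity(5, format="csr") * 2.0
        idx = np.array([3, 4])
        H = kinship.build_Hinv(Ainv, np.eye(2), np.eye(2) * 1.5, idx)
        assert sp.issparse(H)
        np.testing.assert_allclose(
            H.toarray(), np.diag([2, 2, 2, 2.5, 2.5]), atol=1e-12
        )
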