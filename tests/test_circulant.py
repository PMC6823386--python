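"""Circulant detection, filter classification and Fourier eigen-analysis."""

import numpy as np
import pytest

from circuitsym.circuits import subcircuit
from circuitsym.circulant import (CirculantProfile, bcirc, circ,
                                  circulant_eigen, classify_filter,
                                  detect_block_circulant, detect_circulant,
                                  nearest_pseudocirculant)


class TestDetect:
    @pytest.mark.parametrize("matrix,klass", [
        ([[0, 1], [1, 0]], "H"),
        ([[1, 1], [1, 1]], "L"),
    ])
    def test_two_node_filters(self, matrix, klass):
        prof = detect_circulant(np.array(matrix), ("x", "y"))
        assert prof is not None
        assert prof.deviation == 0
        assert prof.filter_class == klass

    def test_asymmetric_two_by_two_is_not_circulant(self):
        assert detect_circulant(np.array([[0, 1], [0, 0]]), ("x", "y")) is None

    def test_scrambled_four_cycle_found_by_reordering(self):
        F = circ(0, 1, 0, 1)
        perm = [2, 0, 3, 1]
        scr = F[np.ix_(perm, perm)]
        prof = detect_circulant(scr, ("a", "b", "c", "d"))
        assert prof is not None
        assert prof.first_row == (0.0, 1.0, 0.0, 1.0)

    def test_relabeling_never_changes_existence(self):
        rng = np.random.default_rng(3)
        C = circ(0, 2, 1, 2)
        for _ in range(5):
            p = rng.permutation(4)
            scr = C[np.ix_(p, p)]
            assert detect_circulant(scr, ("a", "b", "c", "d")) is not None

    def test_large_block_regular_cycle_path(self):
        C = circ(0, 1, 0, 0, 0, 0, 0, 0, 1)     # 9-cycle, above the
        labels = tuple(f"n{i}" for i in range(9))  # exhaustive guard
        prof = detect_circulant(C, labels, max_exhaustive=6)
        assert prof is not None and prof.heuristic


class TestNearestPseudocirculant:
    def test_exact_input_has_zero_deviation(self):
        prof = nearest_pseudocirculant(circ(0, 1, 0, 1))
        assert prof.deviation == 0

    def test_one_flipped_link_gives_quarter_deviation(self):
        B = circ(0, 1, 0, 1)
        B[0, 1] = B[1, 0] = 0
        prof = nearest_pseudocirculant(B)
        assert prof.deviation == pytest.approx(0.25)
        assert prof.first_row == (0.0, 1.0, 0.0, 1.0)

    def test_all_zero_matrix_is_the_trivial_circulant(self):
        prof = nearest_pseudocirculant(np.zeros((4, 4)))
        assert prof.deviation == 0
        assert prof.filter_class == "zero"


class TestBlockCirculant:
    def test_command_block_is_bcirc_h_l(self, command_unit):
        bc = detect_block_circulant(
            command_unit.weights, command_unit.labels,
            [("AVBL", "AVBR"), ("RIBL", "RIBR")])
        assert bc is not None
        assert np.array_equal(bc.block_matrices[0], circ(0, 1))
        assert np.array_equal(bc.block_matrices[1], circ(1, 1))

    def test_motor_blocks_are_bcirc_with_f_component(self, forward_fixture):
        c, _ = forward_fixture
        b1 = ("VB2", "DB3", "DB2", "VB1")
        b2 = ("DB1", "VB4", "VB5", "VB6")
        sub = subcircuit(c, list(b1 + b2))
        bc = detect_block_circulant(sub.weights, sub.labels, [b1, b2])
        assert bc is not None
        assert np.array_equal(bc.block_matrices[0], circ(0, 1, 0, 1))

    def test_aib_rim_block(self, aib_rim):
        c, _ = aib_rim
        bc = detect_block_circulant(
            c.weights, c.labels, [("AIBL", "AIBR"), ("RIML", "RIMR")])
        assert bc is not None
        assert np.array_equal(bc.block_matrices[0], np.zeros((2, 2)))
        assert np.array_equal(bc.block_matrices[1], circ(1, 0))

    def test_unequal_block_sizes_rejected(self, command_unit):
        with pytest.raises(ValueError, match="equal"):
            detect_block_circulant(command_unit.weights, command_unit.labels,
                                   [("AVBL",), ("RIBL", "RIBR")])

    def test_bcirc_assembly_matches_definition(self):
        H, L = circ(0, 1), circ(1, 1)
        M = bcirc(H, L)
        assert np.array_equal(M[:2, :2], H)
        assert np.array_equal(M[:2, 2:], L)
        assert np.array_equal(M[2:, :2], L)
        assert np.array_equal(M[2:, 2:], H)


class TestEigen:
    def test_four_cycle_spectrum(self):
        prof = CirculantProfile((0, 1, 0, 1), ("a", "b", "c", "d"), 0.0)
        eig = circulant_eigen(prof)
        assert sorted(np.real(eig.eigenvalues)) == [-2, 0, 0, 2]
        # eigenvectors match the Fourier modes up to sign
        V = eig.eigenvectors
        lam = np.asarray(eig.eigenvalues, float)
        expected = {
            2.0: [np.array([1, 1, 1, 1]) / 2],
            -2.0: [np.array([-1, 1, -1, 1]) / 2],
            0.0: [np.array([0, -1, 0, 1]) / np.sqrt(2),
                  np.array([-1, 0, 1, 0]) / np.sqrt(2)],
        }
        for k, l in enumerate(lam):
            col = V[:, k]
            assert any(np.allclose(col, v) or np.allclose(col, -v)
                       for v in expected[l])

    @pytest.mark.parametrize("row,expected", [
        ((1, 1), [0, 2]),
        ((0, 1), [-1, 1]),
    ])
    def test_two_node_closed_forms(self, row, expected):
        prof = CirculantProfile(row, ("x", "y"), 0.0)
        eig = circulant_eigen(prof)
        assert sorted(np.real(eig.eigenvalues)) == expected

    @pytest.mark.parametrize("row", [
        (0, 1, 0, 1), (1, 1), (0, 1), (0, 2, 1, 1, 1, 2),
        (0, 1, 1, 0, 0, 0, 1, 1),
    ])
    def test_matches_dense_eigendecomposition(self, row):
        prof = CirculantProfile(row, tuple(f"n{i}" for i in range(len(row))),
                                0.0)
        eig = circulant_eigen(prof)
        dense = np.linalg.eigvalsh(circ(*row).astype(float))
        assert np.allclose(sorted(np.real(eig.eigenvalues)), dense,
                           atol=1e-9)
        # trace preservation: sum of eigenvalues = l * c_1
        assert np.isclose(np.sum(np.real(eig.eigenvalues)),
                          len(row) * row[0])
        # eigenvector property: C v = lambda v
        C = circ(*row).astype(float)
        for k, l in enumerate(eig.eigenvalues):
            v = eig.eigenvectors[:, k]
            assert np.allclose(C @ v, np.real(l) * v, atol=1e-9)
            assert np.isclose(np.linalg.norm(v), 1)

    def test_nonzero_deviation_rejected(self):
        prof = CirculantProfile((0, 1), ("x", "y"), 0.1)
        with pytest.raises(ValueError, match="deviation"):
            circulant_eigen(prof)


class TestClassify:
    @pytest.mark.parametrize("row,klass", [
        ((0, 1), "H"), ((1, 1), "L"), ((0, 1, 0, 1), "F"),
        ((0, 0, 0), "zero"), ((0, 1, 1), "other"),
    ])
    def test_catalogue(self, row, klass):
        prof = CirculantProfile(row, tuple(f"n{i}" for i in range(len(row))),
                                0.0)
        assert classify_filter(prof) == klass
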