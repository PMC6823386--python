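"""Commutator norm, automorphism enumeration and pseudosymmetry search."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from circuitsym.circuits import Circuit
from circuitsym.symmetry import (Permutation, automorphism_group,
                                 commutator_norm, epsilon,
                                 find_pseudosymmetries, is_automorphism)

from conftest import brute_force_automorphisms


def random_circuit(seed: int, n: int, directed: bool = False,
                   wmax: int = 3) -> Circuit:
    rng = np.random.default_rng(seed)
    A = rng.integers(0, wmax + 1, size=(n, n))
    np.fill_diagonal(A, 0)
    if not directed:
        A = np.triu(A) + np.triu(A, 1).T
    return Circuit(tuple(f"n{i}" for i in range(n)), A, directed=directed)


class TestCommutatorNorm:
    def test_identity_has_zero_norm(self, command_weighted):
        p = Permutation.identity(command_weighted.labels)
        assert commutator_norm(command_weighted, p) == 0

    def test_double_swap_is_automorphism_of_command_circuit(
            self, command_unit):
        # AVBL <-> RIBR with AVBR <-> RIBL preserves the K4 pattern
        p = Permutation.from_cycles(
            command_unit.labels, [("AVBL", "RIBR"), ("AVBR", "RIBL")])
        assert commutator_norm(command_unit, p) == 0

    def test_path_leaf_swaps(self, path_abc):
        exact = Permutation.transposition(path_abc.labels, "a", "c")
        assert commutator_norm(path_abc, exact) == 0
        broken = Permutation.transposition(path_abc.labels, "b", "c")
        # brute-force oracle: sum |A_ij - A_P(i)P(j)| over all 9 ordered
        # pairs is 4; the swap moves exactly the one link a-b (to a-c),
        # and each moved undirected link accounts for 4 ordered units
        A = path_abc.weights
        imgs = broken.images
        ordered = sum(abs(int(A[i, j]) - int(A[imgs[i], imgs[j]]))
                      for i in range(3) for j in range(3))
        assert ordered == 4
        assert commutator_norm(path_abc, broken) == 1

    @given(st.integers(0, 200))
    @settings(max_examples=40, deadline=None)
    def test_norm_invariant_under_inverse(self, seed):
        c = random_circuit(seed % 50, n=6, directed=bool(seed % 2))
        rng = np.random.default_rng(seed)
        imgs = tuple(rng.permutation(6).tolist())
        p = Permutation(c.labels, imgs)
        assert commutator_norm(c, p) == commutator_norm(c, p.inverse())

    def test_label_mismatch_rejected(self, command_weighted, path_abc):
        p = Permutation.identity(path_abc.labels)
        with pytest.raises(ValueError, match="different labels"):
            commutator_norm(command_weighted, p)


class TestEpsilon:
    def test_calibration_one_broken_link_over_18(self,
                                                 fig_calibration_circuit):
        c = fig_calibration_circuit
        assert c.total_weight == 18
        p = Permutation.transposition(c.labels, "DB5", "DB6")
        ps = epsilon(c, p)
        assert ps.norm == 1
        assert ps.eps == pytest.approx(1 / 18)
        assert ps.biologically_plausible

    def test_exact_automorphism_has_eps_zero(self, command_weighted):
        p = Permutation.from_cycles(
            command_weighted.labels, [("AVBL", "AVBR")])
        assert epsilon(command_weighted, p).eps == 0

    def test_reversing_directed_edge_moves_its_weight(self):
        A = np.zeros((3, 3), dtype=int)
        A[0, 1] = 5   # a -> b, weight 5
        A[2, 0] = 1
        A[2, 1] = 1
        c = Circuit(("a", "b", "x"), A, directed=True)
        p = Permutation.transposition(c.labels, "a", "b")
        ps = epsilon(c, p)
        assert ps.norm == 5   # the whole edge is relocated to b -> a
        assert ps.eps == pytest.approx(5 / 7)


class TestAutomorphismGroup:
    def test_unweighted_k4_has_full_symmetric_group(self, command_unit):
        assert automorphism_group(command_unit).order == 24

    def test_weighted_command_circuit_has_square_symmetry(
            self, command_weighted):
        grp = automorphism_group(command_weighted)
        assert grp.order == 8
        for p in grp.perms():
            assert is_automorphism(command_weighted, p)

    def test_undirected_cycle_c4(self):
        A = np.array([[0, 1, 0, 1], [1, 0, 1, 0],
                      [0, 1, 0, 1], [1, 0, 1, 0]])
        # the 4-cycle as a graph: automorphisms = dihedral, order 8
        c = Circuit(("a", "b", "c", "d"), A)
        assert automorphism_group(c).order == 8

    @pytest.mark.parametrize("seed", range(8))
    @pytest.mark.parametrize("directed", [False, True])
    def test_matches_exhaustive_filtering(self, seed, directed):
        c = random_circuit(seed, n=6, directed=directed)
        grp = automorphism_group(c)
        oracle = {p.images for p in brute_force_automorphisms(c)}
        assert grp.elements == oracle

    def test_closure_under_composition(self, command_weighted):
        grp = automorphism_group(command_weighted)
        perms = grp.perms()
        for p, q in itertools.product(perms, perms):
            assert (p * q).images in grp.elements

    def test_size_guard(self):
        c = random_circuit(0, n=5)
        with pytest.raises(Exception, match="sector-wise"):
            automorphism_group(c, max_nodes=4)


class TestPseudosymmetrySearch:
    def test_eps_zero_returns_exact_only(self, command_weighted):
        out = find_pseudosymmetries(command_weighted, eps_max=0)
        assert len(out["exact"]) == 7  # 8 automorphisms minus identity
        assert out["templates"] == []

    def test_identically_wired_nodes_form_symmetric_template(self):
        # 5 nodes wired identically to one hub: S_5 with eps = 0
        n = 6
        A = np.zeros((n, n), dtype=int)
        A[0, 1:] = A[1:, 0] = 1
        c = Circuit(tuple(["hub"] + [f"m{i}" for i in range(5)]), A)
        out = find_pseudosymmetries(c, eps_max=0.1)
        s5 = [t for t in out["templates"] if t.template == "S_5"]
        assert len(s5) == 1
        assert s5[0].eps == 0
        assert s5[0].sector == ("m0", "m1", "m2", "m3", "m4")

    def test_planted_pair_with_one_broken_link(self):
        # a C_2 pair over 20 unit links, one link removed: eps = 0.05
        labels = ("x", "y", "hub", "pad")
        A = np.zeros((4, 4), dtype=int)
        A[0, 2] = A[2, 0] = 5
        A[1, 2] = A[2, 1] = 4   # broken: x has 5 links to hub, y only 4
        A[2, 3] = A[3, 2] = 11
        c = Circuit(labels, A)
        assert c.total_weight == 20
        out = find_pseudosymmetries(c, eps_max=0.06)
        match = [s for s in out["swaps"]
                 if s.perm.support == frozenset({"x", "y"})]
        assert len(match) == 1
        assert match[0].eps == pytest.approx(0.05)

    def test_results_sorted_by_eps(self, forward_fixture):
        c, _ = forward_fixture
        out = find_pseudosymmetries(c, eps_max=0.25)
        eps_seq = [t.eps for t in out["templates"]]
        assert eps_seq == sorted(eps_seq)

    def test_composition_may_break_tolerance(self):
        # two accepted swaps whose composition exceeds eps_max: the set of
        # pseudosymmetries need not be closed (documented non-closure)
        rng = np.random.default_rng(5)
        A = rng.integers(0, 3, size=(6, 6))
        np.fill_diagonal(A, 0)
        A = np.triu(A) + np.triu(A, 1).T
        c = Circuit(tuple("abcdef"), A)
        M = c.total_weight
        perms = [Permutation.transposition(c.labels, a, b)
                 for a, b in itertools.combinations(c.labels, 2)]
        found = False
        for p, q in itertools.permutations(perms, 2):
            ep, eq = epsilon(c, p).eps, epsilon(c, q).eps
            ec = epsilon(c, p * q).eps
            if ec > max(ep, eq):
                found = True
                break
        assert found
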