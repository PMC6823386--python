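"""Shared fixtures: canonical circuits and brute-force oracles."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from circuitsym.circuits import Circuit
from circuitsym.symmetry import Permutation
from circuitsym.synthetic_data import (backward_aib_rim_fixture,
                                       command_circuit, forward_gap_fixture)


@pytest.fixture(scope="session")
def command_unit() -> Circuit:
    return command_circuit(weighted=False)


@pytest.fixture(scope="session")
def command_weighted() -> Circuit:
    return command_circuit(weighted=True)


@pytest.fixture(scope="session")
def forward_fixture():
    """(circuit, planted truth) of the 21-node ideal forward circuit."""
    return forward_gap_fixture()


@pytest.fixture(scope="session")
def aib_rim():
    return backward_aib_rim_fixture()


@pytest.fixture
def path_abc() -> Circuit:
    """Undirected path a - b - c."""
    A = np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]])
    return Circuit(("a", "b", "c"), A)


@pytest.fixture
def fig_calibration_circuit() -> Circuit:
    """18-link circuit where swapping DB5 and DB6 breaks exactly the one
    link DB5-AVBR (the eps = 1/18 calibration example)."""
    labels = ("DB5", "DB6", "AVBL", "AVBR", "PAD")
    A = np.zeros((5, 5), dtype=int)

    def add(a, b, w):
        i, j = labels.index(a), labels.index(b)
        A[i, j] = A[j, i] = w

    add("DB5", "AVBL", 4)
    add("DB6", "AVBL", 4)
    add("DB5", "AVBR", 1)
    add("AVBR", "PAD", 9)
    return Circuit(labels, A)


# ---------------------------------------------------------------------------
# oracles


def brute_force_automorphisms(c: Circuit) -> list[Permutation]:
    """Exhaustive n! filtering; the independent oracle for small circuits."""
    A = c.weights
    out = []
    for imgs in itertools.permutations(range(c.n)):
        idx = np.asarray(imgs)
        if np.array_equal(A, A[np.ix_(idx, idx)]):
            out.append(Permutation(c.labels, imgs))
    return out


def all_set_partitions(items):
    """Every partition of a sequence into nonempty parts."""
    items = list(items)
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in all_set_partitions(rest):
        for k in range(len(part)):
            yield part[:k] + [[first] + part[k]] + part[k + 1:]
        yield [[first]] + part


def sympy_group(perms):
    """sympy PermutationGroup from our Permutation objects (oracle only)."""
    from sympy.combinatorics import Permutation as SPerm
    from sympy.combinatorics import PermutationGroup

    ps = [SPerm(list(p.images)) for p in perms]
    return PermutationGroup(ps) if ps else PermutationGroup(SPerm([0]))
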