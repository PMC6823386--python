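"""Construct the eps -> 0 ideal circuit for a group of pseudosymmetries.

The ideal circuit is the group average of the adjacency matrix: every
link orbit (orbit of ordered node pairs under the group) is replaced by
the rounded mean of its weights.  Rounding is performed orbit-wise (all
pairs in one orbit receive the same value, halves rounding up), which
guarantees that every element of the group is an exact automorphism of
the result.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .circuits import Circuit, CircuitError
from .group_structure import PermGroup

__all__ = ["IdealizationReport", "idealize", "idealize_report"]


@dataclass(frozen=True)
class IdealizationReport:
    ideal: Circuit
    distance: float          # ||A - A_ideal|| in link units
    distance_fraction: float  # distance / M of the input circuit
    orbit_values: tuple      # ((pairs...), original weights, ideal value)


def _pair_orbits(n: int, g: PermGroup) -> list[list[tuple[int, int]]]:
    """Orbits of ordered off-diagonal pairs under the group.

    Union-find over the generator action; orbits under the generated
    group equal connected components under the generators.
    """
    gens = [p.images for p in g.generators]
    if not gens and g.order > 1:
        gens = list(g.elements)
    idx = {}
    pairs = []
    for i in range(n):
        for j in range(n):
            if i != j:
                idx[(i, j)] = len(pairs)
                pairs.append((i, j))
    parent = list(range(len(pairs)))

    def find(k: int) -> int:
        while parent[k] != k:
            parent[k] = parent[parent[k]]
            k = parent[k]
        return k

    for e in gens:
        for k, (i, j) in enumerate(pairs):
            r1, r2 = find(k), find(idx[(e[i], e[j])])
            if r1 != r2:
                parent[r1] = r2
    cells: dict[int, list[tuple[int, int]]] = {}
    for k, pair in enumerate(pairs):
        cells.setdefault(find(k), []).append(pair)
    return [sorted(v) for v in cells.values()]


def idealize_report(c: Circuit, g: PermGroup) -> IdealizationReport:
    """Group-average the circuit and report the repair distance."""
    if tuple(g.labels) != tuple(c.labels):
        raise CircuitError("group acts on different labels than the circuit")
    if g.order == 0:
        raise CircuitError("empty group")
    A = c.weights
    n = c.n
    ideal = np.zeros_like(A)
    records = []
    for orb in _pair_orbits(n, g):
        vals = [int(A[i, j]) for i, j in orb]
        mean = sum(vals) / len(vals)
        rounded = math.floor(mean + 0.5)   # half rounds up
        for i, j in orb:
            ideal[i, j] = rounded
        labs = tuple((c.labels[i], c.labels[j]) for i, j in orb)
        records.append((labs, tuple(vals), rounded))

    if not c.directed:
        # group averaging preserves symmetry; assert rather than trust
        assert np.array_equal(ideal, ideal.T)
    out = Circuit(c.labels, ideal, directed=c.directed, link_type=c.link_type)
    dist = float(np.abs(A - ideal).sum())
    if not c.directed:
        dist /= 2
    M = c.total_weight
    return IdealizationReport(out, dist, dist / M if M else 0.0,
                              tuple(records))


def idealize(c: Circuit, g: PermGroup) -> Circuit:
    """The eps -> 0 circuit on which every element of ``g`` is exact."""
    return idealize_report(c, g).ideal
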