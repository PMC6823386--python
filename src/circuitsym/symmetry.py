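"""Commutator norm, exact automorphisms and pseudosymmetry search.

An automorphism of a circuit is a node permutation ``P`` with
``P A P^{-1} = A``, i.e. a relabeling that preserves every weighted
connection.  Because connectomes vary from animal to animal (about 25% of
connections), exact symmetry is an idealization: a *pseudosymmetry* is a
permutation whose commutator norm ``||[P, A]||`` — the number of link
units it fails to preserve — stays below a fraction ``eps`` of the
circuit's total weight ``M``.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .circuits import Circuit, CircuitError

__all__ = [
    "Permutation",
    "PseudoSymmetry",
    "TemplateResult",
    "commutator_norm",
    "is_automorphism",
    "epsilon",
    "automorphism_group",
    "find_pseudosymmetries",
    "PLAUSIBILITY_BOUND",
]

#: Animal-to-animal variability of the connectome: pseudosymmetries with
#: eps below this fraction are flagged biologically plausible.
PLAUSIBILITY_BOUND = 0.25


@dataclass(frozen=True)
class Permutation:
    """A bijection on a fixed ordered label set.

    ``images[i]`` is the index that position ``i`` maps to.  The label
    tuple is part of the identity of the permutation: permutations over
    different label sets never compare equal and cannot be composed.
    """

    labels: tuple[str, ...]
    images: tuple[int, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "labels", tuple(self.labels))
        object.__setattr__(self, "images", tuple(int(i) for i in self.images))
        n = len(self.labels)
        if sorted(self.images) != list(range(n)):
            raise ValueError("images must be a permutation of 0..n-1")

    # -- constructors ----------------------------------------------------

    @classmethod
    def identity(cls, labels: Sequence[str]) -> "Permutation":
        return cls(tuple(labels), tuple(range(len(labels))))

    @classmethod
    def from_mapping(cls, labels: Sequence[str],
                     mapping: dict[str, str]) -> "Permutation":
        labels = tuple(labels)
        pos = {lab: i for i, lab in enumerate(labels)}
        images = list(range(len(labels)))
        for src, dst in mapping.items():
            if src not in pos or dst not in pos:
                raise ValueError(f"mapping uses labels outside the circuit: "
                                 f"{src!r} -> {dst!r}")
            images[pos[src]] = pos[dst]
        return cls(labels, tuple(images))

    @classmethod
    def from_cycles(cls, labels: Sequence[str],
                    cycles: Iterable[Sequence[str]]) -> "Permutation":
        mapping: dict[str, str] = {}
        for cyc in cycles:
            for a, b in zip(cyc, list(cyc[1:]) + [cyc[0]]):
                mapping[a] = b
        return cls.from_mapping(labels, mapping)

    @classmethod
    def transposition(cls, labels: Sequence[str], a: str, b: str) -> "Permutation":
        return cls.from_mapping(labels, {a: b, b: a})

    # -- group operations ------------------------------------------------

    def __call__(self, label: str) -> str:
        return self.labels[self.images[self.labels.index(label)]]

    def compose(self, other: "Permutation") -> "Permutation":
        """``self`` after ``other``: (self * other)(x) = self(other(x))."""
        if self.labels != other.labels:
            raise ValueError("permutations act on different label sets")
        imgs = tuple(self.images[j] for j in other.images)
        return Permutation(self.labels, imgs)

    def __mul__(self, other: "Permutation") -> "Permutation":
        return self.compose(other)

    def inverse(self) -> "Permutation":
        inv = [0] * len(self.images)
        for i, j in enumerate(self.images):
            inv[j] = i
        return Permutation(self.labels, tuple(inv))

    @property
    def support(self) -> frozenset[str]:
        return frozenset(self.labels[i] for i, j in enumerate(self.images)
                         if i != j)

    @property
    def is_identity(self) -> bool:
        return all(i == j for i, j in enumerate(self.images))

    def order(self) -> int:
        k, p = 1, self
        while not p.is_identity:
            p = p.compose(self)
            k += 1
        return k

    def cycles(self) -> list[tuple[str, ...]]:
        """Nontrivial cycles, each starting at its lexicographically
        smallest label, sorted by that label."""
        seen: set[int] = set()
        out = []
        for i in range(len(self.labels)):
            if i in seen or self.images[i] == i:
                continue
            cyc = [i]
            j = self.images[i]
            while j != i:
                cyc.append(j)
                j = self.images[j]
            seen.update(cyc)
            labs = [self.labels[k] for k in cyc]
            m = labs.index(min(labs))
            out.append(tuple(labs[m:] + labs[:m]))
        return sorted(out)

    def __str__(self) -> str:
        cyc = self.cycles()
        if not cyc:
            return "id"
        return "".join("(" + " ".join(c) + ")" for c in cyc)


@dataclass(frozen=True)
class PseudoSymmetry:
    """A permutation with its commutator norm and uncertainty constant."""

    perm: Permutation
    norm: float
    eps: float

    @property
    def is_exact(self) -> bool:
        return self.norm == 0

    @property
    def biologically_plausible(self) -> bool:
        return self.eps < PLAUSIBILITY_BOUND


@dataclass(frozen=True)
class TemplateResult:
    """A candidate subgroup template found by the pseudosymmetry search.

    ``eps`` is the maximum generator-wise uncertainty (conservative);
    ``eps_mean`` the mean over generators.
    """

    template: str                      # e.g. "S_5", "C_2", "involution"
    sector: tuple[str, ...]
    generators: tuple[Permutation, ...]
    eps: float
    eps_mean: float


# ---------------------------------------------------------------------------
# norms


def _check_perm(c: Circuit, p: Permutation) -> None:
    if tuple(p.labels) != tuple(c.labels):
        raise ValueError("permutation is defined on different labels than the circuit")


def commutator_norm(c: Circuit, p: Permutation) -> float:
    """Number of link units ``P`` fails to preserve (the commutator norm).

    ``P A P^{-1}`` rearranges the entries of ``A``, so the raw L1 sum
    ``sum_ij |A_ij - A_{P(i)P(j)}|`` counts every moved link twice (once
    where it was lost, once where it reappeared) and, for undirected
    circuits, in both orientations.  The norm is that sum divided by 2
    (directed) or 4 (undirected), calibrated so that a permutation that
    moves exactly one link scores exactly 1.
    """
    _check_perm(c, p)
    idx = np.asarray(p.images)
    A = c.weights
    B = A[np.ix_(idx, idx)]          # B_ij = A_{P(i)P(j)}
    s = int(np.abs(A - B).sum())
    return s / 2 if c.directed else s / 4


def is_automorphism(c: Circuit, p: Permutation) -> bool:
    return commutator_norm(c, p) == 0


def epsilon(c: Circuit, p: Permutation, denominator: str = "circuit") -> PseudoSymmetry:
    """Uncertainty constant eps = ||[P, A]|| / M of a permutation.

    ``denominator="circuit"`` uses the whole circuit's total weight M;
    ``"support"`` restricts M to links incident to the permutation's
    support (the stricter local reading).
    """
    _check_perm(c, p)
    norm = commutator_norm(c, p)
    if denominator == "circuit":
        M = c.total_weight
    elif denominator == "support":
        sup = [i for i, j in enumerate(p.images) if i != j]
        mask = np.zeros(c.n, dtype=bool)
        mask[sup] = True
        # links with at least one endpoint in the support, each counted once
        if c.directed:
            M = int(c.weights[mask, :].sum()
                    + c.weights[np.ix_(~mask, mask)].sum())
        else:
            M = int(c.weights[mask, :].sum()
                    - c.weights[np.ix_(mask, mask)].sum() // 2)
    else:
        raise ValueError(f"unknown denominator mode {denominator!r}")
    if M == 0:
        raise CircuitError("circuit (or support) has no links; eps undefined")
    return PseudoSymmetry(p, norm, norm / M)


# ---------------------------------------------------------------------------
# exact automorphism enumeration


def _refine_colors(A: np.ndarray, directed: bool) -> np.ndarray:
    """Weighted 1-WL color refinement; returns an integer color per node."""
    n = A.shape[0]
    colors = np.zeros(n, dtype=np.int64)
    for _ in range(n + 1):
        sigs = []
        for i in range(n):
            out_sig = tuple(sorted((int(A[i, j]), int(colors[j]))
                                   for j in range(n) if A[i, j]))
            if directed:
                in_sig = tuple(sorted((int(A[j, i]), int(colors[j]))
                                      for j in range(n) if A[j, i]))
                sigs.append((int(colors[i]), out_sig, in_sig))
            else:
                sigs.append((int(colors[i]), out_sig))
        uniq = {s: k for k, s in enumerate(sorted(set(sigs)))}
        new = np.array([uniq[s] for s in sigs], dtype=np.int64)
        if _partition_key(new) == _partition_key(colors):
            return new
        colors = new
    return colors


def _partition_key(colors: np.ndarray) -> tuple:
    cells: dict[int, list[int]] = {}
    for i, col in enumerate(colors.tolist()):
        cells.setdefault(col, []).append(i)
    return tuple(sorted(tuple(v) for v in cells.values()))


def automorphism_group(c: Circuit, max_nodes: int = 64,
                       order_cap: int = 10 ** 6):
    """Enumerate the full group of exact automorphisms.

    Backtracking over a color-refined partition: nodes may only map to
    nodes of the same refined color, and every partial mapping must
    preserve weights against all previously assigned nodes.  Raises if the
    circuit exceeds ``max_nodes`` or the group order exceeds ``order_cap``.

    Returns a :class:`~circuitsym.group_structure.PermGroup`.
    """
    from .group_structure import PermGroup

    n = c.n
    if n > max_nodes:
        raise CircuitError(
            f"automorphism search guarded at {max_nodes} nodes (got {n}); "
            "analyze sector-wise instead"
        )
    A = c.weights
    colors = _refine_colors(A, c.directed)

    # process small color cells first: cheap branching near the root
    cells: dict[int, list[int]] = {}
    for i, col in enumerate(colors.tolist()):
        cells.setdefault(col, []).append(i)
    node_order = [i for cell in sorted(cells.values(), key=len) for i in cell]

    found: list[tuple[int, ...]] = []
    images = [-1] * n
    used = [False] * n

    def extend(k: int) -> None:
        if k == n:
            found.append(tuple(images))
            if len(found) > order_cap:
                raise CircuitError(
                    f"automorphism group order exceeds cap {order_cap}"
                )
            return
        i = node_order[k]
        for j in range(n):
            if used[j] or colors[j] != colors[i]:
                continue
            ok = True
            for kk in range(k):
                m = node_order[kk]
                if A[i, m] != A[j, images[m]] or A[m, i] != A[images[m], j]:
                    ok = False
                    break
            if ok:
                images[i] = j
                used[j] = True
                extend(k + 1)
                used[j] = False
                images[i] = -1

    extend(0)
    perms = [Permutation(c.labels, imgs) for imgs in found]
    return PermGroup.from_elements(c.labels, perms)


# ---------------------------------------------------------------------------
# pseudosymmetry search


def swap_cost_matrix(c: Circuit, denominator: str = "circuit") -> np.ndarray:
    """eps of every transposition (i, j), as a symmetric matrix."""
    n = c.n
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            p = Permutation.transposition(c.labels, c.labels[i], c.labels[j])
            out[i, j] = out[j, i] = epsilon(c, p, denominator).eps
    return out


def _template_eps(c: Circuit, gens: Sequence[Permutation],
                  denominator: str) -> tuple[float, float]:
    vals = [epsilon(c, g, denominator).eps for g in gens]
    return max(vals), float(np.mean(vals))


def _cyclic_orderings(sector: Sequence[str]) -> Iterable[tuple[str, ...]]:
    """Distinct directed cycles on the sector, first label fixed."""
    first, rest = sector[0], list(sector[1:])
    for tail in itertools.permutations(rest):
        yield (first,) + tail


def find_pseudosymmetries(
    c: Circuit,
    eps_max: float = PLAUSIBILITY_BOUND,
    *,
    denominator: str = "circuit",
    max_cycle_len: int = 6,
    auto_max_nodes: int = 64,
) -> dict:
    """Deterministic three-stage pseudosymmetry search.

    1. exact automorphisms (when the circuit is small enough to enumerate);
    2. all transpositions with eps <= eps_max, recorded as C_2 candidates;
    3. greedy sector growth: labels whose pairwise swap costs are all
       <= eps_max are clustered into candidate sectors, and each sector is
       tested against subgroup templates (full symmetric group, cyclic
       rotations for small sectors, a single pair-matching involution).

    Returns a dict with keys ``exact`` (list of Permutation), ``swaps``
    (list of PseudoSymmetry for accepted transpositions), ``templates``
    (list of TemplateResult) and ``sectors`` (candidate label sets).
    Output is sorted by (eps ascending, support size descending,
    lexicographic labels) for reproducibility.
    """
    if not (0 <= eps_max <= 1):
        raise ValueError("eps_max must be in [0, 1]")

    exact: list[Permutation] = []
    exact_group = None
    if c.n <= auto_max_nodes:
        try:
            exact_group = automorphism_group(c, max_nodes=auto_max_nodes)
            exact = sorted((p for p in exact_group.perms()
                            if not p.is_identity),
                           key=lambda p: (len(p.support), str(p)))
        except CircuitError:
            exact = []

    cost = swap_cost_matrix(c, denominator)
    swaps: list[PseudoSymmetry] = []
    n = c.n
    for i in range(n):
        for j in range(i + 1, n):
            if cost[i, j] <= eps_max:
                p = Permutation.transposition(c.labels, c.labels[i], c.labels[j])
                swaps.append(epsilon(c, p, denominator))
    swaps.sort(key=lambda ps: (ps.eps, sorted(ps.perm.support)))

    if eps_max == 0:
        return {"exact": exact, "exact_group": exact_group, "swaps": swaps,
                "templates": [], "sectors": []}

    # stage 3: candidate sectors = connected components of the cheap-swap graph
    adj = cost <= eps_max
    np.fill_diagonal(adj, False)
    sectors: list[tuple[str, ...]] = []
    seen: set[int] = set()
    for i in range(n):
        if i in seen or not adj[i].any():
            continue
        comp = {i}
        frontier = [i]
        while frontier:
            k = frontier.pop()
            for j in np.flatnonzero(adj[k]):
                if j not in comp:
                    comp.add(int(j))
                    frontier.append(int(j))
        seen |= comp
        sectors.append(tuple(sorted(c.labels[k] for k in comp)))
    sectors.sort()

    templates: list[TemplateResult] = []
    for sector in sectors:
        k = len(sector)
        # full symmetric group: generators = all transpositions
        gens = tuple(
            Permutation.transposition(c.labels, a, b)
            for a, b in itertools.combinations(sector, 2)
        )
        mx, mean = _template_eps(c, gens, denominator)
        if mx <= eps_max:
            name = "C_2" if k == 2 else f"S_{k}"
            templates.append(TemplateResult(name, sector, gens, mx, mean))
        # cyclic rotation over orderings (small sectors only)
        if 3 <= k <= max_cycle_len:
            best = None
            for ordering in _cyclic_orderings(sector):
                rot = Permutation.from_cycles(c.labels, [ordering])
                e = epsilon(c, rot, denominator).eps
                if e <= eps_max and (best is None or e < best[0]):
                    best = (e, rot)
            if best is not None:
                templates.append(
                    TemplateResult(f"C_{k}", sector, (best[1],), best[0], best[0])
                )
        # single involution pairing nodes (even sectors)
        if k >= 4 and k % 2 == 0:
            pairs = _greedy_matching(sector, c, cost)
            if pairs is not None:
                inv = Permutation.from_cycles(c.labels, pairs)
                e = epsilon(c, inv, denominator).eps
                if e <= eps_max:
                    templates.append(
                        TemplateResult("D_1", sector, (inv,), e, e)
                    )
    templates.sort(key=lambda t: (t.eps, -len(t.sector), t.sector))
    return {"exact": exact, "exact_group": exact_group, "swaps": swaps,
            "templates": templates, "sectors": sectors}


def _greedy_matching(sector: Sequence[str], c: Circuit,
                     cost: np.ndarray) -> list[tuple[str, str]] | None:
    """Pair up sector labels greedily by ascending swap cost."""
    pos = {lab: c.labels.index(lab) for lab in sector}
    cand = sorted(
        (cost[pos[a], pos[b]], a, b)
        for a, b in itertools.combinations(sorted(sector), 2)
    )
    taken: set[str] = set()
    pairs: list[tuple[str, str]] = []
    for _, a, b in cand:
        if a in taken or b in taken:
            continue
        pairs.append((a, b))
        taken |= {a, b}
    if len(taken) != len(sector):
        return None
    return pairs
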