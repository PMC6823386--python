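"""Finite permutation-group algebra.

Closure of a generating set, normality tests, direct-product factorization
into subgroups acting on disjoint neuron *sectors*, and naming of the
resulting factors with the cyclic / dihedral / symmetric tags used
throughout the analysis.

The factorization is the core structural statement: when the symmetry
group of a circuit is a direct product of subgroups with pairwise disjoint
supports, each factor acts independently on its own sector of neurons and
the sector partition is unique.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Sequence

from .symmetry import Permutation

__all__ = [
    "PermGroup",
    "Factorization",
    "Factor",
    "closure",
    "is_normal",
    "factorize",
    "identify_group",
]


class GroupError(ValueError):
    pass


@dataclass(frozen=True)
class PermGroup:
    """A finite permutation group on a fixed label set, fully materialized.

    ``elements`` is the set of image tuples; ``generators`` a (small)
    generating set.  The four group axioms (identity, inverse, closure,
    associativity) are guaranteed by construction via :func:`closure`.
    """

    labels: tuple[str, ...]
    generators: tuple[Permutation, ...]
    elements: frozenset[tuple[int, ...]]

    @property
    def order(self) -> int:
        return len(self.elements)

    def perms(self) -> list[Permutation]:
        return [Permutation(self.labels, imgs) for imgs in sorted(self.elements)]

    def __contains__(self, p: Permutation) -> bool:
        if tuple(p.labels) != self.labels:
            return False
        return p.images in self.elements

    def contains_images(self, images: tuple[int, ...]) -> bool:
        return images in self.elements

    @property
    def moved(self) -> frozenset[str]:
        out: set[str] = set()
        for imgs in self.elements:
            out.update(self.labels[i] for i, j in enumerate(imgs) if i != j)
        return frozenset(out)

    def orbit_partition(self) -> list[frozenset[str]]:
        from .imprimitivity import orbits

        return orbits(self)

    @classmethod
    def from_elements(cls, labels: Sequence[str],
                      perms: Iterable[Permutation]) -> "PermGroup":
        labels = tuple(labels)
        elems = {p.images for p in perms}
        elems.add(tuple(range(len(labels))))
        gens = _reduce_generators(labels, elems)
        return cls(labels, gens, frozenset(elems))

    @classmethod
    def trivial(cls, labels: Sequence[str]) -> "PermGroup":
        labels = tuple(labels)
        ident = tuple(range(len(labels)))
        return cls(labels, (), frozenset({ident}))


def _compose(a: tuple[int, ...], b: tuple[int, ...]) -> tuple[int, ...]:
    """(a . b)(x) = a(b(x)) on image tuples."""
    return tuple(a[j] for j in b)


def _bfs_closure(labels: tuple[str, ...],
                 gens: Sequence[tuple[int, ...]],
                 cap: int) -> set[tuple[int, ...]]:
    ident = tuple(range(len(labels)))
    elems = {ident}
    frontier = [ident]
    while frontier:
        nxt = []
        for e in frontier:
            for g in gens:
                prod = _compose(g, e)
                if prod not in elems:
                    elems.add(prod)
                    nxt.append(prod)
                    if len(elems) > cap:
                        raise GroupError(
                            f"closure exceeds cap {cap}; partial order "
                            f">= {len(elems)}"
                        )
        frontier = nxt
    return elems


def _reduce_generators(labels: tuple[str, ...],
                       elems: set[tuple[int, ...]]) -> tuple[Permutation, ...]:
    """Greedy small generating set for a materialized element set."""
    ident = tuple(range(len(labels)))
    if elems <= {ident}:
        return ()
    gens: list[tuple[int, ...]] = []
    have: set[tuple[int, ...]] = {ident}
    # deterministic order: most-moving elements first reach big subgroups fast
    for e in sorted(elems, key=lambda t: (-sum(i != j for i, j in enumerate(t)), t)):
        if e in have:
            continue
        gens.append(e)
        have = _bfs_closure(labels, gens, cap=len(elems))
        if len(have) == len(elems):
            break
    return tuple(Permutation(labels, g) for g in gens)


def closure(gens: Sequence[Permutation], cap: int = 10 ** 6) -> PermGroup:
    """Group generated by ``gens`` via breadth-first products."""
    if not gens:
        raise GroupError("closure needs at least one generator (or use "
                         "PermGroup.trivial)")
    labels = tuple(gens[0].labels)
    for g in gens:
        if tuple(g.labels) != labels:
            raise GroupError("generators act on different label sets")
    elems = _bfs_closure(labels, [g.images for g in gens], cap)
    nontrivial = tuple(g for g in gens if not g.is_identity)
    return PermGroup(labels, nontrivial or (), frozenset(elems))


def is_normal(h: PermGroup, g: PermGroup) -> bool:
    """True iff ``x H x^{-1} = H`` for every ``x`` in ``g`` (gH = Hg).

    Conjugating by a generating set of ``g`` suffices: conjugation by a
    product is the composition of conjugations.
    """
    if h.labels != g.labels:
        raise GroupError("groups act on different label sets")
    if not h.elements <= g.elements:
        raise GroupError("h is not a subgroup of g")
    conjugators = [p.images for p in g.generators] or list(g.elements)
    for x in conjugators:
        xinv = [0] * len(x)
        for i, j in enumerate(x):
            xinv[j] = i
        xinv = tuple(xinv)
        for e in h.elements:
            if _compose(_compose(x, e), xinv) not in h.elements:
                return False
    return True


@dataclass(frozen=True)
class Factor:
    subgroup: PermGroup
    sector: tuple[str, ...]
    name: str


@dataclass(frozen=True)
class Factorization:
    group: PermGroup
    factors: tuple[Factor, ...]
    residual: bool

    @property
    def sectors(self) -> list[tuple[str, ...]]:
        return [f.sector for f in self.factors]

    def names(self) -> list[str]:
        return [f.name for f in self.factors]


def _restriction(images: tuple[int, ...], comp: frozenset[int]) -> tuple[int, ...]:
    """Restrict a permutation to the index set ``comp``, identity elsewhere."""
    return tuple(images[i] if i in comp else i for i in range(len(images)))


def factorize(g: PermGroup, dihedral_order_naming: bool = True) -> Factorization:
    """Factor ``g`` into subgroups acting on disjoint sectors.

    Starting from the orbit partition, orbits are merged whenever some
    group element's restriction to one candidate component is not itself a
    member of ``g`` (the restriction test detects coupling between orbits;
    it suffices to test a generating set, since restriction to a fixed
    component is a homomorphism).  Each final component yields a factor
    whose elements are the restrictions of the group to that component.
    Verification (orders multiply to |g|, mutual normality) failures are
    encoded in ``residual``, never raised.
    """
    from .imprimitivity import orbits

    labels = g.labels
    pos = {lab: i for i, lab in enumerate(labels)}
    orbs = [frozenset(pos[l] for l in orb) for orb in orbits(g)
            if len(orb) > 1]
    if not orbs:
        return Factorization(g, (), residual=g.order != 1)

    comps: list[set[int]] = [set(o) for o in orbs]

    def comp_of(i: int) -> int:
        for k, cmp_ in enumerate(comps):
            if i in cmp_:
                return k
        return -1

    gens = [p.images for p in g.generators] or list(g.elements)
    changed = True
    while changed:
        changed = False
        for gen in gens:
            moved_comps = sorted({comp_of(i) for i, j in enumerate(gen)
                                  if i != j})
            if len(moved_comps) <= 1:
                continue
            failing = [k for k in moved_comps
                       if not g.contains_images(
                           _restriction(gen, frozenset(comps[k])))]
            if failing:
                merged = set()
                for k in failing:
                    merged |= comps[k]
                comps = [cmp_ for k, cmp_ in enumerate(comps)
                         if k not in failing]
                comps.append(merged)
                changed = True
                break

    # deterministic sector order: by first-appearing label index
    comps.sort(key=lambda cmp_: min(cmp_))

    factors: list[Factor] = []
    residual = False
    order_product = 1
    for cmp_ in comps:
        fro = frozenset(cmp_)
        elems = {_restriction(e, fro) for e in g.elements}
        if not all(e in g.elements for e in elems):
            residual = True
        sub = PermGroup(labels, _reduce_generators(labels, set(elems)),
                        frozenset(elems))
        sector = tuple(sorted((labels[i] for i in cmp_)))
        factors.append(Factor(sub, sector,
                              identify_group(sub, dihedral_order_naming)))
        order_product *= sub.order

    if order_product != g.order:
        residual = True
    if not residual:
        for f in factors:
            if not is_normal(f.subgroup, g):
                residual = True
                break
    return Factorization(g, tuple(factors), residual)


# ---------------------------------------------------------------------------
# group naming


def _element_orders(h: PermGroup) -> list[int]:
    out = []
    ident = tuple(range(len(h.labels)))
    for e in h.elements:
        k, p = 1, e
        while p != ident:
            p = _compose(e, p)
            k += 1
        out.append(k)
    return out


def _is_full_symmetric(h: PermGroup, moved: frozenset[str]) -> bool:
    import math

    k = len(moved)
    if h.order != math.factorial(k):
        return False
    # order alone suffices only with faithful action on the moved points;
    # verify the restrictions realize k! distinct arrangements
    pos = [i for i, lab in enumerate(h.labels) if lab in moved]
    seen = {tuple(e[i] for i in pos) for e in h.elements}
    return len(seen) == math.factorial(k)


def _is_dihedral(h: PermGroup) -> int | None:
    """Return m when h is dihedral of order 2m (m >= 2), else None."""
    n = h.order
    if n % 2 or n < 4:
        return None
    m = n // 2
    orders = _element_orders(h)
    if m == 2:
        # Klein four-group: the degenerate dihedral group of order 4
        return 2 if all(o in (1, 2) for o in orders) else None
    rot = [e for e, o in zip(h.elements, orders) if o == m]
    if not rot:
        return None
    r = rot[0]
    invs = [e for e, o in zip(h.elements, orders) if o == 2]
    rinv = [0] * len(r)
    for i, j in enumerate(r):
        rinv[j] = i
    rinv = tuple(rinv)
    for s in invs:
        if _compose(s, _compose(r, s)) == rinv:
            # <r, s> must be the whole group
            sub = _bfs_closure(h.labels, [r, s], cap=n + 1)
            if len(sub) == n:
                return m
    return None


def identify_group(h: PermGroup, dihedral_order_naming: bool = True) -> str:
    """Name a factor: C_n, D_n, S_k or ``other(order)``.

    Conventions follow the circuit-analysis usage: an order-2 group whose
    generator is a single transposition is C_2, while an order-2 group
    whose involution moves more than two points is D_1.  Dihedral groups
    are named by their order (the square's symmetry group of 8 elements is
    D_8) when ``dihedral_order_naming`` is true, by the polygon size
    otherwise.
    """
    n = h.order
    if n == 1:
        return "C_1"
    moved = h.moved
    if n == 2:
        return "C_2" if len(moved) == 2 else "D_1"
    if _is_full_symmetric(h, moved):
        return f"S_{len(moved)}"
    orders = _element_orders(h)
    if max(orders) == n:
        return f"C_{n}"
    m = _is_dihedral(h)
    if m is not None:
        return f"D_{2 * m}" if dihedral_order_naming else f"D_{m}"
    return f"other({n})"
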