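"""Orbits, minimal block systems and primitivity tests.

A *block of imprimitivity* of a transitive group action is a node set that
every group element maps wholly onto itself or onto a disjoint set.  The
conjugate blocks tile the orbit (a *system of imprimitivity*); equal block
size divides the orbit size.  A transitive action with no nontrivial block
system is *primitive*.
"""

from __future__ import annotations

from dataclasses import dataclass

from .group_structure import PermGroup, GroupError

__all__ = [
    "BlockSystem",
    "orbits",
    "minimal_blocks",
    "block_systems",
    "is_primitive",
    "sector_block_candidates",
]


@dataclass(frozen=True)
class BlockSystem:
    """Disjoint equal-size blocks covering one orbit of ``parent``."""

    blocks: tuple[tuple[str, ...], ...]
    parent: PermGroup

    @property
    def block_size(self) -> int:
        return len(self.blocks[0])

    @property
    def is_trivial(self) -> bool:
        return self.block_size == 1 or len(self.blocks) == 1

    def key(self) -> tuple:
        return tuple(sorted(tuple(sorted(b)) for b in self.blocks))

    def verify(self) -> bool:
        """Exhaustive block-property check over all group elements."""
        labels = self.parent.labels
        pos = {lab: i for i, lab in enumerate(labels)}
        blocks_idx = [frozenset(pos[l] for l in b) for b in self.blocks]
        for e in self.parent.elements:
            for b in blocks_idx:
                img = frozenset(e[i] for i in b)
                if img != b and img & b:
                    return False
        return True


def orbits(g: PermGroup) -> list[frozenset[str]]:
    """Orbit partition of the label set (connected components of the union
    of generator mappings); includes singleton orbits of fixed labels."""
    n = len(g.labels)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(a: int, b: int) -> None:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb

    gens = [p.images for p in g.generators] or list(g.elements)
    for imgs in gens:
        for i, j in enumerate(imgs):
            if i != j:
                union(i, j)
    cells: dict[int, set[str]] = {}
    for i in range(n):
        cells.setdefault(find(i), set()).add(g.labels[i])
    return sorted((frozenset(v) for v in cells.values()),
                  key=lambda s: sorted(s))


def _check_transitive(g: PermGroup, orbit: frozenset[str]) -> None:
    for orb in orbits(g):
        if orb == orbit:
            return
        if orb & orbit:
            break
    raise GroupError(
        f"group is not transitive on {sorted(orbit)}; analyze per orbit"
    )


def minimal_blocks(g: PermGroup, orbit, seed_pair) -> BlockSystem:
    """Minimal block system whose block contains both seed labels.

    Union-find refinement: merge the seed pair, then propagate images of
    merged pairs under the generators until stable (Atkinson's algorithm).
    """
    orbit = frozenset(orbit)
    a, b = seed_pair
    if a not in orbit or b not in orbit:
        raise GroupError(f"seed pair ({a}, {b}) not inside the orbit")
    _check_transitive(g, orbit)

    labels = g.labels
    pos = {lab: i for i, lab in enumerate(labels)}
    parent: dict[int, int] = {pos[l]: pos[l] for l in orbit}

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    gens = [p.images for p in g.generators] or list(g.elements)
    queue = [(pos[a], pos[b])]
    while queue:
        x, y = queue.pop()
        rx, ry = find(x), find(y)
        if rx == ry:
            continue
        parent[rx] = ry
        for imgs in gens:
            queue.append((imgs[x], imgs[y]))

    cells: dict[int, list[str]] = {}
    for i in parent:
        cells.setdefault(find(i), []).append(labels[i])
    blocks = tuple(sorted((tuple(sorted(v)) for v in cells.values())))
    return BlockSystem(blocks, g)


def block_systems(g: PermGroup, orbit, include_trivial: bool = False
                  ) -> list[BlockSystem]:
    """All distinct minimal block systems on the orbit.

    Seeds the refinement with (first label, every other label) and
    deduplicates.  Trivial systems (singletons / the whole orbit) are
    excluded unless requested.
    """
    orbit = frozenset(orbit)
    _check_transitive(g, orbit)
    first = sorted(orbit)[0]
    seen: dict[tuple, BlockSystem] = {}
    for other in sorted(orbit):
        if other == first:
            continue
        bs = minimal_blocks(g, orbit, (first, other))
        seen.setdefault(bs.key(), bs)
    out = [bs for bs in seen.values()
           if include_trivial or not bs.is_trivial]
    return sorted(out, key=lambda bs: bs.key())


def is_primitive(g: PermGroup, orbit) -> bool:
    """True iff the transitive action on the orbit has no nontrivial
    block system."""
    return not block_systems(g, orbit)


def sector_block_candidates(c, g: PermGroup, sector) -> list[BlockSystem]:
    """Conjugate-block candidates for a factor that is *intransitive* on
    its sector (e.g. a single involution pairing nodes).

    When the factor action is intransitive the classic seed-pair
    refinement only reaches within orbits, yet sets spanning several
    orbits can still satisfy the block property (every element maps them
    onto themselves or onto a disjoint set).  Candidates enumerated here:

    * the orbit partition itself (always a valid system);
    * connected components of each edge-weight class of the sector's
      induced subcircuit, when they are equal-size, tile the sector and
      satisfy the block property — this recovers conjugate cycle blocks;
    * for an involution acting as k 2-cycles (k <= 6), all transversal
      splits {B, sigma(B)} with one node per orbit.

    Results are deduplicated, verified, and sorted with connected
    (structurally supported) systems first.
    """
    from .circuits import subcircuit

    sector = tuple(sorted(sector))
    pos = {lab: i for i, lab in enumerate(g.labels)}
    orbs = [sorted(o) for o in orbits(g) if o <= frozenset(sector)]
    moved = [o for o in orbs if len(o) > 1]
    systems: dict[tuple, tuple[BlockSystem, bool]] = {}

    def consider(blocks, connected: bool) -> None:
        if not blocks or len({len(b) for b in blocks}) != 1:
            return
        if sorted(l for b in blocks for l in b) != list(sector):
            return
        bs = BlockSystem(tuple(sorted(tuple(sorted(b)) for b in blocks)), g)
        if bs.verify():
            prev = systems.get(bs.key())
            if prev is None or (connected and not prev[1]):
                systems[bs.key()] = (bs, connected)

    consider([tuple(o) for o in orbs], connected=False)

    sub = subcircuit(c, sector)
    weights = sorted({int(w) for w in sub.weights.flat if w})
    import networkx as nx

    for w in weights:
        G = nx.Graph()
        G.add_nodes_from(sector)
        for i, a in enumerate(sector):
            for j, b in enumerate(sector):
                if i < j and (sub.weights[i, j] == w or sub.weights[j, i] == w):
                    G.add_edge(a, b)
        comps = [tuple(sorted(cc)) for cc in nx.connected_components(G)
                 if len(cc) > 1]
        consider(comps, connected=True)

    # transversal splits of a pure involution action
    if all(len(o) == 2 for o in moved) and 1 < len(moved) <= 6:
        import itertools

        for choice in itertools.product(*[range(2) for _ in moved]):
            if choice[0] == 1:
                continue  # (B, sigma B) and (sigma B, B) are the same split
            B = tuple(sorted(o[k] for o, k in zip(moved, choice)))
            Bc = tuple(sorted(o[1 - k] for o, k in zip(moved, choice)))
            consider([B, Bc], connected=False)

    ordered = sorted(systems.values(),
                     key=lambda t: (not t[1], -t[0].block_size, t[0].key()))
    return [bs for bs, _ in ordered]
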