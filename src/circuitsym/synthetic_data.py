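"""Planted-symmetry circuit generator and controlled perturbations.

Circuits are assembled from disjoint *sectors*, each carrying a planted
permutation group (C_n, D_n or S_n) realized by circulant internal blocks
and block couplings, wired to hub "command" nodes by per-node feedforward
weights.  The generator verifies by construction that every planted
generator is an exact automorphism of the unperturbed circuit, so the
planted direct product is contained in the circuit's symmetry group.

:func:`perturb` then emulates animal-to-animal variability by flipping a
controlled fraction of link units (weight +-1 steps), the noise model
under which exact symmetries degrade into pseudosymmetries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import yaml

from .circuits import Circuit, CircuitError
from .symmetry import Permutation, commutator_norm
from .group_structure import PermGroup, closure

__all__ = [
    "SectorSpec",
    "PlantSpec",
    "PlantedTruth",
    "plant_circuit",
    "perturb",
    "command_circuit",
    "forward_gap_fixture",
    "backward_aib_rim_fixture",
]


@dataclass(frozen=True)
class SectorSpec:
    """One planted sector.

    ``group`` is the template tag (``C_2``, ``C_n``, ``S_n``, ``D_1``).
    ``hub_weight`` is either one integer (same weight to every hub) or a
    mapping label -> weight; weights must be constant on the planted
    orbits or planting fails.  ``first_row`` gives the internal circulant
    of each block; for ``D_1`` two equal-size ``blocks`` and a symmetric
    ``coupling`` matrix between them are required.
    """

    group: str
    labels: tuple[str, ...]
    hub_weight: int | dict[str, int] = 1
    first_row: tuple[int, ...] | None = None
    blocks: tuple[tuple[str, ...], ...] | None = None
    coupling: tuple[tuple[int, ...], ...] | None = None

    def hub_weight_of(self, label: str) -> int:
        if isinstance(self.hub_weight, dict):
            return int(self.hub_weight[label])
        return int(self.hub_weight)


@dataclass(frozen=True)
class PlantSpec:
    sectors: tuple[SectorSpec, ...]
    hubs: tuple[str, ...] = ()
    hub_edges: tuple[tuple[str, str, int], ...] = ()
    hub_pairs: tuple[tuple[str, str], ...] = ()
    directed: bool = False
    link_type: str = "gap"
    perturb_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        all_labels = [l for s in self.sectors for l in s.labels]
        all_labels += list(self.hubs)
        if len(set(all_labels)) != len(all_labels):
            raise CircuitError("sectors and hubs must be pairwise disjoint")
        if not (0 <= self.perturb_fraction < 1):
            raise CircuitError("perturb_fraction must be in [0, 1)")

    # -- YAML round trip -------------------------------------------------

    def to_yaml(self) -> str:
        doc = {
            "hubs": list(self.hubs),
            "hub_edges": [list(e) for e in self.hub_edges],
            "hub_pairs": [list(p) for p in self.hub_pairs],
            "directed": self.directed,
            "link_type": self.link_type,
            "perturb_fraction": self.perturb_fraction,
            "seed": self.seed,
            "sectors": [
                {
                    "group": s.group,
                    "labels": list(s.labels),
                    "hub_weight": (dict(s.hub_weight)
                                   if isinstance(s.hub_weight, dict)
                                   else s.hub_weight),
                    **({"first_row": list(s.first_row)}
                       if s.first_row else {}),
                    **({"blocks": [list(b) for b in s.blocks]}
                       if s.blocks else {}),
                    **({"coupling": [list(r) for r in s.coupling]}
                       if s.coupling else {}),
                }
                for s in self.sectors
            ],
        }
        return yaml.safe_dump(doc, sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "PlantSpec":
        doc = yaml.safe_load(text)
        sectors = tuple(
            SectorSpec(
                group=s["group"],
                labels=tuple(s["labels"]),
                hub_weight=(s.get("hub_weight", 1)
                            if not isinstance(s.get("hub_weight"), dict)
                            else {k: int(v) for k, v in s["hub_weight"].items()}),
                first_row=tuple(s["first_row"]) if "first_row" in s else None,
                blocks=tuple(tuple(b) for b in s["blocks"])
                if "blocks" in s else None,
                coupling=tuple(tuple(r) for r in s["coupling"])
                if "coupling" in s else None,
            )
            for s in doc["sectors"]
        )
        return cls(
            sectors=sectors,
            hubs=tuple(doc.get("hubs", ())),
            hub_edges=tuple((a, b, int(w)) for a, b, w in doc.get("hub_edges", ())),
            hub_pairs=tuple(tuple(p) for p in doc.get("hub_pairs", ())),
            directed=doc.get("directed", False),
            link_type=doc.get("link_type", "gap"),
            perturb_fraction=float(doc.get("perturb_fraction", 0.0)),
            seed=int(doc.get("seed", 0)),
        )


@dataclass(frozen=True)
class PlantedTruth:
    """Ground truth: planted sectors, group names and generators."""

    sectors: tuple[tuple[str, ...], ...]
    names: tuple[str, ...]
    generators: tuple[tuple[Permutation, ...], ...]

    def group(self) -> PermGroup:
        gens = [g for gs in self.generators for g in gs]
        return closure(gens)


def _sector_generators(spec: SectorSpec, labels: tuple[str, ...]
                       ) -> list[Permutation]:
    import itertools

    tag = spec.group
    labs = spec.labels
    if tag.startswith("S_") or tag == "C_2":
        if tag == "C_2" and len(labs) != 2:
            raise CircuitError("C_2 sector needs exactly 2 labels")
        return [Permutation.transposition(labels, a, b)
                for a, b in itertools.combinations(labs, 2)]
    if tag.startswith("C_"):
        return [Permutation.from_cycles(labels, [labs])]
    if tag == "D_1":
        if spec.blocks is None or len(spec.blocks) != 2:
            raise CircuitError("D_1 sector needs two blocks")
        b1, b2 = spec.blocks
        pairs = list(zip(b1, b2))
        return [Permutation.from_cycles(labels, pairs)]
    raise CircuitError(f"unsupported planted group {tag!r}")


def plant_circuit(spec: PlantSpec) -> tuple[Circuit, PlantedTruth]:
    """Assemble the planted circuit and verify the planted symmetries.

    Raises when a coupling or hub weight breaks a planted generator, with
    the offending sector named.
    """
    labels = tuple(spec.hubs) + tuple(l for s in spec.sectors for l in s.labels)
    pos = {lab: i for i, lab in enumerate(labels)}
    n = len(labels)
    A = np.zeros((n, n), dtype=np.int64)

    def add(a: str, b: str, w: int) -> None:
        A[pos[a], pos[b]] += w
        if not spec.directed:
            A[pos[b], pos[a]] += w

    for a, b, w in spec.hub_edges:
        add(a, b, w)

    for s in spec.sectors:
        # hub feedforward wiring
        for lab in s.labels:
            w = s.hub_weight_of(lab)
            if w:
                for hub in spec.hubs:
                    add(hub, lab, w)  # directed circuits feed hub -> sector
        # internal structure
        if s.group == "D_1":
            b1, b2 = s.blocks
            if s.first_row is not None:
                for blk in (b1, b2):
                    _add_circulant(add, blk, s.first_row, spec.directed)
            if s.coupling is not None:
                C = np.asarray(s.coupling)
                if not spec.directed and not np.array_equal(C, C.T):
                    raise CircuitError(
                        f"sector {s.labels}: undirected block coupling must "
                        "be symmetric for the planted involution to hold"
                    )
                for i, la in enumerate(b1):
                    for j, lb in enumerate(b2):
                        if C[i, j]:
                            add(la, lb, int(C[i, j]))
        elif s.first_row is not None:
            _add_circulant(add, s.labels, s.first_row, spec.directed)

    c = Circuit(labels, A, directed=spec.directed, link_type=spec.link_type)

    sectors: list[tuple[str, ...]] = []
    names: list[str] = []
    gens_per: list[tuple[Permutation, ...]] = []
    for s in spec.sectors:
        gens = _sector_generators(s, labels)
        for g in gens:
            if commutator_norm(c, g) != 0:
                raise CircuitError(
                    f"planted generator {g} of sector {s.labels} is broken "
                    "by the wiring (check couplings and hub weights)"
                )
        sectors.append(tuple(sorted(s.labels)))
        names.append(s.group)
        gens_per.append(tuple(gens))
    for a, b in spec.hub_pairs:
        g = Permutation.transposition(labels, a, b)
        if commutator_norm(c, g) != 0:
            raise CircuitError(f"hub pair ({a}, {b}) is not exchangeable")
        sectors.append((min(a, b), max(a, b)))
        names.append("C_2")
        gens_per.append((g,))

    return c, PlantedTruth(tuple(sectors), tuple(names), tuple(gens_per))


def _add_circulant(add, labs: Sequence[str], first_row: Sequence[int],
                   directed: bool) -> None:
    k = len(labs)
    if len(first_row) != k:
        raise CircuitError("first_row length must equal block size")
    row = list(first_row)
    if not directed:
        # each undirected link added once: use the upper offsets only
        for i in range(k):
            for d in range(1, k):
                j = (i + d) % k
                if row[d] and i < j:
                    if row[d] != row[(k - d) % k]:
                        raise CircuitError(
                            "undirected circulant template must be symmetric "
                            f"(row {tuple(row)})"
                        )
                    add(labs[i], labs[j], row[d])
    else:
        for i in range(k):
            for d in range(1, k):
                if row[d]:
                    add(labs[i], labs[(i + d) % k], row[d])


def perturb(c: Circuit, fraction: float, seed: int = 0) -> tuple[Circuit, float]:
    """Flip ``round(fraction * M)`` link units uniformly at random.

    Each change removes one unit from a random existing link or adds one
    unit to a random off-diagonal pair (probability 1/2 each, undirected
    links changed symmetrically).  Returns the perturbed circuit and the
    realized fraction of changed link units.  ``fraction = 0`` returns the
    circuit unchanged.
    """
    if not (0 <= fraction < 1):
        raise CircuitError("fraction must be in [0, 1)")
    M = c.total_weight
    k = int(round(fraction * M))
    if k == 0:
        return c, 0.0
    rng = np.random.default_rng(seed)
    A = c.weights.copy()
    A.setflags(write=True)
    n = c.n
    for _ in range(k):
        if rng.integers(0, 2) and A.sum() > 0:
            # remove one unit from a randomly chosen existing link
            if c.directed:
                nz = np.argwhere(A > 0)
                units = A[tuple(nz.T)]
            else:
                iu = np.triu_indices(n, 1)
                mask = A[iu] > 0
                nz = np.column_stack([iu[0][mask], iu[1][mask]])
                units = A[tuple(nz.T)]
            probs = units / units.sum()
            pick = nz[rng.choice(len(nz), p=probs)]
            i, j = int(pick[0]), int(pick[1])
            A[i, j] -= 1
            if not c.directed:
                A[j, i] -= 1
        else:
            i, j = rng.integers(0, n, size=2)
            while i == j:
                i, j = rng.integers(0, n, size=2)
            A[i, j] += 1
            if not c.directed:
                A[j, i] += 1
    out = Circuit(c.labels, A, directed=c.directed, link_type=c.link_type)
    return out, k / M


# ---------------------------------------------------------------------------
# canonical fixtures


def command_circuit(weighted: bool = False) -> Circuit:
    """The 4-neuron command interneuron gap-junction circuit.

    Unweighted: the bcirc(H, L) pattern (every pair connected once).
    Weighted: within-pair links (AVBL-AVBR, RIBL-RIBR) at weight 1 and
    the four cross links at weight 2, so the symmetry is that of a square
    (8 automorphisms out of 24 permutations).
    """
    labels = ("AVBL", "AVBR", "RIBL", "RIBR")
    cross = 2 if weighted else 1
    A = np.array([
        [0, 1, cross, cross],
        [1, 0, cross, cross],
        [cross, cross, 0, 1],
        [cross, cross, 1, 0],
    ])
    return Circuit(labels, A, directed=False, link_type="gap")


#: hub weights of the motor D_1 sector, constant on the involution's orbits
_D1_HUB_WEIGHTS = {
    "VB2": 3, "DB1": 3,
    "DB3": 2, "VB4": 2,
    "DB2": 1, "VB5": 1,
    "VB1": 4, "VB6": 4,
}

#: symmetric cross-block coupling of the motor blocks (weight 2 so the
#: cross links are distinguished from the weight-1 internal 4-cycles)
_D1_COUPLING = (
    (0, 0, 0, 2),
    (0, 0, 2, 0),
    (0, 2, 0, 0),
    (2, 0, 0, 0),
)


def forward_gap_spec() -> PlantSpec:
    """Plant spec of the 21-node ideal forward gap-junction fixture."""
    return PlantSpec(
        hubs=("AVBL", "AVBR"),
        hub_edges=(("AVBL", "AVBR", 1),),
        hub_pairs=(("AVBL", "AVBR"),),
        sectors=(
            SectorSpec("C_2", ("RIBL", "RIBR"), hub_weight=1,
                       first_row=(0, 1)),
            SectorSpec("S_5", ("DB5", "DB6", "DB7", "VB10", "VB11"),
                       hub_weight=1),
            SectorSpec("D_1",
                       ("VB2", "DB3", "DB2", "VB1",
                        "DB1", "VB4", "VB5", "VB6"),
                       hub_weight=_D1_HUB_WEIGHTS,
                       first_row=(0, 1, 0, 1),
                       blocks=(("VB2", "DB3", "DB2", "VB1"),
                               ("DB1", "VB4", "VB5", "VB6")),
                       coupling=_D1_COUPLING),
            SectorSpec("C_2", ("VB3", "VB7"), hub_weight=6),
            SectorSpec("C_2", ("VB8", "VB9"), hub_weight=7),
        ),
        link_type="gap",
    )


def forward_gap_fixture() -> tuple[Circuit, PlantedTruth]:
    """Ideal forward gap-junction circuit: command C_2 x C_2 driving a
    motor sector S_5 x D_1 x C_2 x C_2 (symmetry group order 1920)."""
    return plant_circuit(forward_gap_spec())


def backward_aib_rim_fixture() -> tuple[Circuit, PlantedTruth]:
    """The 4-neuron AIB/RIM backward block: bcirc(circ(0,0), circ(1,0)),
    i.e. two parallel gap junctions carrying a D_1 involution."""
    spec = PlantSpec(
        sectors=(
            SectorSpec("D_1", ("AIBL", "AIBR", "RIML", "RIMR"),
                       hub_weight=0,
                       blocks=(("AIBL", "AIBR"), ("RIML", "RIMR")),
                       coupling=((1, 0), (0, 1))),
        ),
        link_type="gap",
    )
    return plant_circuit(spec)
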