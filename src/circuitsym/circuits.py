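"""Circuit data model, TSV I/O and sub-circuit extraction.

A :class:`Circuit` is a labeled, weighted adjacency matrix.  Gap-junction
circuits are undirected (symmetric matrix); chemical-synapse circuits are
directed.  Weights are nonnegative integers counting the number of
connections between two neurons; the diagonal is zero (self-synapses are
out of scope).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Circuit",
    "CircuitError",
    "load_circuit",
    "write_circuit",
    "total_weight",
    "subcircuit",
]


class CircuitError(ValueError):
    """Raised for malformed circuit files or invalid circuit operations."""


@dataclass(frozen=True)
class Circuit:
    """Weighted circuit on named neurons.

    Parameters
    ----------
    labels:
        Unique neuron names, in a fixed order that defines matrix indexing.
    weights:
        Square nonnegative-integer matrix ``A`` with ``A[i, j]`` the number
        of connections from neuron ``i`` to neuron ``j``.
    directed:
        ``False`` for gap-junction (electrical) circuits, whose matrix must
        be symmetric; ``True`` for chemical-synapse circuits.
    link_type:
        One of ``"gap"``, ``"chemical"``, ``"generic"``.
    """

    labels: tuple[str, ...]
    weights: np.ndarray = field(repr=False)
    directed: bool = False
    link_type: str = "generic"

    def __post_init__(self) -> None:
        A = np.asarray(self.weights)
        if A.ndim != 2 or A.shape[0] != A.shape[1]:
            raise CircuitError(f"weights must be square, got shape {A.shape}")
        if len(self.labels) != A.shape[0]:
            raise CircuitError(
                f"{len(self.labels)} labels for a {A.shape[0]}x{A.shape[1]} matrix"
            )
        if len(set(self.labels)) != len(self.labels):
            raise CircuitError("node labels must be unique")
        if not np.issubdtype(A.dtype, np.integer):
            if not np.allclose(A, np.round(A)):
                raise CircuitError("weights must be integers")
            A = np.round(A).astype(np.int64)
        else:
            A = A.astype(np.int64)
        if (A < 0).any():
            raise CircuitError("weights must be nonnegative")
        if np.diagonal(A).any():
            raise CircuitError("self-connections (diagonal entries) are not allowed")
        if not self.directed and not np.array_equal(A, A.T):
            raise CircuitError("undirected circuit requires a symmetric matrix")
        if self.link_type not in ("gap", "chemical", "generic"):
            raise CircuitError(f"unknown link type {self.link_type!r}")
        A.setflags(write=False)
        object.__setattr__(self, "labels", tuple(self.labels))
        object.__setattr__(self, "weights", A)

    # -- basic queries ---------------------------------------------------

    @property
    def n(self) -> int:
        return len(self.labels)

    def index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise CircuitError(f"unknown label {label!r}") from None

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Circuit):
            return NotImplemented
        return (
            self.labels == other.labels
            and self.directed == other.directed
            and self.link_type == other.link_type
            and np.array_equal(self.weights, other.weights)
        )

    def __hash__(self) -> int:
        return hash((self.labels, self.directed, self.link_type,
                     self.weights.tobytes()))

    # -- derived quantities ----------------------------------------------

    @property
    def total_weight(self) -> int:
        """Total number of links including weights (M).

        Undirected circuits count each unordered pair once (half the full
        matrix sum); directed circuits count every ordered pair.
        """
        s = int(self.weights.sum())
        return s // 2 if not self.directed else s

    def degree_sequence(self, weighted: bool = True) -> dict[str, int]:
        """Per-node degree (weighted strength by default).

        For directed circuits the value is the (out, in) pair encoded as a
        tuple; for undirected circuits a single integer.
        """
        A = self.weights if weighted else (self.weights > 0).astype(np.int64)
        if self.directed:
            return {
                lab: (int(A[i].sum()), int(A[:, i].sum()))
                for i, lab in enumerate(self.labels)
            }
        return {lab: int(A[i].sum()) for i, lab in enumerate(self.labels)}

    def edges(self) -> list[tuple[str, str, int]]:
        """Weighted link list; undirected links reported once (i < j)."""
        out = []
        A = self.weights
        for i in range(self.n):
            js = range(self.n) if self.directed else range(i + 1, self.n)
            for j in js:
                if A[i, j]:
                    out.append((self.labels[i], self.labels[j], int(A[i, j])))
        return out

    def to_networkx(self):
        import networkx as nx

        G = nx.DiGraph() if self.directed else nx.Graph()
        G.add_nodes_from(self.labels)
        for a, b, w in self.edges():
            G.add_edge(a, b, weight=w)
        return G


def total_weight(c: Circuit) -> int:
    """Total number of network links including weights (M)."""
    return c.total_weight


def subcircuit(c: Circuit, labels: Sequence[str]) -> Circuit:
    """Induced sub-circuit on ``labels``, in the given order."""
    idx = [c.index(lab) for lab in labels]
    A = c.weights[np.ix_(idx, idx)]
    return Circuit(tuple(labels), A.copy(), directed=c.directed,
                   link_type=c.link_type)


_HEADER = ("source", "target", "weight", "type")


def load_circuit(path, directed: bool | None = None) -> Circuit:
    """Load a circuit from a TSV edge list.

    The file must have a header ``source  target  weight  type`` with one
    link per row.  ``type`` is ``gap`` (undirected) or ``chemical``
    (directed); when ``directed`` is given explicitly it overrides the
    inference from the type column.  Duplicate declarations of the same
    (ordered) pair are summed.  For undirected circuits a pair declared in
    both orientations must carry equal accumulated weight (a mirrored
    declaration); unequal weights are rejected as ambiguous.
    """
    rows: list[tuple[str, str, int, str]] = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise CircuitError(f"{path}: empty file") from None
        if [h.strip().lower() for h in header[:4]] != list(_HEADER):
            raise CircuitError(
                f"{path}: expected header {'/'.join(_HEADER)}, got {header!r}"
            )
        for lineno, row in enumerate(reader, start=2):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) < 4:
                raise CircuitError(f"{path}:{lineno}: malformed row {row!r}")
            src, tgt, w_raw, ltype = (f.strip() for f in row[:4])
            if not src or not tgt:
                raise CircuitError(f"{path}:{lineno}: empty node label")
            try:
                w = int(w_raw)
            except ValueError:
                raise CircuitError(
                    f"{path}:{lineno}: weight {w_raw!r} is not an integer"
                ) from None
            if w <= 0:
                raise CircuitError(f"{path}:{lineno}: weight must be positive")
            if src == tgt:
                raise CircuitError(f"{path}:{lineno}: self-link {src!r}")
            rows.append((src, tgt, w, ltype))

    if not rows:
        raise CircuitError(f"{path}: no links (empty circuit)")

    types = {r[3] for r in rows}
    if len(types) > 1:
        raise CircuitError(
            f"{path}: mixed link types {sorted(types)}; one circuit carries one type"
        )
    link_type = types.pop()
    if link_type not in ("gap", "chemical", "generic"):
        raise CircuitError(f"{path}: unknown link type {link_type!r}")
    if directed is None:
        directed = link_type == "chemical"

    labels: list[str] = []
    seen: dict[str, int] = {}
    for src, tgt, _, _ in rows:
        for lab in (src, tgt):
            if lab not in seen:
                seen[lab] = len(labels)
                labels.append(lab)
    n = len(labels)
    A = np.zeros((n, n), dtype=np.int64)
    for src, tgt, w, _ in rows:
        A[seen[src], seen[tgt]] += w

    if not directed:
        both = (A > 0) & (A.T > 0)
        if both.any():
            if not np.array_equal(A[both], A.T[both]):
                i, j = np.argwhere(both & (A != A.T))[0]
                raise CircuitError(
                    f"{path}: undirected pair ({labels[i]}, {labels[j]}) declared "
                    f"in both orientations with unequal weights "
                    f"{A[i, j]} vs {A[j, i]}"
                )
            # mirrored declaration: keep the single shared value
            sym = np.where(both, A, A + A.T)
        else:
            sym = A + A.T
        np.fill_diagonal(sym, 0)
        A = sym

    return Circuit(tuple(labels), A, directed=directed, link_type=link_type)


def write_circuit(c: Circuit, path) -> None:
    """Write the circuit in the same TSV dialect read by :func:`load_circuit`."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(_HEADER)
        for a, b, w in c.edges():
            writer.writerow([a, b, w, c.link_type])


def write_graphml(c: Circuit, path) -> None:
    """GraphML export for visualization tools."""
    import networkx as nx

    nx.write_graphml(c.to_networkx(), path)
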