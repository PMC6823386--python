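"""Circulant and block-circulant structure detection and eigen-analysis.

A circulant matrix ``circ(c_1, ..., c_l)`` has every row equal to the
previous row shifted one position to the right (wrapped around); it is
fully determined by its first row and its eigenvectors are the discrete
Fourier modes.  Three small circulants recur in the locomotion circuits
and act as linear signal-processing filters:

* ``H = circ(0, 1)`` — high-pass (blocks the low-frequency content),
* ``L = circ(1, 1)`` — low-pass (eliminates the high frequencies),
* ``F = circ(0, 1, 0, 1)`` — a subsampling/oscillation kernel.

Block-circulant matrices ``bcirc(A_1, ..., A_m)`` repeat the same pattern
with matrix entries, nesting circulants hierarchically.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "CirculantProfile",
    "BlockCirculantProfile",
    "EigenDecomposition",
    "circ",
    "bcirc",
    "detect_circulant",
    "nearest_pseudocirculant",
    "detect_block_circulant",
    "circulant_eigen",
    "classify_filter",
    "HIGH_PASS",
    "LOW_PASS",
    "FOUR_CYCLE",
]

HIGH_PASS = (0, 1)
LOW_PASS = (1, 1)
FOUR_CYCLE = (0, 1, 0, 1)


def circ(*first_row: float) -> np.ndarray:
    """Build the circulant matrix with the given first row."""
    row = np.asarray(first_row)
    l = len(row)
    return np.array([np.roll(row, k) for k in range(l)])


def bcirc(*blocks: np.ndarray) -> np.ndarray:
    """Assemble a block-circulant matrix from equally sized square blocks."""
    mats = [np.asarray(b) for b in blocks]
    n = mats[0].shape[0]
    if any(b.shape != (n, n) for b in mats):
        raise ValueError("all blocks must be square and equally sized")
    m = len(mats)
    rows = []
    for r in range(m):
        rows.append(np.hstack([mats[(c - r) % m] for c in range(m)]))
    return np.vstack(rows)


@dataclass(frozen=True)
class CirculantProfile:
    first_row: tuple[float, ...]
    ordering: tuple[str, ...]
    deviation: float
    heuristic: bool = False

    @property
    def length(self) -> int:
        return len(self.first_row)

    @property
    def filter_class(self) -> str:
        return classify_filter(self)

    def matrix(self) -> np.ndarray:
        return circ(*self.first_row)


@dataclass(frozen=True)
class BlockCirculantProfile:
    block_matrices: tuple[np.ndarray, ...] = field(repr=False)
    block_order: tuple[tuple[str, ...], ...]

    @property
    def m(self) -> int:
        return len(self.block_matrices)

    @property
    def n(self) -> int:
        return self.block_matrices[0].shape[0]

    def component_profiles(self) -> list["CirculantProfile | None"]:
        labels = [tuple(f"b{i}" for i in range(self.n))] * self.m
        return [detect_circulant(B, labels[k])
                for k, B in enumerate(self.block_matrices)]

    def matrix(self) -> np.ndarray:
        return bcirc(*self.block_matrices)


@dataclass(frozen=True)
class EigenDecomposition:
    eigenvalues: tuple[complex, ...]
    eigenvectors: np.ndarray = field(repr=False)  # columns, unit norm


def _is_circulant(A: np.ndarray) -> bool:
    l = A.shape[0]
    first = A[0]
    return all(np.array_equal(A[r], np.roll(first, r)) for r in range(1, l))


def _matrix_weight(A: np.ndarray, symmetric: bool) -> float:
    s = float(np.abs(A).sum())
    return s / 2 if symmetric else s


def detect_circulant(sub: np.ndarray, block: Sequence[str],
                     max_exhaustive: int = 8) -> CirculantProfile | None:
    """Search for a node ordering that makes the matrix exactly circulant.

    For blocks of size <= ``max_exhaustive`` the first label is fixed and
    all orderings of the rest are tried.  For larger blocks, a regular
    l-cycle is searched in the block's automorphism group and used to
    generate the ordering.
    """
    A = np.asarray(sub)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("detect_circulant needs a square matrix")
    l = A.shape[0]
    if l != len(block):
        raise ValueError("label count does not match matrix size")
    if l == 1:
        return CirculantProfile((float(A[0, 0]),), tuple(block), 0.0)

    if l <= max_exhaustive:
        for tail in itertools.permutations(range(1, l)):
            order = (0,) + tail
            P = A[np.ix_(order, order)]
            if _is_circulant(P):
                return CirculantProfile(
                    tuple(float(x) for x in P[0]),
                    tuple(block[i] for i in order),
                    0.0,
                )
        return None

    # large blocks: look for an l-cycle acting regularly
    order = _regular_cycle_order(A)
    if order is None:
        return None
    P = A[np.ix_(order, order)]
    if _is_circulant(P):
        return CirculantProfile(
            tuple(float(x) for x in P[0]),
            tuple(block[i] for i in order),
            0.0,
            heuristic=True,
        )
    return None


def _regular_cycle_order(A: np.ndarray) -> tuple[int, ...] | None:
    from .circuits import Circuit
    from .symmetry import automorphism_group

    l = A.shape[0]
    directed = not np.array_equal(A, A.T)
    # the automorphism search needs a zero diagonal; constant diagonals can
    # be stripped without changing the symmetry
    B = A.copy()
    if len(set(np.diagonal(B).tolist())) > 1:
        return None
    np.fill_diagonal(B, 0)
    c = Circuit(tuple(f"n{i}" for i in range(l)), B, directed=directed)
    try:
        grp = automorphism_group(c)
    except Exception:
        return None
    for p in grp.perms():
        cyc = p.cycles()
        if len(cyc) == 1 and len(cyc[0]) == l:
            order = [0]
            while len(order) < l:
                order.append(p.images[order[-1]])
            return tuple(order)
    return None


def nearest_pseudocirculant(sub: np.ndarray, block: Sequence[str] | None = None,
                            max_exhaustive: int = 10) -> CirculantProfile:
    """Best circulant approximation over orderings and first rows.

    Minimizes the fraction of differing link units: the L1 difference to
    the fitted circulant divided by max(weight of the matrix, weight of
    the fit).  Ties break toward the lexicographically smallest first row,
    then
    ordering.  Sizes above ``max_exhaustive`` use the regular-cycle
    heuristic and are flagged.
    """
    A = np.asarray(sub, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("nearest_pseudocirculant needs a square matrix")
    l = A.shape[0]
    if block is None:
        block = tuple(f"n{i}" for i in range(l))
    symmetric = bool(np.array_equal(A, A.T))

    def fit(order: tuple[int, ...]) -> tuple[float, tuple[float, ...]]:
        P = A[np.ix_(order, order)]
        row = []
        diff = 0.0
        for d in range(l):
            vals = np.array([P[i, (i + d) % l] for i in range(l)])
            c_d = float(np.median(vals))
            if float(c_d).is_integer() is False:
                # integer weights: compare floor/ceil around the median
                lo, hi = np.floor(c_d), np.ceil(c_d)
                c_d = lo if np.abs(vals - lo).sum() <= np.abs(vals - hi).sum() else hi
            diff += float(np.abs(vals - c_d).sum())
            row.append(float(c_d))
        if symmetric:
            diff /= 2
        return diff, tuple(row)

    best: tuple[float, tuple[float, ...], tuple[int, ...]] | None = None
    heuristic = False
    if l <= max_exhaustive:
        orders = [(0,) + t for t in itertools.permutations(range(1, l))] \
            if l > 1 else [(0,)]
    else:
        heuristic = True
        ro = _regular_cycle_order((A > 0).astype(int))
        orders = [ro if ro is not None else tuple(range(l))]
    wA = _matrix_weight(A, symmetric)
    for order in orders:
        diff, row = fit(order)
        denom = max(wA, _matrix_weight(circ(*row), symmetric), 1.0)
        key = (diff / denom, row, tuple(block[i] for i in order))
        if best is None or key < best[:2] + (tuple(block[i] for i in best[2]),):
            best = (diff / denom, row, order)

    dev, row, order = best
    return CirculantProfile(row, tuple(block[i] for i in order),
                            deviation=dev, heuristic=heuristic)


def detect_block_circulant(A: np.ndarray, labels: Sequence[str],
                           blocks: Sequence[Sequence[str]],
                           max_exhaustive_blocks: int = 4
                           ) -> BlockCirculantProfile | None:
    """Check the block-shift property for the given block partition.

    ``blocks`` are equally sized label sequences partitioning a subset of
    ``labels``; their internal orders are respected, and block orderings
    are tried exhaustively for up to ``max_exhaustive_blocks`` blocks.
    """
    sizes = {len(b) for b in blocks}
    if len(sizes) != 1:
        raise ValueError("blocks must have equal sizes")
    n = sizes.pop()
    m = len(blocks)
    pos = {lab: i for i, lab in enumerate(labels)}
    idx = [[pos[l] for l in b] for b in blocks]
    A = np.asarray(A)

    def block_mat(r: int, s: int, order: Sequence[int]) -> np.ndarray:
        return A[np.ix_(idx[order[r]], idx[order[s]])]

    orders = itertools.permutations(range(m)) if m <= max_exhaustive_blocks \
        else [tuple(range(m))]
    for order in orders:
        comp: list[np.ndarray | None] = [None] * m
        ok = True
        for r in range(m):
            for s in range(m):
                d = (s - r) % m
                B = block_mat(r, s, order)
                if comp[d] is None:
                    comp[d] = B
                elif not np.array_equal(comp[d], B):
                    ok = False
                    break
            if not ok:
                break
        if ok:
            return BlockCirculantProfile(
                tuple(np.asarray(b) for b in comp),
                tuple(tuple(blocks[k]) for k in order),
            )
    return None


def circulant_eigen(profile: CirculantProfile) -> EigenDecomposition:
    """Eigen-decomposition of an exact circulant via the DFT of its first row.

    Symmetric first rows (``c_j = c_{l-j}``) yield real eigenvalues and a
    real orthonormal Fourier basis (cosine/sine modes); the generic case
    returns the complex Fourier modes.  Eigenvector signs are fixed by
    making the first nonzero component positive.
    """
    if profile.deviation != 0:
        raise ValueError("eigen-analysis requires an exact circulant "
                         f"(deviation {profile.deviation})")
    c = np.asarray(profile.first_row, dtype=float)
    l = len(c)
    lam = np.fft.fft(c)
    symmetric = np.allclose(c, np.concatenate(([c[0]], c[1:][::-1])))
    if not symmetric:
        vecs = np.array([
            [np.exp(2j * np.pi * j * k / l) / np.sqrt(l) for k in range(l)]
            for j in range(l)
        ])
        vecs = _fix_signs(vecs)
        return EigenDecomposition(tuple(lam), vecs)

    lam = lam.real
    vals: list[float] = []
    cols: list[np.ndarray] = []
    j = np.arange(l)
    for k in range(l // 2 + 1):
        if k == 0:
            vals.append(float(lam[0]))
            cols.append(np.ones(l) / np.sqrt(l))
        elif 2 * k == l:
            vals.append(float(lam[k]))
            cols.append(((-1.0) ** j) / np.sqrt(l))
        else:
            cosv = np.cos(2 * np.pi * k * j / l)
            sinv = np.sin(2 * np.pi * k * j / l)
            vals.extend([float(lam[k]), float(lam[k])])
            cols.append(cosv / np.linalg.norm(cosv))
            cols.append(sinv / np.linalg.norm(sinv))
    vecs = _fix_signs(np.column_stack(cols))
    return EigenDecomposition(tuple(vals), vecs)


def _fix_signs(vecs: np.ndarray) -> np.ndarray:
    out = vecs.copy()
    for k in range(out.shape[1]):
        col = out[:, k]
        nz = np.flatnonzero(np.abs(col) > 1e-12)
        if nz.size and (col[nz[0]].real < 0
                        or (col[nz[0]].real == 0 and col[nz[0]].imag < 0)):
            out[:, k] = -col
    return out


def classify_filter(profile: CirculantProfile) -> str:
    """H / L / F / zero catalogue; anything else reports ``other`` (its
    frequency response is the DFT magnitude of the first row)."""
    row = tuple(int(x) if float(x).is_integer() else x
                for x in profile.first_row)
    if all(x == 0 for x in row):
        return "zero"
    if row == HIGH_PASS:
        return "H"
    if row == LOW_PASS:
        return "L"
    if row == FOUR_CYCLE:
        return "F"
    return "other"


def frequency_response(profile: CirculantProfile) -> np.ndarray:
    return np.abs(np.fft.fft(np.asarray(profile.first_row, dtype=float)))
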