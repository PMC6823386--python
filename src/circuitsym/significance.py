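"""Degree-preserving null model and p-values for pseudosymmetry subgroups.

The null ensemble randomizes the circuit by repeated double-edge swaps on
link units, preserving every node's weighted degree (strength) exactly and
the total weight M exactly.  The p-value of an observed subgroup is the
probability that a randomized circuit contains a subgroup of the same type
and sector size with uncertainty constant eps* <= the observed eps.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np

from .circuits import Circuit, CircuitError
from .symmetry import Permutation, epsilon, swap_cost_matrix

__all__ = ["NullResult", "randomize_degree_preserving", "subgroup_pvalue",
           "best_null_epsilon"]


@dataclass(frozen=True)
class NullResult:
    subgroup_type: str
    sector_size: int
    observed_eps: float
    samples: int
    null_eps: tuple[float, ...]
    p: float
    p_guarded: float
    seed: int


def _unit_links(c: Circuit) -> list[tuple[int, int]]:
    links = []
    A = c.weights
    for i in range(c.n):
        js = range(c.n) if c.directed else range(i + 1, c.n)
        for j in js:
            links.extend([(i, j)] * int(A[i, j]))
    return links


def randomize_degree_preserving(c: Circuit, seed: int,
                                n_swaps: int | None = None,
                                degree_mode: str = "weighted") -> Circuit:
    """Rewire by double-edge swaps, preserving the degree sequence.

    ``degree_mode="weighted"`` (default) swaps individual link units, so
    the weighted degree (strength) sequence and M are preserved exactly.
    ``"unweighted"`` swaps whole weighted links, preserving the unweighted
    degree sequence instead (weights travel with their link).  Defaults to
    10 swap attempts per link; deterministic for a given seed.
    """
    rng = np.random.default_rng(seed)
    if degree_mode == "weighted":
        links = _unit_links(c)
    elif degree_mode == "unweighted":
        links = [(c.index(a), c.index(b)) for a, b, _ in c.edges()]
        weights = {k: w for k, (_, _, w) in enumerate(c.edges())}
    else:
        raise ValueError(f"unknown degree mode {degree_mode!r}")
    if len(links) < 2:
        raise CircuitError("circuit too small to swap (needs >= 2 links)")
    if n_swaps is None:
        n_swaps = 10 * len(links)

    # unweighted mode must not merge two links into one (that would drop
    # a node's link count); unit-link mode allows weight merging
    forbid_merge = degree_mode == "unweighted"

    def present(i: int, j: int) -> bool:
        return (i, j) in link_set or (not c.directed and (j, i) in link_set)

    link_set = set(links) if forbid_merge else set()
    successes = 0
    for _ in range(n_swaps):
        k1, k2 = rng.integers(0, len(links), size=2)
        if k1 == k2:
            continue
        a, b = links[k1]
        cc, d = links[k2]
        if not c.directed and rng.integers(0, 2):
            cc, d = d, cc
        if len({a, b, cc, d}) < 4:
            continue
        if forbid_merge and (present(a, d) or present(cc, b)):
            continue
        if forbid_merge:
            link_set -= {links[k1], links[k2]}
            link_set |= {(a, d), (cc, b)}
        links[k1] = (a, d)
        links[k2] = (cc, b)
        successes += 1
    if successes == 0:
        warnings.warn("no valid double-edge swap found; circuit returned "
                      "unchanged (e.g. a star has no swappable pairs)")

    A = np.zeros((c.n, c.n), dtype=np.int64)
    if degree_mode == "weighted":
        for i, j in links:
            A[i, j] += 1
            if not c.directed:
                A[j, i] += 1
    else:
        for k, (i, j) in enumerate(links):
            A[i, j] += weights[k]
            if not c.directed:
                A[j, i] += weights[k]
    return Circuit(c.labels, A, directed=c.directed, link_type=c.link_type)


# ---------------------------------------------------------------------------
# best template eps in a (null) circuit


def best_null_epsilon(c: Circuit, subgroup_type: str, sector_size: int,
                      denominator: str = "circuit") -> float:
    """Minimum eps of a subgroup of the given type/size anywhere in ``c``.

    C_2 scans all transpositions exhaustively.  S_k and the single
    involution (D_1) use greedy growth/matching on the pairwise swap-cost
    matrix; C_k (k <= 6) tries all cyclic orderings of the greedily chosen
    sector.  The greedy stages make the search a slight over-estimate of
    the true minimum for k > 2, which is conservative for p-values.
    """
    cost = swap_cost_matrix(c, denominator)
    n = c.n
    if sector_size > n:
        raise CircuitError(f"sector size {sector_size} exceeds circuit size {n}")
    base = subgroup_type.split("_")[0]

    if subgroup_type == "C_2" or (base == "S" and sector_size == 2):
        iu = np.triu_indices(n, 1)
        return float(cost[iu].min())

    if base == "S":
        best = np.inf
        order = np.argsort(cost[np.triu_indices(n, 1)])
        pairs = list(itertools.combinations(range(n), 2))
        for kk in order[:max(10, n)]:
            i, j = pairs[kk]
            members = [i, j]
            cur = cost[i, j]
            while len(members) < sector_size:
                cand_best, cand_val = None, np.inf
                for m in range(n):
                    if m in members:
                        continue
                    val = max(cost[m, mm] for mm in members)
                    if val < cand_val:
                        cand_best, cand_val = m, val
                members.append(cand_best)
                cur = max(cur, cand_val)
            best = min(best, cur)
        return float(best)

    if subgroup_type == "D_1":
        if sector_size % 2:
            raise CircuitError("D_1 sector size must be even")
        m = sector_size // 2
        tri = sorted(
            ((cost[i, j], i, j) for i, j in itertools.combinations(range(n), 2))
        )
        taken: set[int] = set()
        pairs = []
        for _, i, j in tri:
            if i in taken or j in taken:
                continue
            pairs.append((c.labels[i], c.labels[j]))
            taken |= {i, j}
            if len(pairs) == m:
                break
        if len(pairs) < m:
            raise CircuitError("not enough nodes for the involution template")
        inv = Permutation.from_cycles(c.labels, pairs)
        return epsilon(c, inv, denominator).eps

    if base == "C":
        k = sector_size
        if k > 6:
            raise CircuitError("cyclic template search limited to k <= 6")
        # greedy sector, then exhaustive cyclic orderings
        best = np.inf
        iu = list(itertools.combinations(range(n), 2))
        start = min(iu, key=lambda ij: cost[ij])
        members = list(start)
        while len(members) < k:
            cand = min((m for m in range(n) if m not in members),
                       key=lambda m: max(cost[m, mm] for mm in members))
            members.append(cand)
        labs = [c.labels[i] for i in members]
        for tail in itertools.permutations(labs[1:]):
            rot = Permutation.from_cycles(c.labels, [(labs[0],) + tail])
            best = min(best, epsilon(c, rot, denominator).eps)
        return float(best)

    raise CircuitError(f"unsupported subgroup template {subgroup_type!r}")


def subgroup_pvalue(c: Circuit, subgroup_type: str, sector_size: int,
                    observed_eps: float, R: int = 1000, seed: int = 0,
                    denominator: str = "circuit",
                    degree_mode: str = "weighted") -> NullResult:
    """p-value of an observed pseudosymmetry subgroup under the null.

    For each of ``R`` degree-preserving randomizations, the best
    (minimum-eps) subgroup of the same type and sector size is searched
    anywhere in the circuit; ``p`` is the fraction with eps* <= observed.
    The guarded estimate ``(1 + count) / (R + 1)`` avoids reporting an
    exact zero.
    """
    if R < 1:
        raise CircuitError("R must be >= 1")
    rng = np.random.default_rng(seed)
    null_eps = []
    for _ in range(R):
        sub_seed = int(rng.integers(0, 2 ** 31 - 1))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            null_c = randomize_degree_preserving(c, sub_seed,
                                                 degree_mode=degree_mode)
        null_eps.append(best_null_epsilon(null_c, subgroup_type, sector_size,
                                          denominator))
    count = sum(e <= observed_eps for e in null_eps)
    return NullResult(subgroup_type, sector_size, observed_eps, R,
                      tuple(null_eps), count / R, (1 + count) / (R + 1),
                      seed)
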