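"""Baseline partitions and partition-agreement scoring.

Modularity communities and eigenvector-centrality strata are the standard
structure-detection tools the symmetry sectors are compared against; the
adjusted Rand index quantifies agreement between any two partitions of
the same node set.
"""

from __future__ import annotations

import networkx as nx
import numpy as np
from sklearn.metrics import adjusted_rand_score

from .circuits import Circuit, CircuitError

__all__ = ["modularity_partition", "eigenvector_centrality",
           "partition_agreement"]


def modularity_partition(c: Circuit, seed: int = 0,
                         restarts: int = 8) -> list[frozenset[str]]:
    """Louvain communities on the weighted graph, best of ``restarts``
    runs by modularity; deterministic for a given seed."""
    if c.n == 0:
        raise CircuitError("empty circuit")
    G = c.to_networkx()
    if c.directed:
        G = G.to_undirected()
    if not nx.is_connected(G):
        raise CircuitError("modularity baseline expects a connected circuit")
    rng = np.random.default_rng(seed)
    best, best_q = None, -np.inf
    for _ in range(restarts):
        sub_seed = int(rng.integers(0, 2 ** 31 - 1))
        parts = nx.community.louvain_communities(G, weight="weight",
                                                 seed=sub_seed)
        q = nx.community.modularity(G, parts, weight="weight")
        if q > best_q:
            best, best_q = parts, q
    return sorted((frozenset(p) for p in best), key=lambda s: sorted(s))


def eigenvector_centrality(c: Circuit, tol: float = 1e-10,
                           max_iter: int = 10_000) -> dict[str, float]:
    """Principal-eigenvector scores by power iteration, normalized to
    unit maximum."""
    G = c.to_networkx()
    if c.directed:
        G = G.to_undirected()
    if not nx.is_connected(G):
        raise CircuitError("eigenvector centrality expects a connected circuit")
    scores = nx.eigenvector_centrality(G, weight="weight", tol=tol,
                                       max_iter=max_iter)
    top = max(scores.values())
    return {lab: scores[lab] / top for lab in c.labels}


def partition_agreement(p1, p2) -> float:
    """Adjusted Rand index between two partitions of the same label set."""
    u1 = {lab for part in p1 for lab in part}
    u2 = {lab for part in p2 for lab in part}
    if u1 != u2:
        raise CircuitError("partitions cover different label universes")
    labs = sorted(u1)
    a1 = _assignment(p1, labs)
    a2 = _assignment(p2, labs)
    return float(adjusted_rand_score(a1, a2))


def _assignment(partition, labs) -> list[int]:
    where = {}
    for k, part in enumerate(sorted((sorted(p) for p in partition))):
        for lab in part:
            where[lab] = k
    return [where[lab] for lab in labs]
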