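"""Markov clustering of the similarity graph into gene families.

The MCL algorithm: add self-loops, column-normalise to a stochastic
matrix, then alternate expansion (matrix squaring) and inflation
(entrywise power + renormalisation) with pruning of tiny entries until
the matrix stops changing.  Clusters are read off from the attractors of
the limit matrix.  Clustering runs per connected component (expansion
never crosses components), which keeps the matrices small.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np

logger = logging.getLogger("paleoks")


@dataclass(frozen=True)
class GeneFamily:
    """A cluster of genes; families partition the node set."""

    family_id: str
    member_ids: frozenset[str]

    @property
    def n(self) -> int:
        return len(self.member_ids)


def _mcl_matrix(m: np.ndarray, inflation: float, max_iter: int,
                prune_threshold: float, tol: float = 1e-8) -> np.ndarray:
    """Iterate expansion/inflation on a column-stochastic matrix."""
    for it in range(max_iter):
        new = m @ m  # expansion
        np.power(new, inflation, out=new)  # inflation
        new[new < prune_threshold] = 0.0
        colsum = new.sum(axis=0, keepdims=True)
        colsum[colsum == 0] = 1.0
        new /= colsum
        delta = np.abs(new - m).max()
        m = new
        if delta < tol:
            return m
    logger.warning("MCL did not converge in %d iterations (delta tracking "
                   "stopped at the last matrix)", max_iter)
    return m


def _clusters_from_limit(m: np.ndarray, prune_threshold: float
                         ) -> list[list[int]]:
    """Attractor-based cluster readout with deterministic overlap handling.

    Attractors (positive diagonal) sharing any attracted node form one
    attractor system; a node attracted to several systems goes to the one
    holding the most of its probability mass, ties broken towards the
    lexicographically first cluster.
    """
    n = m.shape[0]
    attractors = [i for i in range(n) if m[i, i] > prune_threshold]
    if not attractors:  # numerically degenerate; fall back to singletons
        return [[i] for i in range(n)]
    # Union attractors whose rows overlap on any column.
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x: int, y: int) -> None:
        parent[find(x)] = find(y)

    for j in range(n):
        holders = [i for i in attractors if m[i, j] > 0]
        for a, b in zip(holders, holders[1:]):
            union(a, b)
    systems: dict[int, list[int]] = {}
    for i in attractors:
        systems.setdefault(find(i), []).append(i)
    sys_list = sorted(systems.values(), key=min)
    assigned: dict[int, int] = {}
    for j in range(n):
        masses = [sum(m[i, j] for i in sys_members) for sys_members in sys_list]
        best = int(np.argmax(masses))  # argmax takes the first maximum: lexicographic tie-break
        if masses[best] > 0:
            assigned[j] = best
    clusters: dict[int, list[int]] = {}
    for j, c in assigned.items():
        clusters.setdefault(c, []).append(j)
    out = [sorted(v) for v in clusters.values()]
    out.extend([j] for j in range(n) if j not in assigned)
    return sorted(out)


def mcl_cluster(graph: nx.Graph, inflation: float = 2.0, max_iter: int = 200,
                prune_threshold: float = 1e-5) -> list[GeneFamily]:
    """Partition a weighted similarity graph into gene families.

    Self-loop weight is each node's maximum incident edge weight (at
    least 1), the usual MCL regularisation.  Deterministic for a fixed
    node set: nodes are processed in sorted order and family ids are
    assigned by sorted first member.
    """
    if inflation <= 1:
        raise ValueError("inflation must be > 1")
    families: list[frozenset[str]] = []
    for comp in nx.connected_components(graph):
        nodes = sorted(comp)
        if len(nodes) == 1:
            families.append(frozenset(nodes))
            continue
        idx = {v: i for i, v in enumerate(nodes)}
        n = len(nodes)
        m = np.zeros((n, n))
        for u, v, data in graph.subgraph(comp).edges(data=True):
            w = float(data.get("weight", 1.0))
            if w < 0:
                raise ValueError("similarity graph weights must be non-negative")
            m[idx[u], idx[v]] = w
            m[idx[v], idx[u]] = w
        loops = np.maximum(m.max(axis=1), 1.0)
        m[np.diag_indices(n)] = loops
        m /= m.sum(axis=0, keepdims=True)
        limit = _mcl_matrix(m, inflation, max_iter, prune_threshold)
        for members in _clusters_from_limit(limit, prune_threshold):
            families.append(frozenset(nodes[i] for i in members))
    families.sort(key=min)
    return [
        GeneFamily(family_id=f"GF{k:05d}", member_ids=members)
        for k, members in enumerate(families)
    ]


def family_size_spectrum(families: list[GeneFamily]) -> dict[int, int]:
    """Counts of families by member count n; values sum to len(families)."""
    spectrum: dict[int, int] = {}
    for fam in families:
        spectrum[fam.n] = spectrum.get(fam.n, 0) + 1
    return dict(sorted(spectrum.items()))


def write_families_tsv(families: list[GeneFamily], path) -> None:
    """One row per member: family_id <tab> gene_id."""
    from .seqio import write_tsv

    rows = [
        {"family_id": fam.family_id, "gene_id": gid}
        for fam in families
        for gid in sorted(fam.member_ids)
    ]
    write_tsv(rows, path, columns=["family_id", "gene_id"])
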