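"""Markov Clustering (MCL) on weighted undirected graphs.

MCL simulates random walks on a graph: the column-stochastic transition
matrix is alternately *expanded* (raised to a matrix power, letting walks
spread) and *inflated* (raised to an entrywise power and renormalized,
boosting strong transitions and starving weak ones) until the matrix
converges to an idempotent attractor. Clusters are read off as the
connected components of the converged matrix's support.

Used here both for association-module construction (clustering SNPs whose
binary GWAS profiles are identical, a weight-1 clique graph) and for
signature clustering of genes in powerset space.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Hashable, Iterable, Sequence

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components

from .errors import ConfigError, DataError


@dataclass
class MclResult:
    """Partition produced by :func:`mcl_cluster`.

    ``clusters`` is a list of node sets, sorted by their smallest member so
    that output is deterministic; ``converged`` is False if the iteration
    hit ``max_iter`` first (the current partition is still returned).
    """

    clusters: list[frozenset]
    converged: bool
    n_iterations: int

    def as_partition(self) -> dict:
        """Map every node to its (0-based) cluster index."""
        assignment = {}
        for idx, cluster in enumerate(self.clusters):
            for node in cluster:
                assignment[node] = idx
        return assignment


def _column_normalize(matrix: sp.csc_matrix) -> sp.csc_matrix:
    sums = np.asarray(matrix.sum(axis=0)).ravel()
    sums[sums == 0.0] = 1.0
    scale = sp.diags(1.0 / sums)
    return (matrix @ scale).tocsc()


def mcl_cluster(
    edges: Iterable[tuple[Hashable, Hashable, float]],
    nodes: Sequence[Hashable] | None = None,
    inflation: float = 2.0,
    expansion: int = 2,
    self_loops: float = 1.0,
    prune_below: float = 1e-5,
    max_iter: int = 200,
    tol: float = 1e-8,
) -> MclResult:
    """Cluster an undirected weighted graph with MCL.

    ``edges`` are (node, node, weight) triples with weight > 0; ``nodes``
    may add isolated nodes (they come back as singleton clusters). Raises
    :class:`DataError` on non-positive weights and :class:`ConfigError` on
    bad parameters.
    """
    if inflation <= 1.0:
        raise ConfigError(f"inflation must exceed 1, got {inflation}")
    if expansion < 2:
        raise ConfigError(f"expansion must be >= 2, got {expansion}")

    edge_list = list(edges)
    node_set: set = set(nodes) if nodes is not None else set()
    for u, v, w in edge_list:
        if not (w > 0):
            raise DataError(f"edge ({u!r}, {v!r}) has non-positive weight {w}")
        node_set.add(u)
        node_set.add(v)
    if not node_set:
        raise DataError("graph has no nodes")

    labels = sorted(node_set, key=str)
    index = {node: i for i, node in enumerate(labels)}
    n = len(labels)

    rows, cols, data = [], [], []
    for u, v, w in edge_list:
        i, j = index[u], index[v]
        if i == j:
            continue
        rows += [i, j]
        cols += [j, i]
        data += [w, w]
    if self_loops > 0:
        rows += list(range(n))
        cols += list(range(n))
        data += [self_loops] * n
    matrix = sp.csc_matrix((data, (rows, cols)), shape=(n, n))
    matrix.sum_duplicates()
    transition = _column_normalize(matrix)

    converged = False
    iterations = 0
    for iterations in range(1, max_iter + 1):
        previous = transition
        # expansion: walk propagation
        expanded = transition
        for _ in range(expansion - 1):
            expanded = (expanded @ transition).tocsc()
        # inflation: entrywise power, then renormalize
        inflated = expanded.copy()
        inflated.data = np.power(inflated.data, inflation)
        inflated = _column_normalize(inflated)
        # prune vanishing entries to keep the matrix sparse
        inflated.data[inflated.data < prune_below] = 0.0
        inflated.eliminate_zeros()
        transition = _column_normalize(inflated)
        diff = (transition - previous).tocoo()
        change = float(np.max(np.abs(diff.data))) if diff.nnz else 0.0
        if change < tol:
            converged = True
            break

    support = transition + transition.T
    n_comp, assignment = connected_components(support, directed=False)
    groups: dict[int, set] = {}
    for node_idx, comp in enumerate(assignment):
        groups.setdefault(int(comp), set()).add(labels[node_idx])
    clusters = sorted(
        (frozenset(g) for g in groups.values()),
        key=lambda c: str(min(c, key=str)),
    )
    return MclResult(clusters=clusters, converged=converged, n_iterations=iterations)


def read_abc(path: str | Path) -> list[tuple[str, str, float]]:
    """Read an ABC edge list (``node node weight``, whitespace-separated)."""
    edges = []
    with open(path, "rt") as handle:
        for lineno, line in enumerate(handle, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) == 2:
                parts.append("1.0")
            if len(parts) != 3:
                raise DataError(f"{path}, line {lineno}: expected 2-3 fields")
            edges.append((parts[0], parts[1], float(parts[2])))
    return edges


def write_abc(
    edges: Iterable[tuple[Hashable, Hashable, float]], path: str | Path
) -> None:
    with open(path, "wt") as handle:
        for u, v, w in edges:
            handle.write(f"{u}\t{v}\t{w:g}\n")
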