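"""Tripartite network construction and capped shortest-path structure.

Nodes are laid out in fixed block order — diseases, then miRNAs, then
lncRNAs — and the adjacency matrix is 0/1 and symmetric with edges only
in the disease-miRNA and miRNA-lncRNA blocks (the graph is bipartite
between {diseases, lncRNAs} and {miRNAs}).  The shortest-path matrix
stores BFS distances capped at a radius r, which is identical to the
smallest k <= r with a nonzero (i, j) entry of the k-th adjacency-matrix
power; unreachable-within-r pairs are encoded as 0 and must be read as
"no relation", not "distance zero".
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path as _csgraph_shortest_path

from .errors import ConsistencyError, ParameterError
from .io_tables import DISEASE, LNCRNA, MIRNA, AssociationTable


@dataclass(frozen=True)
class TripartiteNetwork:
    """Node registry plus symmetric 0/1 adjacency matrix."""

    diseases: tuple
    mirnas: tuple
    lncrnas: tuple
    am: np.ndarray  # (N, N) int array, N = D + M + L

    def __post_init__(self):
        n = self.n_nodes
        if self.am.shape != (n, n):
            raise ConsistencyError(f"adjacency shape {self.am.shape} != ({n}, {n})")

    @property
    def n_diseases(self) -> int:
        return len(self.diseases)

    @property
    def n_mirnas(self) -> int:
        return len(self.mirnas)

    @property
    def n_lncrnas(self) -> int:
        return len(self.lncrnas)

    @property
    def n_nodes(self) -> int:
        return self.n_diseases + self.n_mirnas + self.n_lncrnas

    @property
    def node_names(self) -> tuple:
        return self.diseases + self.mirnas + self.lncrnas

    def block(self, node_index: int) -> str:
        """Layer label of a global node index."""
        if node_index < 0 or node_index >= self.n_nodes:
            raise IndexError(f"node index {node_index} out of range")
        if node_index < self.n_diseases:
            return DISEASE
        if node_index < self.n_diseases + self.n_mirnas:
            return MIRNA
        return LNCRNA

    def node_index(self, name: str) -> int:
        return self.node_names.index(name)


def build_network(
    dm: AssociationTable,
    ml: AssociationTable,
    diseases: Optional[Sequence[str]] = None,
    mirnas: Optional[Sequence[str]] = None,
    lncrnas: Optional[Sequence[str]] = None,
) -> TripartiteNetwork:
    """Assemble the tripartite network from two intersected tables.

    ``dm`` links diseases to miRNAs, ``ml`` miRNAs to lncRNAs, and both
    should already be restricted to the shared miRNA set.  Explicit
    registries may be passed to keep isolated entities in the matrix;
    by default registries are the sorted names observed in the tables.

    Raises
    ------
    ConsistencyError
        If a table references an entity outside an explicit registry.
    """
    if (dm.left_layer, dm.right_layer) != (DISEASE, MIRNA):
        raise ConsistencyError("dm table must be disease-miRNA")
    if (ml.left_layer, ml.right_layer) != (MIRNA, LNCRNA):
        raise ConsistencyError("ml table must be miRNA-lncRNA")

    d_names = tuple(diseases) if diseases is not None else tuple(sorted(dm.left_names))
    m_names = tuple(mirnas) if mirnas is not None else tuple(
        sorted(dm.right_names | ml.left_names)
    )
    l_names = tuple(lncrnas) if lncrnas is not None else tuple(sorted(ml.right_names))

    d_idx = {n: i for i, n in enumerate(d_names)}
    m_idx = {n: i for i, n in enumerate(m_names)}
    l_idx = {n: i for i, n in enumerate(l_names)}
    D, M = len(d_names), len(m_names)
    N = D + M + len(l_names)

    am = np.zeros((N, N), dtype=np.int8)
    for d, m in dm.edges:
        if d not in d_idx or m not in m_idx:
            raise ConsistencyError(f"dm edge ({d!r}, {m!r}) references an unregistered entity")
        i, j = d_idx[d], D + m_idx[m]
        am[i, j] = am[j, i] = 1
    for m, l in ml.edges:
        if m not in m_idx or l not in l_idx:
            raise ConsistencyError(f"ml edge ({m!r}, {l!r}) references an unregistered entity")
        i, j = D + m_idx[m], D + M + l_idx[l]
        am[i, j] = am[j, i] = 1
    return TripartiteNetwork(d_names, m_names, l_names, am)


@dataclass(frozen=True)
class ShortestPathMatrix:
    """BFS distances capped at ``radius``; 0 means farther than radius."""

    spm: np.ndarray  # (N, N) int array with entries in {0, 1, ..., radius}
    radius: int


def shortest_path_matrix(net: TripartiteNetwork, r: int) -> ShortestPathMatrix:
    """Capped unweighted shortest-path distances between all node pairs.

    Entries equal ``min{k in [1, r] : (AM^k)(i, j) != 0}``, or 0 when no
    such k exists; the diagonal is forced to 0.
    """
    if r < 1:
        raise ParameterError(f"radius must be >= 1, got {r}")
    dist = _csgraph_shortest_path(
        csr_matrix(net.am), method="D", directed=False, unweighted=True
    )
    spm = np.where((dist >= 1) & (dist <= r), dist, 0.0).astype(np.int64)
    np.fill_diagonal(spm, 0)
    return ShortestPathMatrix(spm=spm, radius=int(r))


@dataclass(frozen=True)
class DistanceCorrelationSet:
    """Nodes at capped distance 1..r from a centre node."""

    center: int
    members: frozenset  # of node indices


def distance_correlation_set(spm: ShortestPathMatrix, i: int) -> DistanceCorrelationSet:
    """All nodes j != i with 0 < SPM(i, j) <= r."""
    n = spm.spm.shape[0]
    if i < 0 or i >= n:
        raise IndexError(f"node index {i} out of range for {n} nodes")
    row = spm.spm[i]
    members = frozenset(int(j) for j in np.nonzero((row > 0) & (row <= spm.radius))[0] if j != i)
    return DistanceCorrelationSet(center=i, members=members)


def write_spm_tsv(spm: ShortestPathMatrix, names: Sequence[str], path) -> Path:
    """Debug dump of the capped distance matrix as long-form TSV."""
    path = Path(path)
    mat = spm.spm
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# radius={spm.radius}\n")
        for i, a in enumerate(names):
            for j, b in enumerate(names):
                if mat[i, j]:
                    fh.write(f"{a}\t{b}\t{mat[i, j]}\n")
    return path
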