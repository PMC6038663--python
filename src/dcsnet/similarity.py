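"""miRNA contribution values and shared-neighbour functional similarity.

Rare miRNAs carry more information than promiscuous ones, so each
miRNA m in a bipartite table contributes ``-log_b(deg(m) / |E|)``,
where ``|E|`` is the table's total edge count.  Two entities on the
other side of the table are similar when they share informative miRNA
neighbours: the pairwise score combines the summed contribution of the
shared neighbours, ``S``, with the union neighbourhood size
``Q = |N(i)| + |N(j)| - |N(i) ∩ N(j)|``.  The default convention maps
the pair to ``exp(S / Q)``; ``exp(S) / Q`` is available as an
alternative reading of the same formula.

Disease similarity conventionally uses base-10 logs, lncRNA similarity
base-2; both bases are configurable.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .errors import ConsistencyError, EmptyTableError, ParameterError
from .io_tables import MIRNA, AssociationTable

QUOTIENT_INSIDE_EXP = "quotient_inside_exp"
EXP_OVER_DENOMINATOR = "exp_over_denominator"
CONVENTIONS = (QUOTIENT_INSIDE_EXP, EXP_OVER_DENOMINATOR)


@dataclass(frozen=True)
class ContributionVector:
    """Per-miRNA information weights for one table."""

    values: dict  # miRNA name -> nonnegative float
    log_base: float
    total_edges: int

    def __getitem__(self, name: str) -> float:
        return self.values[name]


def _log(x: float, base: float) -> float:
    # special-case the common bases for full double precision
    if base == 10:
        return math.log10(x)
    if base == 2:
        return math.log2(x)
    return math.log(x) / math.log(base)


def mirna_contribution(table: AssociationTable, log_base: float = 10) -> ContributionVector:
    """Compute ``-log_b(deg(m)/|E|)`` for every miRNA in the table."""
    if log_base <= 0 or log_base == 1:
        raise ParameterError(f"invalid log base {log_base}")
    if MIRNA not in (table.left_layer, table.right_layer):
        raise ConsistencyError("table has no miRNA layer")
    if table.n_edges == 0:
        raise EmptyTableError("cannot compute contributions on an empty table")
    total = table.n_edges
    deg = table.degrees(MIRNA)
    values = {m: -_log(d / total, log_base) for m, d in deg.items()}
    return ContributionVector(values=values, log_base=log_base, total_edges=total)


@dataclass(frozen=True)
class SimilarityMatrix:
    """Symmetric nonnegative similarity over one ordered entity list."""

    entity_names: tuple
    values: np.ndarray  # square, float64
    side: str  # "disease" | "lncRNA"

    def __post_init__(self):
        n = len(self.entity_names)
        if self.values.shape != (n, n):
            raise ConsistencyError(
                f"similarity matrix shape {self.values.shape} does not match {n} names"
            )

    def index(self, name: str) -> int:
        return self.entity_names.index(name)

    def subset(self, names: Sequence[str]) -> "SimilarityMatrix":
        """Reindex to an explicit name order (all names must be present)."""
        pos = {n: i for i, n in enumerate(self.entity_names)}
        missing = [n for n in names if n not in pos]
        if missing:
            raise ConsistencyError(f"names absent from similarity matrix: {missing[:5]}")
        idx = np.array([pos[n] for n in names], dtype=int)
        return SimilarityMatrix(tuple(names), self.values[np.ix_(idx, idx)], self.side)

    def to_tsv(self, path) -> Path:
        path = Path(path)
        with open(path, "w", encoding="utf-8") as fh:
            for i, a in enumerate(self.entity_names):
                for j, b in enumerate(self.entity_names):
                    fh.write(f"{a}\t{b}\t{self.values[i, j]!r}\n")
        return path


def identity_similarity(names: Sequence[str], side: str) -> SimilarityMatrix:
    """Identity matrix — the 'similarity off' arm of the ablation."""
    return SimilarityMatrix(tuple(names), np.eye(len(names)), side)


def functional_similarity(
    table: AssociationTable,
    contributions: ContributionVector,
    side: str,
    convention: str = QUOTIENT_INSIDE_EXP,
    entities: Optional[Sequence[str]] = None,
) -> SimilarityMatrix:
    """Shared-miRNA functional similarity between entities of ``side``.

    Parameters
    ----------
    table:
        Bipartite table with one miRNA layer and one ``side`` layer.
    contributions:
        Output of :func:`mirna_contribution` on the same (full) table.
    side:
        The non-miRNA layer whose entities are compared.
    convention:
        ``quotient_inside_exp`` (default): entry = exp(S/Q).
        ``exp_over_denominator``: entry = exp(S)/Q.
    entities:
        Optional explicit entity order.  May include names absent from
        the table (isolated entities, empty neighbourhood); pairs of two
        isolated entities have Q = 0 and are defined as 1 with a warning.

    The diagonal is computed by the same literal formula:
    ``exp(sum C(N(i)) / |N(i)|)`` under the default convention.
    """
    if convention not in CONVENTIONS:
        raise ParameterError(f"unknown convention {convention!r}")
    if side == MIRNA or side not in (table.left_layer, table.right_layer):
        raise ConsistencyError(f"table has no non-miRNA layer {side!r}")
    nbrs = table.neighborhoods(side)
    names = tuple(entities) if entities is not None else tuple(sorted(nbrs))
    mirnas = sorted(table.layer_names(MIRNA))
    missing = [m for m in mirnas if m not in contributions.values]
    if missing:
        raise ConsistencyError(f"miRNAs without contribution values: {missing[:5]}")
    m_idx = {m: k for k, m in enumerate(mirnas)}

    # incidence matrix B (entities x miRNAs) and weight vector c
    B = np.zeros((len(names), len(mirnas)))
    for i, name in enumerate(names):
        for m in nbrs.get(name, ()):
            B[i, m_idx[m]] = 1.0
    c = np.array([contributions[m] for m in mirnas])

    S = (B * c) @ B.T                # summed contribution of shared miRNAs
    inter = B @ B.T                  # |N(i) ∩ N(j)|
    deg = B.sum(axis=1)
    Q = deg[:, None] + deg[None, :] - inter

    if np.any(Q == 0):
        warnings.warn(
            "entity pair(s) with empty union neighbourhood; similarity defined as 1",
            stacklevel=2,
        )
    if convention == QUOTIENT_INSIDE_EXP:
        ratio = np.divide(S, Q, out=np.zeros_like(S), where=Q > 0)
        vals = np.exp(ratio)
    else:
        vals = np.divide(np.exp(S), Q, out=np.ones_like(S), where=Q > 0)
    # enforce exact symmetry against BLAS rounding asymmetries
    vals = (vals + vals.T) / 2.0
    return SimilarityMatrix(names, vals, side)
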