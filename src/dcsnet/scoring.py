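"""From capped distances to prediction scores.

Each ordered pair of nodes gets a distance correlation coefficient
``1 - k/(r+1)`` (0 when unreachable within r); the coefficient matrix
DCCM has diagonal ``r/(r+1)``.  Association degrees average the row and
column mass of the DCCM, ``AD(i,j) = (rowsum_i + colsum_j) / N``, and
the disease-rows x lncRNA-columns block C13 of AD is the raw prediction.
Optionally the final score matrix is ``FSD @ C13 @ FSL``, blending in
functional similarity on both sides.  Scores are unnormalised: only
their ranking matters, and rankings are invariant to positive rescaling
of either similarity matrix.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .errors import AlignmentError, ConsistencyError, ParameterError
from .hetnet import ShortestPathMatrix, TripartiteNetwork
from .similarity import SimilarityMatrix

AD = "AD"
C13 = "C13"
FAD = "FAD"


def distance_correlation_coefficient(spm_entry: int, r: int) -> float:
    """``1 - k/(r+1)`` for a capped distance k > 0, else 0."""
    if r < 1:
        raise ParameterError(f"radius must be >= 1, got {r}")
    if spm_entry < 0 or spm_entry > r:
        raise ParameterError(f"SPM entry {spm_entry} outside [0, {r}]")
    if spm_entry == 0:
        return 0.0
    return 1.0 - spm_entry / (r + 1)


@dataclass(frozen=True)
class DCCMatrix:
    """Distance correlation coefficients; diagonal is r/(r+1)."""

    values: np.ndarray
    radius: int


def build_dccm(spm: ShortestPathMatrix) -> DCCMatrix:
    r = spm.radius
    vals = np.where(spm.spm > 0, 1.0 - spm.spm / (r + 1), 0.0)
    np.fill_diagonal(vals, r / (r + 1))
    return DCCMatrix(values=vals, radius=r)


@dataclass(frozen=True)
class ScoreMatrix:
    """A labelled real matrix; ``kind`` records which pipeline stage."""

    kind: str
    row_names: tuple
    col_names: tuple
    values: np.ndarray

    def __post_init__(self):
        if self.values.shape != (len(self.row_names), len(self.col_names)):
            raise ConsistencyError(
                f"score matrix shape {self.values.shape} does not match labels"
            )

    def to_tsv(self, path) -> Path:
        """Long-form dump: row entity, column entity, score."""
        path = Path(path)
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(f"# kind={self.kind}\n")
            for i, a in enumerate(self.row_names):
                for j, b in enumerate(self.col_names):
                    fh.write(f"{a}\t{b}\t{self.values[i, j]!r}\n")
        return path


def association_degree(dccm: DCCMatrix, node_names: Optional[Sequence[str]] = None) -> ScoreMatrix:
    """``AD(i, j) = (sum_k DCCM(i, k) + sum_k DCCM(k, j)) / N``."""
    vals = dccm.values
    n = vals.shape[0]
    names = tuple(node_names) if node_names is not None else tuple(str(i) for i in range(n))
    if len(names) != n:
        raise ConsistencyError(f"{len(names)} node names for {n} nodes")
    rowsums = vals.sum(axis=1)
    colsums = vals.sum(axis=0)
    ad = (rowsums[:, None] + colsums[None, :]) / n
    return ScoreMatrix(kind=AD, row_names=names, col_names=names, values=ad)


def extract_c13(ad: ScoreMatrix, net: TripartiteNetwork) -> ScoreMatrix:
    """Disease-rows x lncRNA-columns block of the association degrees."""
    if ad.kind != AD:
        raise ConsistencyError(f"expected an AD matrix, got kind={ad.kind!r}")
    if ad.values.shape != (net.n_nodes, net.n_nodes):
        raise ConsistencyError(
            f"AD shape {ad.values.shape} does not match network with {net.n_nodes} nodes"
        )
    if net.n_diseases == 0 or net.n_lncrnas == 0:
        raise ConsistencyError("network has no diseases or no lncRNAs; C13 would be empty")
    D, M = net.n_diseases, net.n_mirnas
    block = ad.values[:D, D + M:]
    return ScoreMatrix(
        kind=C13, row_names=net.diseases, col_names=net.lncrnas, values=block.copy()
    )


def final_scores(
    c13: ScoreMatrix,
    fsd: Optional[SimilarityMatrix] = None,
    fsl: Optional[SimilarityMatrix] = None,
    use_similarity: bool = True,
) -> ScoreMatrix:
    """``FSD @ C13 @ FSL`` (default) or plain ``C13`` (ablation arm).

    Name orders must already agree; matrices are never silently
    reordered (use :meth:`SimilarityMatrix.subset` first).
    """
    if c13.kind != C13:
        raise ConsistencyError(f"expected a C13 matrix, got kind={c13.kind!r}")
    if not use_similarity:
        return ScoreMatrix(FAD, c13.row_names, c13.col_names, c13.values.copy())
    if fsd is None or fsl is None:
        raise ParameterError("use_similarity=True requires both FSD and FSL")
    if tuple(fsd.entity_names) != tuple(c13.row_names):
        raise AlignmentError("disease order of FSD does not match C13 rows")
    if tuple(fsl.entity_names) != tuple(c13.col_names):
        raise AlignmentError("lncRNA order of FSL does not match C13 columns")
    vals = fsd.values @ c13.values @ fsl.values
    return ScoreMatrix(FAD, c13.row_names, c13.col_names, vals)


def prediction_block(net: TripartiteNetwork, r: int) -> ScoreMatrix:
    """Convenience: network -> SPM -> DCCM -> AD -> C13 in one call."""
    from .hetnet import shortest_path_matrix

    spm = shortest_path_matrix(net, r)
    dccm = build_dccm(spm)
    ad = association_degree(dccm, node_names=net.node_names)
    return extract_c13(ad, net)
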