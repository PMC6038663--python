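"""Leave-one-out evaluation, ROC/AUC, ablation, and top-list extraction.

The scorer never consumes the gold-standard pairs, so "leave one out"
reduces to scoring once and ranking each gold pair against the pool of
unconfirmed candidate pairs — either one global pool (default) or the
pool restricted to the same disease.  AUC is the tie-corrected rank
statistic (Mann-Whitney), cross-checked against trapezoidal integration
of the threshold-swept ROC curve.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from scipy.stats import rankdata

from .errors import EvaluationError, ParameterError
from .hetnet import TripartiteNetwork
from .io_tables import DISEASE, LNCRNA, AssociationTable
from .scoring import ScoreMatrix, final_scores, prediction_block
from .similarity import SimilarityMatrix

GLOBAL = "global"
PER_DISEASE = "per_disease"
POLICIES = (GLOBAL, PER_DISEASE)


@dataclass(frozen=True)
class EvaluationResult:
    per_test_ranks: tuple  # of (disease, lncRNA, rank, candidate_count)
    roc: tuple  # of (FPR, TPR)
    auc: float
    settings: dict

    def write_ranks_tsv(self, path) -> Path:
        path = Path(path)
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("disease\tlncRNA\trank\tcandidates\n")
            for d, l, rank, n in self.per_test_ranks:
                fh.write(f"{d}\t{l}\t{rank!r}\t{n}\n")
        return path

    def write_roc_tsv(self, path) -> Path:
        path = Path(path)
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("FPR\tTPR\n")
            for fpr, tpr in self.roc:
                fh.write(f"{fpr!r}\t{tpr!r}\n")
        return path


def rank_auc(test_scores, candidate_scores) -> float:
    """Tie-corrected Mann-Whitney AUC of tests vs candidates."""
    t = np.asarray(test_scores, dtype=float)
    c = np.asarray(candidate_scores, dtype=float)
    if t.size == 0 or c.size == 0:
        raise EvaluationError("need at least one test and one candidate score")
    ranks = rankdata(np.concatenate([t, c]))
    return float((ranks[: t.size].sum() - t.size * (t.size + 1) / 2) / (t.size * c.size))


def roc_points(test_scores, candidate_scores):
    """Threshold-swept ROC curve as a list of (FPR, TPR) points.

    One point per distinct score value (threshold = "score >= t"),
    bracketed by (0, 0) and (1, 1); both coordinates are nondecreasing.
    """
    t = np.asarray(test_scores, dtype=float)
    c = np.asarray(candidate_scores, dtype=float)
    if t.size == 0 or c.size == 0:
        raise EvaluationError("need at least one test and one candidate score")
    thresholds = np.unique(np.concatenate([t, c]))[::-1]
    pts = [(0.0, 0.0)]
    for th in thresholds:
        pts.append((float((c >= th).mean()), float((t >= th).mean())))
    if pts[-1] != (1.0, 1.0):
        pts.append((1.0, 1.0))
    # drop consecutive duplicates
    out = [pts[0]]
    for p in pts[1:]:
        if p != out[-1]:
            out.append(p)
    return out


def trapezoid_auc(points) -> float:
    """Area under a (FPR, TPR) polyline."""
    fpr = np.array([p[0] for p in points])
    tpr = np.array([p[1] for p in points])
    return float(np.trapezoid(tpr, fpr))


def _gold_cells(fad: ScoreMatrix, gold: AssociationTable):
    """Map gold pairs to (row, col) indices of the score matrix."""
    layers = {gold.left_layer, gold.right_layer}
    if layers != {DISEASE, LNCRNA}:
        raise EvaluationError(f"gold table must link diseases and lncRNAs, got {layers}")
    d_idx = {n: i for i, n in enumerate(fad.row_names)}
    l_idx = {n: i for i, n in enumerate(fad.col_names)}
    d_col = 0 if gold.left_layer == DISEASE else 1
    cells = []
    for e in sorted(gold.edges):
        d, l = e[d_col], e[1 - d_col]
        if d not in d_idx or l not in l_idx:
            raise EvaluationError(f"gold pair ({d!r}, {l!r}) is outside the score matrix")
        cells.append((d_idx[d], l_idx[l]))
    return cells


def _per_disease_quantiles(values: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Replace each cell by its quantile among same-row candidate cells.

    The transform is strictly increasing within each row and maps a
    test score tied with candidates to the same quantile as those
    candidates, so single-disease evaluation coincides exactly with the
    global policy.
    """
    q = np.full(values.shape, np.nan)
    for i in range(values.shape[0]):
        cand = values[i, ~mask[i]]
        if cand.size == 0:
            raise EvaluationError(
                f"row {i} has no candidate pairs under the per-disease policy"
            )
        row = values[i]
        below = (cand[None, :] < row[:, None]).sum(axis=1)
        ties = (cand[None, :] == row[:, None]).sum(axis=1)
        q[i] = (below + 0.5 * ties) / cand.size
    return q


def loocv_evaluate(
    fad: ScoreMatrix, gold: AssociationTable, policy: str = GLOBAL
) -> EvaluationResult:
    """Rank every gold pair against unconfirmed candidate pairs.

    Scores are computed once (the model never sees the gold pairs);
    each gold pair's rank is taken against all non-gold pairs (global
    policy) or non-gold pairs of the same disease (per_disease policy).
    """
    if policy not in POLICIES:
        raise ParameterError(f"unknown ranking policy {policy!r}")
    cells = _gold_cells(fad, gold)
    if not cells:
        raise EvaluationError("gold standard is empty")
    mask = np.zeros(fad.values.shape, dtype=bool)
    for i, j in cells:
        mask[i, j] = True
    if mask.all():
        raise EvaluationError("every pair is a gold pair; no candidates remain")

    values = fad.values
    if policy == PER_DISEASE:
        values = _per_disease_quantiles(values, mask)

    tests = values[mask]
    cands = values[~mask]
    auc = rank_auc(tests, cands)
    roc = tuple(roc_points(tests, cands))

    ranks = []
    if policy == GLOBAL:
        for i, j in cells:
            s = fad.values[i, j]
            rank = 1 + (cands > s).sum() + 0.5 * (cands == s).sum()
            ranks.append((fad.row_names[i], fad.col_names[j], float(rank), int(cands.size)))
    else:
        for i, j in cells:
            row_cand = fad.values[i, ~mask[i]]
            s = fad.values[i, j]
            rank = 1 + (row_cand > s).sum() + 0.5 * (row_cand == s).sum()
            ranks.append(
                (fad.row_names[i], fad.col_names[j], float(rank), int(row_cand.size))
            )
    settings = {"policy": policy}
    return EvaluationResult(tuple(ranks), roc, auc, settings)


def ablation_compare(
    net: TripartiteNetwork,
    fsd: SimilarityMatrix,
    fsl: SimilarityMatrix,
    gold: AssociationTable,
    r: int,
    policy: str = GLOBAL,
):
    """LOOCV AUC with similarity blending vs raw C13, on identical inputs."""
    c13 = prediction_block(net, r)
    fad_with = final_scores(c13, fsd, fsl, use_similarity=True)
    fad_without = final_scores(c13, use_similarity=False)
    auc_with = loocv_evaluate(fad_with, gold, policy).auc
    auc_without = loocv_evaluate(fad_without, gold, policy).auc
    return auc_with, auc_without


@dataclass(frozen=True)
class PredictionList:
    """Top-scoring pairs; ties broken by (disease, lncRNA) name order."""

    rows: tuple  # of (disease, lncRNA, score, rank, known_flag)
    fraction: float

    def write_tsv(self, path) -> Path:
        path = Path(path)
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("disease\tlncRNA\tscore\trank\tknown\n")
            for d, l, s, rank, known in self.rows:
                fh.write(f"{d}\t{l}\t{s!r}\t{rank}\t{int(known)}\n")
        return path


def top_fraction(
    fad: ScoreMatrix, fraction: float = 0.005, gold: Optional[AssociationTable] = None
) -> PredictionList:
    """The top ``ceil(fraction * D * L)`` pairs by descending score."""
    if not (0 < fraction <= 1):
        raise ParameterError(f"fraction must be in (0, 1], got {fraction}")
    known = set()
    if gold is not None and gold.edges:
        known = {(fad.row_names[i], fad.col_names[j]) for i, j in _gold_cells(fad, gold)}
    pairs = [
        (d, l, float(fad.values[i, j]))
        for i, d in enumerate(fad.row_names)
        for j, l in enumerate(fad.col_names)
    ]
    pairs.sort(key=lambda p: (-p[2], p[0], p[1]))
    k = math.ceil(fraction * len(pairs))
    rows = tuple(
        (d, l, s, rank, (d, l) in known)
        for rank, (d, l, s) in enumerate(pairs[:k], start=1)
    )
    return PredictionList(rows=rows, fraction=fraction)
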