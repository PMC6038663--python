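"""Synthetic association tables with controllable planted signal.

Generates the three tables the pipeline consumes: disease-miRNA and
miRNA-lncRNA background edges drawn independently with configurable
densities over a shared miRNA name space, plus an optional planted
signal — for each gold (disease, lncRNA) pair, a handful of miRNAs is
wired to both endpoints, creating the short disease-miRNA-lncRNA paths
and shared neighbourhoods that the scorer is designed to reward.  Also
provides the fixed star network used as a worked example for distance
correlation sets.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import EmptyTableError, ParameterError
from .hetnet import TripartiteNetwork, build_network
from .io_tables import (
    DISEASE,
    LNCRNA,
    MIRNA,
    AssociationTable,
    write_association_table,
)


@dataclass(frozen=True)
class GeneratorConfig:
    n_diseases: int = 20
    n_mirnas: int = 30
    n_lncrnas: int = 25
    p_dm: float = 0.05
    p_ml: float = 0.05
    n_gold: int = 10
    signal_overlap: int = 3
    seed: int = 0

    def validate(self) -> None:
        if min(self.n_diseases, self.n_mirnas, self.n_lncrnas) < 1:
            raise ParameterError("layer sizes must be positive")
        if not (0 < self.p_dm < 1) or not (0 < self.p_ml < 1):
            raise ParameterError("edge probabilities must lie in (0, 1)")
        if self.n_gold < 0 or self.signal_overlap < 0:
            raise ParameterError("n_gold and signal_overlap must be >= 0")
        if self.n_gold > self.n_diseases * self.n_lncrnas:
            raise ParameterError(
                f"cannot plant {self.n_gold} gold pairs in a "
                f"{self.n_diseases}x{self.n_lncrnas} grid"
            )
        if self.signal_overlap > self.n_mirnas:
            raise ParameterError("signal_overlap exceeds the number of miRNAs")


def _names(prefix: str, n: int) -> list:
    return [f"{prefix}{i:03d}" for i in range(n)]


def generate(config: GeneratorConfig):
    """Draw (dm, ml, gold) tables; deterministic for a fixed seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    d_names = _names("d", config.n_diseases)
    m_names = _names("m", config.n_mirnas)
    l_names = _names("l", config.n_lncrnas)

    dm_mask = rng.random((config.n_diseases, config.n_mirnas)) < config.p_dm
    ml_mask = rng.random((config.n_mirnas, config.n_lncrnas)) < config.p_ml

    gold_pairs = []
    if config.n_gold:
        flat = rng.choice(
            config.n_diseases * config.n_lncrnas, size=config.n_gold, replace=False
        )
        for f in flat:
            di, li = divmod(int(f), config.n_lncrnas)
            gold_pairs.append((di, li))
            if config.signal_overlap:
                ms = rng.choice(config.n_mirnas, size=config.signal_overlap, replace=False)
                dm_mask[di, ms] = True
                ml_mask[ms, li] = True

    dm_edges = frozenset(
        (d_names[i], m_names[j]) for i, j in zip(*np.nonzero(dm_mask))
    )
    ml_edges = frozenset(
        (m_names[i], l_names[j]) for i, j in zip(*np.nonzero(ml_mask))
    )
    if not dm_edges or not ml_edges:
        raise EmptyTableError(
            "generated an empty table; increase densities or plant a signal"
        )
    prov = f"synthetic(seed={config.seed})"
    dm = AssociationTable(DISEASE, MIRNA, dm_edges, provenance=prov)
    ml = AssociationTable(MIRNA, LNCRNA, ml_edges, provenance=prov)
    gold = AssociationTable(
        LNCRNA,
        DISEASE,
        frozenset((l_names[li], d_names[di]) for di, li in gold_pairs),
        provenance=prov,
    )
    return dm, ml, gold


def write_tables(dm, ml, gold, out_dir):
    """Write the three tables in the TSV dialect the parser reads."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "dm": write_association_table(dm, out_dir / "dm.tsv"),
        "ml": write_association_table(ml, out_dir / "ml.tsv"),
        "gold": write_association_table(gold, out_dir / "gold.tsv"),
    }
    return paths


def worked_example_network() -> TripartiteNetwork:
    """Fixed star network: one disease hub, 4 miRNAs, 5 lncRNAs.

    D1 is adjacent to all of M1-M4 and every lncRNA hangs off at least
    one of them, so at radius 2 the distance correlation set of D1 is
    all nine other nodes.
    """
    dm = AssociationTable(
        DISEASE,
        MIRNA,
        frozenset({("D1", "M1"), ("D1", "M2"), ("D1", "M3"), ("D1", "M4")}),
        provenance="worked-example",
    )
    ml = AssociationTable(
        MIRNA,
        LNCRNA,
        frozenset(
            {("M1", "L1"), ("M2", "L2"), ("M3", "L3"), ("M4", "L4"), ("M1", "L5")}
        ),
        provenance="worked-example",
    )
    return build_network(
        dm,
        ml,
        diseases=("D1",),
        mirnas=("M1", "M2", "M3", "M4"),
        lncrnas=("L1", "L2", "L3", "L4", "L5"),
    )
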