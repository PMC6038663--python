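"""Reading, normalising and filtering of bipartite association tables.

The pipeline consumes three tab-separated edge lists: disease-miRNA
associations, miRNA-lncRNA associations, and a gold-standard
lncRNA-disease table used only for evaluation.  This module parses the
TSV dialect (2+ columns, ``#`` comments, UTF-8), normalises entity
names (miRNA names get special treatment so locus copies producing the
same mature miRNA collapse to one name), removes duplicates, and
restricts the two scoring tables to their shared miRNA name space.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

from .errors import (
    ConsistencyError,
    EmptyTableError,
    NoSharedMirnasError,
    ParseError,
)

#: Canonical layer labels used throughout the package.
DISEASE = "disease"
MIRNA = "miRNA"
LNCRNA = "lncRNA"
LAYERS = (DISEASE, MIRNA, LNCRNA)


@dataclass(frozen=True)
class NameNormalizationPolicy:
    """Deterministic rules applied to every name before deduplication.

    Attributes
    ----------
    lowercase:
        Casefold every name (all layers).
    merge_locus_suffix:
        Collapse trailing ``-1``/``-2``/``-3`` locus-copy suffixes on
        miRNA names, but only when the preceding dash-separated token
        carries a digit (``hsa-mir-121-1`` -> ``hsa-mir-121`` while
        ``hsa-mir-1`` is untouched).  Locus copies of one gene produce
        the same mature miRNA and must be merged.
    keep_arm_suffix:
        Treat ``-5p``/``-3p`` arms as distinct mature miRNAs.  When
        disabled the arm suffix is stripped as well.
    """

    lowercase: bool = True
    merge_locus_suffix: bool = True
    keep_arm_suffix: bool = True


DEFAULT_POLICY = NameNormalizationPolicy()

_ARM_RE = re.compile(r"-([35]p)$", re.IGNORECASE)


def normalize_mirna_name(name: str, policy: NameNormalizationPolicy = DEFAULT_POLICY) -> str:
    """Return the canonical form of a miRNA name under ``policy``.

    The mapping is deterministic and idempotent: applying it twice
    yields the same string as applying it once.

    Raises
    ------
    ValueError
        If ``name`` is empty or whitespace-only.
    """
    s = name.strip()
    if not s:
        raise ValueError("empty miRNA name")
    # iterate to a fixed point so the mapping is idempotent even for
    # degenerate names with stacked suffixes
    prev = None
    while s != prev:
        prev = s
        s = _normalize_once(s, policy)
    return s


def _normalize_once(s: str, policy: NameNormalizationPolicy) -> str:
    if policy.lowercase:
        s = s.casefold()
    arm = ""
    m = _ARM_RE.search(s)
    if m:
        arm = m.group(0)
        s = s[: m.start()]
    if not policy.keep_arm_suffix:
        arm = ""
    if policy.merge_locus_suffix:
        tokens = s.split("-")
        if (
            len(tokens) >= 2
            and tokens[-1] in {"1", "2", "3"}
            and any(ch.isdigit() for ch in tokens[-2])
        ):
            s = "-".join(tokens[:-1])
    return s + arm


def normalize_entity_name(
    name: str, layer: str, policy: NameNormalizationPolicy = DEFAULT_POLICY
) -> str:
    """Normalise a name for any layer (miRNA names get the full policy)."""
    if layer == MIRNA:
        return normalize_mirna_name(name, policy)
    s = name.strip()
    if not s:
        raise ValueError(f"empty {layer} name")
    return s.casefold() if policy.lowercase else s


@dataclass(frozen=True)
class AssociationTable:
    """A deduplicated bipartite edge list between two named layers."""

    left_layer: str
    right_layer: str
    edges: frozenset  # of (left_name, right_name) string pairs
    provenance: str = ""

    def __post_init__(self):
        if self.left_layer not in LAYERS or self.right_layer not in LAYERS:
            raise ValueError(f"unknown layer label(s): {self.left_layer!r}, {self.right_layer!r}")
        if self.left_layer == self.right_layer:
            raise ValueError("left and right layers must differ")
        for left, right in self.edges:
            if not left or not right:
                raise ValueError("edge with empty entity name")

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def left_names(self) -> set:
        return {e[0] for e in self.edges}

    @property
    def right_names(self) -> set:
        return {e[1] for e in self.edges}

    def layer_names(self, layer: str) -> set:
        """Distinct names appearing on the side labelled ``layer``."""
        if layer == self.left_layer:
            return self.left_names
        if layer == self.right_layer:
            return self.right_names
        raise ValueError(f"table has no layer {layer!r}")

    def degrees(self, layer: str) -> dict:
        """Edge counts per entity on the given side."""
        idx = 0 if layer == self.left_layer else 1
        if layer not in (self.left_layer, self.right_layer):
            raise ValueError(f"table has no layer {layer!r}")
        deg: dict = {}
        for e in self.edges:
            deg[e[idx]] = deg.get(e[idx], 0) + 1
        return deg

    def neighborhoods(self, layer: str) -> dict:
        """Map each entity of ``layer`` to the set of its partners."""
        idx = 0 if layer == self.left_layer else 1
        if layer not in (self.left_layer, self.right_layer):
            raise ValueError(f"table has no layer {layer!r}")
        out: dict = {}
        for e in self.edges:
            out.setdefault(e[idx], set()).add(e[1 - idx])
        return out


def parse_association_table(
    path,
    left_layer: str,
    right_layer: str,
    policy: NameNormalizationPolicy = DEFAULT_POLICY,
    left_col: int = 0,
    right_col: int = 1,
) -> AssociationTable:
    """Parse a TSV edge list into a deduplicated :class:`AssociationTable`.

    Lines starting with ``#`` and blank lines are skipped.  Each data
    line must provide at least ``max(left_col, right_col) + 1``
    tab-separated fields; extra columns are ignored.

    Raises
    ------
    FileNotFoundError
        If ``path`` does not exist.
    ParseError
        On a line with too few fields (the message names the line number).
    EmptyTableError
        If no edges survive parsing and normalisation.
    """
    path = Path(path)
    need = max(left_col, right_col) + 1
    edges = set()
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < need:
                raise ParseError(
                    f"{path}:{lineno}: expected >= {need} tab-separated fields, got {len(fields)}"
                )
            try:
                left = normalize_entity_name(fields[left_col], left_layer, policy)
                right = normalize_entity_name(fields[right_col], right_layer, policy)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            edges.add((left, right))
    if not edges:
        raise EmptyTableError(f"{path}: empty table after filtering")
    return AssociationTable(left_layer, right_layer, frozenset(edges), provenance=str(path))


def write_association_table(table: AssociationTable, path) -> Path:
    """Write a table as sorted two-column TSV (round-trips with the parser)."""
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# {table.left_layer}\t{table.right_layer}\t{table.provenance}\n")
        for left, right in sorted(table.edges):
            fh.write(f"{left}\t{right}\n")
    return path


def intersect_mirna_space(t1: AssociationTable, t2: AssociationTable):
    """Restrict two tables to their shared miRNA names.

    ``t1`` must carry miRNAs on its right side (disease-miRNA) and
    ``t2`` on its left side (miRNA-lncRNA).  Returns
    ``(shared_mirnas, t1_filtered, t2_filtered)``.

    Raises
    ------
    NoSharedMirnasError
        If the intersection is empty — no path can link the outer layers.
    """
    if t1.right_layer != MIRNA or t2.left_layer != MIRNA:
        raise ConsistencyError(
            "expected t1 right layer and t2 left layer to be miRNA; got "
            f"{t1.right_layer!r} / {t2.left_layer!r}"
        )
    shared = t1.right_names & t2.left_names
    if not shared:
        raise NoSharedMirnasError("no shared miRNAs between the two tables")
    t1f = AssociationTable(
        t1.left_layer,
        t1.right_layer,
        frozenset(e for e in t1.edges if e[1] in shared),
        provenance=t1.provenance,
    )
    t2f = AssociationTable(
        t2.left_layer,
        t2.right_layer,
        frozenset(e for e in t2.edges if e[0] in shared),
        provenance=t2.provenance,
    )
    return shared, t1f, t2f


def filter_gold_standard(
    gold: AssociationTable, diseases: Iterable[str], lncrnas: Iterable[str]
) -> AssociationTable:
    """Keep only gold pairs whose disease and lncRNA are known entities.

    Accepts gold tables in either orientation (disease-lncRNA or
    lncRNA-disease).  An empty result is returned with a warning, not an
    error — evaluation refuses empty gold tables later.
    """
    diseases = set(diseases)
    lncrnas = set(lncrnas)
    layers = {gold.left_layer, gold.right_layer}
    if layers != {DISEASE, LNCRNA}:
        raise ConsistencyError(f"gold table must link diseases and lncRNAs, got {layers}")
    d_idx = 0 if gold.left_layer == DISEASE else 1
    kept = frozenset(
        e for e in gold.edges if e[d_idx] in diseases and e[1 - d_idx] in lncrnas
    )
    if not kept:
        warnings.warn("gold standard is empty after entity filtering", stacklevel=2)
    return AssociationTable(gold.left_layer, gold.right_layer, kept, provenance=gold.provenance)
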