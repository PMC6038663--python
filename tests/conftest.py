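"""Shared fixtures and independent brute-force oracles.

The oracles here recompute the pipeline's quantities from first
principles (matrix powers, explicit double/quadruple loops) and must
stay independent of the implementation they check.
"""

from __future__ import annotations

import math

import numpy as np
import pytest

from dcsnet.hetnet import TripartiteNetwork
from dcsnet.io_tables import DISEASE, LNCRNA, MIRNA, AssociationTable

# ---------------------------------------------------------------------------
# oracles


def spm_power_oracle(am: np.ndarray, r: int) -> np.ndarray:
    """Smallest k in [1, r] with (AM^k)(i, j) != 0, else 0; zero diagonal."""
    n = am.shape[0]
    am = am.astype(np.int64)
    spm = np.zeros((n, n), dtype=np.int64)
    assigned = np.zeros((n, n), dtype=bool)
    ak = np.eye(n, dtype=np.int64)
    for k in range(1, r + 1):
        ak = ak @ am
        hit = (ak != 0) & ~assigned
        spm[hit] = k
        assigned |= hit
    np.fill_diagonal(spm, 0)
    return spm


def fad_brute_oracle(
    am: np.ndarray, D: int, M: int, L: int, r: int, fsd: np.ndarray, fsl: np.ndarray
) -> np.ndarray:
    """Straight-line re-derivation of the full scoring chain with loops."""
    n = D + M + L
    spm = spm_power_oracle(am, r)
    dccm = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i == j:
                dccm[i, j] = r / (r + 1)
            elif 0 < spm[i, j] <= r:
                dccm[i, j] = 1 - spm[i, j] / (r + 1)
    ad = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            ad[i, j] = (dccm[i, :].sum() + dccm[:, j].sum()) / n
    c13 = ad[:D, D + M :]
    fad = np.zeros((D, L))
    for i in range(D):
        for j in range(L):
            acc = 0.0
            for a in range(D):
                for b in range(L):
                    acc += fsd[i, a] * c13[a, b] * fsl[b, j]
            fad[i, j] = acc
    return fad


def similarity_brute_oracle(edges, side_idx: int, base: float, convention: str):
    """Recompute shared-neighbour similarity entry by entry from edge sets.

    ``edges`` are (a, b) pairs with the compared entities at ``side_idx``
    and miRNAs on the other side.  Returns (sorted names, matrix).
    """
    total = len(edges)
    deg_m: dict = {}
    nbrs: dict = {}
    for e in edges:
        ent, m = e[side_idx], e[1 - side_idx]
        deg_m[m] = deg_m.get(m, 0) + 1
        nbrs.setdefault(ent, set()).add(m)
    contrib = {m: -math.log(d / total, base) for m, d in deg_m.items()}
    names = sorted(nbrs)
    n = len(names)
    mat = np.zeros((n, n))
    for i, a in enumerate(names):
        for j, b in enumerate(names):
            inter = nbrs[a] & nbrs[b]
            s = sum(contrib[m] for m in inter)
            q = len(nbrs[a]) + len(nbrs[b]) - len(inter)
            if convention == "quotient_inside_exp":
                mat[i, j] = math.exp(s / q) if q else 1.0
            else:
                mat[i, j] = math.exp(s) / q if q else 1.0
    return names, mat


# ---------------------------------------------------------------------------
# random structure helpers


def random_network(rng: np.random.Generator, D: int, M: int, L: int, p: float = 0.2):
    """Random tripartite network built directly (no table machinery)."""
    n = D + M + L
    am = np.zeros((n, n), dtype=np.int8)
    dm = rng.random((D, M)) < p
    ml = rng.random((M, L)) < p
    for i, j in zip(*np.nonzero(dm)):
        am[i, D + j] = am[D + j, i] = 1
    for i, j in zip(*np.nonzero(ml)):
        am[D + i, D + M + j] = am[D + M + j, D + i] = 1
    return TripartiteNetwork(
        tuple(f"d{i}" for i in range(D)),
        tuple(f"m{i}" for i in range(M)),
        tuple(f"l{i}" for i in range(L)),
        am,
    )


# ---------------------------------------------------------------------------
# fixtures


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def path_network():
    """The 3-node path d1 - m1 - l1."""
    dm = AssociationTable(DISEASE, MIRNA, frozenset({("d1", "m1")}))
    ml = AssociationTable(MIRNA, LNCRNA, frozenset({("m1", "l1")}))
    from dcsnet.hetnet import build_network

    return build_network(dm, ml)


@pytest.fixture
def tiny_tables():
    """Small intersectable pair of tables used across modules."""
    dm = AssociationTable(
        DISEASE,
        MIRNA,
        frozenset({("d1", "m1"), ("d1", "m2"), ("d2", "m2"), ("d2", "m3"), ("d3", "m4")}),
    )
    ml = AssociationTable(
        MIRNA,
        LNCRNA,
        frozenset({("m1", "l1"), ("m2", "l1"), ("m2", "l2"), ("m3", "l3")}),
    )
    return dm, ml


@pytest.fixture
def tsv_writer(tmp_path):
    """Write raw lines to a temp TSV file and return its path."""

    def write(lines, name="table.tsv"):
        p = tmp_path / name
        p.write_text("\n".join(lines) + "\n", encoding="utf-8")
        return p

    return write
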