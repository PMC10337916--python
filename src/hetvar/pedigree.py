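"""Pedigree renumbering, inbreeding, and the additive relationship matrix.

The animal model assumes additive genetic effects a ~ N(0, A sigma2_a) where
A is the numerator relationship matrix of the pedigree.  The mixed-model
equations only ever need A^{-1}, which Henderson's rules assemble directly
and sparsely from parent pointers and inbreeding coefficients; the dense
tabular A is kept as a small-pedigree oracle for testing.

Conventions
-----------
* Unknown parents are coded ``0`` in input files and ``-1`` internally.
* ``renumber`` produces a deterministic topological order (parents before
  offspring, ties broken by original id); all arrays below are indexed in
  that order.
* Inbreeding is accounted for in A^{-1} by default; pass
  ``use_inbreeding=False`` to ``build_a_inverse`` to reproduce the common
  shortcut that treats every animal as non-inbred.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

UNKNOWN = 0


class PedigreeCycleError(ValueError):
    """The pedigree contains a cycle (an animal is its own ancestor)."""


@dataclass
class RelationshipStructure:
    """Renumbered pedigree with inbreeding and (optionally) sparse A^{-1}."""

    order: list
    index: dict
    sire_idx: np.ndarray
    dam_idx: np.ndarray
    inbreeding: np.ndarray | None = None
    a_inverse: sp.csr_matrix | None = None

    @property
    def n_animals(self) -> int:
        return len(self.order)


def _as_frame(pedigree) -> pd.DataFrame:
    ped = pd.DataFrame(pedigree)
    for col in ("animal", "sire", "dam"):
        if col not in ped.columns:
            raise ValueError(f"pedigree is missing column {col!r}")
    return ped


def renumber(pedigree) -> RelationshipStructure:
    """Topologically sort a pedigree so parents precede offspring.

    Deterministic: among animals whose parents are already placed, the one
    with the smallest original id goes first (Kahn's algorithm with a heap).

    Raises
    ------
    PedigreeCycleError
        If an animal is its own ancestor; the message names the animals
        left unplaced.
    """
    ped = _as_frame(pedigree)
    animals = list(ped["animal"])
    if len(set(animals)) != len(animals):
        raise ValueError("duplicate animal ids in pedigree")
    known = set(animals)
    parents = {}
    for row in ped.itertuples(index=False):
        for par in (row.sire, row.dam):
            if par != UNKNOWN and par not in known:
                raise ValueError(f"parent {par!r} of {row.animal!r} has no pedigree row")
        parents[row.animal] = (row.sire, row.dam)

    children: dict = {a: [] for a in animals}
    pending = {}
    ready = []
    for a, (s, d) in parents.items():
        deps = [p for p in (s, d) if p != UNKNOWN]
        if a in deps:
            raise PedigreeCycleError(f"animal {a!r} is listed as its own parent")
        if s == d and s != UNKNOWN:
            raise ValueError(f"animal {a!r} has the same sire and dam ({s!r})")
        pending[a] = len(deps)
        for p in deps:
            children[p].append(a)
        if not deps:
            heapq.heappush(ready, a)

    order = []
    while ready:
        a = heapq.heappop(ready)
        order.append(a)
        for c in children[a]:
            pending[c] -= 1
            if pending[c] == 0:
                heapq.heappush(ready, c)
    if len(order) != len(animals):
        stuck = sorted(a for a, k in pending.items() if k > 0)
        raise PedigreeCycleError(f"pedigree cycle involving animals {stuck}")

    index = {a: i for i, a in enumerate(order)}
    sire_idx = np.array([index.get(parents[a][0], -1) for a in order], dtype=np.int64)
    dam_idx = np.array([index.get(parents[a][1], -1) for a in order], dtype=np.int64)
    return RelationshipStructure(order=order, index=index, sire_idx=sire_idx, dam_idx=dam_idx)


def _mendelian_variance(i: int, sire: np.ndarray, dam: np.ndarray, F: np.ndarray) -> float:
    """Within-family (Mendelian sampling) variance d_i, as a fraction of sigma2_a."""
    s, d = sire[i], dam[i]
    if s >= 0 and d >= 0:
        return 0.5 - 0.25 * (F[s] + F[d])
    if s >= 0 or d >= 0:
        return 0.75 - 0.25 * F[max(s, d)]
    return 1.0


def compute_inbreeding(rs: RelationshipStructure) -> np.ndarray:
    """Inbreeding coefficients by the Meuwissen–Luo row-tracing recursion.

    For each animal i with both parents known, the row of the T matrix in
    A = T D T' is traced back through the ancestors, giving
    a_ii = sum_j t_ij^2 d_j and F_i = a_ii - 1.  Founders have F = 0.
    """
    n = rs.n_animals
    sire, dam = rs.sire_idx, rs.dam_idx
    F = np.zeros(n)
    dval = np.empty(n)
    for i in range(n):
        dval[i] = _mendelian_variance(i, sire, dam, F)
        if sire[i] < 0 or dam[i] < 0:
            continue
        s, d = sire[i], dam[i]
        if sire[s] < 0 and dam[s] < 0 and sire[d] < 0 and dam[d] < 0:
            # both parents are founders: a_sd = 0 unless they coincide
            F[i] = 0.5 * (1.0 + F[s]) if s == d else 0.0
            continue
        v = np.zeros(i + 1)
        v[i] = 1.0
        aii = 0.0
        for j in range(i, -1, -1):
            vj = v[j]
            if vj == 0.0:
                continue
            aii += vj * vj * dval[j]
            if sire[j] >= 0:
                v[sire[j]] += 0.5 * vj
            if dam[j] >= 0:
                v[dam[j]] += 0.5 * vj
        F[i] = aii - 1.0
        # d of later animals uses this F, recomputed lazily in their turn
    rs.inbreeding = F
    return F


def build_a_inverse(rs: RelationshipStructure, use_inbreeding: bool = True) -> sp.csr_matrix:
    """Assemble sparse A^{-1} by Henderson's rules.

    Per animal i with Mendelian variance d_i, alpha = 1/d_i contributes
    alpha at (i,i), -alpha/2 between i and each known parent, and alpha/4
    among the known parents.  Symmetric positive definite by construction.
    """
    if rs.inbreeding is None:
        compute_inbreeding(rs)
    n = rs.n_animals
    F = rs.inbreeding if use_inbreeding else np.zeros(n)
    sire, dam = rs.sire_idx, rs.dam_idx
    rows, cols, vals = [], [], []

    def add(r, c, v):
        rows.append(r)
        cols.append(c)
        vals.append(v)
        if r != c:
            rows.append(c)
            cols.append(r)
            vals.append(v)

    for i in range(n):
        alpha = 1.0 / _mendelian_variance(i, sire, dam, F)
        add(i, i, alpha)
        for par in (sire[i], dam[i]):
            if par >= 0:
                add(i, par, -0.5 * alpha)
                add(par, par, 0.25 * alpha)
        if sire[i] >= 0 and dam[i] >= 0:
            add(sire[i], dam[i], 0.25 * alpha)
    ainv = sp.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()
    ainv.sum_duplicates()
    rs.a_inverse = ainv
    return ainv


def build_a_tabular(rs: RelationshipStructure, max_animals: int = 2000) -> np.ndarray:
    """Dense A by the recursive tabular method (test oracle; small pedigrees).

    a_ij = 0.5 (a_{s(i),j} + a_{d(i),j}) for j < i, a_ii = 1 + 0.5 a_{s(i),d(i)};
    unknown-parent terms drop out.  Guarded because the dense recursion is
    O(n^2) memory.
    """
    n = rs.n_animals
    if n > max_animals:
        raise ValueError(f"tabular A refused for n={n} > max_animals={max_animals}")
    sire, dam = rs.sire_idx, rs.dam_idx
    A = np.zeros((n, n))
    for i in range(n):
        s, d = sire[i], dam[i]
        row = np.zeros(i)
        if s >= 0:
            row += 0.5 * A[s, :i]
        if d >= 0:
            row += 0.5 * A[d, :i]
        A[i, :i] = row
        A[:i, i] = row
        A[i, i] = 1.0 + (0.5 * A[s, d] if (s >= 0 and d >= 0) else 0.0)
    return A


def load_pedigree_csv(path) -> pd.DataFrame:
    """Read a pedigree CSV (animal,sire,dam,birth_date,frac_breed1,frac_breed2)."""
    ped = pd.read_csv(path)
    if "birth_date" in ped.columns:
        ped["birth_date"] = pd.to_datetime(ped["birth_date"])
    return ped


def write_a_inverse_coo(rs: RelationshipStructure, path) -> None:
    """Write lower-triangle A^{-1} entries as 1-based coordinate text."""
    if rs.a_inverse is None:
        build_a_inverse(rs)
    coo = sp.tril(rs.a_inverse).tocoo()
    with open(path, "w", encoding="utf-8") as fh:
        for r, c, v in zip(coo.row, coo.col, coo.data):
            fh.write(f"{r + 1}\t{c + 1}\t{v!r}\n")
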