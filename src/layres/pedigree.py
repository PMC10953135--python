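"""Additive genetic relationship structure from a pedigree.

The numerator relationship matrix :math:`A` encodes expected additive
genetic covariances between animals implied by the pedigree
(``cov(a_i, a_j) = A_ij * sigma_a^2``).  Mixed-model equations only need
its sparse inverse, which is assembled directly from per-animal
Mendelian-sampling variances (Henderson's rules with inbreeding);
the dense tabular recursion is kept for small pedigrees and as the
reference for everything else.

Pedigrees are plain DataFrames with integer columns ``animal``, ``sire``,
``dam`` where 0 marks an unknown parent.  Animals must be ordered
parents-before-offspring.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse


class PedigreeError(ValueError):
    pass


def _parent_indices(ped: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, dict]:
    """Map animal ids to 0-based positions; unknown parent -> -1.

    Raises if an animal appears after its offspring or is its own ancestor.
    """
    animals = ped["animal"].to_numpy()
    if len(np.unique(animals)) != len(animals):
        raise PedigreeError("duplicate animal ids in pedigree")
    pos = {a: i for i, a in enumerate(animals)}
    sire = np.full(len(animals), -1, dtype=np.int64)
    dam = np.full(len(animals), -1, dtype=np.int64)
    for i, (s, d) in enumerate(zip(ped["sire"].to_numpy(), ped["dam"].to_numpy())):
        for val, out in ((s, sire), (d, dam)):
            if val == 0:
                continue
            j = pos.get(val)
            if j is None:
                raise PedigreeError(f"parent {val} of animal {animals[i]} not in pedigree")
            if j >= i:
                raise PedigreeError(
                    f"pedigree not sorted parents-first (animal {animals[i]})"
                )
            out[i] = j
    return sire, dam, pos


def build_A(ped: pd.DataFrame) -> np.ndarray:
    """Dense numerator relationship matrix by the tabular method.

    a_ij = 0.5*(a_{j,s(i)} + a_{j,d(i)}) for j < i, and
    a_ii = 1 + 0.5*a_{s(i),d(i)}.  Intended for pedigrees of up to a few
    thousand animals; the sparse inverse never materializes A.
    """
    sire, dam, _ = _parent_indices(ped)
    n = len(sire)
    A = np.zeros((n, n))
    for i in range(n):
        s, d = sire[i], dam[i]
        A[i, i] = 1.0 + (0.5 * A[s, d] if s >= 0 and d >= 0 else 0.0)
        row_s = A[s, :i] if s >= 0 else 0.0
        row_d = A[d, :i] if d >= 0 else 0.0
        if s >= 0 or d >= 0:
            aij = 0.5 * (row_s + row_d) if (s >= 0 and d >= 0) else 0.5 * (
                row_s if s >= 0 else row_d
            )
            A[i, :i] = aij
            A[:i, i] = aij
    return A


def inbreeding(ped: pd.DataFrame) -> np.ndarray:
    """Inbreeding coefficients F_i = 0.5 * a_{s(i),d(i)}.

    Meuwissen & Luo style recursion: for each animal, relationships of its
    parents to all ancestors are accumulated lazily so memory stays O(n).
    Output equals ``diag(build_A(ped)) - 1`` exactly.
    """
    sire, dam, _ = _parent_indices(ped)
    n = len(sire)
    F = np.zeros(n)
    # L[i] caches a_{s(i),d(i)} computed via recursive kinship
    from functools import lru_cache
    import sys

    sys.setrecursionlimit(max(sys.getrecursionlimit(), 10 * n + 1000))

    @lru_cache(maxsize=None)
    def kin(i: int, j: int) -> float:
        # additive relationship a_ij (not coancestry) via recursion on the
        # younger animal; i, j are 0-based positions, -1 = unknown
        if i < 0 or j < 0:
            return 0.0
        if i == j:
            s, d = sire[i], dam[i]
            return 1.0 + 0.5 * kin(s, d)
        if i < j:
            i, j = j, i
        return 0.5 * (kin(sire[i], j) + kin(dam[i], j))

    for i in range(n):
        s, d = sire[i], dam[i]
        if s >= 0 and d >= 0:
            F[i] = 0.5 * kin(s, d)
    kin.cache_clear()
    return F


def build_A_inverse(
    ped: pd.DataFrame, F: np.ndarray | None = None
) -> sparse.csr_matrix:
    """Sparse inverse of A assembled from Mendelian-sampling variances.

    For animal i with parents s, d the Mendelian-sampling variance ratio is
    ``b_i = 0.5 - 0.25*(F_s + F_d)`` (terms dropped for unknown parents,
    b_i = 1 for founders).  Each animal contributes
    ``alpha_i = 1/b_i`` on the pattern {i, s, d} x {i, s, d} with weights
    (1, -1/2, -1/2) on (i, s, d).
    """
    sire, dam, _ = _parent_indices(ped)
    if F is None:
        F = inbreeding(ped)
    n = len(sire)
    rows, cols, vals = [], [], []
    for i in range(n):
        s, d = sire[i], dam[i]
        b = 1.0
        if s >= 0:
            b -= 0.25 * (1.0 + F[s])
        if d >= 0:
            b -= 0.25 * (1.0 + F[d])
        if b <= 0:
            raise PedigreeError(f"non-positive Mendelian variance at animal row {i}")
        alpha = 1.0 / b
        members = [(i, 1.0)]
        if s >= 0:
            members.append((s, -0.5))
        if d >= 0:
            members.append((d, -0.5))
        for a, wa in members:
            for c, wc in members:
                rows.append(a)
                cols.append(c)
                vals.append(alpha * wa * wc)
    Ainv = sparse.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()
    Ainv.sum_duplicates()
    return Ainv


def mendelian_log_det_A(ped: pd.DataFrame, F: np.ndarray | None = None) -> float:
    """log|A| = sum_i log b_i with b_i the Mendelian-sampling variance ratios."""
    sire, dam, _ = _parent_indices(ped)
    if F is None:
        F = inbreeding(ped)
    total = 0.0
    for i in range(len(sire)):
        s, d = sire[i], dam[i]
        b = 1.0
        if s >= 0:
            b -= 0.25 * (1.0 + F[s])
        if d >= 0:
            b -= 0.25 * (1.0 + F[d])
        total += np.log(b)
    return float(total)


def write_coo(matrix: sparse.spmatrix, path) -> None:
    """Write a sparse matrix as whitespace-delimited COO text (row col value)."""
    m = matrix.tocoo()
    with open(path, "w") as fh:
        fh.write(f"% {m.shape[0]} {m.shape[1]} {m.nnz}\n")
        for r, c, v in zip(m.row, m.col, m.data):
            fh.write(f"{r} {c} {v!r}\n")


def read_coo(path) -> sparse.csr_matrix:
    """Read a matrix written by :func:`write_coo`."""
    with open(path) as fh:
        header = fh.readline().split()
        nr, nc = int(header[1]), int(header[2])
        rows, cols, vals = [], [], []
        for line in fh:
            r, c, v = line.split()
            rows.append(int(r))
            cols.append(int(c))
            vals.append(float(v))
    return sparse.coo_matrix((vals, (rows, cols)), shape=(nr, nc)).tocsr()


@dataclass
class PedigreeRelationship:
    """Ordered animals, inbreeding, sparse A-inverse and log|A|."""

    animals: np.ndarray
    F: np.ndarray
    A_inv: sparse.csr_matrix
    log_det_A: float
    index: dict = field(repr=False, default_factory=dict)

    @classmethod
    def from_pedigree(cls, ped: pd.DataFrame) -> "PedigreeRelationship":
        F = inbreeding(ped)
        A_inv = build_A_inverse(ped, F)
        logdet = mendelian_log_det_A(ped, F)
        animals = ped["animal"].to_numpy()
        return cls(
            animals=animals,
            F=F,
            A_inv=A_inv,
            log_det_A=logdet,
            index={a: i for i, a in enumerate(animals)},
        )

    @property
    def n(self) -> int:
        return len(self.animals)

    def positions(self, ids) -> np.ndarray:
        return np.array([self.index[a] for a in ids], dtype=np.int64)
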