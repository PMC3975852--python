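"""Relationship matrices: pedigree numerator A (via its sparse inverse) and
the genomic relationship matrix G.

A-inverse is assembled directly with Henderson's rules, using inbreeding
coefficients from the Meuwissen-Luo algorithm, so the dense A is never
formed.  G follows VanRaden's first method, ``G = ZZ' / (2 sum p(1-p))``
with Z the allele counts centered at twice the allele frequency.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg as sla
import scipy.sparse as sp
from numba import njit

UNKNOWN = -1


class PedigreeError(ValueError):
    """Raised for cyclic pedigrees or references to missing parents."""


class DegenerateMatrixError(ValueError):
    """Raised when a relationship matrix cannot be formed (e.g. no
    polymorphic markers)."""


@njit(cache=True)
def _meuwissen_luo_f(sire: np.ndarray, dam: np.ndarray) -> np.ndarray:
    """Inbreeding coefficients for a parents-before-offspring pedigree.

    Traces, for each animal with both parents known, the contributions
    L_j^2 * d_j of every ancestor j to the diagonal a_ii = 1 + F_i, using a
    sorted linked list of pending ancestors (Meuwissen & Luo's method).
    """
    n = sire.size
    F = np.zeros(n)
    L = np.zeros(n)
    point = np.full(n, -1, dtype=np.int64)
    for i in range(n):
        if sire[i] < 0 or dam[i] < 0:
            continue
        fi = -1.0
        L[i] = 1.0
        j = i
        while j != -1:
            r = 0.5 * L[j]
            sj = sire[j]
            dj = dam[j]
            if sj >= 0:
                L[sj] += r
                k = j
                while point[k] > sj:
                    k = point[k]
                if point[k] != sj:
                    point[sj] = point[k]
                    point[k] = sj
            if dj >= 0:
                L[dj] += r
                k = j
                while point[k] > dj:
                    k = point[k]
                if point[k] != dj:
                    point[dj] = point[k]
                    point[k] = dj
            if sj >= 0 and dj >= 0:
                dvar = 0.5 - 0.25 * (F[sj] + F[dj])
            elif sj >= 0:
                dvar = 0.75 - 0.25 * F[sj]
            elif dj >= 0:
                dvar = 0.75 - 0.25 * F[dj]
            else:
                dvar = 1.0
            fi += L[j] * L[j] * dvar
            L[j] = 0.0
            nxt = point[j]
            point[j] = -1
            j = nxt
        F[i] = fi
    return F


@dataclass
class RelationshipMatrix:
    """A relationship matrix plus the metadata the mixed model needs.

    kind is one of ``pedigree_A_inverse`` (matrix holds sparse A-inverse),
    ``genomic_G`` (dense G) or ``genomic_G_inverse``.  ``logdet`` is the log
    determinant of the relationship matrix K itself (A or ridged G), and
    ``inbreeding`` the per-animal F (diag(K) - 1).
    """

    kind: str
    ids: np.ndarray
    matrix: object
    ridge: float = 0.0
    inbreeding: np.ndarray | None = None
    logdet: float | None = None
    _chol: object = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        self.ids = np.asarray(self.ids)
        if self.ids.size != np.unique(self.ids).size:
            raise PedigreeError("duplicate animal ids in relationship matrix")
        if self.matrix.shape != (self.ids.size, self.ids.size):
            raise PedigreeError("matrix dimension does not match id count")

    @property
    def n(self) -> int:
        return self.ids.size

    def positions(self, ids) -> np.ndarray:
        """Map external animal ids to row positions (error if absent)."""
        lookup = pd.Index(self.ids)
        pos = lookup.get_indexer(np.asarray(ids))
        if np.any(pos < 0):
            missing = np.asarray(ids)[pos < 0][:5]
            raise PedigreeError(f"animals not in relationship matrix: {missing}")
        return pos

    # -- quantities used by the mixed-model engine -------------------------
    def _cholesky(self):
        if self._chol is None:
            if self.kind != "genomic_G":
                raise DegenerateMatrixError("dense factorization requires genomic_G")
            self._chol = sla.cho_factor(np.asarray(self.matrix), lower=True)
        return self._chol

    def precision(self):
        """(K^-1, logdet K): sparse for the pedigree kind, dense otherwise."""
        if self.kind == "pedigree_A_inverse":
            return self.matrix, self.logdet
        c, lower = self._cholesky()
        kinv = sla.cho_solve((c, lower), np.eye(self.n))
        logdet = 2.0 * np.sum(np.log(np.diag(c)))
        return kinv, logdet

    def submatrix(self, positions: np.ndarray) -> np.ndarray:
        """Dense K restricted to the given row/column positions.

        For the pedigree kind the A block is recovered by solving
        A^-1 X = E without ever forming the full A.
        """
        positions = np.asarray(positions)
        if self.kind == "pedigree_A_inverse":
            lu = sp.linalg.splu(sp.csc_matrix(self.matrix))
            e = np.zeros((self.n, positions.size))
            e[positions, np.arange(positions.size)] = 1.0
            cols = lu.solve(e)
            return cols[positions]
        return np.asarray(self.matrix)[np.ix_(positions, positions)]

    def inbreeding_of(self, positions: np.ndarray) -> np.ndarray:
        if self.inbreeding is not None:
            return self.inbreeding[np.asarray(positions)]
        if self.kind == "genomic_G":
            return np.asarray(self.matrix).diagonal()[np.asarray(positions)] - 1.0
        raise DegenerateMatrixError("no inbreeding information available")


def _toposort(animal: np.ndarray, sire: np.ndarray, dam: np.ndarray) -> np.ndarray:
    """Order positions so parents precede offspring; raise on cycles."""
    n = animal.size
    order = np.empty(n, dtype=np.int64)
    state = np.zeros(n, dtype=np.int8)  # 0 unvisited, 1 in-stack, 2 done
    k = 0
    for start in range(n):
        if state[start]:
            continue
        stack = [(start, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                state[node] = 2
                order[k] = node
                k += 1
                continue
            if state[node] == 2:
                continue
            if state[node] == 1:
                raise PedigreeError("cyclic pedigree")
            state[node] = 1
            stack.append((node, True))
            for p in (sire[node], dam[node]):
                if p >= 0 and state[p] == 1:
                    raise PedigreeError("cyclic pedigree")
                if p >= 0 and state[p] == 0:
                    stack.append((p, False))
    return order


def build_a_inverse(pedigree: pd.DataFrame) -> RelationshipMatrix:
    """Sparse A-inverse with inbreeding, by Henderson's rules.

    ``pedigree`` needs columns animal, sire, dam; unknown parents are -1
    (or any id absent from the animal column is an error).  Rows need not be
    sorted; a topological order is established internally and the result is
    indexed by the animal ids as given.
    """
    animal = pedigree["animal"].to_numpy()
    idx = pd.Index(animal)
    if idx.has_duplicates:
        raise PedigreeError("duplicate animal ids")

    def parent_pos(col):
        raw = pedigree[col].to_numpy()
        pos = idx.get_indexer(raw)
        bad = (pos < 0) & (raw != UNKNOWN)
        if np.any(bad):
            raise PedigreeError(f"unknown {col} ids referenced: {raw[bad][:5]}")
        return pos

    sire = parent_pos("sire")
    dam = parent_pos("dam")

    order = _toposort(np.arange(animal.size), sire, dam)
    inv_order = np.empty_like(order)
    inv_order[order] = np.arange(order.size)
    s_sorted = np.where(sire[order] >= 0, inv_order[np.clip(sire[order], 0, None)], -1)
    d_sorted = np.where(dam[order] >= 0, inv_order[np.clip(dam[order], 0, None)], -1)

    F_sorted = _meuwissen_luo_f(s_sorted.astype(np.int64), d_sorted.astype(np.int64))
    F = np.empty_like(F_sorted)
    F[order] = F_sorted

    n = animal.size
    both = (sire >= 0) & (dam >= 0)
    one_s = (sire >= 0) & (dam < 0)
    one_d = (sire < 0) & (dam >= 0)
    d_var = np.ones(n)
    d_var[both] = 0.5 - 0.25 * (F[sire[both]] + F[dam[both]])
    d_var[one_s] = 0.75 - 0.25 * F[sire[one_s]]
    d_var[one_d] = 0.75 - 0.25 * F[dam[one_d]]
    alpha = 1.0 / d_var

    rows, cols, vals = [np.arange(n)], [np.arange(n)], [alpha]
    for p in (sire, dam):
        known = p >= 0
        i, pp, a = np.arange(n)[known], p[known], alpha[known]
        rows += [i, pp, pp]
        cols += [pp, i, pp]
        vals += [-a / 2, -a / 2, a / 4]
    cross = both
    i, s, d, a = np.arange(n)[cross], sire[cross], dam[cross], alpha[cross]
    rows += [s, d]
    cols += [d, s]
    vals += [a / 4, a / 4]
    ainv = sp.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n, n),
    ).tocsr()
    return RelationshipMatrix(
        kind="pedigree_A_inverse",
        ids=animal,
        matrix=ainv,
        inbreeding=F,
        logdet=float(np.sum(np.log(d_var))),
    )


def vanraden_g(
    dosages: np.ndarray,
    freqs: np.ndarray | None = None,
    ids: np.ndarray | None = None,
) -> RelationshipMatrix:
    """Genomic relationship matrix, VanRaden method 1.

    ``dosages`` is animals x markers with allele counts in {0, 1, 2};
    ``freqs`` the per-marker frequency of the counted allele (observed
    frequencies across the genotyped animals by default).  Monomorphic
    markers contribute zero to both numerator and denominator, so G is
    invariant to their presence.
    """
    d = np.asarray(dosages, dtype=float)
    if d.ndim != 2:
        raise DegenerateMatrixError("dosage matrix must be 2-D")
    if freqs is None:
        freqs = d.mean(axis=0) / 2.0
    freqs = np.asarray(freqs, dtype=float)
    if np.any((freqs < 0) | (freqs > 1)):
        raise DegenerateMatrixError("allele frequencies must lie in [0, 1]")
    het = 2.0 * np.sum(freqs * (1.0 - freqs))
    if het <= 0:
        raise DegenerateMatrixError("all markers monomorphic")
    z = d - 2.0 * freqs
    g = (z @ z.T) / het
    if ids is None:
        ids = np.arange(d.shape[0])
    return RelationshipMatrix(kind="genomic_G", ids=np.asarray(ids), matrix=g)


def ensure_invertible(G: RelationshipMatrix, ridge: float = 1e-6) -> RelationshipMatrix:
    """Return G + ridge * I (positive definite for any PSD G, ridge > 0)."""
    if ridge < 0:
        raise DegenerateMatrixError("ridge must be non-negative")
    m = np.asarray(G.matrix) + ridge * np.eye(G.n)
    return RelationshipMatrix(
        kind=G.kind, ids=G.ids, matrix=m, ridge=G.ridge + ridge,
        inbreeding=G.inbreeding,
    )
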