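"""Pedigrees and the numerator relationship matrix.

A pedigree is a list of individual–sire–dam triples. The additive (numerator)
relationship matrix ``A`` collects the expected additive genetic relationships
implied by the pedigree; its Kronecker product with the genetic covariance
matrix ``G`` gives the covariance of the vector of breeding values in the
animal model. ``A`` is built by the tabular method (which handles inbreeding
exactly), and its sparse inverse is assembled directly from per-individual
Mendelian-sampling variances, Henderson style, without ever inverting ``A``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Hashable, Iterable, Sequence

import numpy as np
from scipy import sparse

__all__ = [
    "Pedigree",
    "PedigreeError",
    "toposort_pedigree",
    "build_A",
    "build_A_inverse",
]

#: dense A is refused above this size; the tabular method is O(s^2) memory
MAX_DENSE = 5000

UNKNOWN = {0, "0", "", ".", "NA", None}


class PedigreeError(ValueError):
    """Raised for structurally invalid pedigrees (cycles, duplicates...)."""


@dataclass(frozen=True)
class Pedigree:
    """A topologically sorted pedigree.

    Attributes
    ----------
    labels : tuple
        Original individual identifiers, in sorted (parents-first) order.
    sire, dam : ndarray of int
        Index of each individual's sire/dam within ``labels``; ``-1`` marks
        an unknown parent. Parents always precede offspring.
    """

    labels: tuple
    sire: np.ndarray
    dam: np.ndarray
    _cache: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        s, d = np.asarray(self.sire), np.asarray(self.dam)
        idx = np.arange(self.size)
        if np.any(s >= idx) or np.any(d >= idx):
            raise PedigreeError("pedigree is not topologically sorted")

    @property
    def size(self) -> int:
        """Number of individuals (the animal-model dimension ``s``)."""
        return len(self.labels)

    @property
    def founders(self) -> np.ndarray:
        """Indices of individuals with both parents unknown."""
        return np.flatnonzero((self.sire < 0) & (self.dam < 0))

    def index_of(self, labels: Iterable[Hashable]) -> np.ndarray:
        """Map external identifiers to pedigree row indices."""
        lookup = {lab: i for i, lab in enumerate(self.labels)}
        try:
            return np.array([lookup[lab] for lab in labels], dtype=np.int64)
        except KeyError as err:
            raise PedigreeError(f"id {err.args[0]!r} not in pedigree") from None

    # -- relationship matrices -------------------------------------------

    def relationship_matrix(self) -> np.ndarray:
        """Dense numerator relationship matrix ``A`` (cached)."""
        if "A" not in self._cache:
            self._cache["A"] = build_A(self)
        return self._cache["A"]

    def relationship_inverse(self) -> sparse.csr_matrix:
        """Sparse ``A^{-1}`` (cached)."""
        if "Ainv" not in self._cache:
            self._cache["Ainv"] = build_A_inverse(self)
        return self._cache["Ainv"]

    def inbreeding(self) -> np.ndarray:
        """Inbreeding coefficients ``F_i = A[i,i] - 1`` (cached).

        Computed by memoized pairwise-kinship recursion (``F_i`` is half the
        relationship between the parents), so it does not require the dense
        tabular A and works for pedigrees of any size.
        """
        if "F" not in self._cache:
            self._cache["F"] = _inbreeding_recursive(self.sire, self.dam)
        return self._cache["F"]


def _is_unknown(code) -> bool:
    return code in UNKNOWN


def toposort_pedigree(records: Sequence[tuple]) -> Pedigree:
    """Sort raw (individual, sire, dam) triples parents-first.

    The order is stable: among individuals whose parents are already placed,
    input order is preserved. Unknown parents may be coded 0, "0", "", "."
    or "NA".

    Raises
    ------
    PedigreeError
        On duplicate individual ids, on a parent id that never appears as an
        individual, or on a cycle (an individual that is its own ancestor).
    """
    records = list(records)
    ids = [r[0] for r in records]
    seen: set = set()
    for i in ids:
        if i in seen:
            raise PedigreeError(f"duplicate individual id {i!r}")
        seen.add(i)
    pos = {ind: k for k, ind in enumerate(ids)}
    parents = {}
    for ind, s, d in records:
        ps = None if _is_unknown(s) else s
        pd_ = None if _is_unknown(d) else d
        for p in (ps, pd_):
            if p is not None and p not in pos:
                raise PedigreeError(
                    f"parent {p!r} of {ind!r} never appears as an individual"
                )
        if ind in (ps, pd_):
            raise PedigreeError(f"individual {ind!r} is its own parent")
        parents[ind] = (ps, pd_)

    # Kahn's algorithm over parent->child edges, stable via index-ordered heap.
    import heapq

    n_unplaced_parents = {
        ind: sum(p is not None for p in ps) for ind, ps in parents.items()
    }
    children: dict = {ind: [] for ind in ids}
    for ind, (s, d) in parents.items():
        for p in {s, d} - {None}:
            children[p].append(ind)
    ready = [pos[i] for i in ids if n_unplaced_parents[i] == 0]
    heapq.heapify(ready)
    order: list = []
    while ready:
        k = heapq.heappop(ready)
        ind = ids[k]
        order.append(ind)
        for ch in children[ind]:
            n_unplaced_parents[ch] -= 1
            if n_unplaced_parents[ch] == 0:
                heapq.heappush(ready, pos[ch])
    if len(order) != len(ids):
        stuck = sorted(set(ids) - set(order), key=pos.get)
        raise PedigreeError(f"cycle detected in pedigree involving id {stuck[0]!r}")

    new_pos = {ind: k for k, ind in enumerate(order)}
    sire = np.array(
        [-1 if parents[i][0] is None else new_pos[parents[i][0]] for i in order],
        dtype=np.int64,
    )
    dam = np.array(
        [-1 if parents[i][1] is None else new_pos[parents[i][1]] for i in order],
        dtype=np.int64,
    )
    return Pedigree(labels=tuple(order), sire=sire, dam=dam)


def build_A(pedigree: Pedigree) -> np.ndarray:
    """Numerator relationship matrix by the tabular method.

    ``A[i,i] = 1 + 0.5*A[s,d]`` and ``A[i,j] = 0.5*(A[j,s] + A[j,d])`` for
    earlier ``j``, where unknown parents contribute nothing. Inbreeding is
    therefore exact.
    """
    s = pedigree.size
    if s > MAX_DENSE:
        raise PedigreeError(
            f"dense A refused for {s} > {MAX_DENSE} individuals; "
            "use relationship_inverse() for the mixed-model equations"
        )
    A = np.zeros((s, s))
    si, di = pedigree.sire, pedigree.dam
    for i in range(s):
        v = np.zeros(i)
        if si[i] >= 0:
            v += 0.5 * A[si[i], :i]
        if di[i] >= 0:
            v += 0.5 * A[di[i], :i]
        A[i, :i] = v
        A[:i, i] = v
        f = 0.5 * A[si[i], di[i]] if (si[i] >= 0 and di[i] >= 0) else 0.0
        A[i, i] = 1.0 + f
    return A


def _inbreeding_recursive(sire: np.ndarray, dam: np.ndarray) -> np.ndarray:
    """F by memoized kinship recursion, linear in practice for shallow pedigrees."""
    import sys
    from functools import lru_cache

    si = sire.tolist()
    di = dam.tolist()

    @lru_cache(maxsize=None)
    def rel(i: int, j: int) -> float:
        if i < 0 or j < 0:
            return 0.0
        if i == j:
            if si[i] >= 0 and di[i] >= 0:
                return 1.0 + 0.5 * rel(*sorted((si[i], di[i]), reverse=True))
            return 1.0
        if i < j:
            i, j = j, i
        return 0.5 * (rel(*sorted((j, si[i]), reverse=True))
                      + rel(*sorted((j, di[i]), reverse=True)))

    old = sys.getrecursionlimit()
    sys.setrecursionlimit(max(old, 10 * len(si) + 1000))
    try:
        return np.array([
            0.5 * rel(*sorted((si[i], di[i]), reverse=True))
            if si[i] >= 0 and di[i] >= 0 else 0.0
            for i in range(len(si))
        ])
    finally:
        sys.setrecursionlimit(old)


def mendelian_variances(pedigree: Pedigree) -> np.ndarray:
    """Mendelian-sampling variances ``d_i`` (in units of the genetic variance).

    ``d_i = 1 - 0.25*(A[s,s] + A[d,d])`` with two known parents,
    ``1 - 0.25*A[p,p]`` with one, and 1 for founders — equivalently
    ``0.5 - 0.25*(F_s + F_d)``.
    """
    diag = 1.0 + pedigree.inbreeding()
    si, di = pedigree.sire, pedigree.dam
    d = np.ones(pedigree.size)
    has_s, has_d = si >= 0, di >= 0
    d[has_s] -= 0.25 * diag[si[has_s]]
    d[has_d] -= 0.25 * diag[di[has_d]]
    if np.any(d <= 0):
        bad = int(np.argmax(d <= 0))
        raise PedigreeError(
            f"non-positive Mendelian-sampling variance for {pedigree.labels[bad]!r}"
            " (corrupt pedigree)"
        )
    return d


def build_A_inverse(pedigree: Pedigree) -> sparse.csr_matrix:
    """Sparse ``A^{-1}`` from per-individual contributions (Henderson's rules).

    Each individual contributes ``alpha_i = 1/d_i`` at ``(i,i)``,
    ``-alpha_i/2`` at (individual, known parent) and ``alpha_i/4`` at each
    (known parent, known parent) pair.
    """
    d = mendelian_variances(pedigree)
    alpha = 1.0 / d
    si, di = pedigree.sire, pedigree.dam
    rows, cols, vals = [], [], []
    for i in range(pedigree.size):
        a = alpha[i]
        rows.append(i); cols.append(i); vals.append(a)
        for p in (si[i], di[i]):
            if p >= 0:
                rows += [i, p]; cols += [p, i]; vals += [-0.5 * a, -0.5 * a]
        known = [p for p in (si[i], di[i]) if p >= 0]
        for p in known:
            for q in known:
                rows.append(p); cols.append(q); vals.append(0.25 * a)
    s = pedigree.size
    return sparse.coo_matrix((vals, (rows, cols)), shape=(s, s)).tocsr()
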