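"""Compiled inner loops for the Gibbs sampler.

The single-site update of the breeding values is the only O(s)-per-iteration
sequential loop; it is written as a numba kernel with hand-rolled small-matrix
Cholesky/solves so one sweep over a few thousand individuals costs
milliseconds. Randomness enters only through pre-generated standard-normal
draws so the whole sampler is driven by a single seeded generator.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True, inline="always")
def _chol_small(C, L):
    """In-place Cholesky of a small SPD matrix; returns False if not PD."""
    m = C.shape[0]
    for i in range(m):
        for j in range(i + 1):
            s = C[i, j]
            for k in range(j):
                s -= L[i, k] * L[j, k]
            if i == j:
                if s <= 0.0:
                    return False
                L[i, i] = np.sqrt(s)
            else:
                L[i, j] = s / L[j, j]
    return True


@njit(cache=True)
def gibbs_u_sweep(indptr, indices, data, Ginv, Rinv, W, rec_row, u, z):
    """One systematic scan of single-site draws of u_i | everything else.

    Full conditional: precision C_i = a_ii * Ginv + Rinv (data term only for
    recorded individuals), mean C_i^{-1} (Rinv W_i - Ginv sum_{j!=i} a_ij u_j)
    where W_i = y_i - X_i b for the individual's (augmented) record and a_ij
    are entries of A^{-1} in CSR form. ``z`` holds one standard-normal
    m-vector per individual; the draw is mu + L'^{-1} z with C_i = L L'.

    Returns the index of the first individual whose conditional precision
    failed the Cholesky even after a jitter retry, or -1.
    """
    s, m = u.shape
    C = np.empty((m, m))
    L = np.zeros((m, m))
    rhs = np.empty(m)
    tmp = np.empty(m)
    gu = np.empty(m)
    for i in range(s):
        aii = 0.0
        for t in range(m):
            gu[t] = 0.0
        for k in range(indptr[i], indptr[i + 1]):
            j = indices[k]
            a = data[k]
            if j == i:
                aii = a
            else:
                for t in range(m):
                    gu[t] += a * u[j, t]
        r = rec_row[i]
        for t1 in range(m):
            for t2 in range(m):
                v = aii * Ginv[t1, t2]
                if r >= 0:
                    v += Rinv[t1, t2]
                C[t1, t2] = v
        for t1 in range(m):
            v = 0.0
            for t2 in range(m):
                v -= Ginv[t1, t2] * gu[t2]
            if r >= 0:
                for t2 in range(m):
                    v += Rinv[t1, t2] * W[r, t2]
            rhs[t1] = v
        ok = _chol_small(C, L)
        if not ok:
            # jitter-and-retry once
            eps = 1e-8
            for t in range(m):
                C[t, t] += eps * C[t, t] + 1e-12
            ok = _chol_small(C, L)
            if not ok:
                return i
        # forward solve L tmp = rhs
        for t1 in range(m):
            v = rhs[t1]
            for t2 in range(t1):
                v -= L[t1, t2] * tmp[t2]
            tmp[t1] = v / L[t1, t1]
        # back solve L' x = tmp + z  ->  x = mu + L'^{-1} z
        for t1 in range(m - 1, -1, -1):
            v = tmp[t1] + z[i, t1]
            for t2 in range(t1 + 1, m):
                v -= L[t2, t1] * u[i, t2]
            u[i, t1] = v / L[t1, t1]
    return -1
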