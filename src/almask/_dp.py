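"""Numba dynamic-programming kernels for the pair HMM.

All recurrences run in probability space with per-row rescaling (scale
factors accumulated in log space), which is both overflow-safe for
sequences of several thousand residues and much faster than cell-wise
log-sum-exp.

State order everywhere: 0 = M (match), 1 = X (short gap in B, emits A),
2 = Y (short gap in A, emits B), 3 = LX, 4 = LY (long-gap extensions).
Cell (i, j) means i residues of sequence A and j of sequence B emitted.
"""

from __future__ import annotations

import numpy as np
from numba import njit

M, X, Y, LX, LY = 0, 1, 2, 3, 4


@njit(cache=True)
def forward_tables(a, b, pm, q, T, tau, start):  # pragma: no cover - numba
    """Scaled forward tables.

    Returns ``(F, cs, logp)`` where ``F`` has shape (5, m+1, n+1), row i of
    every state table is the true value times ``exp(-sum(cs[:i+1]))``, and
    ``logp`` is the log full probability of the sequence pair.
    """
    m = a.shape[0]
    n = b.shape[0]
    F = np.zeros((5, m + 1, n + 1))
    cs = np.zeros(m + 1)
    begin = 1.0  # virtual-begin mass, kept on the scale of row 0 then row 1
    for i in range(m + 1):
        for j in range(n + 1):
            if i == 0 and j == 0:
                continue
            if i > 0 and j > 0:
                if i == 1 and j == 1:
                    inc = start[M] * begin
                else:
                    inc = (
                        T[M, M] * F[M, i - 1, j - 1]
                        + T[X, M] * F[X, i - 1, j - 1]
                        + T[Y, M] * F[Y, i - 1, j - 1]
                        + T[LX, M] * F[LX, i - 1, j - 1]
                        + T[LY, M] * F[LY, i - 1, j - 1]
                    )
                F[M, i, j] = pm[a[i - 1], b[j - 1]] * inc
            if i > 0:
                if i == 1 and j == 0:
                    incx = start[X] * begin
                    inclx = start[LX] * begin
                else:
                    incx = T[M, X] * F[M, i - 1, j] + T[X, X] * F[X, i - 1, j]
                    inclx = T[X, LX] * F[X, i - 1, j] + T[LX, LX] * F[LX, i - 1, j]
                e = q[a[i - 1]]
                F[X, i, j] = e * incx
                F[LX, i, j] = e * inclx
            if j > 0:
                if i == 0 and j == 1:
                    incy = start[Y] * begin
                    incly = start[LY] * begin
                else:
                    incy = T[M, Y] * F[M, i, j - 1] + T[Y, Y] * F[Y, i, j - 1]
                    incly = T[Y, LY] * F[Y, i, j - 1] + T[LY, LY] * F[LY, i, j - 1]
                e = q[b[j - 1]]
                F[Y, i, j] = e * incy
                F[LY, i, j] = e * incly
        # rescale the finished row
        s = 0.0
        for st in range(5):
            for j in range(n + 1):
                if F[st, i, j] > s:
                    s = F[st, i, j]
        if s <= 0.0:
            s = 1.0
        for st in range(5):
            for j in range(n + 1):
                F[st, i, j] /= s
        begin /= s
        cs[i] = np.log(s)
    total = 0.0
    for st in range(5):
        total += F[st, m, n] * tau[st]
    logp = np.log(total) + cs.sum()
    return F, cs, logp


@njit(cache=True)
def backward_tables(a, b, pm, q, T, tau):  # pragma: no cover - numba
    """Scaled backward tables ``(B, ds)``.

    Row i of every state table is the true value times
    ``exp(-sum(ds[i:]))``.
    """
    m = a.shape[0]
    n = b.shape[0]
    B = np.zeros((5, m + 1, n + 1))
    ds = np.zeros(m + 1)
    for st in range(5):
        B[st, m, n] = tau[st]
    for i in range(m, -1, -1):
        for j in range(n, -1, -1):
            if i == m and j == n:
                continue
            bm = pm[a[i], b[j]] * B[M, i + 1, j + 1] if (i < m and j < n) else 0.0
            if i < m:
                e = q[a[i]]
                bx = e * B[X, i + 1, j]
                blx = e * B[LX, i + 1, j]
            else:
                bx = 0.0
                blx = 0.0
            if j < n:
                e = q[b[j]]
                by = e * B[Y, i, j + 1]
                bly = e * B[LY, i, j + 1]
            else:
                by = 0.0
                bly = 0.0
            B[M, i, j] = T[M, M] * bm + T[M, X] * bx + T[M, Y] * by
            B[X, i, j] = T[X, M] * bm + T[X, X] * bx + T[X, LX] * blx
            B[Y, i, j] = T[Y, M] * bm + T[Y, Y] * by + T[Y, LY] * bly
            B[LX, i, j] = T[LX, M] * bm + T[LX, LX] * blx
            B[LY, i, j] = T[LY, M] * bm + T[LY, LY] * bly
        s = 0.0
        for st in range(5):
            for j in range(n + 1):
                if B[st, i, j] > s:
                    s = B[st, i, j]
        if s <= 0.0:
            s = 1.0
        for st in range(5):
            for j in range(n + 1):
                B[st, i, j] /= s
        ds[i] = np.log(s)
    return B, ds
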