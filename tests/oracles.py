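"""Independent brute-force oracles used by the test suite.

The pair-HMM oracle enumerates every complete state path explicitly (no
dynamic programming, no memoisation) and sums plain-float path
probabilities, so it shares nothing with the forward-backward
implementation it checks.
"""

from __future__ import annotations

import numpy as np

M, X, Y, LX, LY = range(5)
_STEP = {M: (1, 1), X: (1, 0), Y: (0, 1), LX: (1, 0), LY: (0, 1)}


def enumerate_paths(a, b, params):
    """Total path probability and per-(x, y) match-path mass.

    ``a``, ``b`` are integer symbol arrays.  Returns ``(total, match)``
    where ``match[(x, y)]`` sums the probabilities of all complete paths
    whose match state emits residues x of a and y of b together.
    """
    T, tau, start = params.trans, params.end, params.start
    pm, q = params.match_emission, params.gap_emission
    m, n = len(a), len(b)
    total = 0.0
    match: dict[tuple[int, int], float] = {}

    def emit(s, i, j):
        if s == M:
            return pm[a[i - 1], b[j - 1]]
        if s in (X, LX):
            return q[a[i - 1]]
        return q[b[j - 1]]

    def rec(i, j, s, p, matches):
        nonlocal total
        if i == m and j == n:
            pe = p * tau[s]
            total += pe
            for xy in matches:
                match[xy] = match.get(xy, 0.0) + pe
            return
        for s2 in range(5):
            di, dj = _STEP[s2]
            i2, j2 = i + di, j + dj
            if i2 > m or j2 > n:
                continue
            t = start[s2] if (i == 0 and j == 0) else T[s, s2]
            if t == 0.0:
                continue
            rec(
                i2, j2, s2, p * t * emit(s2, i2, j2),
                matches + ([(i2 - 1, j2 - 1)] if s2 == M else []),
            )

    rec(0, 0, M, 1.0, [])
    return total, match


def all_sequences(alphabet_size: int, max_len: int):
    """Every integer sequence of length 1..max_len over the alphabet."""
    seqs = []
    frontier = [[]]
    for _ in range(max_len):
        frontier = [s + [c] for s in frontier for c in range(alphabet_size)]
        seqs.extend(np.array(s, dtype=np.int64) for s in frontier)
    return seqs
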