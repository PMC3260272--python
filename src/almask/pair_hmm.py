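"""Pair hidden Markov model and posterior match probabilities.

The model emits two ungapped protein sequences jointly.  Besides the match
state M and the two short-gap states X/Y (one per sequence), a pair of
long-gap extension states LX/LY captures the heavier-than-geometric tail
of real indel lengths: short and long gaps each decay geometrically but
with different extension probabilities, giving a two-component mixture of
gap lengths.

``pair_posteriors`` computes, for every residue pair (x, y), the
probability over *all* alignments of the two sequences that x and y are
matched — the quantity the column score aggregates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from . import _dp
from .msa_io import AMBIGUOUS, AMINO_ACIDS, SYMBOL_INDEX
from .substitution import SUPPORTED_PAM, background_frequencies, match_emission

STATES = ("M", "X", "Y", "LX", "LY")

#: Structurally allowed transitions; everything else is fixed at zero.
_ALLOWED_MASK = np.array(
    [
        # M  X  Y  LX LY
        [1, 1, 1, 0, 0],  # M
        [1, 1, 0, 1, 0],  # X
        [1, 0, 1, 0, 1],  # Y
        [1, 0, 0, 1, 0],  # LX
        [1, 0, 0, 0, 1],  # LY
    ],
    dtype=bool,
)

_TOL = 1e-12

# Ambiguity-code membership used to extend the 20-letter emission tables.
_B_MEMBERS = ("N", "D")
_Z_MEMBERS = ("Q", "E")


@dataclass(frozen=True)
class PairHMMParams:
    """Transition and emission parameters of the pair HMM.

    ``trans`` is a 5x5 row matrix over ``STATES``; together with the
    per-state termination probability ``end`` each row sums to 1.
    ``match_emission``/``gap_emission`` are indexed by the 23-symbol
    alphabet (20 residues + B, Z, X) of :data:`almask.msa_io.SYMBOL_INDEX`.
    """

    trans: np.ndarray
    end: np.ndarray
    start: np.ndarray
    match_emission: np.ndarray
    gap_emission: np.ndarray
    pam_distance: int

    def validate(self) -> None:
        t = self.trans
        if t.shape != (5, 5):
            raise ValueError("transition matrix must be 5x5")
        if np.any(t < 0) or np.any(self.end < 0) or np.any(self.start < 0):
            raise ValueError("negative probability in HMM parameters")
        if np.any(t[~_ALLOWED_MASK] != 0):
            raise ValueError("transition set outside the allowed state graph")
        rows = t.sum(axis=1) + self.end
        if np.any(np.abs(rows - 1.0) > _TOL):
            raise ValueError(f"transition rows (incl. end) must sum to 1, got {rows}")
        if abs(self.start.sum() - 1.0) > 1e-9:
            raise ValueError("start distribution must sum to 1")
        core = self.match_emission[:20, :20]
        if abs(core.sum() - 1.0) > 1e-9 or not np.allclose(core, core.T):
            raise ValueError("match emissions must be a symmetric joint distribution")
        if abs(self.gap_emission[:20].sum() - 1.0) > 1e-9:
            raise ValueError("gap emissions must sum to 1")

    def with_match_emission(
        self, joint: np.ndarray, background: np.ndarray
    ) -> "PairHMMParams":
        """Replace the emission tables (e.g. for a reduced test alphabet)."""
        me, ge = _extend_emissions(joint, background)
        return replace(self, match_emission=me, gap_emission=ge)


def _extend_emissions(
    joint: np.ndarray, background: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Extend 20x20 joint emissions to the 23-symbol alphabet.

    B and Z emit the unweighted mean of their member residues; X emits the
    background mixture.
    """
    k = joint.shape[0]
    if k == 20:
        weights = []
        for code in AMBIGUOUS:
            w = np.zeros(20)
            if code == "B":
                members = _B_MEMBERS
            elif code == "Z":
                members = _Z_MEMBERS
            else:  # X
                w[:] = background
                weights.append(w)
                continue
            for aa in members:
                w[AMINO_ACIDS.index(aa)] = 1.0 / len(members)
            weights.append(w)
        w = np.vstack([np.eye(20), np.array(weights)])  # 23 x 20
    else:  # reduced alphabet used in tests: no ambiguity extension
        w = np.eye(k)
    me = w @ joint @ w.T
    ge = w @ background
    return me, ge


def default_params(
    pam_distance: int = 120,
    *,
    gap_open: float = 0.02,
    gap_extend: float = 0.6,
    long_open: float = 0.1,
    long_extend: float = 0.9,
    tau: float = 0.005,
) -> PairHMMParams:
    """Default pair-HMM parameterisation.

    Parameters
    ----------
    pam_distance : int
        PAM distance of the match-emission matrix (one of
        :data:`almask.substitution.SUPPORTED_PAM`).
    gap_open : float
        M -> X and M -> Y.
    gap_extend : float
        X -> X and Y -> Y; mean short-gap length 1/(1-gap_extend).
    long_open : float
        X -> LX and Y -> LY (long gaps are entered from short-gap states).
    long_extend : float
        LX -> LX and LY -> LY; mean long-gap extension 1/(1-long_extend).
    tau : float
        Per-step termination probability, 1/(mean emitted length).

    All remaining row mass returns to M.  The start distribution is the
    stationary distribution of the transition matrix conditioned on not
    terminating.
    """
    if pam_distance not in SUPPORTED_PAM:
        raise ValueError(
            f"unsupported PAM distance {pam_distance}; supported: {SUPPORTED_PAM}"
        )
    t = np.zeros((5, 5))
    t[0, 1] = t[0, 2] = gap_open
    t[0, 0] = 1.0 - 2.0 * gap_open - tau
    t[1, 1] = t[2, 2] = gap_extend
    t[1, 3] = t[2, 4] = long_open
    t[1, 0] = t[2, 0] = 1.0 - gap_extend - long_open - tau
    t[3, 3] = t[4, 4] = long_extend
    t[3, 0] = t[4, 0] = 1.0 - long_extend - tau
    if np.any(t < 0):
        raise ValueError("transition probabilities leave no mass to return to M")
    start = _stationary(t / (1.0 - tau))
    pi = background_frequencies()
    me, ge = _extend_emissions(match_emission(pam_distance), pi)
    params = PairHMMParams(
        trans=t,
        end=np.full(5, tau),
        start=start,
        match_emission=me,
        gap_emission=ge,
        pam_distance=pam_distance,
    )
    params.validate()
    return params


def _stationary(p: np.ndarray) -> np.ndarray:
    vals, vecs = np.linalg.eig(p.T)
    k = int(np.argmin(np.abs(vals - 1.0)))
    v = np.real(vecs[:, k])
    v = np.abs(v)
    return v / v.sum()


def encode(seq: str) -> np.ndarray:
    """Map an ungapped sequence to int64 symbol indices."""
    try:
        idx = np.array([SYMBOL_INDEX[c] for c in seq.upper()], dtype=np.int64)
    except KeyError as exc:
        raise ValueError(f"illegal residue {exc.args[0]!r}") from None
    if np.any(idx == SYMBOL_INDEX["-"]):
        raise ValueError("gap character in ungapped sequence")
    return idx


@dataclass(frozen=True)
class PosteriorTable:
    """Posterior match probabilities for one sequence pair."""

    probs: np.ndarray
    log_prob: float
    pair: tuple[int, int] | None = None


def _check(seq: str) -> None:
    if len(seq) == 0:
        raise ValueError("pair HMM requires non-empty sequences")


def _encoded(seq_a, seq_b) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(seq_a, str):
        _check(seq_a)
        seq_a = encode(seq_a)
    if isinstance(seq_b, str):
        _check(seq_b)
        seq_b = encode(seq_b)
    if len(seq_a) == 0 or len(seq_b) == 0:
        raise ValueError("pair HMM requires non-empty sequences")
    return np.asarray(seq_a, dtype=np.int64), np.asarray(seq_b, dtype=np.int64)


def _odds_emissions(params: PairHMMParams) -> tuple[np.ndarray, np.ndarray]:
    """Emissions as odds ratios against the background null model.

    Every complete path emits each residue of both sequences exactly once,
    so dividing each step's emission by the background probability of the
    residues it emits divides all path probabilities by one constant —
    posteriors are unchanged and the DP cells stay within float range even
    for long, dissimilar sequences.
    """
    q = params.gap_emission
    return params.match_emission / np.outer(q, q), np.ones_like(q)


def _background_prefix(params: PairHMMParams, a: np.ndarray) -> np.ndarray:
    """Cumulative log background probability of the first i residues."""
    out = np.zeros(len(a) + 1)
    out[1:] = np.cumsum(np.log(params.gap_emission[a]))
    return out


def forward(seq_a, seq_b, params: PairHMMParams) -> tuple[float, np.ndarray]:
    """Log full probability and log-space forward tables (5, m+1, n+1)."""
    a, b = _encoded(seq_a, seq_b)
    pmo, qo = _odds_emissions(params)
    F, cs, logp_odds = _dp.forward_tables(
        a, b, pmo, qo, params.trans, params.end, params.start
    )
    qa = _background_prefix(params, a)
    qb = _background_prefix(params, b)
    with np.errstate(divide="ignore"):
        logF = (
            np.log(F)
            + np.cumsum(cs)[None, :, None]
            + qa[None, :, None]
            + qb[None, None, :]
        )
    return float(logp_odds + qa[-1] + qb[-1]), logF


def backward(seq_a, seq_b, params: PairHMMParams) -> tuple[float, np.ndarray]:
    """Log full probability (via the backward pass) and log-space tables."""
    a, b = _encoded(seq_a, seq_b)
    pmo, qo = _odds_emissions(params)
    B, ds = _dp.backward_tables(a, b, pmo, qo, params.trans, params.end)
    qa = _background_prefix(params, a)
    qb = _background_prefix(params, b)
    dcum = np.cumsum(ds[::-1])[::-1]
    with np.errstate(divide="ignore"):
        logB = (
            np.log(B)
            + dcum[None, :, None]
            + (qa[-1] - qa)[None, :, None]
            + (qb[-1] - qb)[None, None, :]
        )
    logp = _backward_logp(a, b, params, logB)
    return float(logp), logB


def _backward_logp(a, b, params: PairHMMParams, logB: np.ndarray) -> float:
    pm, q = params.match_emission, params.gap_emission
    s = params.start
    terms = [
        math.log(s[0] * pm[a[0], b[0]]) + logB[0, 1, 1],
        math.log(s[1] * q[a[0]]) + logB[1, 1, 0],
        math.log(s[3] * q[a[0]]) + logB[3, 1, 0],
        math.log(s[2] * q[b[0]]) + logB[2, 0, 1],
        math.log(s[4] * q[b[0]]) + logB[4, 0, 1],
    ]
    hi = max(terms)
    return hi + math.log(sum(math.exp(t - hi) for t in terms))


def pair_posteriors(
    seq_a, seq_b, params: PairHMMParams, pair: tuple[int, int] | None = None
) -> PosteriorTable:
    """Posterior probability that residue x of A matches residue y of B.

    ``probs[x, y] = P(paths through M at (x, y)) / P(all paths)``; each row
    sum is at most 1, the residual being the probability that the residue
    is gapped.
    """
    a, b = _encoded(seq_a, seq_b)
    pmo, qo = _odds_emissions(params)
    F, cs, logp_odds = _dp.forward_tables(
        a, b, pmo, qo, params.trans, params.end, params.start
    )
    B, ds = _dp.backward_tables(a, b, pmo, qo, params.trans, params.end)
    ccum = np.cumsum(cs)
    dcum = np.cumsum(ds[::-1])[::-1]
    # the background constant of the odds transform cancels between
    # numerator and denominator, so logp_odds is the right normaliser
    with np.errstate(divide="ignore"):
        logpost = (
            np.log(F[0, 1:, 1:])
            + np.log(B[0, 1:, 1:])
            + (ccum[1:] + dcum[1:])[:, None]
            - logp_odds
        )
    probs = np.exp(logpost)
    np.clip(probs, 0.0, 1.0, out=probs)
    qa = _background_prefix(params, a)
    qb = _background_prefix(params, b)
    logp = float(logp_odds + qa[-1] + qb[-1])
    return PosteriorTable(probs=probs, log_prob=logp, pair=pair)
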