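"""Dayhoff/PAM amino-acid substitution model.

The package ships the classic Dayhoff exchangeability matrix and
equilibrium frequencies as plain-text data files.  From those we build the
reversible rate matrix Q (normalised to one expected substitution per site
per unit time) and the PAM-n transition matrices

    PAM_n = expm(n * t1 * Q),

where ``t1`` is calibrated so that PAM1 corresponds to an expected 1% of
sites substituted, matching the original definition of the PAM unit.  By
construction ``PAM_n`` equals the n-th matrix power of ``PAM1``.
"""

from __future__ import annotations

from functools import lru_cache
from importlib import resources

import numpy as np
from scipy.linalg import expm
from scipy.optimize import brentq

from .msa_io import AMINO_ACIDS

#: PAM distances exposed on the command line.
SUPPORTED_PAM = (30, 60, 120, 160, 250)


def _read_table(name: str) -> list[list[str]]:
    text = resources.files("almask.data").joinpath(name).read_text()
    return [
        line.split()
        for line in text.splitlines()
        if line.strip() and not line.startswith("#")
    ]


@lru_cache(maxsize=1)
def background_frequencies() -> np.ndarray:
    """Dayhoff equilibrium amino-acid frequencies (length 20, sums to 1)."""
    rows = _read_table("dayhoff_frequencies.txt")
    assert rows[0] == list(AMINO_ACIDS)
    pi = np.array([float(x) for x in rows[1]])
    return pi / pi.sum()


@lru_cache(maxsize=1)
def rate_matrix() -> np.ndarray:
    """Normalised reversible Dayhoff rate matrix Q (20x20).

    Q[a, b] = s[a, b] * pi[b] off the diagonal, rows sum to zero, and
    -sum_a pi_a Q[a, a] == 1.
    """
    rows = _read_table("dayhoff_exchangeabilities.txt")
    assert rows[0] == list(AMINO_ACIDS)
    s = np.array([[float(x) for x in r] for r in rows[1:]])
    if not np.allclose(s, s.T):
        raise ValueError("exchangeability matrix must be symmetric")
    pi = background_frequencies()
    q = s * pi[None, :]
    np.fill_diagonal(q, 0.0)
    np.fill_diagonal(q, -q.sum(axis=1))
    rate = -(pi * np.diag(q)).sum()
    return q / rate


@lru_cache(maxsize=1)
def _pam1_time() -> float:
    """Branch length at which the expected fraction of substituted sites is 1%."""
    q = rate_matrix()
    pi = background_frequencies()

    def diff(t: float) -> float:
        p = expm(q * t)
        return float((pi * (1.0 - np.diag(p))).sum()) - 0.01

    return brentq(diff, 1e-6, 0.1, xtol=1e-14)


@lru_cache(maxsize=None)
def pam_matrix(distance: int) -> np.ndarray:
    """PAM transition matrix P(a -> b) at the given PAM distance."""
    if distance < 1:
        raise ValueError(f"PAM distance must be >= 1, got {distance}")
    return expm(rate_matrix() * (_pam1_time() * distance))


def transition_matrix(t: float, rates: np.ndarray | None = None) -> np.ndarray:
    """P(t) = expm(Q t); with ``rates`` given, one matrix per site rate.

    Returns (20, 20) or (len(rates), 20, 20).  Uses the symmetrised
    eigendecomposition of Q, so per-site matrices cost one eigh total.
    """
    lam, v, vinv = _eigen()
    if rates is None:
        return (v * np.exp(lam * t)[None, :]) @ vinv
    tau = np.asarray(rates, dtype=float) * t
    e = np.exp(np.outer(tau, lam))  # (S, 20)
    return np.einsum("ak,sk,kb->sab", v, e, vinv, optimize=True)


@lru_cache(maxsize=1)
def _eigen() -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    q = rate_matrix()
    pi = background_frequencies()
    d = np.sqrt(pi)
    sym = (q * d[:, None]) / d[None, :]
    lam, u = np.linalg.eigh((sym + sym.T) / 2.0)
    v = u / d[:, None]
    vinv = u.T * d[None, :]
    return lam, v, vinv


def match_emission(distance: int) -> np.ndarray:
    """Joint match-emission probabilities p(a, b) = pi_a PAM_n[a, b].

    Symmetrised; exactly symmetric already for a reversible model, the
    averaging only removes floating-point asymmetry.  Sums to 1.
    """
    pi = background_frequencies()
    joint = pi[:, None] * pam_matrix(distance)
    joint = (joint + joint.T) / 2.0
    return joint / joint.sum()
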