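"""Column confidence scores, masking and column-weight export.

The confidence score of a column C is the weighted sum of pair posteriors

    S(C) = sum_{(i,j) in pairs} w_ij * P_ij(C) / sum_{(i,j) in pairs} w_ij

where ``P_ij(C)`` is the posterior probability that the residues of
sequences i and j in that column are matched (0 whenever either is a
gap), and ``w_ij`` are the guide-tree pair weights.  The denominator runs
over the full pair set, so gappy columns — exactly the regions masking is
meant to catch — score low, and every score lies in [0, 1].
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path

import numpy as np

from . import pair_hmm
from .guide_weights import GuideTree, pair_weights, tree_from_alignment
from .msa_io import Alignment, degap_pair
from .pair_hmm import PairHMMParams, default_params

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ColumnScores:
    """Per-column confidence scores plus the pair weighting that made them."""

    scores: np.ndarray
    pairs_used: tuple[tuple[int, int], ...]
    weights: np.ndarray

    def __post_init__(self) -> None:
        s = np.asarray(self.scores, dtype=float)
        if s.size and (s.min() < -1e-9 or s.max() > 1.0 + 1e-9):
            raise ValueError("column scores must lie in [0, 1]")


def sample_pairs(
    n: int, size: int | None, seed: int
) -> tuple[tuple[int, int], ...]:
    """Uniform sample (without replacement) of unordered sequence pairs.

    ``size`` is clamped up to ``n`` (at least one pair per sequence on
    average) and down to the total pair count.  ``size=None`` means all
    pairs.
    """
    all_pairs = list(combinations(range(n), 2))
    if size is None:
        return tuple(all_pairs)
    total = len(all_pairs)
    if size > total:
        logger.warning(
            "requested sample of %d exceeds the %d available pairs; "
            "using all pairs", size, total,
        )
        return tuple(all_pairs)
    if size < n:
        logger.warning("sample size %d raised to the minimum N = %d", size, n)
        size = n
    size = min(size, total)
    rng = np.random.default_rng(seed)
    chosen = rng.choice(total, size=size, replace=False)
    chosen.sort()
    return tuple(all_pairs[k] for k in chosen)


def column_score(
    column: str,
    posteriors: dict[tuple[int, int], "pair_hmm.PosteriorTable"],
    colmaps: dict[int, np.ndarray],
    weights: np.ndarray,
    pairs: tuple[tuple[int, int], ...],
    col_index: int,
) -> float:
    """Score one column from per-pair posterior tables (reference path).

    ``score_alignment`` computes all columns at once; this entry point
    exists for spot checks and small inputs.
    """
    num = 0.0
    den = 0.0
    for (i, j) in pairs:
        w = weights[i, j]
        den += w
        xi = colmaps[i][col_index]
        yj = colmaps[j][col_index]
        if xi >= 0 and yj >= 0 and (i, j) in posteriors:
            num += w * posteriors[(i, j)].probs[xi, yj]
    return num / den if den > 0 else 0.0


def score_alignment(
    aln: Alignment,
    params: PairHMMParams | None = None,
    tree: GuideTree | None = None,
    sample: int | None = None,
    seed: int = 0,
) -> ColumnScores:
    """Score every column of ``aln``.

    Full mode uses all N(N-1)/2 sequence pairs; with ``sample`` given, a
    seeded uniform subset of at least N pairs.  Posterior tables are
    computed once per pair and projected onto alignment columns through
    the degap position maps.
    """
    if aln.N < 2:
        raise ValueError("need at least two sequences to score an alignment")
    if params is None:
        params = default_params()
    if tree is None:
        tree = tree_from_alignment(aln)
    w = pair_weights(tree, aln.ids)
    pairs = sample_pairs(aln.N, sample, seed)
    if sum(w[i, j] for i, j in pairs) == 0.0:
        # degenerate family (all sequences identical): tree-derived weights
        # vanish, so weight the pairs uniformly instead of scoring 0
        logger.warning(
            "all pair weights are zero (identical sequences?); "
            "falling back to uniform pair weights"
        )
        w = np.ones_like(w)
    num = np.zeros(aln.L)
    den = 0.0
    cols = np.arange(aln.L)
    for (i, j) in pairs:
        wij = w[i, j]
        den += wij
        if wij == 0.0:
            continue
        seq_i, seq_j, map_i, map_j = degap_pair(aln, i, j)
        if not seq_i or not seq_j:
            continue  # an all-gap row cannot support any residue pair
        post = pair_hmm.pair_posteriors(seq_i, seq_j, params, pair=(i, j))
        both = (map_i >= 0) & (map_j >= 0)
        num[cols[both]] += wij * post.probs[map_i[both], map_j[both]]
    scores = num / den if den > 0 else np.zeros(aln.L)
    np.clip(scores, 0.0, 1.0, out=scores)
    return ColumnScores(scores=scores, pairs_used=pairs, weights=w)


def mask_alignment(
    aln: Alignment, scores: ColumnScores | np.ndarray, cutoff: float = 0.4
) -> tuple[Alignment, np.ndarray]:
    """Keep exactly the columns scoring at or above ``cutoff``."""
    if not 0.0 <= cutoff <= 1.0:
        raise ValueError(f"cutoff must be in [0, 1], got {cutoff}")
    s = scores.scores if isinstance(scores, ColumnScores) else np.asarray(scores)
    if len(s) != aln.L:
        raise ValueError("score vector length does not match alignment length")
    keep = np.flatnonzero(s >= cutoff)
    return aln.take_columns(keep), keep


def write_scores(scores: ColumnScores | np.ndarray, path: str | Path) -> None:
    """One score per line (column order, 6 decimal places)."""
    s = scores.scores if isinstance(scores, ColumnScores) else scores
    with open(path, "w") as fh:
        for val in s:
            fh.write(f"{val:.6f}\n")


def read_scores(path: str | Path) -> np.ndarray:
    return np.loadtxt(path, ndmin=1)


def export_weights(
    scores: ColumnScores | np.ndarray, path: str | Path, scale: int = 100
) -> None:
    """Integer column weights, ``round(score * scale)``, one line.

    The single-line whitespace-separated dialect is what maximum-
    likelihood tree programs accept as a column-weight file.
    """
    if scale < 1:
        raise ValueError(f"weight scale must be >= 1, got {scale}")
    s = scores.scores if isinstance(scores, ColumnScores) else scores
    ints = np.rint(np.asarray(s) * scale).astype(int)
    Path(path).write_text(" ".join(str(v) for v in ints) + "\n")
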