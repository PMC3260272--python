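"""Evaluation metrics for alignment masking.

All metrics reduce alignments to sets of aligned residue pairs in
*ungapped* coordinates — ``((id_a, x), (id_b, y))`` meaning residue x of
sequence a is in the same column as residue y of sequence b — which makes
two alignments of the same sequences directly comparable:

* masking sensitivity: fraction of correctly aligned residue pairs
  (present in both test and reference alignment) that fall in columns
  marked reliable;
* masking specificity: fraction of incorrectly aligned pairs (in the test
  but not the reference alignment) that fall in columns marked unreliable;
* discrepancy fraction: proportion of residue pairs paired differently
  between two alternative alignments (Jaccard distance of the pair sets),
  the head-or-tail measure of alignment uncertainty.
"""

from __future__ import annotations

import warnings

import numpy as np

from .msa_io import GAP, Alignment

ResiduePair = tuple[tuple[str, int], tuple[str, int]]


def extract_pairs(aln: Alignment) -> set[ResiduePair]:
    """Aligned residue pairs of ``aln`` in ungapped coordinates.

    One entry per unordered sequence pair per column where both symbols
    are residues; pairs are canonically ordered by sequence id.
    """
    return set(_pairs_with_columns(aln))


def _pairs_with_columns(aln: Alignment) -> dict[ResiduePair, int]:
    """Each residue pair mapped to the (unique) column it occupies."""
    counters = np.zeros(aln.N, dtype=int)
    out: dict[ResiduePair, int] = {}
    order = sorted(range(aln.N), key=lambda i: aln.ids[i])
    for k in range(aln.L):
        col = aln.column(k)
        present = [i for i in order if col[i] != GAP]
        for a_pos, i in enumerate(present):
            for j in present[a_pos + 1:]:
                out[((aln.ids[i], int(counters[i])), (aln.ids[j], int(counters[j])))] = k
        for i in present:
            counters[i] += 1
    return out


def _check_same_sequences(a: Alignment, b: Alignment) -> None:
    if set(a.ids) != set(b.ids):
        missing = sorted(set(a.ids) ^ set(b.ids))
        raise ValueError(f"alignments disagree on sequence ids: {missing}")
    for sid in a.ids:
        sa = a.degapped_row(a.ids.index(sid))
        sb = b.degapped_row(b.ids.index(sid))
        if sa != sb:
            raise ValueError(
                f"sequence {sid!r} differs between the two alignments "
                "after removing gaps"
            )


def masking_sensitivity(
    test: Alignment, ref: Alignment, reliable_cols: np.ndarray
) -> float:
    """Fraction of correctly aligned residue pairs in reliable columns.

    ``reliable_cols`` is a boolean flag per column of the *test*
    alignment.  NaN (with a warning) if the alignments share no pair.
    """
    _check_same_sequences(test, ref)
    flags = np.asarray(reliable_cols, dtype=bool)
    test_pairs = _pairs_with_columns(test)
    ref_pairs = extract_pairs(ref)
    correct = [c for p, c in test_pairs.items() if p in ref_pairs]
    if not correct:
        warnings.warn("no correctly aligned pairs; sensitivity undefined")
        return float("nan")
    hits = sum(1 for c in correct if flags[c])
    return hits / len(correct)


def masking_specificity(
    test: Alignment, ref: Alignment, reliable_cols: np.ndarray
) -> float:
    """Fraction of incorrectly aligned residue pairs in unreliable columns.

    NaN (with a warning) when the test alignment contains no incorrect
    pair.
    """
    _check_same_sequences(test, ref)
    flags = np.asarray(reliable_cols, dtype=bool)
    test_pairs = _pairs_with_columns(test)
    ref_pairs = extract_pairs(ref)
    wrong = [c for p, c in test_pairs.items() if p not in ref_pairs]
    if not wrong:
        warnings.warn("no incorrectly aligned pairs; specificity undefined")
        return float("nan")
    hits = sum(1 for c in wrong if not flags[c])
    return hits / len(wrong)


def restricted_pairs(aln: Alignment, reliable_cols: np.ndarray) -> set[ResiduePair]:
    """Residue pairs of ``aln`` occupying columns flagged reliable.

    Residue indices stay in the coordinates of the full (unmasked)
    sequences, so sets from differently masked alignments of the same
    sequences remain comparable.
    """
    flags = np.asarray(reliable_cols, dtype=bool)
    if len(flags) != aln.L:
        raise ValueError("reliability flags do not match alignment length")
    return {p for p, c in _pairs_with_columns(aln).items() if flags[c]}


def discrepancy_fraction(
    aln_head: Alignment,
    aln_tail: Alignment,
    reliable_head: np.ndarray | None = None,
    reliable_tail: np.ndarray | None = None,
) -> float:
    """Proportion of residue pairs paired differently in two alignments.

    Jaccard distance ``1 - |P_h & P_t| / |P_h | P_t|`` of the residue-pair
    sets; 0 when both alignments contain no residue pair at all.  With
    reliability flags given, each alignment contributes only the pairs in
    its reliable (kept) columns — the masked form of the metric.
    """
    _check_same_sequences(aln_head, aln_tail)
    ph = (
        extract_pairs(aln_head)
        if reliable_head is None
        else restricted_pairs(aln_head, reliable_head)
    )
    pt = (
        extract_pairs(aln_tail)
        if reliable_tail is None
        else restricted_pairs(aln_tail, reliable_tail)
    )
    union = ph | pt
    if not union:
        return 0.0
    return 1.0 - len(ph & pt) / len(union)
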