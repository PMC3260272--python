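"""Aligned-FASTA input/output and the alignment data model.

The :class:`Alignment` is the container every other module consumes: an
ordered set of equal-length gapped protein sequences.  Only ``-`` is
accepted as the gap character; ``.`` and ``*`` are rejected so that format
mistakes surface immediately rather than as silently wrong scores.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

#: Canonical residue order used by all substitution-model tables.
AMINO_ACIDS = "ARNDCQEGHILKMFPSTWYV"

#: Ambiguity codes accepted on input (B = N/D, Z = Q/E, X = unknown).
AMBIGUOUS = "BZX"

GAP = "-"

_ALLOWED = frozenset(AMINO_ACIDS + AMBIGUOUS + GAP)

#: Symbol -> integer index.  0..19 are the canonical residues, 20..22 the
#: ambiguity codes, 23 the gap.
SYMBOL_INDEX = {c: k for k, c in enumerate(AMINO_ACIDS + AMBIGUOUS + GAP)}
GAP_INDEX = SYMBOL_INDEX[GAP]


class AlignmentFormatError(ValueError):
    """Raised for malformed aligned FASTA input."""


@dataclass(frozen=True)
class Alignment:
    """An ordered protein multiple sequence alignment.

    Parameters
    ----------
    ids : tuple of str
        Unique sequence identifiers, in file order.
    rows : tuple of str
        Gapped sequences (upper case), all of identical length.
    """

    ids: tuple[str, ...]
    rows: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise AlignmentFormatError("ids and rows differ in count")
        if len(set(self.ids)) != len(self.ids):
            seen: set[str] = set()
            for i in self.ids:
                if i in seen:
                    raise AlignmentFormatError(f"duplicate sequence id: {i!r}")
                seen.add(i)
        rows = tuple(r.upper() for r in self.rows)
        object.__setattr__(self, "rows", rows)
        lengths = {len(r) for r in rows}
        if len(lengths) > 1:
            raise AlignmentFormatError(
                f"ragged alignment: row lengths {sorted(lengths)} differ"
            )
        for sid, row in zip(self.ids, rows):
            for pos, ch in enumerate(row):
                if ch not in _ALLOWED:
                    raise AlignmentFormatError(
                        f"illegal character {ch!r} in sequence {sid!r} "
                        f"at column {pos + 1}"
                    )

    @property
    def N(self) -> int:
        """Number of sequences."""
        return len(self.ids)

    @property
    def L(self) -> int:
        """Number of alignment columns."""
        return len(self.rows[0]) if self.rows else 0

    def column(self, k: int) -> str:
        """The ``N`` symbols of column ``k`` (0-based)."""
        return "".join(r[k] for r in self.rows)

    def columns(self) -> Iterator[str]:
        for k in range(self.L):
            yield self.column(k)

    def to_indices(self) -> np.ndarray:
        """(N, L) int8 matrix of symbol indices (see :data:`SYMBOL_INDEX`)."""
        out = np.empty((self.N, self.L), dtype=np.int8)
        for i, row in enumerate(self.rows):
            out[i] = [SYMBOL_INDEX[c] for c in row]
        return out

    def take_columns(self, keep: "list[int] | np.ndarray") -> "Alignment":
        """A new alignment containing only columns ``keep`` (in order)."""
        keep = list(keep)
        rows = tuple("".join(r[k] for k in keep) for r in self.rows)
        return Alignment(self.ids, rows)

    def degapped_row(self, i: int) -> str:
        return self.rows[i].replace(GAP, "")


@dataclass(frozen=True)
class Column:
    """A single alignment column."""

    index: int
    residues: str


def read_alignment(path: str | Path) -> Alignment:
    """Read an aligned FASTA file.

    Sequences are case-folded to upper case.  Raises
    :class:`AlignmentFormatError` on ragged rows, duplicate identifiers,
    illegal characters or fewer than two records.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) < 2:
        raise AlignmentFormatError(
            f"{path}: need at least 2 FASTA records, found {len(records)}"
        )
    ids = tuple(r.id for r in records)
    rows = tuple(str(r.seq) for r in records)
    return Alignment(ids, rows)


def write_alignment(aln: Alignment, path: str | Path) -> None:
    """Write ``aln`` as aligned FASTA (one line per sequence)."""
    records = [
        SeqRecord(Seq(row), id=sid, description="")
        for sid, row in zip(aln.ids, aln.rows)
    ]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta-2line")


def degap_row(row: str) -> tuple[str, np.ndarray]:
    """Remove gaps from ``row``.

    Returns the ungapped sequence and a length-L int map where entry ``k``
    is the ungapped residue index of column ``k``, or -1 at a gap.
    """
    colmap = np.full(len(row), -1, dtype=np.int64)
    chars = []
    for k, ch in enumerate(row):
        if ch != GAP:
            colmap[k] = len(chars)
            chars.append(ch)
    return "".join(chars), colmap


def degap_pair(
    aln: Alignment, i: int, j: int
) -> tuple[str, str, np.ndarray, np.ndarray]:
    """Ungapped sequences ``S_i``, ``S_j`` plus column -> residue maps.

    The pair-HMM operates on ungapped sequences; the returned maps project
    its posterior tables back onto alignment columns.
    """
    if i == j:
        raise ValueError(f"degap_pair requires two distinct rows, got i == j == {i}")
    seq_i, map_i = degap_row(aln.rows[i])
    seq_j, map_j = degap_row(aln.rows[j])
    return seq_i, seq_j, map_i, map_j
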