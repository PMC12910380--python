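"""Aligned-FASTA input, validation and reference-position indexing.

The :class:`Alignment` is the single source of truth for every profile
downstream: an ordered set of equal-length, upper-cased, gapped protein
sequences with unique identifiers.  Columns and reference residues are
1-based everywhere they face the user.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ._alphabet import (
    AMBIGUOUS_CODE,
    GAP_CODE,
    STANDARD_RESIDUES,
    encode,
)

logger = logging.getLogger(__name__)

__all__ = [
    "Alignment",
    "PositionMap",
    "ResidueCounts",
    "read_msa",
    "write_msa",
    "map_reference_positions",
    "column_composition",
]


class AlignmentShapeError(ValueError):
    """Sequences of unequal length."""


class AlignmentSizeError(ValueError):
    """Fewer than two sequences."""


class AlignmentCharacterError(ValueError):
    """A sequence contains a letter outside the protein alphabet."""


@dataclass(frozen=True)
class Alignment:
    """An in-memory protein MSA.

    Attributes
    ----------
    ids : tuple of str
        Record identifiers (FASTA header up to first whitespace), unique.
    sequences : tuple of str
        Upper-cased gapped sequences, all of length ``n_columns``.
    descriptions : tuple of str
        Full FASTA headers, one per record.
    codes : numpy int8 array, shape (n_sequences, n_columns)
        Integer-encoded residues (see :mod:`teao._alphabet`).
    """

    ids: tuple[str, ...]
    sequences: tuple[str, ...]
    descriptions: tuple[str, ...] = ()
    codes: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if len(self.ids) < 2:
            raise AlignmentSizeError(
                f"an alignment needs at least 2 sequences, got {len(self.ids)}"
            )
        lengths = {len(s) for s in self.sequences}
        if len(lengths) != 1:
            offender = next(
                i for i, s in zip(self.ids, self.sequences)
                if len(s) != len(self.sequences[0])
            )
            raise AlignmentShapeError(
                f"ragged alignment: record {offender!r} has length "
                f"{dict(zip(self.ids, map(len, self.sequences)))[offender]}, "
                f"expected {len(self.sequences[0])}"
            )
        if lengths == {0}:
            raise AlignmentShapeError("alignment has zero columns")
        seen: set[str] = set()
        for i in self.ids:
            if i in seen:
                raise ValueError(f"duplicate identifier {i!r}")
            seen.add(i)
        if not self.descriptions:
            object.__setattr__(self, "descriptions", self.ids)
        if self.codes is None:
            rows = []
            for ident, seq in zip(self.ids, self.sequences):
                try:
                    rows.append(encode(seq))
                except ValueError as exc:
                    raise AlignmentCharacterError(f"record {ident!r}: {exc}") from None
            object.__setattr__(self, "codes", np.vstack(rows))

    @property
    def n_sequences(self) -> int:
        return len(self.ids)

    @property
    def n_columns(self) -> int:
        return len(self.sequences[0])

    def index_of(self, identifier: str) -> int:
        try:
            return self.ids.index(identifier)
        except ValueError:
            raise KeyError(
                f"identifier {identifier!r} not in alignment; available: "
                f"{', '.join(self.ids[:10])}"
                + ("..." if self.n_sequences > 10 else "")
            ) from None

    def subset(self, keep: Iterable[str]) -> "Alignment":
        """New alignment with the given identifiers, original order kept."""
        keep_set = set(keep)
        idx = [i for i, ident in enumerate(self.ids) if ident in keep_set]
        if len(idx) < 2:
            raise AlignmentSizeError(
                f"subset keeps only {len(idx)} sequence(s); at least 2 required"
            )
        return Alignment(
            ids=tuple(self.ids[i] for i in idx),
            sequences=tuple(self.sequences[i] for i in idx),
            descriptions=tuple(self.descriptions[i] for i in idx),
            codes=self.codes[idx],
        )


@dataclass(frozen=True)
class PositionMap:
    """Column <-> reference-residue numbering for one reference sequence.

    ``column_to_residue[c-1]`` is the 1-based residue number of alignment
    column ``c`` in the ungapped reference, or 0 where the reference has a
    gap.  ``residue_to_column`` is the strictly increasing inverse.
    """

    reference_id: str
    column_to_residue: np.ndarray  # int, 0 = unmapped
    residue_to_column: np.ndarray  # 1-based columns, strictly increasing

    @property
    def n_mapped(self) -> int:
        return len(self.residue_to_column)

    def residue_of(self, column: int) -> int | None:
        r = int(self.column_to_residue[column - 1])
        return r or None

    def column_of(self, residue: int) -> int:
        if not 1 <= residue <= self.n_mapped:
            raise IndexError(
                f"residue {residue} outside reference range 1..{self.n_mapped}"
            )
        return int(self.residue_to_column[residue - 1])


@dataclass(frozen=True)
class ResidueCounts:
    """Residue tally of one alignment column (gaps/ambiguity kept apart)."""

    column_index: int
    counts: Mapping[str, int]
    n_gap: int
    n_ambiguous: int

    @property
    def n_residues(self) -> int:
        return sum(self.counts.values())

    @property
    def n_distinct(self) -> int:
        return sum(1 for v in self.counts.values() if v > 0)


def read_msa(path: str | Path) -> Alignment:
    """Read and validate an aligned FASTA file.

    Sequences are upper-cased, ``.`` gaps normalised to ``-``; identifiers
    are the header up to the first whitespace and must be unique.
    """
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise AlignmentSizeError(f"{path}: no FASTA records found")
    ids = tuple(r.id for r in records)
    seqs = tuple(str(r.seq).upper().replace(".", "-") for r in records)
    descriptions = tuple(r.description for r in records)
    return Alignment(ids=ids, sequences=seqs, descriptions=descriptions)


def write_msa(aln: Alignment, path: str | Path, wrap: int = 60) -> None:
    """Write aligned FASTA, ``wrap`` characters per sequence line."""
    records = [
        SeqRecord(Seq(seq), id=ident, description=desc if desc != ident else "")
        for ident, seq, desc in zip(aln.ids, aln.sequences, aln.descriptions)
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=wrap)
        writer.write_file(records)


def map_reference_positions(aln: Alignment, reference_id: str | None = None) -> PositionMap:
    """Map alignment columns to 1-based residue numbers of a reference row.

    Falls back to the first record (logged) when ``reference_id`` is None.
    """
    if reference_id is None:
        reference_id = aln.ids[0]
        logger.info("no reference given; using first record %r", reference_id)
    row = aln.codes[aln.index_of(reference_id)]
    is_res = row != GAP_CODE  # ambiguity codes still occupy a residue position
    col_to_res = np.zeros(aln.n_columns, dtype=np.int64)
    col_to_res[is_res] = np.arange(1, int(is_res.sum()) + 1)
    res_to_col = np.nonzero(is_res)[0] + 1
    if res_to_col.size == 0:
        logger.warning("reference %r is all gaps: empty position map", reference_id)
    return PositionMap(
        reference_id=reference_id,
        column_to_residue=col_to_res,
        residue_to_column=res_to_col,
    )


def column_composition(aln: Alignment, column_index: int) -> ResidueCounts:
    """Tally one column: standard-residue counts plus gap/ambiguity totals."""
    if not 1 <= column_index <= aln.n_columns:
        raise IndexError(
            f"column {column_index} out of range 1..{aln.n_columns}"
        )
    col = aln.codes[:, column_index - 1]
    binc = np.bincount(col, minlength=22)
    counts = {
        STANDARD_RESIDUES[i]: int(binc[i]) for i in range(20) if binc[i] > 0
    }
    return ResidueCounts(
        column_index=column_index,
        counts=counts,
        n_gap=int(binc[GAP_CODE]),
        n_ambiguous=int(binc[AMBIGUOUS_CODE]),
    )
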