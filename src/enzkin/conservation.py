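"""Alignment-column conservation mapped to reference-sequence numbering.

Given a protein multiple alignment, finds the columns whose residue is
invariant (or conserved above a threshold) and reports them as 1-based
positions of a chosen reference sequence — the procedure that turns a
family alignment into a shortlist of candidate catalytic residues
("Lys21"-style) for mutagenesis.

Alignment construction itself (family retrieval, realignment) is out of
scope; any aligned FASTA is accepted.
"""

from __future__ import annotations

import io
import os
from collections import Counter
from dataclasses import dataclass
from typing import Union

from Bio import AlignIO

__all__ = [
    "AlignmentError",
    "MultipleAlignment",
    "ConservationResult",
    "read_alignment",
    "map_columns_to_reference",
    "find_conserved",
    "conservation_tsv",
]

GAP = "-"


class AlignmentError(ValueError):
    """Malformed alignment input."""


@dataclass(frozen=True)
class MultipleAlignment:
    """Ordered (id, gapped sequence) records of equal length."""

    records: tuple

    def __post_init__(self) -> None:
        if not self.records:
            raise AlignmentError("alignment has no records")
        lengths = {len(seq) for _, seq in self.records}
        if len(lengths) != 1:
            raise AlignmentError("ragged alignment: sequences differ in length")
        ids = [rid for rid, _ in self.records]
        if len(set(ids)) != len(ids):
            raise AlignmentError("duplicate sequence ids in alignment")

    @property
    def length(self) -> int:
        return len(self.records[0][1])

    @property
    def ids(self) -> tuple:
        return tuple(rid for rid, _ in self.records)

    def sequence(self, rid: str) -> str:
        for r, seq in self.records:
            if r == rid:
                return seq
        raise AlignmentError(f"unknown sequence id {rid!r}")

    def to_fasta(self) -> str:
        return "".join(f">{rid}\n{seq}\n" for rid, seq in self.records)


@dataclass(frozen=True)
class ConservationResult:
    """Conserved positions in reference numbering.

    ``entries`` holds (reference_position 1-based, residue, column_index
    0-based, identity_fraction) tuples in increasing position order.
    """

    entries: tuple

    @property
    def positions(self) -> tuple:
        return tuple(e[0] for e in self.entries)

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)


def read_alignment(source: Union[str, os.PathLike, io.TextIOBase]) -> MultipleAlignment:
    """Parse aligned FASTA (path, file handle, or raw text starting with '>')."""
    if isinstance(source, str) and (
        source.lstrip().startswith(">") or "\n" in source or not source.strip()
    ):
        return _parse_handle(io.StringIO(source))
    if hasattr(source, "read"):
        return _parse_handle(source)
    with open(source, "r", encoding="utf-8") as fh:
        return _parse_handle(fh)


def _parse_handle(handle) -> MultipleAlignment:
    try:
        aln = AlignIO.read(handle, "fasta")
    except ValueError as exc:
        raise AlignmentError(f"cannot parse alignment: {exc}") from exc
    return MultipleAlignment(
        records=tuple((rec.id, str(rec.seq).upper()) for rec in aln)
    )


def map_columns_to_reference(aln: MultipleAlignment, ref_id: str) -> dict[int, int]:
    """0-based column -> 1-based reference residue number; gap columns unmapped.

    Position k counts the non-gap reference characters up to and including
    the column, so an ungapped reference of length L maps columns 0..L-1 to
    1..L.  The mapping is injective on mapped columns.
    """
    ref = aln.sequence(ref_id)
    mapping: dict[int, int] = {}
    pos = 0
    for col, char in enumerate(ref):
        if char != GAP:
            pos += 1
            mapping[col] = pos
    return mapping


def find_conserved(
    aln: MultipleAlignment,
    ref_id: str,
    threshold: float = 1.0,
    ignore_gaps: bool = False,
) -> ConservationResult:
    """Reference-mapped columns whose most frequent residue reaches ``threshold``.

    At threshold 1.0 with ``ignore_gaps=False`` a single gap or mismatch
    disqualifies a column (a residue absent from any family member is not
    100% conserved).  With ``ignore_gaps=True`` gapped rows are dropped
    from the column's denominator.  Comparison is case-insensitive and the
    unknown-residue code 'X' never counts toward the consensus.
    """
    if not 0.0 < threshold <= 1.0:
        raise AlignmentError("threshold must be in (0, 1]")
    mapping = map_columns_to_reference(aln, ref_id)
    n_rows = len(aln.records)
    entries = []
    for col, ref_pos in mapping.items():
        column = [seq[col].upper() for _, seq in aln.records]
        denom = n_rows
        if ignore_gaps:
            column = [c for c in column if c != GAP]
            denom = len(column)
            if denom == 0:
                continue
        counts = Counter(c for c in column if c not in (GAP, "X"))
        if not counts:
            continue
        residue, count = counts.most_common(1)[0]
        fraction = count / denom
        if fraction >= threshold:
            entries.append((ref_pos, residue, col, fraction))
    entries.sort(key=lambda e: e[0])
    return ConservationResult(entries=tuple(entries))


def conservation_tsv(result: ConservationResult) -> str:
    """TSV rendering: reference_position, residue, column_index, identity_fraction."""
    lines = ["reference_position\tresidue\tcolumn_index\tidentity_fraction"]
    for pos, residue, col, frac in result:
        lines.append(f"{pos}\t{residue}\t{col}\t{frac:.6g}")
    return "\n".join(lines) + "\n"
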