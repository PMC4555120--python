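"""Alignment curation: reference-coordinate truncation, redundancy and
quality culling, and the census of major shared indels.

All residue coordinates are 1-based inclusive and expressed in the ungapped
numbering of a named reference sequence (the style "Asp36-Ser79" used for
human VKORC1), so a span survives re-slicing of the alignment.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Sequence

from .io_formats import GAP, Alignment, SequenceRecord

_GAP_RUN = re.compile(r"-+")


@dataclass(frozen=True)
class ReferenceSpan:
    """A residue span in the ungapped numbering of a reference sequence."""

    ref_id: str
    start: int
    end: int

    def __post_init__(self):
        if not 1 <= self.start <= self.end:
            raise ValueError(f"invalid span {self.start}..{self.end}")

    @property
    def n_positions(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class IndelBlock:
    """A maximal gap run with an identical column span shared by >= 2 rows."""

    col_start: int
    col_end: int
    member_ids: tuple[str, ...]

    @property
    def length(self) -> int:
        return self.col_end - self.col_start + 1


@dataclass(frozen=True)
class Removal:
    id: str
    reason: str


def map_reference_positions(alignment: Alignment, ref_id: str) -> dict[int, int]:
    """Map ungapped residue numbers of ``ref_id`` to 1-based alignment columns."""
    row = alignment[ref_id].residues  # KeyError if absent
    mapping: dict[int, int] = {}
    pos = 0
    for col, ch in enumerate(row, start=1):
        if ch != GAP:
            pos += 1
            mapping[pos] = col
    return mapping


def column_to_reference(alignment: Alignment, ref_id: str) -> dict[int, int]:
    """Inverse of :func:`map_reference_positions` over non-gap columns."""
    return {col: pos for pos, col in map_reference_positions(alignment, ref_id).items()}


def truncate_to_region(alignment: Alignment, span: ReferenceSpan) -> Alignment:
    """Keep the alignment columns delimited by a reference-coordinate span.

    The result contains every row, sliced from the column of ``span.start``
    to the column of ``span.end`` (inclusive); the number of non-gap
    reference positions in the result is exactly ``span.n_positions``.
    """
    mapping = map_reference_positions(alignment, span.ref_id)
    if span.end > len(mapping):
        raise IndexError(
            f"span {span.start}..{span.end} exceeds reference length {len(mapping)}"
        )
    return alignment.slice_columns(mapping[span.start], mapping[span.end])


def cull_redundant(
    records: Sequence[SequenceRecord],
    required_motifs: Iterable[str] = (),
    span: ReferenceSpan | None = None,
    alignment: Alignment | None = None,
) -> tuple[list[SequenceRecord], list[Removal]]:
    """Remove duplicates, span-incomplete records and motif-less records.

    * exact duplicate residue strings: first record (input order) survives;
    * when ``span`` is given (with the containing ``alignment``), any record
      with a gap or 'X' inside the span's columns is removed as partial —
      it does not fully encompass the region of interest;
    * ``required_motifs`` are regular expressions over the amino-acid
      alphabet (e.g. ``"C..C"``); a record whose ungapped sequence lacks any
      of them is removed.

    Returns the survivors (input order) and a removal report.
    """
    if not records:
        raise ValueError("no records to cull")
    motifs = [re.compile(m) for m in required_motifs]
    span_cols: tuple[int, int] | None = None
    if span is not None:
        if alignment is None:
            alignment = Alignment(list(records))
        mapping = map_reference_positions(alignment, span.ref_id)
        if span.end > len(mapping):
            raise IndexError("span exceeds reference length")
        span_cols = (mapping[span.start], mapping[span.end])

    survivors: list[SequenceRecord] = []
    removals: list[Removal] = []
    seen: set[str] = set()
    for rec in records:
        if rec.residues in seen:
            removals.append(Removal(rec.id, "duplicate"))
            continue
        if span_cols is not None:
            region = rec.residues[span_cols[0] - 1 : span_cols[1]]
            if GAP in region or "X" in region:
                removals.append(Removal(rec.id, "partial: incomplete over span"))
                continue
        ungapped = rec.ungapped
        missing = [m.pattern for m in motifs if not m.search(ungapped)]
        if missing:
            removals.append(Removal(rec.id, f"missing motif(s): {','.join(missing)}"))
            continue
        seen.add(rec.residues)
        survivors.append(rec)
    return survivors, removals


def _gap_runs(row: str) -> list[tuple[int, int]]:
    """1-based inclusive (start, end) spans of maximal gap runs in a row."""
    return [(m.start() + 1, m.end()) for m in _GAP_RUN.finditer(row)]


def census_indels(
    alignment: Alignment,
    min_len: int = 2,
    min_members: int = 2,
    exclude_terminal: bool = True,
) -> list[IndelBlock]:
    """Count major shared indels: maximal gap runs with identical column
    spans shared by at least ``min_members`` rows and at least ``min_len``
    columns long.

    A run is "terminal" for a row when it touches the row's first or last
    alignment column; such runs are excluded by default because they can
    reflect incomplete sequence reads rather than evolutionary indels.
    Single-column gaps are excluded by the default ``min_len=2``.
    """
    if len(alignment) < 2:
        raise ValueError("indel census needs >= 2 rows")
    ncol = alignment.n_columns
    spans: dict[tuple[int, int], list[str]] = {}
    for rec in alignment:
        for start, end in _gap_runs(rec.residues):
            if exclude_terminal and (start == 1 or end == ncol):
                continue
            spans.setdefault((start, end), []).append(rec.id)
    blocks = [
        IndelBlock(start, end, tuple(ids))
        for (start, end), ids in spans.items()
        if end - start + 1 >= min_len and len(ids) >= min_members
    ]
    blocks.sort(key=lambda b: (b.col_start, b.col_end))
    return blocks
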