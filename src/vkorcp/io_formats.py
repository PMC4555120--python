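"""Readers and writers for the formats the pipeline touches.

Three formats are supported: FASTA (aligned or unaligned protein sequences),
newick trees (via dendropy, with bootstrap supports stored as internal node
labels), and fixed-column PDB coordinate records.  The FASTA and PDB parsers
are deliberately strict: they validate the residue alphabet and the numeric
fields and report the offending line number instead of silently repairing
input, because downstream stages (likelihoods, contact extraction) assume
clean data.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import dendropy

#: The 20 standard amino acids in the conventional PAML ordering used by the
#: embedded substitution matrices.
AMINO_ACIDS = "ARNDCQEGHILKMFPSTWYV"

#: Characters legal in a residue string.  'X' is unknown, '-' a gap; neither
#: ever counts as identity or conservation evidence.
RESIDUE_ALPHABET = frozenset(AMINO_ACIDS + "X-")

GAP = "-"
UNKNOWN = "X"
MISSING = frozenset({GAP, UNKNOWN})


class ParseError(ValueError):
    """Malformed input; carries the 1-based line number when known."""

    def __init__(self, message: str, line: int | None = None):
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
        self.line = line


@dataclass(frozen=True)
class SequenceRecord:
    """One protein sequence (possibly gapped) with its FASTA identity."""

    id: str
    residues: str
    description: str = ""

    def __post_init__(self):
        if not self.id:
            raise ValueError("sequence id must be non-empty")
        bad = set(self.residues) - RESIDUE_ALPHABET
        if bad:
            raise ValueError(
                f"record {self.id!r}: illegal residue character(s) {sorted(bad)}"
            )

    @property
    def ungapped(self) -> str:
        return self.residues.replace(GAP, "")

    def __len__(self) -> int:
        return len(self.residues)


class Alignment:
    """An ordered collection of equal-length gapped sequence records."""

    def __init__(self, records: Sequence[SequenceRecord]):
        records = list(records)
        if not records:
            raise ValueError("alignment needs at least one record")
        ncol = len(records[0].residues)
        if ncol < 1:
            raise ValueError("alignment columns must be >= 1")
        seen: set[str] = set()
        for rec in records:
            if len(rec.residues) != ncol:
                raise ValueError(
                    f"record {rec.id!r} has length {len(rec.residues)}, "
                    f"expected {ncol}"
                )
            if rec.id in seen:
                raise ValueError(f"duplicate sequence id {rec.id!r}")
            seen.add(rec.id)
        self.records: list[SequenceRecord] = records
        self.n_columns: int = ncol

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __getitem__(self, sequence_id: str) -> SequenceRecord:
        for rec in self.records:
            if rec.id == sequence_id:
                return rec
        raise KeyError(sequence_id)

    @property
    def ids(self) -> list[str]:
        return [rec.id for rec in self.records]

    def column(self, col: int) -> str:
        """Residues of 1-based column ``col`` in record order."""
        if not 1 <= col <= self.n_columns:
            raise IndexError(f"column {col} outside 1..{self.n_columns}")
        return "".join(rec.residues[col - 1] for rec in self.records)

    def slice_columns(self, col_start: int, col_end: int) -> "Alignment":
        """Sub-alignment over 1-based inclusive columns [col_start, col_end]."""
        if not 1 <= col_start <= col_end <= self.n_columns:
            raise IndexError(
                f"columns {col_start}..{col_end} outside 1..{self.n_columns}"
            )
        return Alignment(
            [
                SequenceRecord(r.id, r.residues[col_start - 1 : col_end], r.description)
                for r in self.records
            ]
        )

    def subset(self, keep_ids: Iterable[str]) -> "Alignment":
        keep = set(keep_ids)
        missing = keep - set(self.ids)
        if missing:
            raise KeyError(f"ids not in alignment: {sorted(missing)}")
        return Alignment([r for r in self.records if r.id in keep])


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(source: str | Path | io.TextIOBase) -> list[SequenceRecord]:
    """Parse FASTA records, validating the residue alphabet.

    Raises :class:`ParseError` (with the line number) on content before the
    first header, on an empty header, or on an illegal residue character.
    Lowercase residues are normalized to uppercase.
    """
    if isinstance(source, (str, Path)):
        with open(source) as handle:
            return read_fasta(handle)
    records: list[SequenceRecord] = []
    header: tuple[str, str] | None = None
    chunks: list[str] = []
    header_line = 0

    def flush():
        if header is None:
            return
        seq = "".join(chunks)
        if not seq:
            raise ParseError(f"record {header[0]!r} has no residues", header_line)
        records.append(SequenceRecord(header[0], seq, header[1]))

    for lineno, raw in enumerate(source, start=1):
        line = raw.rstrip("\n").rstrip("\r")
        if not line.strip():
            continue
        if line.startswith(">"):
            flush()
            token = line[1:].strip()
            if not token:
                raise ParseError("empty FASTA header", lineno)
            parts = token.split(None, 1)
            header = (parts[0], parts[1] if len(parts) > 1 else "")
            header_line = lineno
            chunks = []
        else:
            if header is None:
                raise ParseError("sequence data before any '>' header", lineno)
            seq = line.strip().upper()
            bad = set(seq) - RESIDUE_ALPHABET
            if bad:
                raise ParseError(
                    f"illegal residue character(s) {sorted(bad)}", lineno
                )
            chunks.append(seq)
    flush()
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ParseError(f"duplicate sequence id(s): {dupes}")
    return records


def write_fasta(
    records: Iterable[SequenceRecord],
    dest: str | Path | io.TextIOBase,
    width: int = 60,
) -> None:
    """Write records in FASTA, wrapping residue lines at ``width`` columns."""
    if isinstance(dest, (str, Path)):
        with open(dest, "w") as handle:
            write_fasta(records, handle, width=width)
        return
    for rec in records:
        header = f">{rec.id}"
        if rec.description:
            header += f" {rec.description}"
        dest.write(header + "\n")
        seq = rec.residues
        if width <= 0:
            dest.write(seq + "\n")
        else:
            for i in range(0, len(seq), width):
                dest.write(seq[i : i + width] + "\n")


def read_alignment(source: str | Path | io.TextIOBase) -> Alignment:
    return Alignment(read_fasta(source))


# ---------------------------------------------------------------------------
# Newick


def _check_tree(tree: dendropy.Tree) -> dendropy.Tree:
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if len(set(labels)) != len(labels):
        dupes = sorted({l for l in labels if labels.count(l) > 1})
        raise ParseError(f"duplicate leaf label(s): {dupes}")
    for edge in tree.preorder_edge_iter():
        if edge.length is not None and (
            not math.isfinite(edge.length) or edge.length < 0
        ):
            raise ParseError(f"invalid branch length {edge.length!r}")
    return tree


def read_newick(source: str | Path) -> dendropy.Tree:
    """Read a newick tree; internal node labels are kept as supports."""
    try:
        tree = dendropy.Tree.get(
            path=str(source),
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:
        raise ParseError(f"malformed newick ({_newick_reason(exc)})") from exc
    return _check_tree(tree)


def _newick_reason(exc: Exception) -> str:
    msg = str(exc)
    if "Duplicate taxon labels" in msg or "Multiple occurrences" in msg:
        return "duplicate leaf labels"
    return msg.splitlines()[0]


def parse_newick(text: str) -> dendropy.Tree:
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:
        raise ParseError(f"malformed newick ({_newick_reason(exc)})") from exc
    return _check_tree(tree)


def tree_to_newick(tree: dendropy.Tree) -> str:
    return (
        tree.as_string(
            schema="newick",
            unquoted_underscores=True,
            suppress_rooting=True,
        ).strip()
    )


def write_newick(tree: dendropy.Tree, dest: str | Path) -> None:
    Path(dest).write_text(tree_to_newick(tree) + "\n")


# ---------------------------------------------------------------------------
# PDB


@dataclass(frozen=True)
class AtomRecord:
    """One ATOM/HETATM coordinate record (insertion codes ignored)."""

    chain: str
    res_seq: int
    res_name: str
    atom_name: str
    element: str
    x: float
    y: float
    z: float
    hetatm: bool = False
    serial: int = 0

    @property
    def is_hydrogen(self) -> bool:
        return self.element == "H"


def _pdb_float(text: str, what: str, lineno: int) -> float:
    try:
        value = float(text)
    except ValueError:
        raise ParseError(f"non-numeric {what} field {text.strip()!r}", lineno)
    if not math.isfinite(value):
        raise ParseError(f"non-finite {what} coordinate", lineno)
    return value


def read_pdb(
    source: str | Path | io.TextIOBase, chain: str | None = None
) -> list[AtomRecord]:
    """Parse ATOM/HETATM records from the standard fixed-column layout.

    Keeps the first altloc of each atom, ignores insertion codes, retains
    HETATM records (flagged), and optionally filters to one chain.  A
    truncated line or non-numeric coordinate raises :class:`ParseError` with
    the line number.
    """
    if isinstance(source, (str, Path)):
        with open(source) as handle:
            return read_pdb(handle, chain=chain)
    atoms: list[AtomRecord] = []
    seen_altloc: set[tuple[str, int, str]] = set()
    for lineno, raw in enumerate(source, start=1):
        tag = raw[:6].strip()
        if tag not in ("ATOM", "HETATM"):
            continue
        if len(raw.rstrip("\n")) < 54:
            raise ParseError("truncated ATOM/HETATM record", lineno)
        atom_name = raw[12:16].strip()
        altloc = raw[16]
        res_name = raw[17:20].strip()
        chain_id = raw[21]
        try:
            serial = int(raw[6:11])
            res_seq = int(raw[22:26])
        except ValueError:
            raise ParseError("non-integer serial or residue number", lineno)
        key = (chain_id, res_seq, atom_name)
        if altloc not in (" ", "A", "1"):
            continue  # keep first altloc only
        if key in seen_altloc:
            continue
        seen_altloc.add(key)
        x = _pdb_float(raw[30:38], "x", lineno)
        y = _pdb_float(raw[38:46], "y", lineno)
        z = _pdb_float(raw[46:54], "z", lineno)
        element = raw[76:78].strip() if len(raw) >= 78 else ""
        if not element:
            # fall back on the atom-name convention: first letter, two-letter
            # elements only for common heteroatoms
            element = atom_name.lstrip("0123456789")[:1]
        if chain is not None and chain_id != chain:
            continue
        atoms.append(
            AtomRecord(
                chain=chain_id,
                res_seq=res_seq,
                res_name=res_name,
                atom_name=atom_name,
                element=element,
                x=x,
                y=y,
                z=z,
                hetatm=(tag == "HETATM"),
                serial=serial,
            )
        )
    return atoms


def write_pdb(atoms: Iterable[AtomRecord], dest: str | Path | io.TextIOBase) -> None:
    """Write atoms back out in fixed-column PDB format."""
    if isinstance(dest, (str, Path)):
        with open(dest, "w") as handle:
            write_pdb(atoms, handle)
        return
    for i, a in enumerate(atoms, start=1):
        tag = "HETATM" if a.hetatm else "ATOM"
        name = a.atom_name if len(a.atom_name) == 4 else f" {a.atom_name:<3s}"
        dest.write(
            f"{tag:<6s}{i:>5d} {name:<4s} {a.res_name:>3s} {a.chain}"
            f"{a.res_seq:>4d}    {a.x:8.3f}{a.y:8.3f}{a.z:8.3f}"
            f"{1.0:6.2f}{0.0:6.2f}          {a.element:>2s}\n"
        )
    dest.write("END\n")
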