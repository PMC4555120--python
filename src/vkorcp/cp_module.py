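"""Circular-permutation analysis for the four-helix fold families.

The two families thread the same four-helix bundle in different orders
(ABCD for one family, CDAB for the other), so they are related by exchange
of the N- and C-terminal halves of the sequence.  This module provides the
half-swap rearrangement, construction of helix-pair "modules" (helices A+B
or C+D plus their connecting loop), translation-only module alignments
anchored on the invariant CXXC motif or maximizing identity, identity-site
counting across index sequences, conserved-feature matching between the
families, and a general rotation-offset detector based on local alignment
against a doubled sequence.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio.Align import PairwiseAligner, substitution_matrices

from .io_formats import SequenceRecord, UNKNOWN

CXXC = re.compile(r"C..C")


def half_swap(sequence: str, boundary: int) -> str:
    """Exchange the two halves: result = suffix(boundary+1..n) + prefix(1..boundary)."""
    n = len(sequence)
    if not 1 < boundary < n:
        raise ValueError(f"boundary {boundary} outside 2..{n - 1}")
    return sequence[boundary:] + sequence[:boundary]


@dataclass(frozen=True)
class ModuleSequence:
    """A contiguous helix-pair module cut from a reference sequence."""

    family: str
    module: str  # "AB" or "CD"
    residues: str
    origin: tuple[str, int, int]  # (ref_id, start, end), reference numbering
    anchor: int | None = None  # 1-based CXXC position within the module

    def __len__(self) -> int:
        return len(self.residues)

    def ref_to_module(self, ref_position: int) -> int | None:
        """Reference residue number -> 1-based module position (None if outside)."""
        pos = ref_position - self.origin[1] + 1
        return pos if 1 <= pos <= len(self.residues) else None


def build_module(
    sequence: SequenceRecord | str,
    helices: Mapping[str, tuple[int, int]],
    module_id: str,
    family: str = "",
) -> ModuleSequence:
    """Cut the AB or CD module out of an ungapped reference sequence.

    ``helices`` maps labels A-D to inclusive (start, end) residue ranges in
    reference numbering.  The AB module runs from helix A's start to helix
    B's end (loop included); likewise CD.  The first helix of the pair must
    precede the second in the sequence.  The anchor is the first CXXC match
    within the module, if any.
    """
    if module_id not in ("AB", "CD"):
        raise ValueError("module_id must be 'AB' or 'CD'")
    if isinstance(sequence, SequenceRecord):
        ref_id, residues = sequence.id, sequence.ungapped
    else:
        ref_id, residues = "seq", sequence
    first, second = module_id[0], module_id[1]
    for label in (first, second):
        if label not in helices:
            raise KeyError(f"missing helix annotation {label!r}")
    (s1, e1), (s2, e2) = helices[first], helices[second]
    if not (s1 <= e1 < s2 <= e2):
        raise ValueError(
            f"helix {first} ({s1}-{e1}) does not precede helix {second} "
            f"({s2}-{e2}) in the sequence"
        )
    if e2 > len(residues):
        raise IndexError(
            f"helix {second} range {s2}-{e2} exceeds sequence length "
            f"{len(residues)}"
        )
    segment = residues[s1 - 1 : e2]
    match = CXXC.search(segment)
    return ModuleSequence(
        family=family,
        module=module_id,
        residues=segment,
        origin=(ref_id, s1, e2),
        anchor=match.start() + 1 if match else None,
    )


@dataclass(frozen=True)
class ModuleAlignment:
    """Translation-only (gapless) alignment of two modules.

    ``offset`` is the signed shift of module 2 relative to module 1:
    module-1 position p1 pairs with module-2 position p2 when
    ``p1 == p2 + offset``.  Alignment-frame positions are 1-based from the
    leftmost aligned column of either module.
    """

    module1: ModuleSequence
    module2: ModuleSequence
    offset: int

    @property
    def _shift1(self) -> int:
        return max(0, -self.offset)

    @property
    def _shift2(self) -> int:
        return max(0, self.offset)

    def frame_of_p1(self, p1: int) -> int:
        return p1 + self._shift1

    def frame_of_p2(self, p2: int) -> int:
        return p2 + self._shift2

    @property
    def n_frame_columns(self) -> int:
        return max(
            len(self.module1) + self._shift1, len(self.module2) + self._shift2
        )

    @property
    def columns(self) -> list[tuple[int, int, int]]:
        """(frame_position, p1, p2) triples over the overlap."""
        lo = max(1, 1 - self.offset)
        hi = min(len(self.module2), len(self.module1) - self.offset)
        return [
            (self.frame_of_p2(p2), p2 + self.offset, p2)
            for p2 in range(lo, hi + 1)
        ]

    @property
    def identity_columns(self) -> list[tuple[int, int, int]]:
        """Overlap columns whose residues are identical ('X' never matches)."""
        r1, r2 = self.module1.residues, self.module2.residues
        return [
            (f, p1, p2)
            for f, p1, p2 in self.columns
            if r1[p1 - 1] == r2[p2 - 1] and r1[p1 - 1] != UNKNOWN
        ]

    @property
    def n_identities(self) -> int:
        return len(self.identity_columns)


def anchor_align(module1: ModuleSequence, module2: ModuleSequence) -> ModuleAlignment:
    """Translate module 2 so both CXXC anchors fall in the same column."""
    if module1.anchor is None or module2.anchor is None:
        missing = "module1" if module1.anchor is None else "module2"
        raise ValueError(f"{missing} has no CXXC anchor")
    return ModuleAlignment(module1, module2, offset=module1.anchor - module2.anchor)


def best_identity_offset(
    module1: ModuleSequence,
    module2: ModuleSequence,
    min_overlap: int = 10,
) -> ModuleAlignment:
    """The translation maximizing the identity-site count.

    All offsets with at least ``min_overlap`` overlap columns are scanned;
    ties are broken toward the smallest absolute offset, negative before
    positive.
    """
    n1, n2 = len(module1), len(module2)
    offsets = sorted(
        range(-(n2 - 1), n1),
        key=lambda o: (abs(o), o > 0),
    )
    best: ModuleAlignment | None = None
    for offset in offsets:
        overlap = min(n2, n1 - offset) - max(1, 1 - offset) + 1
        if overlap < min_overlap:
            continue
        cand = ModuleAlignment(module1, module2, offset)
        if best is None or cand.n_identities > best.n_identities:
            best = cand
    if best is None:
        raise ValueError(f"no translation with overlap >= {min_overlap}")
    return best


@dataclass(frozen=True)
class IdentityCount:
    """Identity-site census over one or more module alignments that share
    the same family-2 module (the single-index side)."""

    union_count: int
    union_columns: tuple[int, ...]  # module-2 positions
    pairwise_counts: tuple[int, ...]
    triple_count: int
    triple_columns: tuple[int, ...]

    def count(self, mode: str = "union") -> int:
        return {
            "union": self.union_count,
            "pairwise": max(self.pairwise_counts),
            "triple": self.triple_count,
        }[mode]


def count_identity_sites(
    alignments: ModuleAlignment | Sequence[ModuleAlignment],
    mode: str = "union",
) -> IdentityCount:
    """Count columns where the shared family-2 index residue matches the
    family-1 residue(s).

    ``union``: module-2 positions where at least one family-1 index
    sequence matches.  ``pairwise`` counts are always reported alongside,
    as is the stricter ``triple`` count (all family-1 indices match).
    ``mode`` only selects what :meth:`IdentityCount.count` returns.
    """
    if isinstance(alignments, ModuleAlignment):
        alignments = [alignments]
    if not alignments:
        raise ValueError("need at least one module alignment")
    mod2 = alignments[0].module2
    if any(a.module2 is not mod2 and a.module2 != mod2 for a in alignments):
        raise ValueError("all alignments must share the family-2 module")
    if mode not in ("union", "pairwise", "triple"):
        raise ValueError(f"unknown mode {mode!r}")
    per_pair = [
        {p2 for _, _, p2 in a.identity_columns} for a in alignments
    ]
    union = sorted(set().union(*per_pair))
    triple = sorted(set.intersection(*per_pair))
    return IdentityCount(
        union_count=len(union),
        union_columns=tuple(union),
        pairwise_counts=tuple(len(s) for s in per_pair),
        triple_count=len(triple),
        triple_columns=tuple(triple),
    )


@dataclass(frozen=True)
class FeatureMatch:
    frame_position: int
    ref_position_1: int
    ref_position_2: int
    grade_1: int
    grade_2: int


def match_conserved_features(
    module_alignment: ModuleAlignment,
    profile1: Mapping[int, int],
    profile2: Mapping[int, int],
    features1: Iterable[int],
    features2: Iterable[int],
    min_grade: int = 6,
) -> list[FeatureMatch]:
    """Alignment-frame positions where both families carry a feature (e.g.
    helix-helix contact or ligand contact, given as reference residue
    numbers) AND are conserved to at least ``min_grade`` in both family
    profiles (mappings reference position -> grade).

    Feature positions outside their module are ignored with a warning.
    """

    def qualifying(module: ModuleSequence, profile, features) -> dict[int, tuple[int, int]]:
        out: dict[int, tuple[int, int]] = {}
        for ref_pos in features:
            pos = module.ref_to_module(ref_pos)
            if pos is None:
                warnings.warn(
                    f"feature at reference position {ref_pos} lies outside "
                    f"the {module.module} module span "
                    f"{module.origin[1]}-{module.origin[2]}; ignored",
                    stacklevel=3,
                )
                continue
            grade = profile.get(ref_pos)
            if grade is not None and grade >= min_grade:
                out[pos] = (ref_pos, grade)
        return out

    q1 = qualifying(module_alignment.module1, profile1, features1)
    q2 = qualifying(module_alignment.module2, profile2, features2)
    matches: list[FeatureMatch] = []
    for _, p1, p2 in module_alignment.columns:
        if p1 in q1 and p2 in q2:
            matches.append(
                FeatureMatch(
                    frame_position=module_alignment.frame_of_p1(p1),
                    ref_position_1=q1[p1][0],
                    ref_position_2=q2[p2][0],
                    grade_1=q1[p1][1],
                    grade_2=q2[p2][1],
                )
            )
    return matches


# ---------------------------------------------------------------------------
# General rotation-offset detection


@dataclass(frozen=True)
class CPOffset:
    """Result of the doubled-sequence circular-permutation search."""

    offset: int  # 0 means no permutation
    alignment_score: float
    score_profile: np.ndarray = field(repr=False)  # ungapped score per offset
    low_complexity: bool = False


def _blosum62_profile(seq_a: str, seq_b: str) -> np.ndarray:
    mat = substitution_matrices.load("BLOSUM62")
    alphabet = mat.alphabet
    index = {ch: i for i, ch in enumerate(alphabet)}
    arr = np.asarray(mat)
    a = np.array([index[ch] for ch in seq_a])
    b = np.array([index[ch] for ch in seq_b])
    n = len(a)
    m = min(len(a), len(b))
    prof = np.empty(n)
    for k in range(n):
        rot = np.concatenate([a[k:], a[:k]])[:m]
        prof[k] = arr[rot, b[:m]].sum()
    return prof


def find_cp_offset(
    seq_a: str,
    seq_b: str,
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
) -> CPOffset:
    """Locate the circular-permutation point relating two sequences.

    ``seq_b`` is locally aligned (BLOSUM62; affine gaps) against the doubled
    sequence ``seq_a + seq_a``; the permutation point is the start of the
    best alignment modulo ``len(seq_a)``.  The per-offset ungapped score
    profile is returned for diagnostics.  Single-residue-alphabet input is
    flagged low-complexity (every offset is then equivalent).
    """
    seq_a, seq_b = seq_a.upper(), seq_b.upper()
    if min(len(seq_a), len(seq_b)) < 20:
        raise ValueError("sequences must be at least 20 residues long")
    if "-" in seq_a or "-" in seq_b:
        raise ValueError("sequences must be ungapped")
    low = len(set(seq_a)) <= 1 or len(set(seq_b)) <= 1
    if low:
        warnings.warn("low-complexity input: permutation point is arbitrary",
                      stacklevel=2)
    aligner = PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -abs(gap_open)
    aligner.extend_gap_score = -abs(gap_extend)
    alignment = aligner.align(seq_a + seq_a, seq_b)[0]
    start = int(alignment.aligned[0][0][0])
    return CPOffset(
        offset=start % len(seq_a),
        alignment_score=float(alignment.score),
        score_profile=_blosum62_profile(seq_a, seq_b),
        low_complexity=low,
    )
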