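"""Clade extraction from a rooted tree and the comparative column scans:
fully conserved positions, clade-specific absent segments, and single-site
determinant (covariant-marker) detection.

Missing states ('X' and '-') never count as evidence: they are excluded
from both numerator and denominator of all frequencies here.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np

from .io_formats import GAP, MISSING, Alignment


@dataclass(frozen=True)
class CladeAssignment:
    """Sequence id -> clade label, with the labels in a stable order."""

    assignment: Mapping[str, str]
    labels: tuple[str, ...]

    def members(self, label: str) -> list[str]:
        if label not in self.labels:
            raise KeyError(f"unknown clade label {label!r}")
        return sorted(k for k, v in self.assignment.items() if v == label)

    def __getitem__(self, sequence_id: str) -> str:
        return self.assignment[sequence_id]


@dataclass(frozen=True)
class SiteMarker:
    """A column state (nearly) exclusive to a group of sequences."""

    column: int  # 1-based alignment column
    state: str
    group: str
    in_group_freq: float
    out_group_freq: float
    ref_position: int | None = None


@dataclass(frozen=True)
class ConservedSite:
    column: int
    state: str
    occupancy: float
    ref_position: int | None = None


@dataclass(frozen=True)
class AbsentSegment:
    """Columns gapped throughout one clade but occupied in another."""

    col_start: int
    col_end: int
    clade_absent: str
    clade_present: str
    ref_start: int | None = None
    ref_end: int | None = None

    @property
    def length(self) -> int:
        return self.col_end - self.col_start + 1


def clade_partition(
    rooted_tree: dendropy.Tree, seed_taxa: Mapping[str, Iterable[str] | str]
) -> CladeAssignment:
    """Clades grown from seed taxa on the rooted tree.

    Each label's clade starts at the MRCA of its seeds and is expanded to
    the largest enclosing subtree that still contains no other label's
    seeds, so a single exemplar per clade recovers the whole clade when the
    clades are separated.  Clades must be pairwise disjoint (monophyletic
    with respect to each other); any overlap raises an error naming the
    offending labels.
    """
    leaves = {l.taxon.label for l in rooted_tree.leaf_node_iter()}
    assignment: dict[str, str] = {}
    labels = tuple(seed_taxa.keys())
    seed_sets: dict[str, set[str]] = {}
    for label, seeds in seed_taxa.items():
        if isinstance(seeds, str):
            seeds = [seeds]
        seed_sets[label] = set(seeds)
        missing = seed_sets[label] - leaves
        if missing:
            raise KeyError(f"seed taxa not in tree: {sorted(missing)}")
    clade_sets: dict[str, set[str]] = {}
    for label in labels:
        seeds = sorted(seed_sets[label])
        foreign = set().union(
            *(seed_sets[other] for other in labels if other != label)
        ) if len(labels) > 1 else set()
        if len(seeds) == 1:
            node = next(
                l
                for l in rooted_tree.leaf_node_iter()
                if l.taxon.label == seeds[0]
            )
        else:
            node = rooted_tree.mrca(taxon_labels=seeds)
        while node.parent_node is not None:
            parent_leaves = {l.taxon.label for l in node.parent_node.leaf_iter()}
            if parent_leaves & foreign:
                break
            node = node.parent_node
        clade_sets[label] = {l.taxon.label for l in node.leaf_iter()}
    for i, la in enumerate(labels):
        for lb in labels[i + 1 :]:
            overlap = clade_sets[la] & clade_sets[lb]
            if overlap:
                raise ValueError(
                    f"clades {la!r} and {lb!r} overlap on "
                    f"{sorted(overlap)[:5]}{'...' if len(overlap) > 5 else ''}"
                )
    for label in labels:
        for taxon in clade_sets[label]:
            assignment[taxon] = label
    return CladeAssignment(assignment, labels)


def _char_matrix(alignment: Alignment) -> np.ndarray:
    return np.array([list(r.residues) for r in alignment.records])


def fully_conserved_sites(
    alignment: Alignment,
    min_occupancy: float = 0.9,
    ref_id: str | None = None,
) -> list[ConservedSite]:
    """Columns where every non-missing residue is identical and the fraction
    of non-missing rows is at least ``min_occupancy``."""
    if len(alignment) < 2:
        raise ValueError("conservation scan needs >= 2 rows")
    arr = _char_matrix(alignment)
    present = ~np.isin(arr, sorted(MISSING))
    col2ref = _ref_lookup(alignment, ref_id)
    out: list[ConservedSite] = []
    for col in range(alignment.n_columns):
        mask = present[:, col]
        occ = mask.mean()
        if occ < min_occupancy or not mask.any():
            continue
        states = set(arr[mask, col])
        if len(states) == 1:
            out.append(
                ConservedSite(
                    column=col + 1,
                    state=states.pop(),
                    occupancy=float(occ),
                    ref_position=col2ref.get(col + 1),
                )
            )
    return out


def _ref_lookup(alignment: Alignment, ref_id: str | None) -> dict[int, int]:
    if ref_id is None:
        return {}
    from .curation import column_to_reference

    return column_to_reference(alignment, ref_id)


def clade_absent_segments(
    alignment: Alignment,
    assignment: CladeAssignment,
    clade_a: str,
    clade_b: str,
    min_len: int = 2,
    min_presence: float = 0.5,
    ref_id: str | None = None,
) -> list[AbsentSegment]:
    """Maximal column spans gapped throughout ``clade_a`` but occupied in at
    least ``min_presence`` of ``clade_b`` rows, at least ``min_len`` columns
    long, sorted by start column."""
    rows_a = assignment.members(clade_a)
    rows_b = assignment.members(clade_b)
    if not rows_a or not rows_b:
        raise ValueError("both clades must be non-empty")
    arr = _char_matrix(alignment)
    ids = alignment.ids
    idx_a = [ids.index(i) for i in rows_a]
    idx_b = [ids.index(i) for i in rows_b]
    gap_a = (arr[idx_a] == GAP).all(axis=0)
    occ_b = (~np.isin(arr[idx_b], sorted(MISSING))).mean(axis=0)
    qualifies = gap_a & (occ_b >= min_presence)
    col2ref = _ref_lookup(alignment, ref_id)
    out: list[AbsentSegment] = []
    col = 0
    n = alignment.n_columns
    while col < n:
        if not qualifies[col]:
            col += 1
            continue
        start = col
        while col < n and qualifies[col]:
            col += 1
        end = col - 1
        if end - start + 1 >= min_len:
            ref_cols = [
                col2ref[c] for c in range(start + 1, end + 2) if c in col2ref
            ]
            out.append(
                AbsentSegment(
                    col_start=start + 1,
                    col_end=end + 1,
                    clade_absent=clade_a,
                    clade_present=clade_b,
                    ref_start=min(ref_cols) if ref_cols else None,
                    ref_end=max(ref_cols) if ref_cols else None,
                )
            )
    return out


def single_site_markers(
    alignment: Alignment,
    group_members: Iterable[str],
    group_label: str = "group",
    max_out_freq: float = 0.0,
    min_in_freq: float = 1.0,
    ref_id: str | None = None,
) -> list[SiteMarker]:
    """Columns where some residue state is (nearly) fixed within the group
    and (nearly) absent outside it.

    Frequencies are over non-missing rows only.  The defaults
    (``min_in_freq=1``, ``max_out_freq=0``) demand a perfect determinant:
    present in every scored group row and in no scored complement row.
    """
    group = sorted(set(group_members))
    ids = alignment.ids
    missing = set(group) - set(ids)
    if missing:
        raise KeyError(f"group members not in alignment: {sorted(missing)}")
    if not group:
        raise ValueError("group must be non-empty")
    complement = [i for i in ids if i not in set(group)]
    if not complement:
        raise ValueError("complement is empty: marker undefined")
    arr = _char_matrix(alignment)
    idx_in = [ids.index(i) for i in group]
    idx_out = [ids.index(i) for i in complement]
    present = ~np.isin(arr, sorted(MISSING))
    col2ref = _ref_lookup(alignment, ref_id)
    out: list[SiteMarker] = []
    for col in range(alignment.n_columns):
        in_states = arr[idx_in, col][present[idx_in, col]]
        out_states = arr[idx_out, col][present[idx_out, col]]
        if in_states.size == 0:
            continue
        for state in sorted(set(in_states)):
            f_in = float((in_states == state).mean())
            f_out = (
                float((out_states == state).mean()) if out_states.size else 0.0
            )
            if f_in >= min_in_freq and f_out <= max_out_freq:
                out.append(
                    SiteMarker(
                        column=col + 1,
                        state=str(state),
                        group=group_label,
                        in_group_freq=f_in,
                        out_group_freq=f_out,
                        ref_position=col2ref.get(col + 1),
                    )
                )
    return out


def state_spectrum(
    alignment: Alignment,
    assignment: CladeAssignment,
    column: int,
) -> dict[str, dict[str, int]]:
    """Per-clade residue-state counts at one alignment column (1-based);
    the report style used to ask "which clade carries which state" at a
    position of interest."""
    arr = _char_matrix(alignment)
    ids = alignment.ids
    out: dict[str, dict[str, int]] = {}
    for label in assignment.labels:
        rows = [ids.index(i) for i in assignment.members(label) if i in ids]
        states = arr[rows, column - 1]
        counts: dict[str, int] = {}
        for s in states:
            if s in MISSING:
                continue
            counts[str(s)] = counts.get(str(s), 0) + 1
        out[label] = dict(sorted(counts.items(), key=lambda kv: (-kv[1], kv[0])))
    return out
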