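"""Interhelical- and ligand-contact extraction from PDB coordinates.

A contact is a pair of residues on different annotated helices whose
minimum heavy-atom distance is at or below the cutoff (default 4.5 A, the
common van-der-Waals contact convention).  Hydrogens are excluded; author
residue numbering is used throughout.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .io_formats import AtomRecord

DEFAULT_CUTOFF = 4.5


@dataclass(frozen=True)
class HelixAnnotation:
    """One transmembrane helix: label, chain and inclusive residue range."""

    label: str
    chain: str
    res_start: int
    res_end: int

    def __post_init__(self):
        if self.res_start > self.res_end:
            raise ValueError(
                f"helix {self.label}: res_start {self.res_start} > res_end "
                f"{self.res_end}"
            )

    def contains(self, atom: AtomRecord) -> bool:
        return (
            atom.chain == self.chain
            and self.res_start <= atom.res_seq <= self.res_end
        )


@dataclass(frozen=True)
class Contact:
    res_i: int
    helix_i: str
    res_j: int
    helix_j: str
    distance: float


@dataclass(frozen=True)
class ContactSet:
    contacts: tuple[Contact, ...]
    cutoff: float

    def __iter__(self):
        return iter(self.contacts)

    def __len__(self) -> int:
        return len(self.contacts)

    @property
    def residue_pairs(self) -> set[tuple[int, int]]:
        return {tuple(sorted((c.res_i, c.res_j))) for c in self.contacts}


def _heavy(atoms: Iterable[AtomRecord]) -> list[AtomRecord]:
    return [a for a in atoms if not a.is_hydrogen]


def _group_by_residue(atoms: Sequence[AtomRecord]) -> dict[int, np.ndarray]:
    groups: dict[int, list[list[float]]] = {}
    for a in atoms:
        groups.setdefault(a.res_seq, []).append([a.x, a.y, a.z])
    return {k: np.asarray(v) for k, v in groups.items()}


def _min_distance(xyz_a: np.ndarray, xyz_b: np.ndarray) -> float:
    d = np.linalg.norm(xyz_a[:, None, :] - xyz_b[None, :, :], axis=2)
    return float(d.min())


def interhelical_contacts(
    atoms: Sequence[AtomRecord],
    helices: Sequence[HelixAnnotation],
    cutoff: float = DEFAULT_CUTOFF,
) -> ContactSet:
    """Residue pairs on different helices within the heavy-atom cutoff.

    Each unordered residue pair is listed once, with the helix labels and
    the minimum heavy-atom distance.  A helix annotation matching no atoms
    raises an error naming the range.  Output order is deterministic
    (sorted by residue pair) and independent of atom record order.
    """
    labels = [h.label for h in helices]
    if len(set(labels)) != len(labels):
        raise ValueError("helix labels must be unique")
    per_helix: dict[str, dict[int, np.ndarray]] = {}
    for helix in helices:
        mine = _heavy(a for a in atoms if helix.contains(a) and not a.hetatm)
        if not mine:
            raise ValueError(
                f"helix {helix.label} ({helix.chain}:{helix.res_start}-"
                f"{helix.res_end}) matches no atoms"
            )
        per_helix[helix.label] = _group_by_residue(mine)
    contacts: list[Contact] = []
    for i, ha in enumerate(helices):
        for hb in helices[i + 1 :]:
            for ri, xyz_i in per_helix[ha.label].items():
                for rj, xyz_j in per_helix[hb.label].items():
                    d = _min_distance(xyz_i, xyz_j)
                    if d <= cutoff:
                        contacts.append(
                            Contact(ri, ha.label, rj, hb.label, d)
                        )
    contacts.sort(key=lambda c: (c.res_i, c.res_j, c.helix_i, c.helix_j))
    return ContactSet(tuple(contacts), cutoff)


def ligand_contacts(
    atoms: Sequence[AtomRecord],
    ligand_resname: str,
    cutoff: float = DEFAULT_CUTOFF,
) -> list[int]:
    """Protein residues with any heavy atom within the cutoff of any heavy
    ligand atom; deduplicated, sorted by residue number."""
    ligand = _heavy(a for a in atoms if a.hetatm and a.res_name == ligand_resname)
    if not ligand:
        raise ValueError(f"ligand {ligand_resname!r} not found")
    protein = _heavy(a for a in atoms if not a.hetatm)
    lig_xyz = np.asarray([[a.x, a.y, a.z] for a in ligand])
    residues: set[int] = set()
    for res_seq, xyz in _group_by_residue(protein).items():
        if _min_distance(xyz, lig_xyz) <= cutoff:
            residues.add(res_seq)
    return sorted(residues)
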