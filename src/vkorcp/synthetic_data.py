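"""Synthetic study generator with known ground truth.

Every input the pipeline consumes can be generated here: a birth-process
tree with labelled monophyletic clades, an alignment evolved along it under
an empirical substitution model with per-site rates (gamma-drawn, fixed, or
invariant), planted features (a perfect single-site marker, clade-specific
insertion blocks), a circular-permutation partner family, and toy
four-helix-bundle coordinates with exactly enumerated contacts.  The
planted truth is recorded and self-audited against the emitted data, so
every pipeline stage can be tested without external downloads.

Random streams are derived per sub-generator from one seed (via
``numpy.random.SeedSequence.spawn``) so adding one feature does not perturb
the others.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np
import yaml

from .cp_module import half_swap
from .io_formats import (
    AMINO_ACIDS,
    Alignment,
    AtomRecord,
    GAP,
    SequenceRecord,
    tree_to_newick,
    write_fasta,
    write_newick,
    write_pdb,
)
from .structure import HelixAnnotation
from .substitution import N_STATES, SubstitutionModel, get_model


# ---------------------------------------------------------------------------
# Trees


@dataclass(frozen=True)
class CladeSpec:
    """Forced monophyletic groups: ordered label -> size, separated by stem
    branches of the given length."""

    sizes: Mapping[str, int]
    stem_length: float = 0.5

    def __post_init__(self):
        if not self.sizes:
            raise ValueError("clade_spec needs at least one clade")
        if any(s < 1 for s in self.sizes.values()):
            raise ValueError("clade sizes must be >= 1")


def _yule_tree(n_tips: int, rng: np.random.Generator, labels: list[str]) -> dendropy.Node:
    """Pure-birth subtree over ``labels`` (returned as its root node)."""
    root = dendropy.Node()
    tips = [root]
    # grow to n_tips by splitting a random tip after an exponential wait
    while len(tips) < n_tips:
        dt = rng.exponential(1.0 / len(tips))
        for tip in tips:
            tip.edge.length = (tip.edge.length or 0.0) + dt
        victim = tips.pop(int(rng.integers(len(tips))))
        for _ in range(2):
            child = dendropy.Node()
            child.edge.length = 0.0
            victim.add_child(child)
            tips.append(child)
    dt = rng.exponential(1.0 / max(len(tips), 1))
    for tip in tips:
        tip.edge.length = (tip.edge.length or 0.0) + dt
    for tip, label in zip(tips, labels):
        tip.label = label  # taxon attached by caller
    return root


def simulate_tree(
    n_taxa: int,
    seed: int,
    clade_spec: CladeSpec | None = None,
) -> dendropy.Tree:
    """Random birth-process tree, optionally with labelled monophyletic
    clades separated by stem branches; deterministic per seed."""
    if n_taxa < 3:
        raise ValueError("need at least 3 taxa")
    rng = np.random.default_rng(seed)
    if clade_spec is None:
        leaf_labels = [f"t{i:03d}" for i in range(1, n_taxa + 1)]
        root = _yule_tree(n_taxa, rng, leaf_labels)
    else:
        total = sum(clade_spec.sizes.values())
        if total != n_taxa:
            raise ValueError(
                f"clade sizes sum to {total}, expected n_taxa={n_taxa}"
            )
        clade_labels = list(clade_spec.sizes.keys())
        backbone = _yule_tree(len(clade_labels), rng, clade_labels)
        leaf_labels = []
        for tip in list(n for n in backbone.leaf_iter()):
            label = tip.label
            size = clade_spec.sizes[label]
            names = [f"{label}_t{i:02d}" for i in range(1, size + 1)]
            leaf_labels.extend(names)
            if size == 1:
                tip.label = names[0]
                tip.edge.length = (tip.edge.length or 0.0) + clade_spec.stem_length
            else:
                sub = _yule_tree(size, rng, names)
                sub.edge.length = clade_spec.stem_length
                tip.label = None
                tip.add_child(sub)
        root = backbone
    taxa = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxa, seed_node=root)
    for leaf in tree.leaf_node_iter():
        leaf.taxon = taxa.require_taxon(label=leaf.label)
        leaf.label = None
    tree.seed_node.edge.length = None  # a root edge length is meaningless
    tree.is_rooted = True
    return tree


# ---------------------------------------------------------------------------
# Sequence evolution


@dataclass(frozen=True)
class RatePlan:
    """Per-column rate classes for the simulator.

    Columns default to continuous gamma-distributed rates (shape ``alpha``,
    mean 1).  ``invariant_columns`` evolve at rate 0; ``invariant_states``
    optionally forces their (root) state.  ``fixed_rates`` pins individual
    columns to exact rate values (the two-speed designs used in rate
    recovery tests).  All columns are 1-based.
    """

    alpha: float = 1.0
    invariant_columns: tuple[int, ...] = ()
    invariant_states: Mapping[int, str] = field(default_factory=dict)
    fixed_rates: Mapping[int, float] = field(default_factory=dict)

    def column_rates(self, n_sites: int, rng: np.random.Generator) -> np.ndarray:
        rates = rng.gamma(self.alpha, 1.0 / self.alpha, size=n_sites)
        for col, rate in self.fixed_rates.items():
            rates[col - 1] = rate
        for col in self.invariant_columns:
            rates[col - 1] = 0.0
        return rates


@dataclass
class SyntheticTruth:
    """Ground truth planted by the generators (all coordinates 1-based)."""

    tree: dendropy.Tree
    site_rates: np.ndarray
    invariant_columns: tuple[int, ...]
    clade_labels: dict[str, str]
    seed: int
    marker: tuple[int, str, tuple[str, ...]] | None = None  # (col, state, ids)
    insertion_blocks: dict[str, tuple[int, int]] = field(default_factory=dict)
    cp_boundary: int | None = None
    contact_pairs: set[tuple[int, int]] = field(default_factory=set)
    helices: dict[str, tuple[int, int]] = field(default_factory=dict)

    def to_json(self) -> str:
        payload = {
            "tree": tree_to_newick(self.tree),
            "site_rates": [round(float(r), 10) for r in self.site_rates],
            "invariant_columns": list(self.invariant_columns),
            "clade_labels": dict(sorted(self.clade_labels.items())),
            "seed": self.seed,
            "marker": (
                [self.marker[0], self.marker[1], sorted(self.marker[2])]
                if self.marker
                else None
            ),
            "insertion_blocks": {
                k: list(v) for k, v in sorted(self.insertion_blocks.items())
            },
            "cp_boundary": self.cp_boundary,
            "contact_pairs": sorted(list(p) for p in self.contact_pairs),
            "helices": {k: list(v) for k, v in sorted(self.helices.items())},
        }
        return json.dumps(payload, indent=1, sort_keys=True)


def _clade_of(label: str) -> str:
    return label.rsplit("_", 1)[0] if "_t" in label else ""


def evolve_alignment(
    tree: dendropy.Tree,
    model: SubstitutionModel,
    n_sites: int,
    rate_plan: RatePlan,
    seed: int,
) -> tuple[Alignment, SyntheticTruth]:
    """Evolve an ungapped alignment along the tree.

    The root is drawn from the equilibrium frequencies (invariant columns
    can be pinned to chosen states); each branch applies the transition
    probabilities exp(Q * t * rate) independently per column.  Invariant
    columns are identical in all taxa by construction.
    """
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    rng = np.random.default_rng(seed)
    rates = rate_plan.column_rates(n_sites, rng)
    pi = model.frequencies
    root_states = rng.choice(N_STATES, size=n_sites, p=pi)
    for col, ch in rate_plan.invariant_states.items():
        if col not in rate_plan.invariant_columns:
            raise ValueError(f"column {col} has a pinned state but is not invariant")
        root_states[col - 1] = AMINO_ACIDS.index(ch)
    lam, a_mat, b_mat = model._eigen
    states: dict[int, np.ndarray] = {id(tree.seed_node): root_states}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        t = node.edge.length or 0.0
        parent_states = states[id(node.parent_node)]
        if t == 0.0:
            states[id(node)] = parent_states.copy()
            continue
        ev = np.exp(np.outer(t * rates, lam))  # (S, 20)
        # transition-probability row for each site given its parent state
        rows = np.einsum("sk,kj->sj", a_mat[parent_states] * ev, b_mat)
        np.clip(rows, 0.0, None, out=rows)
        rows /= rows.sum(axis=1, keepdims=True)
        u = rng.random(n_sites)
        states[id(node)] = (u[:, None] > np.cumsum(rows, axis=1)).sum(axis=1)
    records = []
    clade_labels: dict[str, str] = {}
    for leaf in tree.leaf_node_iter():
        label = leaf.taxon.label
        seq = "".join(AMINO_ACIDS[s] for s in states[id(leaf)])
        records.append(SequenceRecord(label, seq))
        clade_labels[label] = _clade_of(label)
    truth = SyntheticTruth(
        tree=tree,
        site_rates=rates,
        invariant_columns=tuple(sorted(rate_plan.invariant_columns)),
        clade_labels=clade_labels,
        seed=seed,
    )
    return Alignment(records), truth


# ---------------------------------------------------------------------------
# Feature planting


@dataclass(frozen=True)
class MarkerSpec:
    """A perfect single-site determinant: the group gets ``state``, every
    other row gets ``out_state``."""

    column: int
    state: str
    group_ids: tuple[str, ...]
    out_state: str = "I"

    def __post_init__(self):
        if self.state == self.out_state:
            raise ValueError("marker state must differ from out_state")


@dataclass(frozen=True)
class InsertionSpec:
    """A block of columns carried only by the given clades (gapped in all
    other rows), inserted after ``after_col``."""

    clades: tuple[str, ...]
    length: int
    after_col: int
    label: str = ""


def plant_features(
    alignment: Alignment,
    truth: SyntheticTruth,
    marker_spec: MarkerSpec | None = None,
    insertion_specs: Sequence[InsertionSpec] = (),
    frequencies: np.ndarray | None = None,
    seed: int = 0,
) -> tuple[Alignment, SyntheticTruth]:
    """Plant a marker and/or clade-specific insertion blocks.

    Insertions are applied first (in order of ``after_col``); the marker
    column is interpreted in post-insertion coordinates.  Planting
    overwrites evolved states, so the signal is exact by construction.
    """
    rng = np.random.default_rng(seed)
    if frequencies is None:
        frequencies = get_model("WAG").frequencies
    rows = {r.id: list(r.residues) for r in alignment.records}
    known_clades = set(truth.clade_labels.values())
    shift = 0
    site_rates = list(truth.site_rates)
    invariant = list(truth.invariant_columns)
    marker = truth.marker
    insertions = dict(truth.insertion_blocks)

    for spec in sorted(insertion_specs, key=lambda s: s.after_col):
        unknown = set(spec.clades) - known_clades
        if unknown:
            raise KeyError(f"insertion references unknown clades: {sorted(unknown)}")
        at = spec.after_col + shift
        members = {
            rid
            for rid, clade in truth.clade_labels.items()
            if clade in spec.clades
        }
        for rid, chars in rows.items():
            if rid in members:
                block = [
                    AMINO_ACIDS[i]
                    for i in rng.choice(N_STATES, size=spec.length, p=frequencies)
                ]
            else:
                block = [GAP] * spec.length
            rows[rid] = chars[:at] + block + chars[at:]
        site_rates[at:at] = [float("nan")] * spec.length
        invariant = [c if c <= at else c + spec.length for c in invariant]
        label = spec.label or "+".join(spec.clades)
        insertions[label] = (at + 1, at + spec.length)
        shift += spec.length

    if marker_spec is not None:
        unknown = set(marker_spec.group_ids) - set(rows)
        if unknown:
            raise KeyError(f"marker references unknown ids: {sorted(unknown)}")
        col = marker_spec.column
        for rid, chars in rows.items():
            if chars[col - 1] == GAP:
                continue
            chars[col - 1] = (
                marker_spec.state
                if rid in marker_spec.group_ids
                else marker_spec.out_state
            )
        marker = (col, marker_spec.state, tuple(sorted(marker_spec.group_ids)))
        if col - 1 < len(site_rates):
            site_rates[col - 1] = float("nan")
        invariant = [c for c in invariant if c != col]

    new_aln = Alignment(
        [
            SequenceRecord(r.id, "".join(rows[r.id]), r.description)
            for r in alignment.records
        ]
    )
    new_truth = SyntheticTruth(
        tree=truth.tree,
        site_rates=np.array(site_rates),
        invariant_columns=tuple(invariant),
        clade_labels=truth.clade_labels,
        seed=truth.seed,
        marker=marker,
        insertion_blocks=insertions,
        cp_boundary=truth.cp_boundary,
        contact_pairs=truth.contact_pairs,
        helices=truth.helices,
    )
    return new_aln, new_truth


# ---------------------------------------------------------------------------
# CP partner family


def make_cp_family(
    alignment: Alignment,
    truth: SyntheticTruth,
    boundary: int,
    divergence: float,
    seed: int,
    model: SubstitutionModel | None = None,
) -> tuple[Alignment, SyntheticTruth]:
    """Partner family whose sequences are the originals rotated at
    ``boundary`` (suffix + prefix), then mutated at an expected
    ``divergence`` substitutions per site."""
    if not 0 <= divergence < 1:
        raise ValueError("divergence must be in [0, 1)")
    if model is None:
        model = get_model("WAG")
    rng = np.random.default_rng(seed)
    records = []
    for rec in alignment.records:
        seq = rec.ungapped
        if not 1 < boundary < len(seq):
            raise ValueError(
                f"boundary {boundary} outside sequence {rec.id} (len {len(seq)})"
            )
        rotated = half_swap(seq, boundary)
        if divergence > 0:
            states = np.array([AMINO_ACIDS.index(c) for c in rotated])
            p = model.transition_matrices([divergence])[0]
            u = rng.random(len(states))
            states = (u[:, None] > np.cumsum(p[states], axis=1)).sum(axis=1)
            rotated = "".join(AMINO_ACIDS[s] for s in states)
        records.append(SequenceRecord(f"cp_{rec.id}", rotated))
    truth.cp_boundary = boundary
    return Alignment(records), truth


# ---------------------------------------------------------------------------
# Toy helix bundle


@dataclass
class ToyBundle:
    atoms: list[AtomRecord]
    helices: list[HelixAnnotation]
    true_contacts: set[tuple[int, int]]
    true_ligand_contacts: list[int]
    cutoff: float


def make_toy_bundle(
    n_helices: int = 4,
    residues_per_helix: int = 12,
    spacing: float = 9.5,
    seed: int = 0,
    cutoff: float = 4.5,
    with_ligand: bool = False,
) -> ToyBundle:
    """Ideal alpha-helices (1.5 A rise, 100 deg per residue) on a square of
    side ``spacing``, one C-alpha and one side-chain pseudo-atom per
    residue; the true contact list is enumerated by brute force over all
    heavy-atom pairs and stored in the result."""
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    rng = np.random.default_rng(seed)
    corners = [(0.0, 0.0), (spacing, 0.0), (spacing, spacing), (0.0, spacing)]
    atoms: list[AtomRecord] = []
    helices: list[HelixAnnotation] = []
    for h in range(n_helices):
        cx, cy = corners[h % 4]
        phase = rng.uniform(0, 2 * np.pi)
        start_res = h * 100 + 1
        label = chr(ord("A") + h)
        helices.append(
            HelixAnnotation(label, "A", start_res, start_res + residues_per_helix - 1)
        )
        for i in range(residues_per_helix):
            angle = phase + np.deg2rad(100.0) * i
            z = 1.5 * i
            if h % 2 == 1:  # antiparallel neighbours
                z = 1.5 * (residues_per_helix - 1) - z
            for name, radius in (("CA", 2.3), ("CB", 3.4)):
                atoms.append(
                    AtomRecord(
                        chain="A",
                        res_seq=start_res + i,
                        res_name="ALA",
                        atom_name=name,
                        element="C",
                        x=cx + radius * np.cos(angle),
                        y=cy + radius * np.sin(angle),
                        z=z,
                    )
                )
    if with_ligand:
        # one heteroatom ring parked at the bundle center, mid-height
        zc = 1.5 * (residues_per_helix - 1) / 2
        for j in range(3):
            atoms.append(
                AtomRecord(
                    chain="A",
                    res_seq=900,
                    res_name="LIG",
                    atom_name=f"C{j + 1}",
                    element="C",
                    x=spacing / 2 + 0.6 * j,
                    y=spacing / 2,
                    z=zc,
                    hetatm=True,
                )
            )

    # brute-force truth: every residue pair on different helices
    helix_of = {}
    for hel in helices:
        for r in range(hel.res_start, hel.res_end + 1):
            helix_of[r] = hel.label
    coords: dict[int, list[tuple[float, float, float]]] = {}
    for a in atoms:
        if a.hetatm or a.is_hydrogen:
            continue
        coords.setdefault(a.res_seq, []).append((a.x, a.y, a.z))
    true_contacts: set[tuple[int, int]] = set()
    residues = sorted(coords)
    for ii, ri in enumerate(residues):
        for rj in residues[ii + 1 :]:
            if helix_of[ri] == helix_of[rj]:
                continue
            dmin = min(
                ((p[0] - q[0]) ** 2 + (p[1] - q[1]) ** 2 + (p[2] - q[2]) ** 2)
                ** 0.5
                for p in coords[ri]
                for q in coords[rj]
            )
            if dmin <= cutoff:
                true_contacts.add((ri, rj))
    lig = [(a.x, a.y, a.z) for a in atoms if a.hetatm]
    true_lig: list[int] = []
    if lig:
        for r in residues:
            dmin = min(
                ((p[0] - q[0]) ** 2 + (p[1] - q[1]) ** 2 + (p[2] - q[2]) ** 2)
                ** 0.5
                for p in coords[r]
                for q in lig
            )
            if dmin <= cutoff:
                true_lig.append(r)
    return ToyBundle(atoms, helices, true_contacts, true_lig, cutoff)


# ---------------------------------------------------------------------------
# Full study bundle


@dataclass(frozen=True)
class StudyConfig:
    """Desk-scale study conditions for the end-to-end synthetic bundle."""

    clade_sizes: Mapping[str, int] = field(
        default_factory=lambda: {
            "clade1": 20,
            "clade2": 8,
            "clade3": 6,
            "clade4": 10,
            "clade5": 16,
        }
    )
    stem_length: float = 0.6
    n_sites: int = 160
    alpha: float = 0.7
    model_name: str = "WAG"
    # invariant "catalytic" columns emulating the conserved C, C, S, C-x-x-C
    invariant_columns: Mapping[int, str] = field(
        default_factory=lambda: {40: "C", 48: "C", 54: "S", 120: "C", 123: "C"}
    )
    marker_column: int = 126
    marker_state: str = "C"
    marker_out_state: str = "I"
    marker_group_size: int = 6
    insertion_clades: tuple[str, ...] = ("clade2", "clade3", "clade4")
    insertion_length: int = 13
    insertion_after_col: int = 80
    cp_boundary: int = 107
    cp_divergence: float = 0.10
    helices: Mapping[str, tuple[int, int]] = field(
        default_factory=lambda: {
            "C": (10, 30),
            "D": (85, 105),
            "A": (110, 130),
            "B": (135, 155),
        }
    )
    bundle_spacing: float = 9.5
    bundle_residues: int = 12

    @property
    def n_taxa(self) -> int:
        return sum(self.clade_sizes.values())


@dataclass
class StudyBundle:
    alignment: Alignment  # with planted insertions and marker
    core_alignment: Alignment  # pre-planting, ungapped
    tree: dendropy.Tree
    cp_partner: Alignment
    toy: ToyBundle
    truth: SyntheticTruth
    config: StudyConfig


def _audit(bundle: StudyBundle) -> None:
    """Verify that the emitted data are consistent with the planted truth."""
    truth, cfg = bundle.truth, bundle.config
    aln = bundle.alignment
    for col in truth.invariant_columns:
        states = {c for c in aln.column(col) if c not in "-X"}
        if len(states) != 1:
            raise AssertionError(f"invariant column {col} is not constant")
    if truth.marker:
        col, state, group = truth.marker
        for rec in aln:
            ch = rec.residues[col - 1]
            if ch == GAP:
                continue
            expected = state if rec.id in group else cfg.marker_out_state
            if ch != expected:
                raise AssertionError(f"marker column {col} inconsistent at {rec.id}")
    for label, (s, e) in truth.insertion_blocks.items():
        members = {
            rid
            for rid, cl in truth.clade_labels.items()
            if cl in set(label.split("+"))
        }
        for rec in aln:
            block = rec.residues[s - 1 : e]
            if rec.id in members and GAP in block:
                raise AssertionError(f"insertion {label}: member {rec.id} gapped")
            if rec.id not in members and block != GAP * (e - s + 1):
                raise AssertionError(f"insertion {label}: {rec.id} not all-gap")
    for rec_core, rec_cp in zip(bundle.core_alignment, bundle.cp_partner):
        if len(rec_cp.residues) != len(rec_core.residues):
            raise AssertionError("cp partner length mismatch")
    leaves = {l.taxon.label for l in bundle.tree.leaf_node_iter()}
    if leaves != set(aln.ids):
        raise AssertionError("tree leaves do not match alignment ids")


def generate_study_bundle(
    config: StudyConfig | None = None,
    seed: int = 1,
    out_dir: str | Path | None = None,
) -> StudyBundle:
    """Generate the complete synthetic study; optionally write it to disk.

    Emits (when ``out_dir`` is given): ``msa.fasta`` (planted alignment),
    ``core.fasta`` (pre-planting core), ``tree.nwk``, ``cp_partner.fasta``,
    ``bundle.pdb``, ``helices.yaml`` and ``truth.json``.  A self-audit
    verifies truth consistency before anything is written.
    """
    cfg = config or StudyConfig()
    if not cfg.clade_sizes:
        raise ValueError("config must name at least one clade")
    ss = np.random.SeedSequence(seed)
    sub = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(6)]
    model = get_model(cfg.model_name, alpha=cfg.alpha)

    tree = simulate_tree(
        cfg.n_taxa,
        sub[0],
        CladeSpec(cfg.clade_sizes, cfg.stem_length),
    )
    plan = RatePlan(
        alpha=cfg.alpha,
        invariant_columns=tuple(cfg.invariant_columns),
        invariant_states=dict(cfg.invariant_columns),
    )
    core, truth = evolve_alignment(tree, model, cfg.n_sites, plan, sub[1])
    truth.helices = dict(cfg.helices)

    cp_partner, truth = make_cp_family(
        core, truth, cfg.cp_boundary, cfg.cp_divergence, sub[2], model
    )

    # marker group: a scattered subset drawn from the first and last clades,
    # mimicking a polyphyletic pathogen group
    labels = list(cfg.clade_sizes.keys())
    first, last = labels[0], labels[-1]
    ids_first = sorted(
        rid for rid, cl in truth.clade_labels.items() if cl == first
    )
    ids_last = sorted(rid for rid, cl in truth.clade_labels.items() if cl == last)
    half = cfg.marker_group_size // 2
    group = tuple(ids_first[:half] + ids_last[: cfg.marker_group_size - half])

    planted, truth = plant_features(
        core,
        truth,
        marker_spec=MarkerSpec(
            cfg.marker_column, cfg.marker_state, group, cfg.marker_out_state
        ),
        insertion_specs=[
            InsertionSpec(
                cfg.insertion_clades, cfg.insertion_length, cfg.insertion_after_col
            )
        ],
        frequencies=model.frequencies,
        seed=sub[3],
    )
    toy = make_toy_bundle(
        residues_per_helix=cfg.bundle_residues,
        spacing=cfg.bundle_spacing,
        seed=sub[4],
        with_ligand=True,
    )
    truth.contact_pairs = set(toy.true_contacts)

    bundle = StudyBundle(planted, core, tree, cp_partner, toy, truth, cfg)
    _audit(bundle)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_fasta(planted.records, out / "msa.fasta")
        write_fasta(core.records, out / "core.fasta")
        write_newick(tree, out / "tree.nwk")
        write_fasta(cp_partner.records, out / "cp_partner.fasta")
        write_pdb(toy.atoms, out / "bundle.pdb")
        with open(out / "helices.yaml", "w") as fh:
            yaml.safe_dump(
                {
                    "sequence_helices": {
                        k: list(v) for k, v in sorted(cfg.helices.items())
                    },
                    "bundle_helices": [
                        {
                            "label": h.label,
                            "chain": h.chain,
                            "start": h.res_start,
                            "end": h.res_end,
                        }
                        for h in toy.helices
                    ],
                },
                fh,
                sort_keys=True,
            )
        (out / "truth.json").write_text(truth.to_json() + "\n")
    return bundle
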