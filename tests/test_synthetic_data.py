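import numpy as np
import pytest

from vkorcp.cp_module import find_cp_offset, half_swap
from vkorcp.io_formats import parse_newick, tree_to_newick
from vkorcp.substitution import get_model
from vkorcp.synthetic_data import (
    CladeSpec,
    InsertionSpec,
    MarkerSpec,
    RatePlan,
    StudyConfig,
    evolve_alignment,
    generate_study_bundle,
    make_cp_family,
    make_toy_bundle,
    plant_features,
    simulate_tree,
)


class TestSimulateTree:
    def test_deterministic_per_seed(self):
        assert tree_to_newick(simulate_tree(5, seed=3)) == tree_to_newick(
            simulate_tree(5, seed=3)
        )
        assert tree_to_newick(simulate_tree(5, seed=3)) != tree_to_newick(
            simulate_tree(5, seed=4)
        )

    def test_clade_spec_round_trip(self):
        from vkorcp.clade_analysis import clade_partition

        spec = CladeSpec({"a": 4, "b": 6, "c": 5}, stem_length=0.5)
        tree = simulate_tree(15, seed=5, clade_spec=spec)
        part = clade_partition(
            tree, {"a": "a_t01", "b": "b_t01", "c": "c_t01"}
        )
        for leaf in tree.leaf_node_iter():
            assert part[leaf.taxon.label] == leaf.taxon.label.split("_")[0]

    def test_infeasible_clade_spec(self):
        with pytest.raises(ValueError, match="sum"):
            simulate_tree(10, seed=1, clade_spec=CladeSpec({"a": 3, "b": 3}))

    def test_total_length_grows_with_taxa(self):
        def mean_total(n):
            totals = []
            for seed in range(20):
                tree = simulate_tree(n, seed=seed)
                totals.append(tree.length())
            return np.mean(totals)

        assert mean_total(5) < mean_total(15) < mean_total(40)


class TestEvolveAlignment:
    def test_zero_branch_lengths_copy_root(self, wag):
        tree = parse_newick("(A:0.0,B:0.0,C:0.0);")
        aln, _ = evolve_alignment(tree, wag, 50, RatePlan(alpha=1.0), seed=6)
        rows = {r.residues for r in aln.records}
        assert len(rows) == 1

    def test_divergence_matches_closed_form(self, wag):
        """Two taxa at distance 1.0: the observed fraction of differing
        sites must match 1 - sum_i pi_i P_ii(1) within 3 standard errors."""
        tree = parse_newick("(A:0.5,B:0.5);")
        n = 50_000
        aln, _ = evolve_alignment(tree, wag, n, RatePlan(alpha=1e9), seed=7)
        diff = np.mean(
            [a != b for a, b in zip(aln.records[0].residues, aln.records[1].residues)]
        )
        p = wag.transition_matrix(1.0)
        expected = 1.0 - float(wag.frequencies @ np.diag(p))
        se = (expected * (1 - expected) / n) ** 0.5
        assert abs(diff - expected) <= 3 * se

    def test_invariant_columns_constant_with_pinned_states(self, wag):
        tree = simulate_tree(12, seed=8)
        plan = RatePlan(
            alpha=1.0, invariant_columns=(3, 9), invariant_states={3: "C", 9: "S"}
        )
        aln, truth = evolve_alignment(tree, wag, 20, plan, seed=9)
        assert set(aln.column(3)) == {"C"}
        assert set(aln.column(9)) == {"S"}
        assert truth.invariant_columns == (3, 9)
        assert truth.site_rates[2] == 0.0


class TestPlantFeatures:
    def test_marker_round_trip(self, wag):
        from vkorcp.clade_analysis import single_site_markers

        tree = simulate_tree(10, seed=10)
        aln, truth = evolve_alignment(tree, wag, 60, RatePlan(alpha=1.0), seed=11)
        group = tuple(aln.ids[:4])
        planted, truth2 = plant_features(
            aln, truth, marker_spec=MarkerSpec(40, "C", group, out_state="L")
        )
        found = single_site_markers(planted, group)
        assert [(m.column, m.state) for m in found] == [(40, "C")]

    def test_insertion_round_trip(self, wag):
        from vkorcp.clade_analysis import CladeAssignment, clade_absent_segments

        spec = CladeSpec({"c1": 5, "c4": 5}, 0.5)
        tree = simulate_tree(10, seed=12, clade_spec=spec)
        model = wag
        aln, truth = evolve_alignment(tree, model, 60, RatePlan(alpha=1.0), seed=13)
        planted, truth2 = plant_features(
            aln, truth, insertion_specs=[InsertionSpec(("c4",), 13, 30)], seed=14
        )
        assert truth2.insertion_blocks["c4"] == (31, 43)
        part = CladeAssignment(truth2.clade_labels, ("c1", "c4"))
        segs = clade_absent_segments(planted, part, "c1", "c4")
        assert [(s.col_start, s.col_end) for s in segs] == [(31, 43)]

    def test_insertion_shifts_downstream_truth(self, wag):
        tree = simulate_tree(6, seed=15)
        plan = RatePlan(alpha=1.0, invariant_columns=(50,), invariant_states={50: "C"})
        aln, truth = evolve_alignment(tree, wag, 60, plan, seed=16)
        for leaf in truth.clade_labels:
            truth.clade_labels[leaf] = "g"
        planted, truth2 = plant_features(
            aln, truth, insertion_specs=[InsertionSpec(("g",), 5, 10)], seed=17
        )
        assert truth2.invariant_columns == (55,)
        assert set(planted.column(55)) == {"C"}

    def test_empty_specs_identity(self, wag):
        tree = simulate_tree(5, seed=18)
        aln, truth = evolve_alignment(tree, wag, 30, RatePlan(alpha=1.0), seed=19)
        planted, _ = plant_features(aln, truth)
        assert [r.residues for r in planted] == [r.residues for r in aln.records]


class TestCpFamily:
    def test_zero_divergence_exact_recovery(self, wag):
        tree = simulate_tree(6, seed=20)
        aln, truth = evolve_alignment(tree, wag, 120, RatePlan(alpha=1.0), seed=21)
        partner, truth2 = make_cp_family(aln, truth, 45, 0.0, seed=22)
        assert truth2.cp_boundary == 45
        for orig, rot in zip(aln.records, partner.records):
            assert rot.residues == half_swap(orig.residues, 45)
            assert find_cp_offset(orig.residues, rot.residues).offset == 45

    def test_involution(self, wag):
        tree = simulate_tree(4, seed=23)
        aln, truth = evolve_alignment(tree, wag, 80, RatePlan(alpha=1.0), seed=24)
        once, _ = make_cp_family(aln, truth, 30, 0.0, seed=25)
        twice, _ = make_cp_family(once, truth, 50, 0.0, seed=26)
        for orig, back in zip(aln.records, twice.records):
            assert back.residues == orig.residues

    def test_boundary_validation(self, wag):
        tree = simulate_tree(4, seed=27)
        aln, truth = evolve_alignment(tree, wag, 40, RatePlan(alpha=1.0), seed=28)
        with pytest.raises(ValueError, match="boundary"):
            make_cp_family(aln, truth, 40, 0.0, seed=29)


class TestToyBundle:
    def test_far_spacing_no_contacts(self):
        toy = make_toy_bundle(spacing=40.0, seed=30)
        assert toy.true_contacts == set()

    def test_deterministic_coordinates(self):
        a = make_toy_bundle(seed=31)
        b = make_toy_bundle(seed=31)
        assert [(x.x, x.y, x.z) for x in a.atoms] == [(x.x, x.y, x.z) for x in b.atoms]

    def test_invalid_spacing(self):
        with pytest.raises(ValueError):
            make_toy_bundle(spacing=0.0)


class TestStudyBundle:
    def test_end_to_end_consistency(self, bundle):
        # the generator's self-audit ran at construction; spot-check shapes
        cfg = bundle.config
        assert len(bundle.alignment) == cfg.n_taxa
        assert bundle.alignment.n_columns == cfg.n_sites + cfg.insertion_length
        assert len(bundle.truth.invariant_columns) == len(cfg.invariant_columns)
        assert bundle.truth.cp_boundary == cfg.cp_boundary

    def test_byte_identical_outputs_per_seed(self, tmp_path):
        small = StudyConfig(
            clade_sizes={"c1": 4, "c2": 4, "c3": 4},
            n_sites=60,
            invariant_columns={20: "C", 23: "C"},
            marker_column=30,
            insertion_clades=("c2",),
            insertion_after_col=40,
            cp_boundary=25,
            helices={"C": (2, 8), "D": (12, 18), "A": (28, 38), "B": (45, 55)},
        )
        generate_study_bundle(small, seed=9, out_dir=tmp_path / "a")
        generate_study_bundle(small, seed=9, out_dir=tmp_path / "b")
        for name in ["msa.fasta", "tree.nwk", "cp_partner.fasta", "bundle.pdb",
                     "truth.json", "helices.yaml", "core.fasta"]:
            assert (tmp_path / "a" / name).read_bytes() == (
                tmp_path / "b" / name
            ).read_bytes()

    def test_empty_clades_rejected(self):
        with pytest.raises(ValueError):
            generate_study_bundle(StudyConfig(clade_sizes={}), seed=1)
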