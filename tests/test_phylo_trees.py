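"""Tree estimation: neighbor joining, branch-length optimization,
rate-parameter estimation, information criteria, bootstrap, rooting,
pruning."""

import math

import numpy as np
import pandas as pd
import pytest

from conftest import additive_matrix
from vkorcp.io_formats import Alignment, SequenceRecord, parse_newick
from vkorcp import phylo
from vkorcp.substitution import get_model
from vkorcp.synthetic_data import CladeSpec, RatePlan, evolve_alignment, simulate_tree


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        dm = pd.DataFrame(
            [[0, 3, 4], [3, 0, 5], [4, 5, 0]],
            index=list("ABC"), columns=list("ABC"), dtype=float,
        )
        tree = phylo.nj_tree(dm)
        lengths = {
            l.taxon.label: l.edge.length for l in tree.leaf_node_iter()
        }
        # three-point formulas: a=(d_ab+d_ac-d_bc)/2 etc.
        assert lengths["A"] == pytest.approx(1.0)
        assert lengths["B"] == pytest.approx(2.0)
        assert lengths["C"] == pytest.approx(3.0)

    def test_additive_six_taxon_recovery(self):
        tree = parse_newick(
            "((A:0.1,B:0.2):0.08,((C:0.3,D:0.15):0.06,E:0.25):0.04,F:0.4);"
        )
        nj = phylo.nj_tree(additive_matrix(tree))
        assert phylo.robinson_foulds(nj, tree) == 0

    def test_tie_determinism(self):
        dm = pd.DataFrame(
            np.array(
                [[0, 2, 4, 4], [2, 0, 4, 4], [4, 4, 0, 2], [4, 4, 2, 0]],
                dtype=float,
            ),
            index=list("ABCD"), columns=list("ABCD"),
        )
        first = phylo.nj_tree(dm).as_string(schema="newick")
        for _ in range(3):
            assert phylo.nj_tree(dm).as_string(schema="newick") == first

    def test_asymmetric_matrix_rejected(self):
        bad = pd.DataFrame(
            [[0, 1, 2], [1.5, 0, 1], [2, 1, 0]],
            index=list("ABC"), columns=list("ABC"), dtype=float,
        )
        with pytest.raises(ValueError, match="symmetric"):
            phylo.nj_tree(bad)

    def test_random_additive_matrices(self):
        for seed in range(10):
            tree = simulate_tree(int(np.random.default_rng(seed).integers(4, 13)),
                                 seed=seed)
            nj = phylo.nj_tree(additive_matrix(tree))
            assert phylo.robinson_foulds(nj, tree) == 0


class TestBranchLengths:
    def test_recovery_on_simulated_data(self, wag):
        true_tree = simulate_tree(8, seed=3)
        for edge in true_tree.preorder_edge_iter():
            if edge.length is not None:
                edge.length = max(edge.length, 0.05)
        aln, _ = evolve_alignment(true_tree, wag, 3000, RatePlan(alpha=1e6), seed=7)
        # a bifurcating root leaves the two root-adjacent lengths jointly
        # unidentifiable (only their sum matters); compare on the unrooted tree
        true_tree.deroot()
        start = true_tree.clone(depth=1)
        for edge in start.preorder_edge_iter():
            if edge.length is not None:
                edge.length = 0.2
        fitted = phylo.optimize_branch_lengths(start, aln, wag, max_passes=6)
        true_lengths = {
            frozenset(l.taxon.label for l in n.leaf_iter()): n.edge.length
            for n in true_tree.postorder_node_iter()
            if n is not true_tree.seed_node
        }
        for node in fitted.postorder_node_iter():
            if node is fitted.seed_node:
                continue
            key = frozenset(l.taxon.label for l in node.leaf_iter())
            truth = true_lengths[key]
            if truth >= 0.05:
                assert node.edge.length == pytest.approx(truth, rel=0.15)

    def test_fixed_point_and_ascent(self, wag):
        tree = simulate_tree(6, seed=1)
        aln, _ = evolve_alignment(tree, wag, 300, RatePlan(alpha=1e6), seed=2)
        before = phylo.total_log_likelihood(aln, tree, wag)
        once = phylo.optimize_branch_lengths(tree, aln, wag, max_passes=4)
        mid = phylo.total_log_likelihood(aln, once, wag)
        assert mid >= before
        twice = phylo.optimize_branch_lengths(once, aln, wag, max_passes=1)
        after = phylo.total_log_likelihood(aln, twice, wag)
        assert after >= mid
        assert after - mid < 1e-3  # essentially converged: a fixed point


class TestRateParams:
    def test_homogeneous_rates_push_alpha_high(self, wag):
        tree = simulate_tree(20, seed=4)
        aln, _ = evolve_alignment(tree, wag, 300, RatePlan(alpha=1e6), seed=5)
        alpha, _ = phylo.estimate_rate_params(aln, tree, wag.with_rates(alpha=1.0))
        assert alpha >= 5.0

    def test_p_inv_near_zero_without_constant_columns(self, wag):
        tree = simulate_tree(12, seed=6)
        model = wag.with_rates(alpha=1.0, p_inv=0.0)
        aln, _ = evolve_alignment(tree, wag, 400, RatePlan(alpha=2.0), seed=8)
        variable = [
            c for c in range(1, aln.n_columns + 1)
            if len(set(aln.column(c))) > 1
        ]
        sub = Alignment(
            [
                SequenceRecord(r.id, "".join(r.residues[c - 1] for c in variable))
                for r in aln.records
            ]
        )
        _, p_inv = phylo.estimate_rate_params(sub, tree, model)
        assert p_inv <= 0.05

    def test_degenerate_alignment_warns(self, wag):
        tree = parse_newick("(A:0.1,B:0.1,C:0.1);")
        aln = Alignment([SequenceRecord(x, "AAAA") for x in "ABC"])
        with pytest.warns(UserWarning, match="no variable columns"):
            phylo.estimate_rate_params(aln, tree, wag.with_rates(alpha=1.0))


class TestInformationCriteria:
    def test_formula_arithmetic(self, wag):
        fit = phylo.ModelFit(wag, log_likelihood=-100.0, k=3, n=50)
        assert fit.aic == 206.0
        assert fit.aicc == pytest.approx(206.0 + 2 * 3 * 4 / (50 - 3 - 1))
        assert fit.bic == pytest.approx(200.0 + 3 * math.log(50))

    def test_degenerate_zero_parameters(self, wag):
        fit = phylo.ModelFit(wag, log_likelihood=0.0, k=0, n=100)
        assert fit.aic == 0.0 and fit.bic == 0.0

    def test_aicc_undefined_flagged(self, wag):
        fit = phylo.ModelFit(wag, log_likelihood=-10.0, k=3, n=4)
        assert not fit.aicc_defined
        assert math.isnan(fit.aicc)

    def test_select_model_identities(self, wag):
        tree = simulate_tree(6, seed=2)
        aln, _ = evolve_alignment(tree, wag, 120, RatePlan(alpha=0.5), seed=3)
        fits = phylo.select_model(aln, tree, ["WAG", "WAG+G"], opt_passes=1)
        for fit in fits:
            assert fit.aic == pytest.approx(-2 * fit.log_likelihood + 2 * fit.k)
            assert fit.bic == pytest.approx(
                -2 * fit.log_likelihood + fit.k * math.log(fit.n)
            )
        assert [f.bic for f in fits] == sorted(f.bic for f in fits)


class TestBootstrap:
    def test_single_replicate_supports_are_binary(self, wag):
        tree = simulate_tree(6, seed=9)
        aln, _ = evolve_alignment(tree, wag, 150, RatePlan(alpha=1.0), seed=10)
        builder = phylo.distance_nj_builder(wag)
        result = phylo.bootstrap_supports(aln, 1, seed=0, tree_builder=builder)
        supports = [
            n.support
            for n in result.postorder_internal_node_iter()
            if hasattr(n, "support")
        ]
        assert supports and all(s in (0.0, 100.0) for s in supports)

    def test_same_seed_reproducible(self, wag):
        tree = simulate_tree(6, seed=11)
        aln, _ = evolve_alignment(tree, wag, 150, RatePlan(alpha=1.0), seed=12)
        builder = phylo.distance_nj_builder(wag)
        a = phylo.bootstrap_supports(aln, 20, seed=7, tree_builder=builder)
        b = phylo.bootstrap_supports(aln, 20, seed=7, tree_builder=builder)
        sa = sorted(n.support for n in a.postorder_internal_node_iter() if hasattr(n, "support"))
        sb = sorted(n.support for n in b.postorder_internal_node_iter() if hasattr(n, "support"))
        assert sa == sb


class TestRootingAndPruning:
    def test_root_bisects_outgroup_branch(self):
        tree = parse_newick("(A:1.0,B:2.0,C:3.0);")
        rooted = phylo.root_with_outgroup(tree, "A")
        assert rooted.is_rooted
        kids = rooted.seed_node.child_nodes()
        assert len(kids) == 2
        out = [k for k in kids if k.is_leaf() and k.taxon.label == "A"]
        assert out and out[0].edge.length == pytest.approx(0.5)

    def test_reroot_then_unroot_preserves_splits(self):
        tree = simulate_tree(10, seed=13)
        label = sorted(l.taxon.label for l in tree.leaf_node_iter())[3]
        rooted = phylo.root_with_outgroup(tree, label)
        assert phylo.tree_splits(rooted) == phylo.tree_splits(tree)

    def test_missing_outgroup(self):
        with pytest.raises(KeyError):
            phylo.root_with_outgroup(parse_newick("(A:1,B:1,C:1);"), "Z")

    def test_prune_keep_all_is_identity(self):
        tree = simulate_tree(8, seed=14)
        keep = sorted(l.taxon.label for l in tree.leaf_node_iter())
        pruned = phylo.prune_to_taxa(tree, keep)
        assert phylo.tree_splits(pruned) == phylo.tree_splits(tree)

    def test_prune_preserves_path_lengths(self):
        tree = simulate_tree(6, seed=15)
        labels = sorted(l.taxon.label for l in tree.leaf_node_iter())
        keep = labels[1:]
        pruned = phylo.prune_to_taxa(tree, keep)
        before = additive_matrix(tree).loc[keep, keep]
        after = additive_matrix(pruned).loc[keep, keep]
        assert np.allclose(before.to_numpy(), after.to_numpy(), atol=1e-9)

    def test_prune_errors(self):
        tree = parse_newick("(A:1,B:1,(C:1,D:1):1);")
        with pytest.raises(KeyError):
            phylo.prune_to_taxa(tree, {"A", "Z"})
        with pytest.raises(ValueError):
            phylo.prune_to_taxa(tree, {"A"})
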