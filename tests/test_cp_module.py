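import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from vkorcp.cp_module import (
    ModuleAlignment,
    ModuleSequence,
    anchor_align,
    best_identity_offset,
    build_module,
    count_identity_sites,
    find_cp_offset,
    half_swap,
    match_conserved_features,
)
from vkorcp.io_formats import AMINO_ACIDS


class TestHalfSwap:
    def test_hand_checkable(self):
        assert half_swap("ABCDEF", 3) == "DEFABC"

    @given(st.text(alphabet=AMINO_ACIDS, min_size=3, max_size=80),
           st.integers(2, 78))
    @settings(max_examples=50, derandomize=True, deadline=None)
    def test_involution_with_complementary_boundary(self, seq, k):
        if not 1 < k < len(seq) - 1:  # complement n-k must also be a valid boundary
            return
        swapped = half_swap(seq, k)
        assert half_swap(swapped, len(seq) - k) == seq

    @pytest.mark.parametrize("bad", [0, 1, 6, 7])
    def test_boundary_out_of_range(self, bad):
        with pytest.raises(ValueError):
            half_swap("ABCDEF", bad)


HELICES = {"C": (10, 30), "D": (85, 105), "A": (110, 130), "B": (135, 155)}


def synthetic_reference(seed=0):
    rng = np.random.default_rng(seed)
    chars = list(rng.choice(list("ARNDEQGHILKMFPSTVWY"), 160))
    chars[119:123] = list("CAAC")  # CXXC inside the A-B span
    return "".join(chars)


class TestBuildModule:
    def test_ab_and_cd_spans(self):
        seq = synthetic_reference()
        ab = build_module(seq, HELICES, "AB")
        cd = build_module(seq, HELICES, "CD")
        assert ab.origin == ("seq", 110, 155)
        assert cd.origin == ("seq", 10, 105)
        assert ab.residues == seq[109:155]
        assert cd.residues == seq[9:105]
        assert ab.anchor == 120 - 110 + 1  # first CXXC, module numbering

    def test_modules_disjoint_and_cover_helices(self):
        seq = synthetic_reference()
        ab = build_module(seq, HELICES, "AB")
        cd = build_module(seq, HELICES, "CD")
        ab_span = set(range(ab.origin[1], ab.origin[2] + 1))
        cd_span = set(range(cd.origin[1], cd.origin[2] + 1))
        assert not ab_span & cd_span
        for start, end in HELICES.values():
            assert set(range(start, end + 1)) <= ab_span | cd_span

    def test_cd_before_ab_reconstructs_core(self):
        seq = synthetic_reference()
        ab = build_module(seq, HELICES, "AB")
        cd = build_module(seq, HELICES, "CD")
        inter = seq[cd.origin[2] : ab.origin[1] - 1]
        assert cd.residues + inter + ab.residues == seq[
            cd.origin[1] - 1 : ab.origin[2]
        ]

    def test_wrong_helix_order_rejected(self):
        with pytest.raises(ValueError, match="precede"):
            build_module("A" * 160, {"A": (50, 60), "B": (10, 20)}, "AB")


class TestAnchorAlign:
    def _module(self, residues, family="f"):
        from vkorcp.cp_module import CXXC

        m = CXXC.search(residues)
        return ModuleSequence(family, "AB", residues,
                              ("x", 1, len(residues)),
                              anchor=m.start() + 1 if m else None)

    def test_shift_arithmetic(self):
        m1 = self._module("A" * 9 + "CAAC" + "A" * 10)   # anchor at 10
        m2 = self._module("G" * 13 + "CAAC" + "G" * 10)  # anchor at 14
        alignment = anchor_align(m1, m2)
        assert alignment.offset == -4
        # the anchored columns coincide in the alignment frame
        assert alignment.frame_of_p1(10) == alignment.frame_of_p2(14)

    def test_identical_modules(self):
        m = self._module("AC" * 5 + "CAAC" + "DE" * 5)
        alignment = anchor_align(m, m)
        assert alignment.offset == 0
        assert alignment.n_identities == len(m)

    def test_missing_anchor_rejected(self):
        m1 = self._module("A" * 9 + "CAAC" + "A" * 10)
        m2 = self._module("G" * 24)
        with pytest.raises(ValueError, match="anchor"):
            anchor_align(m1, m2)


def _plain_module(residues, family="f", module="AB"):
    return ModuleSequence(family, module, residues, ("x", 1, len(residues)))


class TestBestIdentityOffset:
    def test_recovers_planted_shift(self):
        rng = np.random.default_rng(40)
        core = "".join(rng.choice(list("ARNDEQGHILKM"), 30))
        m1 = _plain_module("WW" + core + "YY")
        m2 = _plain_module("FFFFFFF" + core + "PP")
        alignment = best_identity_offset(m1, m2)
        assert alignment.offset == 2 - 7
        assert alignment.n_identities >= 30

    def test_matches_exhaustive_scan(self):
        rng = np.random.default_rng(41)
        for _ in range(10):
            m1 = _plain_module("".join(rng.choice(list("ACDE"), 25)))
            m2 = _plain_module("".join(rng.choice(list("ACDE"), 22)))
            best = best_identity_offset(m1, m2)
            brute = max(
                ModuleAlignment(m1, m2, o).n_identities
                for o in range(-21, 25)
                if len(ModuleAlignment(m1, m2, o).columns) >= 10
            )
            assert best.n_identities == brute

    def test_tie_break_smallest_absolute_then_negative(self):
        m1 = _plain_module("A" * 20)
        m2 = _plain_module("A" * 20)
        # all offsets tie on identity count; the contract picks offset 0
        assert best_identity_offset(m1, m2).offset == 0
        m3 = _plain_module("C" * 20)
        m4 = _plain_module("D" * 20)
        # zero identities everywhere: still deterministic
        assert best_identity_offset(m3, m4).offset == 0

    def test_no_sufficient_overlap(self):
        with pytest.raises(ValueError, match="overlap"):
            best_identity_offset(
                _plain_module("ACDEF"), _plain_module("ACDEF"), min_overlap=10
            )


class TestIdentityCounting:
    def test_identical_pair_counts_full_length(self):
        m = _plain_module("ACDEFGHIKL")
        counts = count_identity_sites(ModuleAlignment(m, m, 0))
        assert counts.count("union") == 10
        assert counts.union_columns == tuple(range(1, 11))

    def test_hand_built_three_matches(self):
        m1 = _plain_module("ACDEFGHIKL")
        m2 = _plain_module("AXDXXGXXXX")
        counts = count_identity_sites(ModuleAlignment(m1, m2, 0))
        assert counts.count("union") == 3
        assert counts.union_columns == (1, 3, 6)

    def test_union_pairwise_triple_modes(self):
        shared = _plain_module("ACDEFGHIKL", family="two")
        a1 = ModuleAlignment(_plain_module("ACDEFXXXXX"), shared, 0)
        a2 = ModuleAlignment(_plain_module("AXXXXGHIKX"), shared, 0)
        counts = count_identity_sites([a1, a2])
        assert counts.pairwise_counts == (5, 5)
        assert counts.union_count == 9
        assert counts.triple_count == 1  # only column 1 matches both
        assert counts.triple_columns == (1,)

    def test_translation_invariance(self):
        m1 = _plain_module("ACDEFGHIKLMNPQRS")
        m2 = _plain_module("XCDEFGHIKLMNPQRX")
        base = count_identity_sites(ModuleAlignment(m1, m2, 0)).union_count
        # padding both modules identically shifts nothing
        p1 = _plain_module("WWW" + m1.residues)
        p2 = _plain_module("WWW" + m2.residues)
        assert count_identity_sites(ModuleAlignment(p1, p2, 0)).union_count == base + 3


class TestFeatureMatching:
    def test_empty_features_empty_matches(self):
        m = _plain_module("ACDEFGHIKL")
        assert match_conserved_features(
            ModuleAlignment(m, m, 0), {}, {}, [], []
        ) == []

    def test_planted_coincident_features_with_decoys(self):
        n = 40
        m1 = ModuleSequence("f1", "AB", "A" * n, ("r1", 101, 100 + n))
        m2 = ModuleSequence("f2", "AB", "A" * n, ("r2", 1, n))
        planted = [5, 12, 20, 33]  # module positions
        feats1 = [100 + p for p in planted] + [100 + 8]         # decoy: only family 1
        feats2 = [p for p in planted] + [26]                    # decoy: only family 2
        prof1 = {100 + p: 9 for p in range(1, n + 1)}
        prof2 = {p: 8 for p in range(1, n + 1)}
        prof2[33] = 9
        matches = match_conserved_features(
            ModuleAlignment(m1, m2, 0), prof1, prof2, feats1, feats2, min_grade=6
        )
        assert [m.frame_position for m in matches] == planted
        assert all(m.grade_1 == 9 for m in matches)

    def test_low_grade_features_filtered(self):
        m = _plain_module("ACDEFGHIKL")
        matches = match_conserved_features(
            ModuleAlignment(m, m, 0), {3: 4}, {3: 9}, [3], [3], min_grade=6
        )
        assert matches == []

    def test_outside_module_feature_warns(self):
        m = ModuleSequence("f", "AB", "ACDEFGHIKL", ("r", 10, 19))
        with pytest.warns(UserWarning, match="outside"):
            match_conserved_features(
                ModuleAlignment(m, m, 0), {}, {}, [99], []
            )


class TestFindCpOffset:
    def test_identity_is_offset_zero(self):
        rng = np.random.default_rng(42)
        seq = "".join(rng.choice(list(AMINO_ACIDS), 80))
        assert find_cp_offset(seq, seq).offset == 0

    def test_exact_rotation_recovered(self):
        rng = np.random.default_rng(43)
        seq = "".join(rng.choice(list(AMINO_ACIDS), 150))
        rotated = seq[37:] + seq[:37]
        result = find_cp_offset(seq, rotated)
        assert result.offset == 37
        assert int(np.argmax(result.score_profile)) == 37

    @pytest.mark.parametrize("k", [1, 25, 74, 149])
    def test_rotation_property(self, k):
        rng = np.random.default_rng(44 + k)
        seq = "".join(rng.choice(list(AMINO_ACIDS), 150))
        assert find_cp_offset(seq, seq[k:] + seq[:k]).offset == k

    def test_low_complexity_flagged(self):
        with pytest.warns(UserWarning, match="low-complexity"):
            result = find_cp_offset("A" * 30, "A" * 30)
        assert result.low_complexity

    def test_short_input_rejected(self):
        with pytest.raises(ValueError, match="20"):
            find_cp_offset("ACDEF", "ACDEF")
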