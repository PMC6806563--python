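import random

import pytest
from hypothesis import given, strategies as st

from bescan._sequence import Strand, revcomp
from bescan.oracle import oracle_enumerate, oracle_scan
from bescan.panel import CombineMode, EditorPanel, EditorSpec, PamSide
from bescan.targeting import (classify_preferential, combine_panel,
                              enumerate_guides, match_pam, panel_statistics,
                              scan_sequence)
from bescan.variants import EditClass, FlankedTarget

from conftest import cand_tuple, random_editor, random_seq


class TestMatchPam:
    @pytest.mark.parametrize("pattern,obs,expected", [
        ("NGG", "AGG", True),
        ("TTTV", "TTTT", False),   # V excludes T
        ("TTTV", "TTTA", True),
        ("NNGRRT", "AAGAGT", True),
        ("NGG", "AGA", False),
        ("NGG", "NGG", False),     # ambiguous observed base never matches
    ])
    def test_examples(self, pattern, obs, expected):
        assert match_pam(pattern, obs) is expected

    def test_length_mismatch_is_error(self):
        with pytest.raises(ValueError, match="length"):
            match_pam("NGG", "AG")

    @given(st.text(alphabet="ACGT", min_size=1, max_size=6))
    def test_all_n_matches_any_acgt_string(self, obs):
        assert match_pam("N" * len(obs), obs)

    @given(st.text(alphabet="ACGT", min_size=1, max_size=6))
    def test_pattern_equal_to_observed_matches(self, obs):
        assert match_pam(obs, obs)


def _target(seq: str, offset: int, strand: Strand = Strand.PLUS):
    return FlankedTarget(sequence=seq, target_offset=offset,
                         target_strand=strand)


def build_target_61mer(p: int, editor: EditorSpec, background: str = "T",
                       pam: str = None) -> FlankedTarget:
    """A 61-mer with one C at the centre placed at window position p.

    Background excludes C and G so the only PAM present is the planted one.
    """
    t = 30
    seq = [background] * 61
    seq[t] = "C"
    start = t - (p - 1)
    if pam is None:
        pam = {"NGG": "AGG", "TTTV": "TTTA"}[editor.pam_pattern]
    if editor.pam_side is PamSide.THREE_PRIME:
        lo = start + editor.spacer_length
    else:
        lo = start - len(pam)
    seq[lo:lo + len(pam)] = list(pam)
    return _target("".join(seq), t)


class TestEnumerateGuides:
    def test_single_planted_pam_yields_one_preferential_candidate(self, be3):
        target = build_target_61mer(6, be3)
        cands = enumerate_guides(target, be3)
        assert len(cands) == 1
        c = cands[0]
        assert c.target_window_position == 6
        assert c.bystander_positions == ()
        assert c.preferential and classify_preferential(c)
        assert c.pam_observed == "AGG"
        assert len(c.spacer_sequence) == 20
        # independent brute force agrees
        oracle = oracle_enumerate(target.sequence, 30, "+", "NGG",
                                  "three_prime", 20, 4, 8)
        assert [cand_tuple(c) for c in cands] == oracle

    def test_degenerate_pam_full_window_yields_window_width(self):
        ed = EditorSpec("deg", "NNN", PamSide.THREE_PRIME, 20, 1, 20)
        target = _target("A" * 30 + "C" + "A" * 30, 30)
        cands = enumerate_guides(target, ed)
        assert len(cands) == 20
        assert [c.target_window_position for c in cands] == list(range(1, 21))

    def test_no_pam_anywhere_yields_zero_candidates(self, be3):
        target = _target("A" * 30 + "C" + "A" * 30, 30)
        assert enumerate_guides(target, be3) == []

    def test_bystander_cytosines_recorded_on_target_strand_only(self, be3):
        # extra C at window position 5 and a G (not a bystander) at 7
        target = build_target_61mer(6, be3)
        s = list(target.sequence)
        start = 30 - (6 - 1)
        s[start + 4] = "C"   # window position 5
        s[start + 6] = "G"   # window position 7: G is not a bystander
        target = _target("".join(s), 30)
        [c] = enumerate_guides(target, be3)
        assert c.bystander_positions == (5,)
        assert not c.preferential

    def test_ambiguous_base_in_placement_rejected_and_tallied(self, be3):
        target = build_target_61mer(6, be3)
        s = list(target.sequence)
        s[30 - 5 + 2] = "N"  # inside the protospacer
        diags = {}
        assert enumerate_guides(_target("".join(s), 30), be3,
                                diagnostics=diags) == []
        # every in-bounds placement (p=4..8) spans the N and is tallied
        assert diags["ambiguous_rejected"] == 5

    def test_candidates_ordered_by_window_position(self, be3):
        rng = random.Random(99)
        for _ in range(50):
            seq = random_seq(rng, 61)
            i = seq.find("C")
            if i < 0:
                continue
            cands = enumerate_guides(_target(seq, i), be3)
            pos = [c.target_window_position for c in cands]
            assert pos == sorted(pos)


class TestOracleAgreement:
    def test_matches_brute_force_on_random_sequences(self, panel):
        rng = random.Random(12345)
        editors = list(panel) + [random_editor(rng, f"r{i}") for i in range(10)]
        n_nonempty = 0
        for trial in range(300):
            seq = random_seq(rng, 61)
            targets = [i for i, b in enumerate(seq) if b in "CG"]
            if not targets:
                continue
            i = rng.choice(targets)
            strand = Strand.PLUS if seq[i] == "C" else Strand.MINUS
            ed = rng.choice(editors)
            got = [cand_tuple(c) for c in
                   enumerate_guides(_target(seq, i, strand), ed)]
            want = oracle_enumerate(seq, i, strand.value, ed.pam_pattern,
                                    ed.pam_side.value, ed.spacer_length,
                                    ed.window_start, ed.window_end)
            assert got == want
            n_nonempty += bool(want)
        assert n_nonempty > 20  # the comparison actually exercised hits


class TestMonotonicityAndSymmetry:
    def test_widening_window_never_loses_candidates(self):
        rng = random.Random(7)
        for _ in range(100):
            seq = random_seq(rng, 61)
            i = next((k for k, b in enumerate(seq) if b == "C"), None)
            if i is None:
                continue
            narrow = EditorSpec("n", "NG", PamSide.THREE_PRIME, 20, 5, 7)
            wide = EditorSpec("w", "NG", PamSide.THREE_PRIME, 20, 3, 9)
            n = len(enumerate_guides(_target(seq, i), narrow))
            w = len(enumerate_guides(_target(seq, i), wide))
            assert w >= n

    def test_tightening_pam_never_gains_candidates(self):
        rng = random.Random(8)
        loose = EditorSpec("l", "NNN", PamSide.THREE_PRIME, 20, 4, 8)
        tight = EditorSpec("t", "NGN", PamSide.THREE_PRIME, 20, 4, 8)
        tighter = EditorSpec("tt", "NGG", PamSide.THREE_PRIME, 20, 4, 8)
        for _ in range(100):
            seq = random_seq(rng, 61)
            i = next((k for k, b in enumerate(seq) if b == "C"), None)
            if i is None:
                continue
            counts = [len(enumerate_guides(_target(seq, i), ed))
                      for ed in (loose, tight, tighter)]
            assert counts[0] >= counts[1] >= counts[2]

    def test_strand_symmetry_under_reverse_complement(self, panel):
        rng = random.Random(9)
        editors = list(panel)
        for _ in range(100):
            seq = random_seq(rng, 61)
            i = next((k for k, b in enumerate(seq) if b in "CG"), None)
            if i is None:
                continue
            strand = Strand.PLUS if seq[i] == "C" else Strand.MINUS
            ed = rng.choice(editors)
            fwd = enumerate_guides(_target(seq, i, strand), ed)
            rc = revcomp(seq)
            j = len(seq) - 1 - i
            rstrand = Strand.MINUS if strand is Strand.PLUS else Strand.PLUS
            rev = enumerate_guides(_target(rc, j, rstrand), ed)
            assert len(fwd) == len(rev)
            for a, b in zip(fwd, rev):
                assert a.spacer_sequence == b.spacer_sequence
                assert a.pam_observed == b.pam_observed
                assert a.target_window_position == b.target_window_position
                assert a.bystander_positions == b.bystander_positions
                # intervals mirror: plus-strand coords of the rc sequence
                s, e = a.protospacer_interval
                assert b.protospacer_interval == (len(seq) - e, len(seq) - s)


class TestScanSequence:
    def test_sequence_without_c_or_g_yields_nothing(self, panel):
        assert scan_sequence("AT" * 40, panel) == []

    def test_non_nucleotide_characters_listed(self, panel):
        with pytest.raises(ValueError, match="5"):
            scan_sequence("ACGTA" + "X" + "ACGT" * 10, panel)

    def test_too_short_sequence_rejected(self, be3):
        with pytest.raises(ValueError, match="shorter"):
            scan_sequence("ACGT", [be3])

    def test_matches_oracle_on_random_200mer(self, be3, cpf1):
        rng = random.Random(4242)
        seq = random_seq(rng, 200)
        for ed in (be3, cpf1):
            got = [(h.position, h.strand.value, cand_tuple(h.candidate))
                   for h in scan_sequence(seq, [ed])]
            want = oracle_scan(seq, ed.pam_pattern, ed.pam_side.value,
                               ed.spacer_length, ed.window_start,
                               ed.window_end)
            assert got == want
            assert len(got) > 0

    def test_reverse_complement_scan_is_mirror_image(self, be3):
        rng = random.Random(77)
        seq = random_seq(rng, 120)
        fwd = {(h.position, h.strand.value, h.candidate.spacer_sequence,
                h.candidate.target_window_position)
               for h in scan_sequence(seq, [be3])}
        rev = {(len(seq) - 1 - h.position,
                "-" if h.strand is Strand.PLUS else "+",
                h.candidate.spacer_sequence,
                h.candidate.target_window_position)
               for h in scan_sequence(revcomp(seq), [be3])}
        assert fwd == rev


class TestCombineAndStatistics:
    def _reports(self):
        from bescan.targeting import TargetabilityReport, GuideCandidate

        def cand(name, pref):
            return GuideCandidate(name, Strand.PLUS, (0, 20), "A" * 20,
                                  "AGG", 5, () if pref else (6,))

        r1 = TargetabilityReport("v1", EditClass.CREATE_C_TO_T,
                                 {"E1": [cand("E1", True)], "E2": []})
        r2 = TargetabilityReport("v2", EditClass.CREATE_C_TO_T,
                                 {"E1": [cand("E1", False)],
                                  "E2": [cand("E2", True)]})
        r3 = TargetabilityReport("v3", EditClass.CORRECT_T_TO_C,
                                 {"E1": [], "E2": []})
        return [r1, r2, r3]

    def test_union_and_intersection_match_set_algebra(self):
        reps = self._reports()
        u = combine_panel(reps, CombineMode.UNION)
        i = combine_panel(reps, CombineMode.INTERSECTION)
        assert list(u["targetable"]) == [True, True, False]
        assert list(i["targetable"]) == [False, True, False]
        assert list(u["preferential"]) == [True, True, False]
        assert list(i["preferential"]) == [False, False, False]
        # union is never below, intersection never above, any single editor
        single = combine_panel(reps, CombineMode.UNION, editors=["E1"])
        assert all(u["targetable"] >= single["targetable"])
        assert all(i["targetable"] <= single["targetable"])

    def test_single_editor_union_equals_intersection(self):
        reps = self._reports()
        u = combine_panel(reps, "union", editors=["E2"])
        i = combine_panel(reps, "intersection", editors=["E2"])
        assert u.equals(i)

    def test_empty_editor_selection_is_error(self):
        with pytest.raises(ValueError, match="empty"):
            combine_panel(self._reports(), "union", editors=[])

    def test_panel_statistics_counts_and_fractions(self):
        stats = panel_statistics(self._reports())
        assert stats.loc["E1", "n_targetable"] == 2
        assert stats.loc["E2", "n_targetable"] == 1
        assert stats.loc["E1", "n_preferential"] == 1
        assert stats.loc["any", "n_targetable"] == 2
        assert stats.loc["any", "frac_targetable"] == pytest.approx(2 / 3)

    def test_preferential_editors_subset_of_targetable(self):
        for rep in self._reports():
            assert rep.preferential_editors <= rep.targetable_editors
            assert rep.any_targetable == bool(rep.targetable_editors)
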