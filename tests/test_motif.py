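import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from uimtools.motif import (DISORDERED_UIM_PATTERN, UIM_CONSENSUS_PATTERN,
                            PatternError, angular_distance, compile_pattern,
                            enrichment, face_members, hit_sequence_count,
                            scan, suboptimal_residue_report, wheel_projection)
from uimtools.synthetic import generate_sequence_database
from oracles import brute_scan

REDUCED_ALPHABET = "EDALSGKVQN"


class TestCompile:
    def test_disordered_uim_pattern_shape(self):
        pat = compile_pattern(DISORDERED_UIM_PATTERN)
        assert len(pat.positions) == 17
        assert pat.min_length == 17 and pat.max_length == 18
        variable = [p for p in pat.positions if p[2] > p[1]]
        assert len(variable) == 1 and variable[0][1:] == (1, 2)

    def test_consensus_symbolic_classes(self):
        pat = compile_pattern(UIM_CONSENSUS_PATTERN)
        assert len(pat.positions) == 17
        assert pat.positions[1][0] == frozenset("DE")      # Ac
        assert pat.positions[5][0] == frozenset("AILMFVW")  # Phi default
        assert pat.positions[8][0] == frozenset("A")
        assert pat.positions[12][0] == frozenset("S")

    def test_custom_hydrophobic_set(self):
        pat = compile_pattern("Phi-x", hydrophobic=frozenset("LI"))
        assert pat.positions[0][0] == frozenset("LI")

    def test_simple_pattern(self):
        pat = compile_pattern("x-S-x")
        assert len(pat.positions) == 3
        assert all(lo == hi == 1 for _, lo, hi in pat.positions)

    @pytest.mark.parametrize("bad", ["x-[ED-x", "x--x", "x-Zz-x", "x-[ED]]-x"])
    def test_malformed_notation_rejected(self, bad):
        with pytest.raises(PatternError):
            compile_pattern(bad)


class TestScan:
    def setup_method(self):
        self.pat = compile_pattern(DISORDERED_UIM_PATTERN)

    def test_17mer_positive_single_hit(self):
        hits = scan([("a", "GEEDALKQAVEGSAAEG")], self.pat)
        assert hits == [type(hits[0])("a", 1, 17, "GEEDALKQAVEGSAAEG")]

    def test_18mer_uses_two_residue_gap(self):
        hits = scan([("a", "GEEDALKQNAVEGSAAEG")], self.pat)
        assert len(hits) == 1
        assert (hits[0].start, hits[0].end) == (1, 18)

    def test_serine_free_sequences_never_hit(self):
        rng = np.random.default_rng(0)
        letters = "EDALGKVQN"
        db = [(f"s{i}", "".join(rng.choice(list(letters), 60)))
              for i in range(30)]
        assert scan(db, self.pat) == []

    def test_hits_stable_under_record_reordering(self):
        db = generate_sequence_database(
            40, 60, planted=("GEEDALKQAVEGSAAEG", 15), seed=4)
        fwd = scan(db, self.pat)
        rev = scan(db[::-1], self.pat)
        assert sorted((h.seq_id, h.start, h.end) for h in fwd) == \
            sorted((h.seq_id, h.start, h.end) for h in rev)

    def test_agrees_with_brute_force_oracle(self):
        """Exhaustive cross-check on mutated positives + random strings."""
        rng = np.random.default_rng(99)
        positives = ["GEEDALKQAVEGSAAEG", "GEEDALKQNAVEGSAAEG"]
        strings = []
        for _ in range(4000):
            base = list(positives[rng.integers(2)])
            for _ in range(rng.integers(0, 4)):
                base[rng.integers(len(base))] = REDUCED_ALPHABET[
                    rng.integers(len(REDUCED_ALPHABET))]
            strings.append("".join(base))
        for _ in range(4000):
            n = rng.integers(1, 19)
            strings.append("".join(rng.choice(list(REDUCED_ALPHABET), n)))
        n_hits = 0
        for k, s in enumerate(strings):
            expected = brute_scan(s, self.pat.positions)
            got = [(h.start - 1, h.end - h.start + 1)
                   for h in scan([(f"s{k}", s)], self.pat)]
            assert got == expected, s
            n_hits += len(expected)
        assert n_hits >= 1000  # the mutated positives keep the check two-sided

    def test_lowercase_uppercased_with_warning(self):
        with pytest.warns(UserWarning, match="lowercase"):
            hits = scan([("a", "geedalkqavegsaaeg")], self.pat)
        assert len(hits) == 1

    def test_sequence_count(self):
        db = generate_sequence_database(
            50, 60, planted=("GEEDALKQAVEGSAAEG", 10), seed=6)
        hits = scan(db, self.pat)
        assert hit_sequence_count(hits) >= 10


class TestEnrichment:
    def setup_method(self):
        self.pat = compile_pattern(DISORDERED_UIM_PATTERN)

    def test_planted_signal_detected(self):
        db = generate_sequence_database(
            60, 60, planted=("GEEDALKQAVEGSAAEG", 20), seed=10)
        res = enrichment(db, self.pat, n_shuffles=60, seed=3)
        assert res.observed >= 20
        assert res.p_value <= 0.05
        assert res.enrichment_ratio > 1.0 or res.enrichment_ratio == float("inf")

    def test_impossible_pattern_gives_p_one(self):
        comp = {aa: 1.0 for aa in "ACDEFGHIKLMNPQRTVWY"}  # serine-free
        db = generate_sequence_database(20, 60, composition=comp, seed=0)
        res = enrichment(db, self.pat, n_shuffles=20, seed=1)
        assert res.observed == 0
        assert set(res.null_counts) == {0}
        assert res.p_value == 1.0
        assert res.enrichment_ratio == 0.0

    def test_deterministic_under_seed(self):
        db = generate_sequence_database(
            20, 60, planted=("GEEDALKQAVEGSAAEG", 5), seed=2)
        a = enrichment(db, self.pat, n_shuffles=15, seed=7)
        b = enrichment(db, self.pat, n_shuffles=15, seed=7)
        assert a == b

    def test_single_shuffle_p_values(self):
        db = generate_sequence_database(
            20, 60, planted=("GEEDALKQAVEGSAAEG", 5), seed=2)
        res = enrichment(db, self.pat, n_shuffles=1, seed=0)
        assert res.p_value in (0.5, 1.0)


class TestWheel:
    def test_definitional_angles(self, demo_seq):
        wheel = wheel_projection(demo_seq.window(336, 350))
        assert wheel.angles[336] == 0.0
        assert wheel.angles[337] == 100.0

    def test_uim3_landmark_angles(self, demo_seq):
        # positions 8, 10, 12, 15 of the window: (k-1)*100 mod 360
        wheel = wheel_projection(demo_seq.window(336, 350))
        assert wheel.angles[343] == 340.0  # conserved Ala
        assert wheel.angles[347] == 20.0   # conserved Ser
        assert wheel.angles[350] == 320.0
        assert wheel.angles[345] == 180.0

    def test_consecutive_steps_100_degrees(self, demo_seq):
        window = demo_seq.window(336, 353)
        wheel = wheel_projection(window)
        nums = list(window.residue_numbers)
        assert len(nums) == 18
        for a, b in zip(nums, nums[1:]):
            step = (wheel.angles[b] - wheel.angles[a]) % 360.0
            assert step == pytest.approx(100.0)

    def test_conserved_face_holds_ala_ser_thr(self, demo_seq):
        wheel = wheel_projection(demo_seq.window(336, 350))
        face = face_members(wheel, 343, half_width=40.0)
        assert {343, 347, 350} <= face

    def test_half_width_extremes(self, demo_seq):
        wheel = wheel_projection(demo_seq.window(336, 350))
        assert face_members(wheel, 343, 0.0) == {343}
        assert face_members(wheel, 343, 180.0) == set(wheel.angles)

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(st.integers(0, 1000))
    def test_face_membership_symmetric(self, demo_seq, seed):
        rng = np.random.default_rng(seed)
        wheel = wheel_projection(demo_seq.window(336, 350))
        nums = list(wheel.angles)
        a, b = rng.choice(nums, 2, replace=False)
        hw = float(rng.uniform(0, 180))
        assert (b in face_members(wheel, a, hw)) == \
            (a in face_members(wheel, b, hw))

    def test_window_outside_sequence_rejected(self, demo_seq):
        with pytest.raises(IndexError):
            demo_seq.window(336, 400)


class TestSuboptimalReport:
    def test_uim3_beta_branched_inventory(self, demo_seq):
        report = suboptimal_residue_report(demo_seq.window(336, 350),
                                           conserved=(343, 347))
        names = [r["residue"] for r in report]
        assert names == ["V344", "T345", "T350"]
        by_name = {r["residue"]: r for r in report}
        assert by_name["T350"]["on_conserved_face"]

    def test_no_beta_branched_empty(self):
        from uimtools.sequences import PeptideSequence
        win = PeptideSequence("w", "AEDQLRKASEQSLGN", 336)
        assert suboptimal_residue_report(win, conserved=(343, 347)) == []

    def test_all_valine_everything_reported(self):
        from uimtools.sequences import PeptideSequence
        win = PeptideSequence("w", "V" * 10, 1)
        with pytest.warns(UserWarning):
            report = suboptimal_residue_report(win, conserved=(3, 7))
        assert len(report) == 10

    def test_angular_distance_is_circle_metric(self):
        assert angular_distance(350.0, 10.0) == 20.0
        assert angular_distance(0.0, 180.0) == 180.0
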