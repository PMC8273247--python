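from pathlib import Path

import numpy as np
import pandas as pd
import pytest

from uimtools.chemshift import (ChemicalShiftSet, ClassificationResult,
                                PredictorVariance, ShiftParseError,
                                classify_motif, helix_population,
                                read_nmrstar, read_shift_table, reduced_chi2,
                                secondary_shifts)
from uimtools.synthetic import load_random_coil_table

DATA = Path(__file__).parent / "data"


def shift_set(rows, provenance="test"):
    return ChemicalShiftSet(
        pd.DataFrame(rows, columns=["residue_number", "residue_type",
                                    "nucleus", "shift_ppm"]), provenance)


class TestNmrStarReader:
    def test_fixture_round_trip(self):
        shifts = read_nmrstar(DATA / "shifts_fixture.str")
        assert len(shifts) == 18
        assert list(shifts.residue_numbers) == [336, 337, 338, 339, 340, 341]
        assert shifts.value(338, "CA") == pytest.approx(54.80)
        assert shifts.residue_types()[340] == "L"

    def test_duplicate_row_rejected(self, tmp_path):
        text = (DATA / "shifts_fixture.str").read_text()
        dup = text.replace("      17 341 ARG CB  30.70\n",
                           "      17 341 ARG CB  30.70\n"
                           "      19 341 ARG CB  30.80\n")
        assert dup != text
        p = tmp_path / "dup.str"
        p.write_text(dup)
        with pytest.raises(ShiftParseError, match="duplicate"):
            read_nmrstar(p)

    def test_unsupported_nuclei_only_gives_empty_set(self, tmp_path):
        text = (DATA / "shifts_fixture.str").read_text()
        p = tmp_path / "hb.str"
        p.write_text(text.replace(" CA ", " HB ").replace(" CB ", " HB2 ")
                     .replace(" N ", " HB3 "))
        shifts = read_nmrstar(p)
        assert len(shifts) == 0

    def test_malformed_value_reported(self, tmp_path):
        text = (DATA / "shifts_fixture.str").read_text()
        p = tmp_path / "bad.str"
        p.write_text(text.replace("57.10", "fiftyseven"))
        with pytest.raises(ShiftParseError, match="malformed"):
            read_nmrstar(p)


class TestShiftSetInvariants:
    def test_conflicting_residue_type_rejected(self):
        with pytest.raises(ShiftParseError, match="conflicting"):
            shift_set([(1, "A", "CA", 52.0), (1, "G", "CB", 20.0)])

    def test_tsv_dialect_round_trip(self, tmp_path):
        from uimtools.io import write_shift_table
        s = shift_set([(336, "E", "CA", 57.1), (336, "E", "CB", 29.7)])
        p = tmp_path / "s.tsv"
        write_shift_table(s, p)
        back = read_shift_table(p)
        pd.testing.assert_frame_equal(back.entries, s.entries)


class TestReducedChi2:
    def test_identical_sets_zero(self):
        s = shift_set([(1, "A", "CA", 52.0), (2, "G", "CA", 45.0)])
        assert reduced_chi2(s, s) == 0.0

    def test_each_deviation_one_sigma_gives_one(self):
        sig = PredictorVariance({"CA": 0.9})
        calc = shift_set([(i, "A", "CA", 52.0 + 0.9) for i in range(4)])
        exp = shift_set([(i, "A", "CA", 52.0) for i in range(4)])
        assert reduced_chi2(calc, exp, sig) == pytest.approx(1.0)

    def test_hand_summed_mixed_nuclei(self):
        # 2 CA deviations of 1.0 ppm (sigma 0.8) + 2 N deviations of 2.0 ppm
        # (sigma 2.0): (2*(1/0.8)^2 + 2*1^2)/4 = 1.28125
        sig = PredictorVariance({"CA": 0.8, "N": 2.0})
        calc = shift_set([(1, "A", "CA", 53.0), (2, "A", "CA", 53.0),
                          (1, "A", "N", 122.0), (2, "A", "N", 122.0)])
        exp = shift_set([(1, "A", "CA", 52.0), (2, "A", "CA", 52.0),
                         (1, "A", "N", 120.0), (2, "A", "N", 120.0)])
        assert reduced_chi2(calc, exp, sig) == pytest.approx(1.28125, abs=1e-12)

    def test_scale_law_doubling_deviations_quadruples(self):
        rng = np.random.default_rng(0)
        base = [(i, "A", "CA", 52.0) for i in range(20)]
        dev = rng.normal(0, 1, 20)
        c1 = shift_set([(i, a, n, v + d) for (i, a, n, v), d in zip(base, dev)])
        c2 = shift_set([(i, a, n, v + 2 * d) for (i, a, n, v), d in zip(base, dev)])
        e = shift_set(base)
        assert reduced_chi2(c2, e) == pytest.approx(4 * reduced_chi2(c1, e))

    def test_sigma_scaled_gaussian_deviations_have_unit_mean(self):
        rng = np.random.default_rng(123)
        sig = PredictorVariance()
        nuclei = ["CA", "CB", "N", "H"]
        rows_exp, rows_calc = [], []
        for i in range(2500):
            for nuc in nuclei:
                v = 100.0
                rows_exp.append((i, "A", nuc, v))
                rows_calc.append((i, "A", nuc,
                                  v + rng.normal(0, sig.for_nucleus(nuc))))
        chi2 = reduced_chi2(shift_set(rows_calc), shift_set(rows_exp), sig)
        assert 0.95 <= chi2 <= 1.05

    def test_no_overlap_rejected(self):
        a = shift_set([(1, "A", "CA", 52.0)])
        b = shift_set([(2, "A", "CA", 52.0)])
        with pytest.raises(ValueError, match="common"):
            reduced_chi2(a, b)

    def test_missing_sigma_reported(self):
        s = shift_set([(1, "A", "HA", 4.3)])
        with pytest.raises(KeyError, match="HA"):
            reduced_chi2(s, s, PredictorVariance({"CA": 0.9}))


class TestSecondaryShifts:
    def test_random_coil_input_gives_zero(self):
        rc = load_random_coil_table()
        s = shift_set([(1, "A", "CA", rc.loc["A", "CA"]),
                       (1, "A", "CB", rc.loc["A", "CB"])])
        sec = secondary_shifts(s)
        assert sec.loc[1, "CA"] == pytest.approx(0.0)
        assert sec.loc[1, "CB"] == pytest.approx(0.0)

    def test_offset_appears_only_on_shifted_nucleus(self):
        rc = load_random_coil_table()
        s = shift_set([(1, "E", "CA", rc.loc["E", "CA"] + 2.8),
                       (1, "E", "CB", rc.loc["E", "CB"])])
        sec = secondary_shifts(s)
        assert sec.loc[1, "CA"] == pytest.approx(2.8)
        assert sec.loc[1, "CB"] == pytest.approx(0.0)


class TestHelixPopulation:
    def sec_frame(self, dca, dcb, resnums=None):
        resnums = resnums or range(1, len(dca) + 1)
        return pd.DataFrame({"CA": dca, "CB": dcb}, index=list(resnums))

    def test_zero_secondary_shifts_give_coil(self):
        prof = helix_population(self.sec_frame([0.0] * 5, [0.0] * 5))
        assert np.all(prof.populations["helix"] == 0.0)
        assert np.all(prof.populations["coil"] == 1.0)

    def test_full_offsets_give_full_helix(self):
        prof = helix_population(self.sec_frame([2.8] * 5, [-0.5] * 5))
        np.testing.assert_allclose(prof.populations["helix"].to_numpy(), 1.0)

    def test_monotone_in_ca_antitone_in_cb(self):
        lower = helix_population(self.sec_frame([1.0] * 5, [0.0] * 5),
                                 smooth_window=1)
        higher_ca = helix_population(self.sec_frame([1.5] * 5, [0.0] * 5),
                                     smooth_window=1)
        higher_cb = helix_population(self.sec_frame([1.0] * 5, [0.3] * 5),
                                     smooth_window=1)
        assert np.all(higher_ca.helix >= lower.helix)
        assert np.all(higher_cb.helix <= lower.helix)

    def test_populations_sum_to_one(self):
        rng = np.random.default_rng(1)
        prof = helix_population(self.sec_frame(rng.normal(1.4, 1.0, 20),
                                               rng.normal(-0.2, 1.0, 20)))
        total = prof.populations[["helix", "extended", "coil"]].sum(axis=1)
        np.testing.assert_allclose(total, 1.0)

    def test_residues_missing_cb_are_excluded(self):
        sec = self.sec_frame([1.0, 1.0, 1.0], [0.0, np.nan, 0.0])
        prof = helix_population(sec, smooth_window=1)
        assert prof.n_missing == 1
        assert 2 not in prof.populations.index

    def test_equal_offsets_rejected(self):
        with pytest.raises(ValueError, match="offset"):
            helix_population(self.sec_frame([1.0], [1.0]),
                             offsets={"CA": 1.0, "CB": 1.0})


class TestClassification:
    def profile(self, p, n=15, start=336):
        pops = pd.DataFrame({"helix": [p] * n, "extended": [0.0] * n,
                             "coil": [1.0 - p] * n},
                            index=range(start, start + n))
        from uimtools.chemshift import SecondaryStructureProfile
        return SecondaryStructureProfile(pops)

    @pytest.mark.parametrize("p,expected", [
        (0.45, "helical"), (0.05, "disordered"), (0.20, "intermediate"),
        (0.30, "intermediate"), (0.10, "intermediate"),
    ])
    def test_threshold_rule(self, p, expected):
        res = classify_motif(self.profile(p), (336, 350))
        assert res.classification == expected
        assert res.n_residues_with_data == 15

    def test_monotone_in_population(self):
        order = {"disordered": 0, "intermediate": 1, "helical": 2}
        last = 0
        for p in (0.02, 0.10, 0.25, 0.35, 0.60):
            cls = classify_motif(self.profile(p), (336, 350)).classification
            assert order[cls] >= last
            last = order[cls]

    def test_no_data_in_motif_rejected(self):
        with pytest.raises(ValueError, match="336-350"):
            classify_motif(self.profile(0.5, n=5, start=100), (336, 350))
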