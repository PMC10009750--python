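"""b/y fragment generation, tolerance matching, and ladder reading."""

import numpy as np
import pytest

from fretscreen.chem import PROTON_MASS, parse_peptide
from fretscreen.fragments import Spectrum, ladder_read, match_peaks, theoretical_fragments
from fretscreen.msio import read_mgf, read_tsv, write_mgf, write_tsv
from conftest import CURRENT, PARENT, random_member


def spectrum_of(peptide, intensity=100.0):
    ions = theoretical_fragments(peptide)
    mz = np.array([f.mz for f in ions])
    return Spectrum(peaks_mz=mz, peaks_intensity=np.full(len(mz), intensity))


class TestTheoreticalFragments:
    def test_gg_b1_y1(self):
        ions = {f.label: f.mz for f in theoretical_fragments("GG")}
        assert ions["b1"] == pytest.approx(58.02874, abs=1e-5)
        assert ions["y1"] == pytest.approx(76.03930, abs=1e-5)

    @pytest.mark.parametrize("seq", ["GG", "GAS", PARENT, CURRENT])
    def test_ion_count_is_2n_minus_2(self, seq):
        n = len(parse_peptide(seq))
        assert len(theoretical_fragments(seq)) == 2 * (n - 1)

    def test_complementarity_identity_ag(self):
        p = parse_peptide("AG")
        ions = {f.label: f.mz for f in theoretical_fragments(p)}
        assert ions["b1"] + ions["y1"] == pytest.approx(
            p.monoisotopic_mass + 2 * PROTON_MASS, abs=1e-6
        )

    def test_complementarity_over_random_library_members(self, fig4a):
        rng = np.random.default_rng(11)
        for _ in range(15):
            p = random_member(rng, fig4a)
            ions = {f.label: f.mz for f in theoretical_fragments(p)}
            n = len(p)
            for i in range(1, n):
                assert ions[f"b{i}"] + ions[f"y{n - i}"] == pytest.approx(
                    p.monoisotopic_mass + 2 * PROTON_MASS, abs=1e-6
                )

    def test_terminal_modifications_enter_fragments(self):
        # N-terminal acyl shifts every b ion, amide shifts every y ion
        plain = {f.label: f.mz for f in theoretical_fragments("TESESR")}
        p = parse_peptide(CURRENT)
        modded = {f.label: f.mz for f in theoretical_fragments(p)}
        assert modded["b1"] > plain["b1"]  # Abz acyl present
        assert modded["y1"] != plain["y1"]  # amide terminus present

    def test_single_residue_rejected(self):
        with pytest.raises(ValueError):
            theoretical_fragments("G")


class TestMatchPeaks:
    def test_identity_spectrum_full_coverage_zero_error(self):
        theo = theoretical_fragments(PARENT)
        res = match_peaks(theo, spectrum_of(PARENT), tol_ppm=10)
        assert res.coverage == 1.0
        assert all(m.ppm_error == 0 for m in res.matched)

    def test_empty_spectrum_matches_nothing(self):
        theo = theoretical_fragments("GAS")
        res = match_peaks(theo, Spectrum(np.array([]), np.array([])), tol_ppm=10)
        assert res.n_matched == 0 and res.coverage == 0.0

    def test_shift_beyond_tolerance_kills_all_matches(self):
        theo = theoretical_fragments(PARENT)
        tol = 10.0
        mz = np.array([f.mz * (1 + 3 * tol * 1e-6) for f in theo])
        s = Spectrum(peaks_mz=mz, peaks_intensity=np.ones(len(mz)))
        assert match_peaks(theo, s, tol_ppm=tol).n_matched == 0

    def test_one_to_one_assignment(self):
        theo = theoretical_fragments("GAS")
        # two peaks both near y1: only one may be consumed, nearest wins
        y1 = [f for f in theo if f.label == "y1"][0].mz
        s = Spectrum(
            peaks_mz=np.array([y1 * (1 + 2e-6), y1 * (1 + 6e-6)]),
            peaks_intensity=np.array([1.0, 1.0]),
        )
        res = match_peaks(theo, s, tol_ppm=10)
        assert res.n_matched == 1
        assert res.matched[0].ppm_error == pytest.approx(2.0, abs=0.01)

    def test_invariant_to_peak_order(self):
        theo = theoretical_fragments(PARENT)
        mz = np.array([f.mz for f in theo])
        rng = np.random.default_rng(3)
        perm = rng.permutation(len(mz))
        a = match_peaks(theo, Spectrum(mz, np.ones(len(mz))), 10)
        b = match_peaks(theo, Spectrum(mz[perm], np.ones(len(mz))), 10)
        assert [(m.ion.label, m.ppm_error) for m in a.matched] == [
            (m.ion.label, m.ppm_error) for m in b.matched
        ]

    def test_empty_theoretical_list_rejected(self):
        with pytest.raises(ValueError):
            match_peaks([], spectrum_of("GG"), 10)


class TestLadderRead:
    def test_y_series_reads_internal_residues(self, registry):
        ions = [f for f in theoretical_fragments("GASV") if f.series == "y"]
        mz = np.array(sorted(f.mz for f in ions))
        s = Spectrum(mz, np.ones(len(mz)))
        alphabet = [registry.residues[t] for t in "GASV"]
        steps = ladder_read(s, alphabet, tol_da=0.01)
        # y1→y2 difference is S, y2→y3 is A (C-to-N along the y series);
        # the two terminal residues are unrecoverable from differences alone
        assert [st.tokens for st in steps] == [("S",), ("A",)]
        assert not any(st.ambiguous for st in steps)

    def test_single_peak_gives_no_steps(self, registry):
        s = Spectrum(np.array([500.0]), np.array([1.0]))
        assert ladder_read(s, list(registry.residues.values()), 0.01) == []

    def test_k_q_disambiguated_at_tight_tolerance(self, registry):
        # ΔM = K mass: Q (128.05858) is 0.036 Da away, outside 0.01 Da
        k_mass = registry.residues["K"].monoisotopic_mass
        s = Spectrum(np.array([300.0, 300.0 + k_mass]), np.ones(2))
        alphabet = [registry.residues["K"], registry.residues["Q"]]
        steps = ladder_read(s, alphabet, tol_da=0.01)
        assert steps[0].tokens == ("K",) and not steps[0].ambiguous

    def test_k_q_ambiguous_at_loose_tolerance(self, registry):
        k_mass = registry.residues["K"].monoisotopic_mass
        s = Spectrum(np.array([300.0, 300.0 + k_mass]), np.ones(2))
        alphabet = [registry.residues["K"], registry.residues["Q"]]
        steps = ladder_read(s, alphabet, tol_da=0.05)
        assert steps[0].tokens == ("K", "Q") and steps[0].ambiguous


class TestIO:
    def test_mgf_roundtrip(self, tmp_path):
        s = spectrum_of(PARENT)
        s.precursor_mz = 1234.5
        path = tmp_path / "out.mgf"
        write_mgf([s], path)
        back = read_mgf(path)[0]
        np.testing.assert_allclose(back.peaks_mz, s.peaks_mz, atol=1e-4)
        assert back.precursor_mz == pytest.approx(1234.5)

    def test_tsv_roundtrip(self, tmp_path):
        s = spectrum_of("GAS")
        path = tmp_path / "out.tsv"
        write_tsv(s, path)
        back = read_tsv(path, precursor_mz=500.0)
        np.testing.assert_allclose(back.peaks_mz, s.peaks_mz, atol=1e-4)
        assert back.precursor_mz == 500.0


def test_spectrum_validation():
    with pytest.raises(ValueError):
        Spectrum(np.array([1.0, 2.0]), np.array([1.0, -1.0]))
    with pytest.raises(ValueError):
        Spectrum(np.array([1.0, np.nan]), np.array([1.0, 1.0]))
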