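"""Cyclic peptide rings, b-ion ladders, cyclospectra and annotation."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from cyclomet import (
    CyclicPeptide,
    MsMsSpectrum,
    annotate_spectrum,
    b_series,
    cyclospectrum,
    default_alphabet,
    get_residue,
    ion_mz,
)

rings = st.lists(
    st.sampled_from(["Gly", "Ala", "Val", "Leu", "Ile", "Pro", "Phe", "NMePhe"]),
    min_size=2,
    max_size=7,
).map(CyclicPeptide)


class TestAlphabet:
    def test_nmephe_mass(self):
        assert get_residue("NMePhe").mass == pytest.approx(161.08406, abs=1e-4)

    def test_pro_mass(self):
        assert get_residue("Pro").mass == pytest.approx(97.05276, abs=1e-4)

    def test_gly_is_smallest(self):
        alphabet = default_alphabet()
        gly = get_residue("Gly")
        assert all(gly.mass <= r.mass for r in alphabet)

    def test_leu_ile_isobaric_but_distinct(self):
        leu, ile = get_residue("Leu"), get_residue("Ile")
        assert leu.mass == ile.mass == pytest.approx(113.08406, abs=1e-4)
        assert leu.name != ile.name
        assert leu.label == ile.label == "Xle"

    def test_isoleu_alias(self):
        assert get_residue("IsoLeu").name == "Ile"


class TestCyclicPeptide:
    def test_precursor_mz_printed_values(self, ellisiiamide_a, ellisiiamide_b):
        assert round(ellisiiamide_a.precursor_mz, 4) == 556.3493
        assert round(ellisiiamide_b.precursor_mz, 4) == 570.3650

    def test_gly_gly_precursor(self):
        assert round(CyclicPeptide(["Gly", "Gly"]).precursor_mz, 4) == 115.0502

    def test_formulas(self, ellisiiamide_a, ellisiiamide_c):
        assert str(ellisiiamide_a.formula) == "C30H45N5O5"
        assert str(ellisiiamide_c.formula) == "C33H51N5O5"
        assert str(CyclicPeptide(["Gly", "Gly"]).formula) == "C4H6N2O2"

    def test_ring_too_small(self):
        with pytest.raises(ValueError):
            CyclicPeptide(["Gly"])

    def test_ring_openings_are_rotations(self):
        p = CyclicPeptide(["Ala", "Val", "Pro"])
        seqs = [[r.name for r in lin] for _, lin in p.ring_openings()]
        assert seqs == [["Ala", "Val", "Pro"], ["Val", "Pro", "Ala"], ["Pro", "Ala", "Val"]]

    def test_pentapeptide_has_five_openings(self, ellisiiamide_a):
        assert len(ellisiiamide_a.ring_openings()) == 5

    def test_pro_nmephe_opening_yields_printed_sequence(self, ellisiiamide_a):
        openings = dict(ellisiiamide_a.ring_openings())
        assert [r.name for r in openings["Pro-NMePhe"]] == ["NMePhe", "Ala", "Ile", "Leu", "Pro"]

    @given(rings, st.integers(0, 6))
    def test_rotation_invariance(self, p, shift):
        rotated = CyclicPeptide(p.residues[shift % len(p):] + p.residues[: shift % len(p)])
        assert rotated.precursor_mz == pytest.approx(p.precursor_mz, abs=1e-9)
        assert str(rotated.formula) == str(p.formula)
        assert np.allclose(cyclospectrum(rotated, dedup=True), cyclospectrum(p, dedup=True))
        assert rotated.rotation_key() == p.rotation_key()

    def test_consistency_with_formula_route(self, ellisiiamide_a):
        assert ellisiiamide_a.precursor_mz == pytest.approx(
            ion_mz(ellisiiamide_a.formula, "[M+H]+"), abs=1e-6
        )


class TestBSeries:
    def test_ellisiiamide_a_ladder(self):
        ladder = b_series(["NMePhe", "Ala", "Ile", "Leu", "Pro"])
        assert [round(b, 1) for b in ladder] == [162.1, 233.1, 346.2, 459.3, 556.3]

    def test_ellisiiamide_c_ladder(self):
        ladder = b_series(["NMePhe", "Ile", "Ile", "Leu", "Pro"])
        assert [round(b, 1) for b in ladder[:4]] == [162.1, 275.2, 388.3, 501.3]

    def test_single_gly(self):
        assert b_series(["Gly"]) == pytest.approx([58.0287], abs=1e-4)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            b_series([])

    @given(rings)
    def test_bn_equals_precursor_and_strictly_increasing(self, p):
        for _, linear in p.ring_openings():
            ladder = b_series(linear)
            assert ladder[-1] == pytest.approx(p.precursor_mz, abs=1e-9)
            assert np.all(np.diff(ladder) > 0)

    @given(rings)
    def test_telescoping(self, p):
        """b_k plus the mass of the unfragmented tail equals b_n."""
        for _, linear in p.ring_openings():
            ladder = b_series(linear)
            for k in range(len(linear)):
                tail = sum(r.mass for r in linear[k + 1:])
                assert ladder[k] + tail == pytest.approx(ladder[-1], abs=1e-9)


class TestCyclospectrum:
    def test_pentapeptide_multiset_size(self, ellisiiamide_a):
        assert len(cyclospectrum(ellisiiamide_a)) == 5 * 4 + 1

    def test_triglycine_dedup(self):
        spec = cyclospectrum(CyclicPeptide(["Gly", "Gly", "Gly"]), dedup=True)
        assert spec == pytest.approx([58.0287, 115.0502, 172.0716], abs=1e-4)

    @given(rings)
    def test_max_is_precursor(self, p):
        assert cyclospectrum(p).max() == pytest.approx(p.precursor_mz, abs=1e-9)


class TestAnnotateSpectrum:
    def test_self_annotation_full_coverage(self, ellisiiamide_a):
        theo = cyclospectrum(ellisiiamide_a, dedup=True)
        spec = MsMsSpectrum(ellisiiamide_a.precursor_mz, theo, np.ones_like(theo))
        _, coverage = annotate_spectrum(ellisiiamide_a, spec, tol=0.02)
        assert all(c == 1.0 for c in coverage.values())

    def test_printed_ladder_selects_pro_nmephe_opening(self, ellisiiamide_a):
        peaks = np.array([162.09, 233.13, 346.21, 459.30])
        spec = MsMsSpectrum(556.35, peaks, np.ones(4))
        _, coverage = annotate_spectrum(ellisiiamide_a, spec, tol=0.05)
        assert coverage["Pro-NMePhe"] == 1.0
        assert max(coverage, key=coverage.get) == "Pro-NMePhe"

    def test_off_ladder_peak_matches_nothing(self, ellisiiamide_a):
        spec = MsMsSpectrum(556.35, np.array([500.0]), np.array([1.0]))
        annotations, coverage = annotate_spectrum(ellisiiamide_a, spec, tol=0.05)
        assert all(a.observed_mz is None for a in annotations)
        assert all(c == 0.0 for c in coverage.values())

    def test_empty_spectrum(self, ellisiiamide_a):
        spec = MsMsSpectrum(556.35, np.array([]), np.array([]))
        annotations, coverage = annotate_spectrum(ellisiiamide_a, spec, tol=0.05)
        assert all(a.observed_mz is None for a in annotations)
        assert all(c == 0.0 for c in coverage.values())

    def test_residue_loss_labels(self, ellisiiamide_a):
        """b4 of the Pro-NMePhe opening is the precursor minus Pro."""
        theo = cyclospectrum(ellisiiamide_a, dedup=True)
        spec = MsMsSpectrum(ellisiiamide_a.precursor_mz, theo, np.ones_like(theo))
        annotations, _ = annotate_spectrum(ellisiiamide_a, spec, tol=0.02)
        b4 = [a for a in annotations if a.opening == "Pro-NMePhe" and a.ordinal == 4]
        assert b4[0].residue_lost_next == "Pro"
        assert round(b4[0].theoretical_mz, 1) == 459.3
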