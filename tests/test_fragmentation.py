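"""Theoretical fragment ions and peak annotation."""

import pytest
from hypothesis import given, strategies as st

from proteokit import masses
from proteokit.fragmentation import (
    NeutralLoss,
    Series,
    Tolerance,
    annotate,
    fragment,
)
from proteokit.masses import monoisotopic_mass
from proteokit.spectra import Spectrum

peptides = st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=2, max_size=30)


def ion_map(ions):
    return {(i.series, i.index, i.charge, i.neutral_loss): i for i in ions}


class TestFragment:
    def test_b1_and_y1_of_ag_match_hand_summed_masses(self):
        ions = ion_map(fragment("AG", {Series.B, Series.Y}))
        b1 = ions[(Series.B, 1, 1, NeutralLoss.NONE)]
        y1 = ions[(Series.Y, 1, 1, NeutralLoss.NONE)]
        assert b1.mz == pytest.approx(71.03711 + masses.PROTON, abs=1e-4)
        assert y1.mz == pytest.approx(57.02146 + 18.01056 + masses.PROTON, abs=1e-4)

    def test_single_residue_peptide_has_no_fragments(self):
        assert fragment("A") == []

    @given(peptide=peptides)
    def test_b_y_complementarity(self, peptide):
        n = len(peptide)
        ions = ion_map(fragment(peptide, {Series.B, Series.Y}))
        total = monoisotopic_mass(peptide) + 2 * masses.PROTON
        for i in range(1, n):
            b = ions[(Series.B, i, 1, NeutralLoss.NONE)].mz
            y = ions[(Series.Y, n - i, 1, NeutralLoss.NONE)].mz
            assert b + y == pytest.approx(total, abs=1e-6)

    def test_sibling_series_offsets_from_b_and_y(self):
        ions = ion_map(
            fragment("PEPTIDEK", set(Series), max_charge=1)
        )
        b3 = ions[(Series.B, 3, 1, NeutralLoss.NONE)].mz
        y3 = ions[(Series.Y, 3, 1, NeutralLoss.NONE)].mz
        assert ions[(Series.A, 3, 1, NeutralLoss.NONE)].mz == pytest.approx(
            b3 - masses.CO, abs=1e-9
        )
        assert ions[(Series.C, 3, 1, NeutralLoss.NONE)].mz == pytest.approx(
            b3 + masses.NH3, abs=1e-9
        )
        assert ions[(Series.X, 3, 1, NeutralLoss.NONE)].mz == pytest.approx(
            y3 + masses.CO - masses.H2, abs=1e-9
        )
        # default z is the z-dot radical (z + 1 H)
        assert ions[(Series.Z, 3, 1, NeutralLoss.NONE)].mz == pytest.approx(
            y3 - masses.NH3 + masses.H, abs=1e-9
        )

    def test_plain_z_available_by_flag(self):
        dot = ion_map(fragment("PEPTIDEK", {Series.Z}))[(Series.Z, 2, 1, NeutralLoss.NONE)]
        plain = ion_map(fragment("PEPTIDEK", {Series.Z}, z_dot=False))[
            (Series.Z, 2, 1, NeutralLoss.NONE)
        ]
        assert dot.mz - plain.mz == pytest.approx(masses.H, abs=1e-9)

    def test_doubly_charged_ions_halve_the_protonated_mass(self):
        ions = ion_map(fragment("PEPTIDEK", {Series.B}, max_charge=2))
        b4_1 = ions[(Series.B, 4, 1, NeutralLoss.NONE)].mz
        b4_2 = ions[(Series.B, 4, 2, NeutralLoss.NONE)].mz
        neutral = b4_1 - masses.PROTON
        assert b4_2 == pytest.approx((neutral + 2 * masses.PROTON) / 2, abs=1e-9)

    def test_chemically_aware_losses_require_a_losing_residue(self):
        # GLAG contains no S/T/E/D and no R/K/N/Q: no loss ions at all
        ions = fragment("GLAG", {Series.B, Series.Y}, losses={NeutralLoss.H2O, NeutralLoss.NH3})
        assert all(i.neutral_loss is NeutralLoss.NONE for i in ions)
        # with awareness off, every ion gets every requested loss
        ions = fragment(
            "GLAG", {Series.B}, losses={NeutralLoss.H2O}, chemically_aware=False
        )
        assert any(i.neutral_loss is NeutralLoss.H2O for i in ions)

    def test_water_loss_only_on_fragments_containing_sted(self):
        ions = fragment("GSGG", {Series.B}, losses={NeutralLoss.H2O})
        with_loss = {i.index for i in ions if i.neutral_loss is NeutralLoss.H2O}
        assert with_loss == {2, 3}  # b1="G" cannot lose water; b2/b3 contain S

    def test_labels_are_deterministic(self):
        ions = ion_map(fragment("PEPTIDEK", {Series.B}, max_charge=2, losses={NeutralLoss.H2O}))
        assert ions[(Series.B, 2, 1, NeutralLoss.NONE)].label == "b2+"
        assert ions[(Series.B, 4, 2, NeutralLoss.H2O)].label == "b4++-H2O"

    def test_modification_shifts_move_the_affected_series(self):
        from proteokit.masses import Modification

        plain = ion_map(fragment("PEPTIDEK", {Series.B, Series.Y}))
        mod = Modification("Phospho", 79.966331)
        shifted = ion_map(
            fragment("PEPTIDEK", {Series.B, Series.Y}, modifications=[(4, mod)])
        )
        # b3 precedes the modification site, y3 ends after it
        assert shifted[(Series.B, 3, 1, NeutralLoss.NONE)].mz == pytest.approx(
            plain[(Series.B, 3, 1, NeutralLoss.NONE)].mz, abs=1e-9
        )
        assert shifted[(Series.B, 4, 1, NeutralLoss.NONE)].mz == pytest.approx(
            plain[(Series.B, 4, 1, NeutralLoss.NONE)].mz + 79.966331, abs=1e-9
        )


class TestTolerance:
    def test_parse_accepts_da_and_ppm(self):
        assert Tolerance.parse("0.01Da") == Tolerance(0.01, "Da")
        assert Tolerance.parse("10 ppm") == Tolerance(10, "ppm")

    def test_window_units(self):
        assert Tolerance(0.5, "Da").window(1000.0) == 0.5
        assert Tolerance(10, "ppm").window(1000.0) == pytest.approx(0.01)

    def test_invalid_tolerances_rejected(self):
        with pytest.raises(ValueError):
            Tolerance(-1, "Da")
        with pytest.raises(ValueError):
            Tolerance(1, "TH")


class TestAnnotate:
    def test_single_peak_match_records_signed_error(self):
        ions = [i for i in fragment("AG", {Series.Y}) if i.index == 1]
        spectrum = Spectrum(mz=[76.0390], intensity=[100.0])
        annotations = annotate(spectrum, ions, Tolerance(0.01, "Da"))
        assert len(annotations) == 1
        assert annotations[0].peak_index == 0
        assert annotations[0].error_mz == pytest.approx(76.0390 - ions[0].mz, abs=1e-9)
        assert annotations[0].error_mz < 0

    def test_empty_spectrum_gives_no_annotations(self):
        ions = fragment("PEPTIDEK")
        assert annotate(Spectrum(mz=[], intensity=[]), ions) == []

    def test_equidistant_tie_broken_by_intensity(self):
        ions = [i for i in fragment("AG", {Series.Y}) if i.index == 1]
        target = ions[0].mz
        spectrum = Spectrum(
            mz=[target - 0.004, target + 0.004], intensity=[10.0, 100.0]
        )
        annotations = annotate(spectrum, ions, Tolerance(0.01, "Da"))
        assert len(annotations) == 1
        assert annotations[0].peak_index == 1

    def test_out_of_tolerance_ion_is_absent(self):
        ions = [i for i in fragment("AG", {Series.Y}) if i.index == 1]
        spectrum = Spectrum(mz=[ions[0].mz + 0.5], intensity=[100.0])
        assert annotate(spectrum, ions, Tolerance(0.01, "Da")) == []

    @given(peptide=peptides)
    def test_output_invariant_under_ion_permutation(self, peptide):
        from proteokit.fixtures import make_spectrum_for

        spectrum = make_spectrum_for(peptide, noise_peaks=5, seed=11)
        ions = fragment(peptide)
        forward = annotate(spectrum, ions, Tolerance(0.01, "Da"))
        backward = annotate(spectrum, list(reversed(ions)), Tolerance(0.01, "Da"))
        assert forward == backward

    @given(peptide=peptides)
    def test_ppm_and_da_agree_at_the_equivalent_width(self, peptide):
        from proteokit.fixtures import make_spectrum_for

        spectrum = make_spectrum_for(peptide, seed=13)
        ions = fragment(peptide)
        for ion in ions:
            da = Tolerance(0.01, "Da")
            ppm = Tolerance(0.01 / ion.mz * 1e6, "ppm")
            a = annotate(spectrum, [ion], da)
            b = annotate(spectrum, [ion], ppm)
            assert a == b

    def test_multiple_ions_may_share_one_peak(self):
        ions = fragment("AG", {Series.Y})
        y1 = [i for i in ions if i.index == 1][0]
        near = Spectrum(mz=[y1.mz], intensity=[5.0])
        doubled = annotate(near, [y1, y1], Tolerance(0.01, "Da"))
        assert len(doubled) == 2
        assert {a.peak_index for a in doubled} == {0}
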