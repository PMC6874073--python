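"""Empirical BCP-energy formulas, QTAIM validity criteria, and dispatch."""

import pytest
from hypothesis import given, strategies as st

from tautkin import (
    ContactClass,
    ContactRecord,
    Formula,
    byh_energy,
    dispatch_energy,
    eml_energy,
    is_valid_contact,
    nbh_energy,
    read_bcp_csv,
    score_structure,
)
from tautkin.qtaim import STRONG_CH_O_THRESHOLD
from tautkin.types import Role, StationaryPoint


def _contact(cls=ContactClass.OH_O, rho=0.04, lap=0.12, **kw):
    base = dict(
        donor_label="O5H", acceptor_label="O4", contact_class=cls,
        rho=rho, lap_rho=lap, ellipticity=0.02, d_AB=2.65, d_HB=1.77,
        angle_AHB=147.3,
    )
    base.update(kw)
    return ContactRecord(**base)


class TestValidity:
    def test_positive_density_and_laplacian_is_valid(self):
        assert is_valid_contact(_contact(rho=0.041, lap=0.124))

    def test_negative_laplacian_fails_criterion(self):
        assert not is_valid_contact(_contact(lap=-0.01))


class TestFormulas:
    @pytest.mark.parametrize(
        "rho, expected",
        [(0.041, 6.71), (0.051, 9.10), (0.107, 22.48)],
    )
    def test_oh_o_linear_formula(self, rho, expected):
        assert nbh_energy(rho) == pytest.approx(expected, abs=0.005)

    def test_oh_o_zero_crossing(self):
        assert nbh_energy(3.09 / 239.0) == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize(
        "rho, expected",
        [(0.116, 28.46), (0.128, 31.44), (0.110, 26.97)],
    )
    def test_strong_ch_o_linear_formula(self, rho, expected):
        assert byh_energy(rho) == pytest.approx(expected, abs=0.005)

    @pytest.mark.parametrize("fn", [nbh_energy, byh_energy])
    def test_nonpositive_density_rejected(self, fn):
        with pytest.raises(ValueError):
            fn(0.0)

    @given(rho=st.floats(1e-4, 0.2))
    def test_both_formulas_monotone_in_density(self, rho):
        assert nbh_energy(rho + 1e-4) > nbh_energy(rho)
        assert byh_energy(rho + 1e-4) > byh_energy(rho)

    def test_eml_magnitude_and_unit_conversion(self):
        assert eml_energy(0.0) == 0.0
        assert eml_energy(-0.02) == pytest.approx(0.5 * 0.02 * 627.5095, rel=1e-12)
        assert eml_energy(-0.04) == pytest.approx(2 * eml_energy(-0.02), rel=1e-12)

    def test_eml_requires_potential_energy_density(self):
        with pytest.raises(ValueError, match="V\\(r\\)"):
            eml_energy(None)


class TestDispatch:
    def test_classical_oh_o_routes_to_nbh(self):
        ce = dispatch_energy(_contact(rho=0.051))
        assert ce.formula_used is Formula.NBH
        assert ce.energy == pytest.approx(9.10, abs=0.005)

    def test_strong_ch2_o_routes_to_byh(self):
        ce = dispatch_energy(_contact(
            cls=ContactClass.CH2_O, rho=0.116,
            donor_label="HC6H", acceptor_label="O7",
        ))
        assert ce.formula_used is Formula.BYH
        assert ce.energy == pytest.approx(28.46, abs=0.005)

    def test_weak_ch_o_without_v_is_unscorable_eml(self):
        ce = dispatch_energy(_contact(
            cls=ContactClass.CH_O, rho=0.018,
            donor_label="C2'H", acceptor_label="O3",
        ))
        assert ce.formula_used is Formula.EML
        assert ce.energy is None and ce.unscorable

    def test_vdw_with_v_is_eml_scored(self):
        ce = dispatch_energy(_contact(
            cls=ContactClass.VDW_CO, rho=0.029, V_bcp=-0.02,
            donor_label="C9", acceptor_label="O1", d_HB=None, angle_AHB=None,
        ))
        assert ce.formula_used is Formula.EML
        assert ce.energy == pytest.approx(6.275, abs=1e-2)

    def test_invalid_contact_rejected(self):
        with pytest.raises(ValueError, match="QTAIM criteria"):
            dispatch_energy(_contact(lap=-0.05))

    @given(rho=st.floats(1e-3, 0.2))
    def test_byh_never_assigned_at_or_below_threshold(self, rho):
        ce = dispatch_energy(_contact(
            cls=ContactClass.CH_O, rho=rho,
            donor_label="C2'H", acceptor_label="O3",
        ))
        if ce.formula_used is Formula.BYH:
            assert ce.energy > STRONG_CH_O_THRESHOLD


class TestScoreStructure:
    def test_reference_conformer_scoring(self, table2):
        s = next(s for s in table2 if s.label == "1")
        energies = score_structure(s)
        assert len(energies) == 3
        by_contact = {ce.contact.label: ce for ce in energies}
        assert by_contact["O5H...O4"].energy == pytest.approx(6.71, abs=0.005)
        assert by_contact["O5H...O4"].formula_used is Formula.NBH

    def test_anomalous_row_recomputes_to_formula_value(self, table2):
        s = next(s for s in table2 if s.label == "TS_5↔5*C8H2")
        ce = next(
            e for e in score_structure(s)
            if e.contact.donor_label == "O3H" and e.contact.acceptor_label == "O4"
        )
        assert ce.energy == pytest.approx(3.12, abs=0.005)
        assert ce.contact.reference.energy == 6.78
        assert ce.contact.reference.inconsistent

    def test_empty_structure_gives_empty_list(self):
        s = StationaryPoint(label="bare", role=Role.MINIMUM)
        assert score_structure(s) == []

    def test_invalid_contacts_flagged_not_dropped(self):
        s = StationaryPoint(
            label="x", role=Role.MINIMUM,
            contacts=(_contact(lap=-0.01), _contact(rho=0.05)),
        )
        energies = score_structure(s)
        assert len(energies) == 2
        assert not energies[0].valid and energies[0].energy is None
        assert energies[1].valid

    def test_scoring_is_permutation_invariant(self, table2):
        s = next(s for s in table2 if len(s.contacts) == 4)
        fwd = score_structure(s)
        rev = score_structure(s.model_copy(update={"contacts": s.contacts[::-1]}))
        assert {(c.contact.label, c.energy) for c in fwd} == \
               {(c.contact.label, c.energy) for c in rev}

    def test_dispatch_agrees_with_annotated_formula(self, table2):
        for s in table2:
            for ce in score_structure(s):
                assert ce.formula_used is ce.contact.reference.formula, (
                    s.label, ce.contact.label
                )


def test_bcp_csv_reader(tmp_path):
    path = tmp_path / "bcp.csv"
    path.write_text(
        "contact_label,class,rho,lap_rho,ellipticity,d_AB,d_HB,angle,V_bcp\n"
        "O5H...O4,OH_O,0.041,0.124,0.0152,2.655,1.770,147.3,\n"
        "C9...O1,vdW_CO,0.029,0.090,0.0246,2.895,,,-0.02\n",
        encoding="utf-8",
    )
    records = read_bcp_csv(path)
    assert len(records) == 2
    assert records[0].contact_class is ContactClass.OH_O
    assert records[1].V_bcp == -0.02
    assert records[1].d_HB is None
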