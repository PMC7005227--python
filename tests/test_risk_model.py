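"""Detriment-adjusted risk with and without gonad shielding."""

import math

import pytest
from hypothesis import given
from hypothesis import strategies as st

from pelvidose import risk_model as rm
from pelvidose.dosimetry import DoseVector
from pelvidose.errors import ValidationError

COEFFS = rm.RiskCoefficients()
SHIELD = rm.ShieldingModel()


def _dose(e, ht, ho, label="x"):
    return DoseVector(label=label, e_dose=e, h_testes=ht, h_ovaries=ho)


# strategy for internally consistent dose vectors: E >= its gonad term
consistent_doses = st.tuples(
    st.floats(0, 200), st.floats(0, 200), st.floats(0, 50)
).map(lambda t: _dose(0.04 * (t[1] + t[2]) + t[0], t[1], t[2]))


class TestPointRisks:
    def test_1958_worked_example_male(self, table3_by_year):
        """5.5e-2 x (1.32e-3 - 0.04 x 17.1e-3) + 5.4e-3 x 15e-3 = 116e-6."""
        r = rm.detriment_risk(table3_by_year["1958"], "male")
        assert r == pytest.approx(1.1598e-4, rel=1e-4)
        assert rm.round_half_up(1e6 * r, 0) == 116

    def test_1905_female(self, table3_by_year):
        r = rm.detriment_risk(table3_by_year["1905"], "female")
        assert r == pytest.approx(3.408e-4, rel=1e-3)

    def test_zero_dose_zero_risk(self):
        for sex in ("male", "female"):
            assert rm.detriment_risk(_dose(0, 0, 0), sex) == 0.0

    def test_1958_male_shielded(self, table3_by_year):
        r = rm.shielded_risk(table3_by_year["1958"], "male")
        assert r == pytest.approx(3.903e-5, rel=1e-3)

    def test_1958_female_shielded(self, table3_by_year):
        r = rm.shielded_risk(table3_by_year["1958"], "female")
        assert r == pytest.approx(4.065e-5, rel=1e-3)

    def test_no_shield_equals_unshielded(self, table3_by_year):
        none = rm.ShieldingModel(gs_male=0.0, gs_female=0.0)
        for sex in ("male", "female"):
            assert rm.shielded_risk(
                table3_by_year["2010"], sex, COEFFS, none
            ) == rm.detriment_risk(table3_by_year["2010"], sex)

    def test_1958_male_reduction(self, table3_by_year):
        assert rm.risk_reduction(table3_by_year["1958"], "male") == pytest.approx(
            7.695e-5, rel=1e-6
        )

    def test_2010_female_reduction(self, table3_by_year):
        assert rm.risk_reduction(table3_by_year["2010"], "female") == pytest.approx(
            3.24e-6, rel=1e-6
        )

    def test_no_gonad_dose_no_reduction(self):
        assert rm.risk_reduction(_dose(1.0, 0, 0), "male") == 0.0
        assert rm.risk_reduction(_dose(1.0, 0, 0), "female") == 0.0

    def test_missing_fields_listed(self):
        with pytest.raises(ValidationError, match="h_testes.*h_ovaries"):
            rm.detriment_risk(DoseVector(label="x", e_dose=1.0), "male")

    def test_unknown_sex_rejected(self):
        with pytest.raises(ValidationError, match="sex"):
            rm.detriment_risk(_dose(1, 1, 1), "other")


class TestProperties:
    @given(dose=consistent_doses, gs=st.floats(0, 1))
    def test_exact_decomposition(self, dose, gs):
        """unshielded = shielded + reduction, for both sexes, any GS."""
        shield = rm.ShieldingModel(gs_male=gs, gs_female=gs)
        for sex in ("male", "female"):
            total = rm.detriment_risk(dose, sex)
            parts = rm.shielded_risk(dose, sex, COEFFS, shield) + rm.risk_reduction(
                dose, sex, COEFFS, shield
            )
            assert parts == pytest.approx(total, rel=1e-12, abs=1e-300)

    @given(dose=consistent_doses)
    def test_full_shield_zeroes_heritable_term(self, dose):
        full = rm.ShieldingModel(gs_male=1.0, gs_female=1.0)
        for sex in ("male", "female"):
            cancer_only = COEFFS.r_cancer * 1e-3 * (
                dose.e_dose - 0.04 * (dose.h_testes + dose.h_ovaries)
            )
            assert rm.shielded_risk(dose, sex, COEFFS, full) == pytest.approx(
                cancer_only, rel=1e-9, abs=1e-300
            )

    @given(
        dose=consistent_doses,
        gs1=st.floats(0, 1),
        gs2=st.floats(0, 1),
    )
    def test_reduction_monotone_in_gs(self, dose, gs1, gs2):
        lo, hi = sorted((gs1, gs2))
        r_lo = rm.risk_reduction(dose, "male", COEFFS, rm.ShieldingModel(gs_male=lo))
        r_hi = rm.risk_reduction(dose, "male", COEFFS, rm.ShieldingModel(gs_male=hi))
        assert r_lo <= r_hi + 1e-18

    @given(dose=consistent_doses, extra=st.floats(0, 100))
    def test_risk_monotone_in_effective_dose(self, dose, extra):
        bigger = _dose(dose.e_dose + extra, dose.h_testes, dose.h_ovaries)
        for sex in ("male", "female"):
            assert rm.detriment_risk(dose, sex) <= rm.detriment_risk(bigger, sex) + 1e-18


class TestShieldingDegradationAndBreakeven:
    @pytest.mark.parametrize(
        "gs, rate, gs_bad, expected",
        [
            (0.95, 1.0, 0.3, 0.95),
            (0.95, 0.0, 0.0, 0.0),
            (0.95, 0.34, 0.2, 0.34 * 0.95 + 0.66 * 0.2),  # ~0.455
        ],
    )
    def test_effective_shielding_factor(self, gs, rate, gs_bad, expected):
        assert rm.effective_shielding_factor(gs, rate, gs_bad) == pytest.approx(expected)

    def test_effective_shielding_factor_range_check(self):
        with pytest.raises(ValidationError, match="placement_correct_rate"):
            rm.effective_shielding_factor(0.95, 1.5, 0.0)

    @pytest.mark.parametrize(
        "reduction, harm, expected",
        [(0.0, 0.5, 0.0), (4.6e-6, 1.0, 4.6), (7.7e-5, 0.01, 7700.0)],
    )
    def test_breakeven_incident_rate(self, reduction, harm, expected):
        assert rm.breakeven_incident_rate(reduction, harm) == pytest.approx(expected)

    def test_breakeven_requires_positive_harm(self):
        with pytest.raises(ValidationError, match="harm_per_incident"):
            rm.breakeven_incident_rate(1e-6, 0.0)


# Printed per-million risk table for the four historical epochs, with the
# number of printed decimals. Three cells (marked None) were printed from
# unrounded intermediate doses and cannot be recovered from the rounded
# dose table at +/-1 of the last digit; they are checked in the dedicated
# acceptance test and excluded here.
PRINTED_RISK_CELLS = {
    "1905": [(1075, 0), (341, 0), (None, 0), (307, 0), (None, 0), (35, 0)],
    "1958": [(116, 0), (47, 0), (39, 0), (41, 0), (77, 0), (5.6, 1)],
    "2010": [(40, 0), (23, 0), (17, 0), (19, 0), (23, 0), (3.3, 1)],
    "2017": [(20, 0), (11, 0), (8.5, 1), (None, 1), (12, 0), (1.7, 1)],
}


class TestRiskTable:
    def test_empty_input_empty_table(self):
        assert rm.build_risk_table([]) == []

    def test_row_errors_reported_with_label(self):
        bad = DoseVector(label="broken row", e_dose=1.0)
        with pytest.raises(ValidationError, match="broken row"):
            rm.build_risk_table([bad])

    def test_result_invariants(self, table3_rows):
        for male, female in rm.build_risk_table(table3_rows):
            for res in (male, female):
                assert res.risk_unshielded == pytest.approx(
                    res.risk_shielded + res.reduction, rel=1e-12
                )
                assert min(res.risk_unshielded, res.risk_shielded, res.reduction) >= 0

    def test_reproduces_printed_cells_from_rounded_doses(self, table3_by_year):
        """Cells of the printed risk table that follow from the rounded
        dose table agree to +/-1 unit of the last printed digit."""
        for year, cells in PRINTED_RISK_CELLS.items():
            male, female = rm.build_risk_table([table3_by_year[year]])[0]
            computed = [
                1e6 * male.risk_unshielded, 1e6 * female.risk_unshielded,
                1e6 * male.risk_shielded, 1e6 * female.risk_shielded,
                1e6 * male.reduction, 1e6 * female.reduction,
            ]
            for got, (printed, decimals) in zip(computed, cells):
                if printed is None:
                    continue
                # half-up round to the printed precision, then allow one
                # unit in the last printed digit
                rounded = rm.round_half_up(got, decimals)
                tol = 10.0 ** -decimals
                assert abs(rounded - printed) <= tol + 1e-9, (year, got, printed)

    def test_per_million_formatting_half_up(self):
        res = rm.RiskResult("x", "male", 116.45e-6, 39.25e-6, 77.2e-6)
        assert res.per_million(0) == (116, 39, 77)
        assert res.per_million(1) == (116.5, 39.3, 77.2)
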