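"""Unit behaviour of the conversion engine: hub arithmetic, patch
selection, breakthrough dosing, rounding, and warnings."""

from decimal import Decimal

import pytest

from opiconvert import (
    ConversionRequest,
    Status,
    TieBreak,
    WarningCode,
    breakthrough_dose,
    convert,
    from_ome,
    parse_formulary,
    renal_warning,
    round_practical,
    select_patch,
    to_ome,
)
from opiconvert.fixtures import F1_DATA

import copy


@pytest.mark.parametrize(
    "drug,route,dose,expected",
    [
        ("morphine", "oral", 60, Decimal(60)),
        ("oxycodone", "oral", 30, Decimal(60)),
        ("codeine", "oral", 100, Decimal(10)),
        ("morphine", "subcutaneous", 30, Decimal(60)),
        ("alfentanil", "subcutaneous", 2, Decimal(60)),
    ],
)
def test_to_ome(f1, drug, route, dose, expected):
    assert to_ome(f1, drug, route, dose) == expected


def test_to_ome_absent_and_invalid(f1):
    assert to_ome(f1, "buprenorphine", "oral", 60) is None
    with pytest.raises(ValueError):
        to_ome(f1, "morphine", "oral", 0)


@pytest.mark.parametrize(
    "drug,route,ome,expected",
    [
        ("oxycodone", "oral", 60, Decimal(30)),
        ("morphine", "subcutaneous", 60, Decimal(30)),
        ("hydromorphone", "oral", 60, Decimal(12)),
    ],
)
def test_from_ome(f1, drug, route, ome, expected):
    assert from_ome(f1, drug, route, ome) == expected


def test_from_ome_rejects_transdermal_target(f1):
    with pytest.raises(ValueError, match="select_patch"):
        from_ome(f1, "fentanyl", "transdermal", 60)


class TestSelectPatch:
    def test_interior(self, f1):
        band, warning = select_patch(f1.patch_table("fentanyl"), 70)
        assert band.strength == Decimal(25)
        assert warning is None

    @pytest.mark.parametrize("border,lower", [(60, 12), (90, 25), (150, 50), (210, 75)])
    def test_border_rounds_down(self, f1, border, lower):
        band, warning = select_patch(f1.patch_table("fentanyl"), border)
        assert band.strength == Decimal(lower)
        assert warning is None

    @pytest.mark.parametrize("border,upper", [(60, 25), (90, 50), (150, 75), (210, 100)])
    def test_legacy_round_up_defect(self, f1, border, upper):
        band, _ = select_patch(f1.patch_table("fentanyl"), border, tie_break=TieBreak.UP)
        assert band.strength == Decimal(upper)

    def test_below_smallest(self, f1):
        band, warning = select_patch(f1.patch_table("fentanyl"), 10)
        assert band is None
        assert warning.code is WarningCode.BELOW_SMALLEST_PATCH

    def test_above_largest(self, f1):
        band, warning = select_patch(f1.patch_table("fentanyl"), 500)
        assert band.strength == Decimal(100)
        assert warning.code is WarningCode.ABOVE_LARGEST_PATCH

    def test_empty_table_is_contract_error(self):
        with pytest.raises(ValueError, match="empty"):
            select_patch([], 60)


class TestConvert:
    def test_simple_oral_to_oral(self, f1):
        result = convert(f1, ConversionRequest("morphine", "oral", Decimal(60), "oxycodone", "oral"))
        assert result.status is Status.OK
        assert result.exact_target_dose == Decimal(30)
        assert result.practical_target_dose == Decimal(30)
        assert result.target_unit == "mg/24h"
        assert result.formulary_version == "F1"

    def test_methadone_always_unsupported(self, f1):
        for req in (
            ConversionRequest("morphine", "oral", Decimal(60), "methadone", "oral"),
            ConversionRequest("methadone", "oral", Decimal(60), "morphine", "oral"),
        ):
            result = convert(f1, req)
            assert result.status is Status.UNSUPPORTED_DRUG
            assert result.ome is None
            assert result.exact_target_dose is None
            assert result.practical_target_dose is None

    def test_missing_equivalence(self, f1):
        result = convert(f1, ConversionRequest("morphine", "oral", Decimal(60), "buprenorphine", "oral"))
        assert result.status is Status.NO_GUIDELINE_EQUIVALENCE
        assert result.practical_target_dose is None

    def test_patch_target_uses_band_strength(self, f1):
        result = convert(f1, ConversionRequest("morphine", "oral", Decimal(70), "fentanyl", "transdermal"))
        assert result.status is Status.OK
        strengths = {b.strength for b in f1.patch_table("fentanyl")}
        assert result.practical_target_dose in strengths
        assert result.target_unit == "microgram/h"

    def test_practical_rounding_floors_to_increment(self, f1):
        # codeine 156 mg -> OME 15.6 -> oxycodone oral exact 7.8 -> floor 7.5
        result = convert(
            f1,
            ConversionRequest("codeine", "oral", Decimal("156"), "oxycodone", "oral",
                              rounding="practical"),
        )
        assert result.exact_target_dose == Decimal("7.8")
        assert result.practical_target_dose == Decimal("7.5")

    def test_renal_warning_attached_for_flagged_target(self, f1):
        result = convert(
            f1,
            ConversionRequest("oxycodone", "oral", Decimal(30), "morphine", "oral",
                              egfr=Decimal(20)),
        )
        assert WarningCode.RENAL_CAUTION.value in result.warning_codes()

    def test_invalid_request_raises(self):
        with pytest.raises(ValueError):
            ConversionRequest("morphine", "oral", Decimal(-5), "oxycodone", "oral")
        with pytest.raises(ValueError):
            ConversionRequest("morphine", "oral", Decimal(60), "oxycodone", "oral", rounding="up")


class TestBreakthrough:
    def test_default_divisor_six(self, f1):
        assert breakthrough_dose(f1, "morphine", "oral", 60) == Decimal(10)
        assert breakthrough_dose(f1, "oxycodone", "oral", 30) == Decimal(5)

    def test_divisor_is_formulary_data(self):
        data = copy.deepcopy(F1_DATA)
        data["defaults"]["breakthrough_divisor"] = 10
        form = parse_formulary(data)
        assert breakthrough_dose(form, "morphine", "oral", 60) == Decimal(6)

    def test_transdermal_refused(self, f1):
        with pytest.raises(ValueError, match="convert the patch"):
            breakthrough_dose(f1, "fentanyl", "transdermal", 25)

    def test_nonpositive_dose_refused(self, f1):
        with pytest.raises(ValueError):
            breakthrough_dose(f1, "morphine", "oral", 0)


class TestRoundPractical:
    def test_floor_to_multiple(self):
        assert round_practical("31.2", "2.5").dose == Decimal("30")

    def test_exact_multiple_unchanged(self):
        rounded = round_practical("30", "2.5")
        assert rounded.dose == Decimal("30")
        assert not rounded.forced_minimum

    def test_never_zero(self):
        rounded = round_practical("1.1", "2.5")
        assert rounded.dose == Decimal("2.5")
        assert rounded.forced_minimum


class TestRenalWarning:
    def test_fires_below_threshold_for_flagged_drug(self, f1):
        warning = renal_warning(f1, "morphine", 20)
        assert warning is not None and warning.code is WarningCode.RENAL_CAUTION

    def test_silent_above_threshold(self, f1):
        assert renal_warning(f1, "morphine", 80) is None

    def test_silent_for_unflagged_drug(self, f1):
        assert renal_warning(f1, "alfentanil", 20) is None

    def test_absent_egfr_never_warns(self, f1):
        assert renal_warning(f1, "morphine", None) is None

    def test_negative_egfr_is_argument_error(self, f1):
        with pytest.raises(ValueError):
            renal_warning(f1, "morphine", -1)
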