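"""Audit log contract (append-only, closed schema) and usage analytics."""

from decimal import Decimal

import pytest

from opiconvert import (
    AuditError,
    AuditLog,
    AuditSchemaError,
    GoldStandard,
    append_record,
    match_rate,
    summarize_usage,
)
from opiconvert.audit import usage_summary_csv
from opiconvert.engine import ConversionRequest
from opiconvert.fixtures import (
    BreakthroughRequest,
    _record_dict,
    fixture_formulary_F1,
    log_request,
)


def _base_record(log, **overrides):
    record = _record_dict(
        log,
        kind="conversion",
        index_drug="morphine",
        index_route="oral",
        index_dose=Decimal(60),
        target_drug="oxycodone",
        target_route="oral",
        practical=Decimal(30),
    )
    record.update(overrides)
    return record


def _fixture_log_l1(f1):
    """Ten conversions and three breakthrough calculations over F1."""
    log = AuditLog()
    pairs = [
        ("morphine", "oral", 60, "oxycodone", "oral"),
        ("morphine", "oral", 90, "fentanyl", "transdermal"),
        ("oxycodone", "oral", 40, "morphine", "subcutaneous"),
        ("codeine", "oral", 200, "morphine", "oral"),
        ("morphine", "subcutaneous", 30, "oxycodone", "oral"),
        ("oxycodone", "subcutaneous", 15, "morphine", "oral"),
        ("diamorphine", "subcutaneous", 20, "morphine", "oral"),
        ("hydromorphone", "oral", 12, "morphine", "oral"),
        ("morphine", "oral", 120, "alfentanil", "subcutaneous"),
        ("morphine", "oral", 45, "fentanyl", "transdermal"),
    ]
    for idx_drug, idx_route, dose, tgt_drug, tgt_route in pairs:
        log_request(log, f1, ConversionRequest(idx_drug, idx_route, Decimal(dose), tgt_drug, tgt_route))
    for drug, route, daily in [("morphine", "oral", 60), ("oxycodone", "oral", 30),
                               ("morphine", "subcutaneous", 30)]:
        log_request(log, f1, BreakthroughRequest(drug, route, Decimal(daily)))
    return log


class TestAppend:
    def test_single_append(self):
        log = AuditLog()
        append_record(log, _base_record(log))
        assert len(log) == 1

    def test_record_ids_gapless(self):
        log = AuditLog()
        for _ in range(3):
            log.append(_base_record(log))
        assert [r.record_id for r in log] == [1, 2, 3]

    def test_gap_rejected(self):
        log = AuditLog()
        log.append(_base_record(log))
        with pytest.raises(AuditSchemaError, match="record_id"):
            log.append(_base_record(log, record_id=5))

    def test_identifiable_field_rejected_by_name(self):
        log = AuditLog()
        record = _base_record(log)
        record["patient_name"] = "John Smith"
        with pytest.raises(AuditSchemaError, match="patient_name"):
            log.append(record)
        assert len(log) == 0

    def test_free_text_indication_rejected(self):
        log = AuditLog()
        with pytest.raises(AuditSchemaError, match="indication"):
            log.append(_base_record(log, indication="Mrs X, ward 9"))

    def test_log_has_no_mutation_interface(self):
        log = AuditLog()
        assert not hasattr(log, "update")
        assert not hasattr(log, "delete")
        assert not hasattr(log, "remove")


class TestSummarize:
    def test_fixture_log_l1(self, f1):
        summary = summarize_usage(_fixture_log_l1(f1))
        assert summary.total_conversions == 10
        assert summary.total_breakthrough == 3
        assert sum(summary.index_counts.values()) == 10
        assert sum(summary.target_counts.values()) == 10
        assert summary.index_counts["morphine"] == 5

    def test_empty_log(self):
        summary = summarize_usage(AuditLog())
        assert summary.total_conversions == 0
        assert summary.total_breakthrough == 0
        assert summary.index_counts == {}

    def test_conservation_between_columns(self, f1):
        summary = summarize_usage(_fixture_log_l1(f1))
        assert (
            sum(summary.index_counts.values())
            == sum(summary.target_counts.values())
            == summary.total_conversions
        )

    def test_csv_export_shape(self, f1):
        csv_text = usage_summary_csv(summarize_usage(_fixture_log_l1(f1)))
        lines = csv_text.splitlines()
        assert lines[0] == "Opioid,As Index Opioid (n),As Target Opioid (n)"
        assert "# total_conversions,10" in lines
        assert "# total_breakthrough,3" in lines


class TestFileRoundTrip:
    def test_write_read_summarize_identical(self, f1, tmp_path):
        path = tmp_path / "audit.jsonl"
        log = AuditLog(path)
        for record in _fixture_log_l1(f1):
            log.append(dict(record.__dict__, warnings=list(record.warnings)))
        reloaded = AuditLog(path)
        assert summarize_usage(reloaded) == summarize_usage(log)

    def test_corrupt_line_quarantined(self, f1, tmp_path):
        path = tmp_path / "audit.jsonl"
        log = AuditLog(path)
        log.append(_base_record(log))
        with path.open("a") as fh:
            fh.write("{not json}\n")
        reloaded = AuditLog(path)
        assert len(reloaded) == 1
        summary = summarize_usage(reloaded)
        assert summary.quarantined == 1


class TestMatchRate:
    def test_all_matching_is_100(self, f1):
        log = _fixture_log_l1(f1)
        summary = match_rate(log, GoldStandard(f1))
        assert summary.excluded_no_equivalence == 0
        assert summary.analyzed == 13
        assert summary.matched == 13
        assert summary.match_rate == 100.0

    def test_exclusion_and_percentage_rounding(self, f1):
        log = _fixture_log_l1(f1)
        # three conversions without guideline equivalence -> excluded
        for _ in range(3):
            log_request(
                log, f1,
                ConversionRequest("morphine", "oral", Decimal(60), "buprenorphine", "oral"),
            )
        # two records doctored to mismatch the gold standard
        for record in list(log)[:2]:
            object.__setattr__(record, "practical_dose", "999")
        summary = match_rate(log, GoldStandard(f1))
        assert summary.excluded_no_equivalence == 3
        assert summary.analyzed == 13
        assert summary.matched == 11
        assert summary.match_rate == 84.6  # 100 * 11/13 = 84.615 -> half-up 84.6
        assert summary.excluded_no_equivalence + summary.analyzed == summary.total_recorded

    def test_empty_analysis_reports_absent_rate(self):
        summary = match_rate(AuditLog(), GoldStandard(fixture_formulary_F1()))
        assert summary.analyzed == 0
        assert summary.match_rate is None

    def test_version_mismatch_is_hard_error(self, f1):
        log = AuditLog()
        log.append(_base_record(log, formulary_version="F2"))
        with pytest.raises(AuditError, match="version mismatch"):
            match_rate(log, GoldStandard(f1))

    def test_order_invariance(self, f1):
        import random

        log = _fixture_log_l1(f1)
        rate1 = match_rate(log, GoldStandard(f1)).match_rate
        shuffled = AuditLog()
        records = list(log)
        random.Random(5).shuffle(records)
        for record in records:
            shuffled.append(
                dict(record.__dict__, record_id=shuffled.next_record_id,
                     warnings=list(record.warnings))
            )
        assert match_rate(shuffled, GoldStandard(f1)).match_rate == rate1
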