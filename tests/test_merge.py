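"""TS_ID merge, repeated-test tracing and positive-rate aggregation."""

from datetime import datetime, timedelta

import pytest

from pathmarker.merge import (
    BiomarkerStat,
    MergedRecord,
    aggregate_stats,
    merge,
    trace_repeat_tests,
)
from pathmarker.model import (
    BiomarkerFinding,
    Mention,
    SlideParagraph,
    UNMATCHED,
    ValidationError,
)
from pathmarker.normalize import TRCategory
from pathmarker.sp import DiagnosisExtraction, SPExtraction

T0 = datetime(2012, 3, 1)


def make_paragraph(ts_id, n_findings=1, report_id="IHC1", timestamp=T0):
    text = f"{ts_id} :\n" + "p53 : positive ;\n" * n_findings
    findings = []
    pos = len(ts_id) + 3
    for _ in range(n_findings):
        bn = Mention(pos, pos + 3, "p53")
        tr = Mention(pos + 6, pos + 14, "positive")
        findings.append(
            BiomarkerFinding(bn, tr, "Tumor Suppressor Protein p53", TRCategory.POSITIVE)
        )
        pos += 17
    return SlideParagraph(
        ts_id=ts_id,
        report_id=report_id,
        timestamp=timestamp,
        span=Mention(0, len(text) - 1, text[:-1]),
        findings=tuple(findings),
    )


def make_extraction(ts_id, patient="P1", organ="Breast", disease="Adenocarcinoma",
                    timestamp=T0, n_diagnoses=1):
    diagnoses = tuple(
        DiagnosisExtraction(
            line=Mention(10, 10 + len(disease), disease),
            disease_norm=disease,
            negated=False,
            metastasis=False,
        )
        for _ in range(n_diagnoses)
    )
    return SPExtraction(
        report_id=ts_id,
        patient_id=patient,
        timestamp=timestamp,
        ts_id=ts_id,
        organ_raw=Mention(0, len(organ), organ),
        organ_norm=organ,
        diagnoses=diagnoses,
    )


def test_three_findings_yield_three_records():
    merged, orphans = merge([make_paragraph("S12-1", 3)], [make_extraction("S12-1")])
    assert len(merged) == 3
    assert orphans == []
    assert {r.organ_norm for r in merged} == {"Breast"}


def test_unmatched_ts_id_becomes_orphan():
    para = make_paragraph("S12-9")
    merged, orphans = merge([para], [make_extraction("S12-1")])
    assert merged == []
    assert orphans == [para]


def test_merge_conserves_finding_counts():
    paragraphs = [make_paragraph(f"S12-{i}", n_findings=i + 1) for i in range(5)]
    extractions = [make_extraction("S12-1"), make_extraction("S12-3")]
    merged, orphans = merge(paragraphs, extractions)
    total = sum(len(p.findings) for p in paragraphs)
    assert len(merged) + sum(len(p.findings) for p in orphans) == total


def test_cross_patient_ts_id_is_an_error():
    with pytest.raises(ValidationError, match="S12-1"):
        merge(
            [make_paragraph("S12-1")],
            [make_extraction("S12-1", patient="P1"),
             make_extraction("S12-1", patient="P2")],
        )


def test_multi_diagnosis_extractions_are_filtered_out():
    ext = make_extraction("S12-1", n_diagnoses=2)
    merged, orphans = merge([make_paragraph("S12-1")], [ext])
    assert merged == [] and len(orphans) == 1
    merged, _ = merge([make_paragraph("S12-1")], [ext], require_single=False)
    assert len(merged) == 1


def test_addendum_latest_extraction_wins():
    old = make_extraction("S12-1", disease="Adenocarcinoma", timestamp=T0)
    new = make_extraction("S12-1", disease="Carcinoma, Gastric",
                          timestamp=T0 + timedelta(days=5))
    merged, _ = merge([make_paragraph("S12-1")], [old, new])
    assert [r.disease_norm for r in merged] == ["Carcinoma, Gastric"]
    merged, _ = merge([make_paragraph("S12-1")], [old, new], keep_all_extractions=True)
    assert sorted(r.disease_norm for r in merged) == ["Adenocarcinoma", "Carcinoma, Gastric"]


def _record(ts_id="S12-1", bn="p53", tr=TRCategory.POSITIVE, timestamp=T0,
            organ="Breast", disease="Adenocarcinoma"):
    return MergedRecord(
        patient_id="P1", ts_id=ts_id, timestamp=timestamp, bn_norm=bn, tr_norm=tr,
        organ_norm=organ, disease_norm=disease, disease_line=disease,
        negated=False, metastasis=False, ihc_report_id="IHC1", sp_report_id=ts_id,
    )


def test_trace_repeat_tests_orders_chronologically():
    records = [
        _record(tr=TRCategory.POSITIVE, timestamp=T0 + timedelta(days=10)),
        _record(tr=TRCategory.ERROR, timestamp=T0),
    ]
    assert trace_repeat_tests(records, "S12-1", "p53") == [
        TRCategory.ERROR,
        TRCategory.POSITIVE,
    ]
    assert trace_repeat_tests(records, "S12-1", "CK 7") == []
    assert trace_repeat_tests([], "S12-1", "p53") == []
    assert trace_repeat_tests([records[1]], "S12-1", "p53") == [TRCategory.ERROR]


def test_unknown_timestamp_orders_last():
    records = [
        _record(tr=TRCategory.NEGATIVE, timestamp=None),
        _record(tr=TRCategory.POSITIVE, timestamp=T0),
    ]
    assert trace_repeat_tests(records, "S12-1", "p53") == [
        TRCategory.POSITIVE,
        TRCategory.NEGATIVE,
    ]


def test_aggregate_stats_positive_rate_arithmetic():
    records = (
        [_record(tr=TRCategory.POSITIVE)] * 2
        + [_record(tr=TRCategory.FOCAL_POSITIVE)]
        + [_record(tr=TRCategory.NEGATIVE)] * 6
        + [_record(tr=TRCategory.ERROR)]
    )
    (stat,), unmatched = aggregate_stats(records)
    assert unmatched == []
    assert (stat.n_total, stat.n_positive, stat.n_focal_positive,
            stat.n_negative, stat.n_error) == (10, 2, 1, 6, 1)
    assert stat.positive_rate == pytest.approx(0.3)


def test_aggregate_stats_empty_and_unmatched():
    assert aggregate_stats([]) == ([], [])
    rec = _record(tr=UNMATCHED)
    stats, unmatched = aggregate_stats([rec])
    assert stats == [] and unmatched == [rec]


def test_aggregation_is_permutation_invariant():
    records = [
        _record(bn=bn, tr=tr, organ=organ)
        for bn in ("p53", "CK 7")
        for organ in ("Breast", "Lung")
        for tr in (TRCategory.POSITIVE, TRCategory.NEGATIVE, TRCategory.ERROR)
    ]
    forward, _ = aggregate_stats(records)
    backward, _ = aggregate_stats(list(reversed(records)))
    assert forward == backward
    for stat in forward:
        assert stat.n_total == (
            stat.n_positive + stat.n_focal_positive + stat.n_negative + stat.n_error
        )


def test_biomarker_stat_rejects_inconsistent_counts():
    with pytest.raises(ValidationError):
        BiomarkerStat("p53", "Breast", "x", n_total=5, n_positive=1,
                      n_focal_positive=1, n_negative=1, n_error=1)
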