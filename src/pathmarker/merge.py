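"""Joining IHC slide paragraphs to SP extractions and aggregating statistics.

The tissue-slide identifier (TS_ID) is the join key: every finding in a
slide paragraph whose TS_ID has a matching SP extraction becomes one merged
record carrying both the biomarker result and the organ/diagnosis context.
Paragraphs without a match are returned as orphans, never dropped silently.
Because the whole point of slide-level association is to prevent assigning
IHC findings to another patient's pathology, a TS_ID claimed by extractions
of two different patients is a hard error.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from datetime import datetime
from typing import Iterable, Mapping, Sequence

from pathmarker.model import SlideParagraph, UNMATCHED, ValidationError
from pathmarker.normalize import TRCategory
from pathmarker.sp import SPExtraction, is_single_organ_single_diagnosis


@dataclass(frozen=True)
class MergedRecord:
    patient_id: str
    ts_id: str
    timestamp: datetime | None
    bn_norm: str
    tr_norm: TRCategory | str
    organ_norm: str
    disease_norm: str
    disease_line: str
    negated: bool
    metastasis: bool
    ihc_report_id: str
    sp_report_id: str

    def to_json(self) -> str:
        d = dict(self.__dict__)
        d["timestamp"] = None if self.timestamp is None else self.timestamp.isoformat()
        d["tr_norm"] = (
            self.tr_norm.value if isinstance(self.tr_norm, TRCategory) else self.tr_norm
        )
        return json.dumps(d, ensure_ascii=False)


@dataclass(frozen=True)
class BiomarkerStat:
    """Per-(biomarker, organ, disease) test-result counts.

    ``positive_rate`` counts focal positives in the numerator; Error results
    count toward the denominator but never the numerator.
    """

    p_bn: str
    organ: str
    disease: str
    n_total: int
    n_positive: int
    n_focal_positive: int
    n_negative: int
    n_error: int

    @property
    def positive_rate(self) -> float:
        return (self.n_positive + self.n_focal_positive) / self.n_total

    def __post_init__(self) -> None:
        if self.n_total != (
            self.n_positive + self.n_focal_positive + self.n_negative + self.n_error
        ):
            raise ValidationError("category counts do not sum to n_total")


def _sort_key(ts: datetime | None) -> tuple[int, datetime]:
    # unknown timestamps order last
    return (1, datetime.min) if ts is None else (0, ts)


def merge(
    paragraphs: Sequence[SlideParagraph],
    extractions: Sequence[SPExtraction],
    keep_all_extractions: bool = False,
    require_single: bool = True,
) -> tuple[list[MergedRecord], list[SlideParagraph]]:
    """Join slide paragraphs to SP extractions by TS_ID.

    When one TS_ID appears in several SP reports of the same patient (the
    addendum scenario) the latest-timestamped extraction wins unless
    ``keep_all_extractions`` is set, in which case each match produces
    records from every extraction. Returns ``(merged, orphans)``.
    """
    by_ts: dict[str, list[SPExtraction]] = {}
    for ext in extractions:
        if require_single and not is_single_organ_single_diagnosis(ext):
            continue
        claims = by_ts.setdefault(ext.ts_id, [])
        for other in claims:
            if other.patient_id != ext.patient_id:
                raise ValidationError(
                    f"TS_ID {ext.ts_id!r} claimed by patients "
                    f"{other.patient_id!r} and {ext.patient_id!r}"
                )
        claims.append(ext)

    merged: list[MergedRecord] = []
    orphans: list[SlideParagraph] = []
    for para in paragraphs:
        claims = by_ts.get(para.ts_id)
        if not claims:
            orphans.append(para)
            continue
        chosen = (
            claims
            if keep_all_extractions
            else [max(claims, key=lambda e: _sort_key(e.timestamp))]
        )
        for ext in chosen:
            diag = ext.diagnoses[0] if ext.diagnoses else None
            for finding in para.findings:
                merged.append(
                    MergedRecord(
                        patient_id=ext.patient_id,
                        ts_id=para.ts_id,
                        timestamp=para.timestamp,
                        bn_norm=finding.bn_norm,
                        tr_norm=finding.tr_norm,
                        organ_norm=ext.organ_norm,
                        disease_norm=diag.disease_norm if diag else UNMATCHED,
                        disease_line=diag.line.surface if diag else "",
                        negated=diag.negated if diag else False,
                        metastasis=diag.metastasis if diag else False,
                        ihc_report_id=para.report_id,
                        sp_report_id=ext.report_id,
                    )
                )
    return merged, orphans


def trace_repeat_tests(
    records: Iterable[MergedRecord], ts_id: str, p_bn: str
) -> list[TRCategory | str]:
    """Chronological test results for one biomarker on one slide.

    Repeated assays (e.g. after an Error result) surface as a time-ordered
    category sequence; the sort is stable on timestamp ties and unknown
    timestamps order last.
    """
    hits = [r for r in records if r.ts_id == ts_id and r.bn_norm == p_bn]
    hits.sort(key=lambda r: _sort_key(r.timestamp))
    return [r.tr_norm for r in hits]


def aggregate_stats(
    records: Iterable[MergedRecord],
) -> tuple[list[BiomarkerStat], list[MergedRecord]]:
    """Count test-result categories per (biomarker, organ, disease).

    Records with an UNMATCHED test result cannot be binned and are returned
    separately for triage. Rows are ordered lexicographically, so the
    output is independent of input order.
    """
    counts: dict[tuple[str, str, str], dict[TRCategory, int]] = {}
    unmatched: list[MergedRecord] = []
    for r in records:
        if not isinstance(r.tr_norm, TRCategory):
            unmatched.append(r)
            continue
        key = (r.bn_norm, r.organ_norm, r.disease_norm)
        bins = counts.setdefault(key, {c: 0 for c in TRCategory})
        bins[r.tr_norm] += 1
    stats = []
    for (p_bn, organ, disease) in sorted(counts):
        bins = counts[(p_bn, organ, disease)]
        stats.append(
            BiomarkerStat(
                p_bn=p_bn,
                organ=organ,
                disease=disease,
                n_total=sum(bins.values()),
                n_positive=bins[TRCategory.POSITIVE],
                n_focal_positive=bins[TRCategory.FOCAL_POSITIVE],
                n_negative=bins[TRCategory.NEGATIVE],
                n_error=bins[TRCategory.ERROR],
            )
        )
    return stats, unmatched
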