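"""End-to-end extraction pipeline over a mixed IHC/SP report stream.

Wires the per-module steps together: IHC style classification, slide
segmentation and grammar parsing; BN/TR normalization; SP tree parsing
with organ/disease recognition; and the TS_ID merge. Also renders the
parser output as standoff annotations so predictions can be scored against
gold with the span evaluator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from pathmarker.evaluation import Annotations
from pathmarker.ihc import ClassificationError, GrammarConfig, parse_ihc_report
from pathmarker.merge import MergedRecord, merge
from pathmarker.model import (
    BiomarkerFinding,
    RawReport,
    SlideParagraph,
    StandoffAnnotation,
    UNMATCHED,
    UnparseableReport,
)
from pathmarker.normalize import (
    DictionaryMatcher,
    TRCategory,
    expand_bn_dictionary,
    normalize_tr,
    read_tr_dictionary,
    strip_lab_terms,
)
from pathmarker.similarity import SimilarityWeights
from pathmarker.sp import SPConfig, SPExtraction, TermRecognizer, extract_sp
from pathmarker.synthesis import Vocabulary


@dataclass
class Normalizers:
    """The run-scoped normalization state shared across documents."""

    bn: DictionaryMatcher
    tr: dict
    organ: TermRecognizer
    disease: TermRecognizer

    @classmethod
    def from_vocabulary(
        cls, vocab: Vocabulary | None = None, weights: SimilarityWeights | None = None
    ) -> "Normalizers":
        vocab = vocab or Vocabulary.bundled()
        return cls(
            bn=DictionaryMatcher(expand_bn_dictionary(list(vocab.bn_entries)), weights),
            tr=read_tr_dictionary(list(vocab.tr_entries)),
            organ=TermRecognizer(list(vocab.organ_entries), weights),
            disease=TermRecognizer(list(vocab.disease_entries), weights),
        )


@dataclass
class PipelineResult:
    paragraphs: list[SlideParagraph] = field(default_factory=list)
    extractions: list[SPExtraction] = field(default_factory=list)
    merged: list[MergedRecord] = field(default_factory=list)
    orphans: list[SlideParagraph] = field(default_factory=list)
    predicted: dict[str, list[StandoffAnnotation]] = field(default_factory=dict)
    skipped: list[tuple[str, str]] = field(default_factory=list)


def _normalize_paragraph(
    para: SlideParagraph, normalizers: Normalizers
) -> SlideParagraph:
    findings = []
    for f in para.findings:
        bn_norm, _ = normalizers.bn.lookup(strip_lab_terms(f.bn.surface))
        tr_norm = normalize_tr(f.tr.surface, normalizers.tr)
        findings.append(
            BiomarkerFinding(bn=f.bn, tr=f.tr, bn_norm=bn_norm, tr_norm=tr_norm)
        )
    return SlideParagraph(
        ts_id=para.ts_id,
        report_id=para.report_id,
        timestamp=para.timestamp,
        span=para.span,
        findings=tuple(findings),
    )


def _ihc_annotations(paragraphs: Sequence[SlideParagraph], report: RawReport):
    from pathmarker.ihc import segment_slide_paragraphs

    anns: list[StandoffAnnotation] = []

    def add(label, mention, norm):
        anns.append(StandoffAnnotation(f"T{len(anns)+1}", label, mention, norm))

    for header, para in zip(segment_slide_paragraphs(report), paragraphs):
        add("TS_ID", header.id_mention, header.ts_id)
        for f in para.findings:
            add("BN", f.bn, f.bn_norm)
            add(
                "TR",
                f.tr,
                f.tr_norm.value if isinstance(f.tr_norm, TRCategory) else f.tr_norm,
            )
    return anns


def _sp_annotations(ext: SPExtraction) -> list[StandoffAnnotation]:
    anns: list[StandoffAnnotation] = []
    if ext.organ_raw is not None:
        anns.append(StandoffAnnotation("T1", "Organ", ext.organ_raw, ext.organ_norm))
    for d in ext.diagnoses:
        anns.append(
            StandoffAnnotation(f"T{len(anns)+1}", "Diagnosis", d.line, d.disease_norm)
        )
    return anns


def merged_to_frame(merged: Sequence[MergedRecord]):
    """Merged records as a DataFrame aligned with the blueprint join columns."""
    import pandas as pd

    rows = [
        {
            "patient_id": r.patient_id,
            "ts_id": r.ts_id,
            "ihc_report_id": r.ihc_report_id,
            "sp_report_id": r.sp_report_id,
            "bn": r.bn_norm,
            "tr": r.tr_norm.value if isinstance(r.tr_norm, TRCategory) else r.tr_norm,
            "organ": r.organ_norm,
            "disease": r.disease_norm,
            "ihc_timestamp": r.timestamp,
        }
        for r in merged
    ]
    columns = [
        "patient_id", "ts_id", "ihc_report_id", "sp_report_id",
        "bn", "tr", "organ", "disease", "ihc_timestamp",
    ]
    return pd.DataFrame(rows, columns=columns)


def matches_blueprint(merged: Sequence[MergedRecord], blueprint) -> bool:
    """True iff the merged records equal the blueprint join as a multiset."""
    got = merged_to_frame(merged)
    want = blueprint[got.columns.tolist()]
    key = got.columns.tolist()
    return (
        got.sort_values(key).reset_index(drop=True)
        .equals(want.sort_values(key).reset_index(drop=True))
    )


def process_reports(
    reports: Sequence[RawReport],
    normalizers: Normalizers | None = None,
    grammar: GrammarConfig | None = None,
    sp_config: SPConfig | None = None,
    require_single: bool = True,
    keep_all_extractions: bool = False,
) -> PipelineResult:
    """Run the full extraction and merge over a mixed report stream.

    Unparseable reports (no slide header, no organ line, empty body) are
    recorded under ``skipped`` with an empty prediction set, mirroring how
    such documents are counted and excluded rather than failing the run.
    """
    normalizers = normalizers or Normalizers.from_vocabulary()
    grammar = grammar or GrammarConfig()
    result = PipelineResult()
    for report in reports:
        try:
            if report.report_type == "IHC":
                _, paragraphs = parse_ihc_report(report, grammar)
                paragraphs = [_normalize_paragraph(p, normalizers) for p in paragraphs]
                result.paragraphs.extend(paragraphs)
                result.predicted[report.report_id] = _ihc_annotations(paragraphs, report)
            else:
                ext = extract_sp(
                    report, normalizers.organ, normalizers.disease, sp_config
                )
                result.extractions.append(ext)
                result.predicted[report.report_id] = _sp_annotations(ext)
        except (UnparseableReport, ClassificationError) as exc:
            result.skipped.append((report.report_id, str(exc)))
            result.predicted[report.report_id] = []
    result.merged, result.orphans = merge(
        result.paragraphs,
        result.extractions,
        keep_all_extractions=keep_all_extractions,
        require_single=require_single,
    )
    return result
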