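"""Synthetic paired IHC/SP corpus with gold annotations and a blueprint join.

Real hospital pathology archives are private; this generator emulates their
two report streams at desk scale so the extraction pipeline can be tested
end to end against known ground truth:

* IHC reports in list style (``p53 : positive ;``) or table style
  (``| p53 | positive |``), each tissue-slide paragraph opened by the
  slide's accession (TS_ID), possibly with several paragraphs per report
  and occasional repeat tests of the same slide in a later report;
* SP reports with the organ on the first line, a numbered diagnosis line,
  and indented microscopic-finding lines, one specimen per report whose
  accession equals the slide's TS_ID.

Alongside the documents the generator emits exact gold standoff
annotations (TS_ID/BN/TR on IHC, Organ/Diagnosis on SP) and a blueprint
join table — the record set a perfect extraction pipeline must reproduce.
Configurable noise injects single-character typos, dictionary-style
biomarker variants, laboratory parentheticals, indentation jitter, and
dropped slide headers. Typos never touch formatting determinants or the
TS_ID itself: separators are the grammar anchors, and the dropped-header
rate is the dial for broken joins.
"""

from __future__ import annotations

import random
import string
from dataclasses import dataclass, field
from datetime import datetime, timedelta
from typing import Sequence

import pandas as pd

from pathmarker.data import bundled_path
from pathmarker.model import (
    DictionaryEntry,
    Mention,
    RawReport,
    StandoffAnnotation,
    ValidationError,
    read_dictionary,
)
from pathmarker.normalize import TRCategory, expand_bn_dictionary

BLUEPRINT_COLUMNS = [
    "patient_id",
    "ts_id",
    "ihc_report_id",
    "sp_report_id",
    "bn",
    "tr",
    "organ",
    "disease",
    "ihc_timestamp",
    "sp_timestamp",
]

_ORGAN_QUALIFIERS = ["", ", left, excision", ", right, biopsy", ", resection", ", punch biopsy"]
_DISEASE_QUALIFIERS = ["", ", multiple", ", residual (see note)", ", well differentiated", ", 1.2 cm"]
_FINDING_LINES = [
    "tumor size 2.3 x 1.1 cm",
    "resection margin, clear",
    "nuclear grade 2",
    "with microcalcification",
    "lymphovascular invasion present",
    "histologic grade 1 of 3",
]
_LAB_PARENTHETICALS = [" (repeat)", " (recut)", " (4)", "(repeat)"]

#: organ-compatible diagnoses (by bundled disease surface); organs not
#: listed here draw from the full disease table
_ORGAN_DISEASES = {
    "Breast": ["Infiltrating duct carcinoma", "Invasive ductal carcinoma", "Fibrocystic change"],
    "Lung": ["Squamous cell carcinoma", "Small cell carcinoma", "Adenocarcinoma"],
    "Stomach": ["Gastric carcinoma", "Signet ring cell carcinoma", "Chronic gastritis", "Adenocarcinoma"],
    "Colon": ["Adenocarcinoma", "Tubular adenoma", "Mucinous adenocarcinoma"],
    "Rectum": ["Adenocarcinoma", "Tubular adenoma"],
    "Liver": ["Hepatocellular carcinoma", "Adenocarcinoma"],
    "Pancreas": ["Adenocarcinoma", "Mucinous adenocarcinoma"],
    "Kidney": ["Renal cell carcinoma", "Urothelial carcinoma"],
    "Prostate": ["Adenocarcinoma"],
    "Thyroid gland": ["Papillary thyroid carcinoma"],
    "Ovary": ["Serous carcinoma", "Mucinous adenocarcinoma"],
    "Uterus": ["Leiomyoma", "Adenocarcinoma"],
    "Uterine cervix": ["Squamous cell carcinoma"],
    "Urinary bladder": ["Urothelial carcinoma"],
    "Skin": ["Melanoma", "Squamous cell carcinoma"],
    "Lymph node": ["Diffuse large B-cell lymphoma", "Melanoma"],
    "Brain": ["Glioblastoma", "Meningioma"],
}

#: planted test-result category mix (positive-heavy, small error rate)
_TR_MIX = [
    (TRCategory.POSITIVE, 0.40),
    (TRCategory.FOCAL_POSITIVE, 0.15),
    (TRCategory.NEGATIVE, 0.40),
    (TRCategory.ERROR, 0.05),
]


@dataclass(frozen=True)
class NoiseConfig:
    typo_rate: float = 0.0
    variant_rate: float = 0.0
    lab_term_rate: float = 0.0
    indent_jitter: int = 0
    missing_ts_id_rate: float = 0.0

    def __post_init__(self) -> None:
        for name in ("typo_rate", "variant_rate", "lab_term_rate", "missing_ts_id_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValidationError(f"{name} must be in [0,1], got {v}")
        if self.indent_jitter < 0:
            raise ValidationError("indent_jitter must be nonnegative")


@dataclass(frozen=True)
class CorpusConfig:
    n_patients: int = 100
    slides_per_patient: tuple[int, int] = (1, 3)
    biomarkers_per_slide: tuple[int, int] = (2, 6)
    style_mix: float = 0.5
    repeat_rate: float = 0.1
    noise: NoiseConfig = field(default_factory=NoiseConfig)
    seed: int = 0
    start_date: datetime = datetime(2012, 1, 2)

    def __post_init__(self) -> None:
        if self.n_patients < 0:
            raise ValidationError("n_patients must be nonnegative")
        if not (0.0 <= self.style_mix <= 1.0):
            raise ValidationError("style_mix must be in [0,1]")
        if not (0.0 <= self.repeat_rate <= 1.0):
            raise ValidationError("repeat_rate must be in [0,1]")
        for name in ("slides_per_patient", "biomarkers_per_slide"):
            lo, hi = getattr(self, name)
            if lo > hi or lo < 1:
                raise ValidationError(f"{name} must satisfy 1 <= lo <= hi")


@dataclass(frozen=True)
class Vocabulary:
    """Terminology tables driving generation (defaults: bundled samples)."""

    bn_entries: tuple[DictionaryEntry, ...]
    tr_entries: tuple[DictionaryEntry, ...]
    organ_entries: tuple[DictionaryEntry, ...]
    disease_entries: tuple[DictionaryEntry, ...]

    @classmethod
    def bundled(cls) -> "Vocabulary":
        return cls(
            bn_entries=tuple(read_dictionary(bundled_path("biomarkers.tsv"))),
            tr_entries=tuple(read_dictionary(bundled_path("test_results.tsv"))),
            organ_entries=tuple(read_dictionary(bundled_path("organs.tsv"))),
            disease_entries=tuple(read_dictionary(bundled_path("diseases.tsv"))),
        )


class _DocBuilder:
    def __init__(self) -> None:
        self._parts: list[str] = []
        self.pos = 0

    def add(self, text: str) -> tuple[int, int]:
        start = self.pos
        self._parts.append(text)
        self.pos += len(text)
        return start, self.pos

    def mention(self, text: str) -> Mention:
        start, end = self.add(text)
        return Mention(start, end, text)

    def text(self) -> str:
        return "".join(self._parts)


def _typo(rng: random.Random, token: str) -> str:
    """One random character-level edit confined to word characters."""
    alnum_positions = [i for i, ch in enumerate(token) if ch.isalnum()]
    if not alnum_positions:
        return token
    i = rng.choice(alnum_positions)
    alphabet = string.ascii_lowercase if token[i].isalpha() else string.digits
    op = rng.choice(["sub", "del", "ins"])
    if op == "del" and len(token) > 1:
        return token[:i] + token[i + 1 :]
    if op == "ins":
        return token[:i] + rng.choice(alphabet) + token[i:]
    repl = rng.choice([c for c in alphabet if c != token[i].lower()])
    if token[i].isupper():
        repl = repl.upper()
    return token[:i] + repl + token[i + 1 :]


def _noisy(rng: random.Random, surface: str, typo_rate: float) -> str:
    if typo_rate <= 0:
        return surface
    out = []
    for piece in surface.split(" "):
        if piece and rng.random() < typo_rate:
            piece = _typo(rng, piece)
        out.append(piece)
    return " ".join(out)


def _weighted_choice(rng: random.Random, options):
    x = rng.random()
    acc = 0.0
    for value, w in options:
        acc += w
        if x < acc:
            return value
    return options[-1][0]


def generate_corpus(
    cfg: CorpusConfig, vocab: Vocabulary | None = None
) -> tuple[list[RawReport], dict[str, list[StandoffAnnotation]], pd.DataFrame]:
    """Generate reports, per-document gold annotations and the blueprint join.

    Deterministic under ``cfg.seed``: identical configs yield byte-identical
    corpora. Gold mention offsets are exact on the final (noisy) text.
    """
    vocab = vocab or Vocabulary.bundled()
    rng = random.Random(cfg.seed)
    noise = cfg.noise
    by_pref_variants: dict[str, list[str]] = {}
    for e in expand_bn_dictionary(list(vocab.bn_entries)):
        by_pref_variants.setdefault(e.preferred, []).append(e.surface)
    tr_surfaces: dict[TRCategory, list[str]] = {c: [] for c in TRCategory}
    for e in vocab.tr_entries:
        tr_surfaces[TRCategory.from_string(e.preferred)].append(e.surface)
    for cat, surfaces in tr_surfaces.items():
        if not surfaces:
            raise ValidationError(f"TR vocabulary has no surface for {cat.value!r}")

    reports: list[RawReport] = []
    gold: dict[str, list[StandoffAnnotation]] = {}
    rows: list[dict] = []
    serial = 1000
    ihc_counter = 0

    for p in range(cfg.n_patients):
        patient_id = f"PT{p:04d}"
        base = cfg.start_date + timedelta(days=p)
        n_slides = rng.randint(*cfg.slides_per_patient)
        slides = []
        disease_by_surface = {e.surface: e for e in vocab.disease_entries}
        for _ in range(n_slides):
            ts_id = f"S{base.year % 100:02d}-{serial}"
            serial += 1
            organ = rng.choice(vocab.organ_entries)
            compatible = [
                disease_by_surface[s]
                for s in _ORGAN_DISEASES.get(organ.preferred, [])
                if s in disease_by_surface
            ]
            disease = rng.choice(compatible or list(vocab.disease_entries))
            slides.append((ts_id, organ, disease))

        # one SP report per specimen; the accession doubles as the TS_ID
        for ts_id, organ, disease in slides:
            sp_time = base
            b = _DocBuilder()
            anns: list[StandoffAnnotation] = []
            organ_surface = _noisy(rng, organ.surface, noise.typo_rate)
            m = b.mention(organ_surface)
            anns.append(StandoffAnnotation("T1", "Organ", m, organ.preferred))
            b.add(rng.choice(_ORGAN_QUALIFIERS) + ":\n")
            b.add("  1. ")
            disease_line = _noisy(rng, disease.surface, noise.typo_rate) + rng.choice(
                _DISEASE_QUALIFIERS
            )
            m = b.mention(disease_line)
            anns.append(StandoffAnnotation(f"T{len(anns)+1}", "Diagnosis", m, disease.preferred))
            b.add("\n")
            for finding in rng.sample(_FINDING_LINES, rng.randint(1, 2)):
                indent = 7 + (rng.randint(0, noise.indent_jitter) if noise.indent_jitter else 0)
                b.add(" " * indent + finding + "\n")
            report = RawReport(
                report_id=ts_id,
                patient_id=patient_id,
                report_type="SP",
                timestamp=sp_time,
                text=b.text(),
            )
            reports.append(report)
            gold[report.report_id] = anns

        # IHC reports: one covering all slides, plus occasional repeat tests
        ihc_jobs: list[tuple[datetime, list[tuple[str, DictionaryEntry, str, list]]]] = []
        main_job = []
        for ts_id, organ, disease in slides:
            n_bn = rng.randint(*cfg.biomarkers_per_slide)
            markers = rng.sample(vocab.bn_entries, min(n_bn, len(vocab.bn_entries)))
            findings = []
            for bn_entry in markers:
                cat = _weighted_choice(rng, _TR_MIX)
                findings.append((bn_entry, cat))
            main_job.append((ts_id, organ, disease, findings))
        ihc_jobs.append((base + timedelta(days=3), main_job))
        for ts_id, organ, disease, findings in main_job:
            if findings and rng.random() < cfg.repeat_rate:
                bn_entry, _ = rng.choice(findings)
                cat = _weighted_choice(rng, _TR_MIX)
                ihc_jobs.append(
                    (
                        base + timedelta(days=17),
                        [(ts_id, organ, disease, [(bn_entry, cat)])],
                    )
                )

        for ihc_time, job in ihc_jobs:
            ihc_counter += 1
            report_id = f"IHC{ihc_counter:05d}"
            table_style = rng.random() < cfg.style_mix
            b = _DocBuilder()
            anns = []

            def _add_ann(label: str, mention: Mention, norm: str) -> None:
                anns.append(StandoffAnnotation(f"T{len(anns)+1}", label, mention, norm))

            for ts_id, organ, disease, findings in job:
                omit_header = rng.random() < noise.missing_ts_id_rate
                if not omit_header:
                    m = b.mention(ts_id)
                    _add_ann("TS_ID", m, ts_id)
                    b.add(" :\n" if not table_style else "\n")
                if table_style:
                    b.add("| Antibody | Result |\n")
                for bn_entry, cat in findings:
                    bn_surface = bn_entry.surface
                    if noise.variant_rate and rng.random() < noise.variant_rate:
                        bn_surface = rng.choice(by_pref_variants[bn_entry.preferred])
                    bn_surface = _noisy(rng, bn_surface, noise.typo_rate)
                    if noise.lab_term_rate and rng.random() < noise.lab_term_rate:
                        bn_surface += rng.choice(_LAB_PARENTHETICALS)
                    tr_surface = _noisy(
                        rng, rng.choice(tr_surfaces[cat]), noise.typo_rate
                    )
                    if table_style:
                        b.add("| ")
                        _add_ann("BN", b.mention(bn_surface), bn_entry.preferred)
                        b.add(" | ")
                        _add_ann("TR", b.mention(tr_surface), cat.value)
                        b.add(" |\n")
                    else:
                        _add_ann("BN", b.mention(bn_surface), bn_entry.preferred)
                        b.add(" : ")
                        _add_ann("TR", b.mention(tr_surface), cat.value)
                        b.add(" ;\n")
                    rows.append(
                        {
                            "patient_id": patient_id,
                            "ts_id": ts_id,
                            "ihc_report_id": report_id,
                            "sp_report_id": ts_id,
                            "bn": bn_entry.preferred,
                            "tr": cat.value,
                            "organ": organ.preferred,
                            "disease": disease.preferred,
                            "ihc_timestamp": ihc_time,
                            "sp_timestamp": base,
                        }
                    )
                b.add("\n")
            report = RawReport(
                report_id=report_id,
                patient_id=patient_id,
                report_type="IHC",
                timestamp=ihc_time,
                text=b.text(),
            )
            reports.append(report)
            gold[report.report_id] = anns

    blueprint = pd.DataFrame(rows, columns=BLUEPRINT_COLUMNS)
    return reports, gold, blueprint
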