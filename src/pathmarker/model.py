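"""Domain types and readers/writers for reports, terminologies and annotations.

Character offsets are 0-based, end-exclusive, over LF-normalized Unicode
text — the convention of the BRAT annotation tool. Every :class:`Mention`
must reproduce the document slice at its offsets; this is checked at the
point where a mention meets its document (standoff I/O, parsing, evaluation),
not on construction, because mentions are also built for free-standing text
fragments.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from datetime import datetime
from pathlib import Path
from typing import Iterable, Sequence

UNMATCHED = "UNMATCHED"

REPORT_TYPES = ("IHC", "SP")

STANDOFF_LABELS = ("TS_ID", "BN", "TR", "Organ", "Diagnosis")


class PathmarkerError(Exception):
    """Base class for errors raised by this package."""


class ValidationError(PathmarkerError):
    """Input violates a documented contract (bad offsets, duplicate keys...)."""


class UnparseableReport(PathmarkerError):
    """A report that the parser must count and skip (e.g. no TS_ID header)."""


def normalize_newlines(text: str) -> str:
    """Normalize CRLF / lone CR to LF. All offsets are computed on this form."""
    return text.replace("\r\n", "\n").replace("\r", "\n")


@dataclass(frozen=True, order=True)
class Mention:
    """A labeled span of document text: ``doc[start:end] == surface``."""

    start: int
    end: int
    surface: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"invalid mention offsets [{self.start},{self.end})"
            )
        if len(self.surface) != self.end - self.start:
            raise ValidationError(
                f"surface length {len(self.surface)} != span width "
                f"{self.end - self.start} for {self.surface!r}"
            )

    def check_against(self, text: str) -> None:
        """Verify the mention matches ``text`` (newlines compare as spaces)."""
        if self.end > len(text):
            raise ValidationError(
                f"mention [{self.start},{self.end}) beyond document length {len(text)}"
            )
        got = text[self.start : self.end].replace("\n", " ")
        if got != self.surface.replace("\n", " "):
            raise ValidationError(
                f"mention surface {self.surface!r} != document slice {got!r} "
                f"at [{self.start},{self.end})"
            )


def mention_from(text: str, start: int, end: int) -> Mention:
    """Build a mention by slicing ``text`` (the slice defines the surface)."""
    if not (0 <= start < end <= len(text)):
        raise ValidationError(f"offsets [{start},{end}) invalid for length {len(text)}")
    return Mention(start, end, text[start:end])


@dataclass(frozen=True)
class RawReport:
    """One pathology document (IHC or SP).

    ``timestamp`` may be ``None`` for real-world reports lacking one; the
    sentinel orders last in repeated-test tracing. The synthetic generator
    always emits timestamps.
    """

    report_id: str
    patient_id: str
    report_type: str
    timestamp: datetime | None
    text: str

    def __post_init__(self) -> None:
        if self.report_type not in REPORT_TYPES:
            raise ValidationError(
                f"report {self.report_id!r}: report_type must be one of "
                f"{REPORT_TYPES}, got {self.report_type!r}"
            )
        if not self.text:
            raise ValidationError(f"report {self.report_id!r}: empty text")
        if "\r" in self.text:
            raise ValidationError(
                f"report {self.report_id!r}: text must be LF-normalized"
            )


@dataclass(frozen=True)
class BiomarkerFinding:
    """A (biomarker-name, test-result) mention pair from one IHC paragraph."""

    bn: Mention
    tr: Mention
    bn_norm: str = UNMATCHED
    tr_norm: str = UNMATCHED

    def __post_init__(self) -> None:
        if self.bn.start < self.tr.end and self.tr.start < self.bn.end:
            raise ValidationError("BN and TR mentions overlap")


@dataclass(frozen=True)
class SlideParagraph:
    """All IHC findings for one tissue slide (TS_P), keyed by TS_ID."""

    ts_id: str
    report_id: str
    timestamp: datetime | None
    span: Mention
    findings: tuple[BiomarkerFinding, ...] = ()

    def __post_init__(self) -> None:
        if not self.ts_id:
            raise ValidationError("empty ts_id")
        for f in self.findings:
            for m in (f.bn, f.tr):
                if not (self.span.start <= m.start and m.end <= self.span.end):
                    raise ValidationError(
                        f"finding mention {m.surface!r} outside paragraph span"
                    )


@dataclass(frozen=True)
class DictionaryEntry:
    surface: str
    preferred: str
    source: str = "original"  # original | expanded

    def __post_init__(self) -> None:
        if not self.surface or not self.preferred:
            raise ValidationError("dictionary surface and preferred must be non-empty")
        if self.source not in ("original", "expanded"):
            raise ValidationError(f"bad dictionary source {self.source!r}")


@dataclass(frozen=True)
class StandoffAnnotation:
    """A BRAT-style labeled span, optionally carrying a normalized term."""

    ann_id: str
    label: str
    mention: Mention
    norm: str | None = None

    def __post_init__(self) -> None:
        if self.label not in STANDOFF_LABELS:
            raise ValidationError(
                f"label must be one of {STANDOFF_LABELS}, got {self.label!r}"
            )


# ---------------------------------------------------------------------------
# report I/O

_TEXT_DIR_STEM = re.compile(r"^(?P<rid>.+)\.(?P<rtype>ihc|sp)$", re.IGNORECASE)


def _parse_timestamp(value: str, where: str) -> datetime:
    try:
        return datetime.fromisoformat(value)
    except (TypeError, ValueError) as exc:
        raise ValidationError(f"{where}: unparseable timestamp {value!r}") from exc


def read_reports(path: str | Path, dialect: str = "jsonl") -> list[RawReport]:
    """Read reports from a JSON-lines file or a directory of ``.txt`` files.

    ``jsonl`` records carry ``report_id, patient_id, report_type, timestamp,
    text``. In ``text_dir`` dialect files are named ``<report_id>.<ihc|sp>.txt``;
    patient id defaults to the report id and the timestamp to the unknown
    sentinel. Text is LF-normalized on read in both dialects.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such path: {path}")
    if dialect == "jsonl":
        reports = []
        for i, line in enumerate(path.read_text(encoding="utf-8").splitlines(), 1):
            if not line.strip():
                continue
            rec = json.loads(line)
            where = f"{path.name} line {i} (report {rec.get('report_id', '?')!r})"
            for key in ("report_id", "patient_id", "report_type", "timestamp", "text"):
                if key not in rec:
                    raise ValidationError(f"{where}: missing field {key!r}")
            reports.append(
                RawReport(
                    report_id=str(rec["report_id"]),
                    patient_id=str(rec["patient_id"]),
                    report_type=str(rec["report_type"]),
                    timestamp=_parse_timestamp(rec["timestamp"], where),
                    text=normalize_newlines(rec["text"]),
                )
            )
        return reports
    if dialect == "text_dir":
        reports = []
        for file in sorted(path.glob("*.txt")):
            m = _TEXT_DIR_STEM.match(file.stem)
            if m is None:
                raise ValidationError(
                    f"{file.name}: cannot determine report_type; expected "
                    "'<report_id>.<ihc|sp>.txt'"
                )
            reports.append(
                RawReport(
                    report_id=m.group("rid"),
                    patient_id=m.group("rid"),
                    report_type=m.group("rtype").upper(),
                    timestamp=None,
                    text=normalize_newlines(file.read_text(encoding="utf-8")),
                )
            )
        return reports
    raise ValidationError(f"unsupported dialect {dialect!r}")


def write_reports(reports: Iterable[RawReport], path: str | Path) -> None:
    """Write reports as JSON-lines (the inverse of the ``jsonl`` dialect)."""
    with open(path, "w", encoding="utf-8") as fh:
        for r in reports:
            fh.write(
                json.dumps(
                    {
                        "report_id": r.report_id,
                        "patient_id": r.patient_id,
                        "report_type": r.report_type,
                        "timestamp": None if r.timestamp is None else r.timestamp.isoformat(),
                        "text": r.text,
                    },
                    ensure_ascii=False,
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# terminology I/O


def read_dictionary(path: str | Path) -> list[DictionaryEntry]:
    """Read a two-column surface→preferred TSV; duplicate surfaces are rejected."""
    entries: list[DictionaryEntry] = []
    seen: dict[str, str] = {}
    dupes: list[str] = []
    for i, line in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise ValidationError(f"{path}: line {i} is not two-column TSV: {line!r}")
        surface, preferred = parts[0].strip(), parts[1].strip()
        if surface in seen:
            dupes.append(surface)
            continue
        seen[surface] = preferred
        entries.append(DictionaryEntry(surface=surface, preferred=preferred))
    if dupes:
        raise ValidationError(f"{path}: duplicate surfaces: {sorted(set(dupes))}")
    return entries


def write_dictionary(entries: Iterable[DictionaryEntry], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for e in entries:
            fh.write(f"{e.surface}\t{e.preferred}\n")


# ---------------------------------------------------------------------------
# BRAT standoff I/O
#
# T-lines:      Tn<TAB>LABEL start end<TAB>surface
# note lines:   #n<TAB>AnnotatorNotes Tn<TAB>norm      (carries the preferred term)

_T_LINE = re.compile(r"^(T\d+)\t(\S+) (\d+) (\d+)\t(.*)$")
_NOTE_LINE = re.compile(r"^#\d+\tAnnotatorNotes (T\d+)\t(.*)$")


def write_standoff(
    doc: RawReport, annotations: Sequence[StandoffAnnotation], path: str | Path
) -> None:
    """Write annotations for ``doc`` as a BRAT ``.ann`` file.

    Newlines inside a span are written as spaces in the text field, per BRAT.
    """
    lines: list[str] = []
    for k, ann in enumerate(annotations, 1):
        ann.mention.check_against(doc.text)
        surface = ann.mention.surface.replace("\n", " ")
        lines.append(f"T{k}\t{ann.label} {ann.mention.start} {ann.mention.end}\t{surface}")
        if ann.norm is not None:
            lines.append(f"#{k}\tAnnotatorNotes T{k}\t{ann.norm}")
    Path(path).write_text("".join(line + "\n" for line in lines), encoding="utf-8")


def read_standoff(doc: RawReport, path: str | Path) -> list[StandoffAnnotation]:
    """Read a BRAT ``.ann`` file and validate every span against ``doc``."""
    t_anns: dict[str, StandoffAnnotation] = {}
    order: list[str] = []
    notes: dict[str, str] = {}
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        if not line.strip():
            continue
        m = _T_LINE.match(line)
        if m:
            tid, label, start, end, surface = m.groups()
            mention = Mention(int(start), int(end), surface)
            mention.check_against(doc.text)
            t_anns[tid] = StandoffAnnotation(ann_id=tid, label=label, mention=mention)
            order.append(tid)
            continue
        m = _NOTE_LINE.match(line)
        if m:
            notes[m.group(1)] = m.group(2)
            continue
        raise ValidationError(f"{path}: unrecognized standoff line {line!r}")
    out = []
    for tid in order:
        ann = t_anns[tid]
        if tid in notes:
            ann = StandoffAnnotation(ann.ann_id, ann.label, ann.mention, notes[tid])
        out.append(ann)
    return out
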