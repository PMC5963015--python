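"""Grammar-based parsing of semi-structured IHC reports.

IHC reports come in two reporting styles. List style writes one finding per
clause, anchored on the colon and semicolon determinants::

    S12-3456 :
    p53 : positive ;
    CK 7 : negative ;

Table style writes one finding per row, anchored on the vertical bar::

    S12-3456
    | Antibody | Result |
    | p53      | positive |

Both begin each tissue-slide paragraph with the slide's serial number
(TS_ID) at the top, per CAP reporting guidelines. The grammars are
deliberately minimal: the three formatting determinants (";", ":", "|")
carry the structure, and everything between them is treated as opaque
token text, tolerant of line breaks and irregular whitespace.
"""

from __future__ import annotations

import enum
import logging
import re
from dataclasses import dataclass, field

from pathmarker.model import (
    BiomarkerFinding,
    Mention,
    PathmarkerError,
    RawReport,
    SlideParagraph,
    UnparseableReport,
    ValidationError,
    mention_from,
)

logger = logging.getLogger(__name__)

#: letter-prefixed accession with an optional block suffix, e.g. "S12-3456-2"
DEFAULT_TS_ID_PATTERN = r"[A-Z]{1,2}\d{2}-\d{3,6}(?:-\d+)?"


class ClassificationError(PathmarkerError):
    """Report body is empty or the style cannot be determined."""


class IHCStyle(enum.Enum):
    LIST = "list"
    TABLE = "table"


@dataclass(frozen=True)
class GrammarConfig:
    """Formatting determinants and the slide-header pattern."""

    pair_separators: frozenset[str] = frozenset({";"})
    kv_separators: frozenset[str] = frozenset({":"})
    column_separators: frozenset[str] = frozenset({"|"})
    ts_id_pattern: str = DEFAULT_TS_ID_PATTERN
    table_threshold: float = 0.5

    def __post_init__(self) -> None:
        sets = (self.pair_separators, self.kv_separators, self.column_separators)
        if sum(map(len, sets)) != len(frozenset().union(*sets)):
            raise ValidationError("separator sets must be disjoint")
        try:
            re.compile(self.ts_id_pattern)
        except re.error as exc:
            raise ValidationError(f"ts_id_pattern does not compile: {exc}") from exc

    @property
    def header_re(self) -> re.Pattern:
        # a slide header is a TS_ID alone on its line, optionally with a
        # trailing colon or dash
        return re.compile(
            rf"^[ \t]*(?P<tsid>{self.ts_id_pattern})[ \t]*[:\-]?[ \t]*$", re.MULTILINE
        )


@dataclass(frozen=True)
class SlideHeader:
    ts_id: str
    id_mention: Mention
    span: Mention


def classify_style(report: RawReport, cfg: GrammarConfig | None = None) -> IHCStyle:
    """Classify an IHC report as list- or table-style.

    A report is table-style when more than ``table_threshold`` of its
    non-empty, non-header body lines contain at least two column-separator
    characters; ties go to the simpler list grammar.
    """
    cfg = cfg or GrammarConfig()
    if report.report_type != "IHC":
        raise ValidationError(f"report {report.report_id!r} is not an IHC report")
    header_re = cfg.header_re
    body = [
        line
        for line in report.text.split("\n")
        if line.strip() and not header_re.match(line)
    ]
    if not body:
        raise ClassificationError(f"report {report.report_id!r}: empty body")
    columnar = sum(
        1 for line in body if sum(line.count(c) for c in cfg.column_separators) >= 2
    )
    if columnar / len(body) > cfg.table_threshold:
        return IHCStyle.TABLE
    return IHCStyle.LIST


def segment_slide_paragraphs(
    report: RawReport, cfg: GrammarConfig | None = None
) -> list[SlideHeader]:
    """Split an IHC report into tissue-slide paragraphs at slide headers.

    Each paragraph runs from its header line to the next header (or end of
    document). A report without any slide header cannot be anchored to a
    tissue slide and is rejected as unparseable.
    """
    cfg = cfg or GrammarConfig()
    if report.report_type != "IHC":
        raise ValidationError(f"report {report.report_id!r} is not an IHC report")
    matches = list(cfg.header_re.finditer(report.text))
    if not matches:
        raise UnparseableReport(
            f"report {report.report_id!r}: no TS_ID slide header found"
        )
    headers = []
    for i, m in enumerate(matches):
        start = m.start()
        end = matches[i + 1].start() if i + 1 < len(matches) else len(report.text)
        span_end = end
        while span_end > start + 1 and report.text[span_end - 1] == "\n":
            span_end -= 1  # trailing blank lines belong to no paragraph
        headers.append(
            SlideHeader(
                ts_id=m.group("tsid"),
                id_mention=mention_from(report.text, m.start("tsid"), m.end("tsid")),
                span=mention_from(report.text, start, span_end),
            )
        )
    return headers


def _trimmed_mention(text: str, start: int, end: int, offset: int) -> Mention | None:
    while start < end and text[start].isspace():
        start += 1
    while end > start and text[end - 1].isspace():
        end -= 1
    if start >= end:
        return None
    return Mention(offset + start, offset + end, text[start:end])


def _parse_list(text: str, cfg: GrammarConfig, offset: int) -> list[tuple[Mention, Mention]]:
    pairs: list[tuple[Mention, Mention]] = []
    chunk_start = 0
    boundaries = [i for i, ch in enumerate(text) if ch in cfg.pair_separators]
    for bound in boundaries + [len(text)]:
        chunk = text[chunk_start:bound]
        if chunk.strip():
            kv = next(
                (i for i, ch in enumerate(chunk) if ch in cfg.kv_separators), None
            )
            if kv is None:
                logger.warning("no key-value separator in finding %r; skipped", chunk.strip())
            else:
                bn = _trimmed_mention(text, chunk_start, chunk_start + kv, offset)
                tr = _trimmed_mention(text, chunk_start + kv + 1, bound, offset)
                if bn is None or tr is None:
                    logger.warning("empty BN or TR in finding %r; skipped", chunk.strip())
                else:
                    pairs.append((bn, tr))
        chunk_start = bound + 1
    return pairs


_BN_HEADERS = {"bn", "biomarker", "antibody", "marker", "stain"}
_TR_HEADERS = {"tr", "result", "results", "test result"}


def _parse_table(text: str, cfg: GrammarConfig, offset: int) -> list[tuple[Mention, Mention]]:
    pairs: list[tuple[Mention, Mention]] = []
    bn_col, tr_col = 0, 1
    header_seen = False
    pos = 0
    for line in text.split("\n"):
        line_start = pos
        pos += len(line) + 1
        if not line.strip() or not any(c in line for c in cfg.column_separators):
            continue
        cuts = [i for i, ch in enumerate(line) if ch in cfg.column_separators]
        edges = [-1] + cuts + [len(line)]
        cells = [
            _trimmed_mention(text, line_start + a + 1, line_start + b, offset)
            for a, b in zip(edges, edges[1:])
        ]
        non_empty = [(i, c) for i, c in enumerate(cells) if c is not None]
        if not header_seen:
            header_seen = True
            labels = {c.surface.casefold(): i for i, c in non_empty}
            bn_hits = [i for lab, i in labels.items() if lab in _BN_HEADERS]
            tr_hits = [i for lab, i in labels.items() if lab in _TR_HEADERS]
            if bn_hits and tr_hits:
                bn_col, tr_col = bn_hits[0], tr_hits[0]
                continue  # recognized header row: not a finding
            if non_empty:
                bn_col, tr_col = non_empty[0][0], (
                    non_empty[1][0] if len(non_empty) > 1 else non_empty[0][0] + 1
                )
            # unlabeled first row falls through and is parsed as a finding
        bn = cells[bn_col] if bn_col < len(cells) else None
        tr = cells[tr_col] if tr_col < len(cells) else None
        if bn is None or tr is None:
            logger.warning("table row %r lacks BN/TR cells; skipped", line.strip())
            continue
        pairs.append((bn, tr))
    return pairs


def parse_findings(
    paragraph_text: str,
    style: IHCStyle,
    cfg: GrammarConfig | None = None,
    offset: int = 0,
) -> list[tuple[Mention, Mention]]:
    """Extract (BN, TR) mention pairs from one slide paragraph.

    ``offset`` shifts mention offsets into document coordinates. A leading
    slide-header line is skipped; clauses or rows matching neither grammar
    are logged and dropped without aborting the paragraph.
    """
    cfg = cfg or GrammarConfig()
    m = cfg.header_re.match(paragraph_text)
    body_start = m.end() + 1 if m and m.end() < len(paragraph_text) else (m.end() if m else 0)
    body = paragraph_text[body_start:]
    if style is IHCStyle.LIST:
        return _parse_list(body, cfg, offset + body_start)
    return _parse_table(body, cfg, offset + body_start)


def parse_ihc_report(
    report: RawReport, cfg: GrammarConfig | None = None
) -> tuple[IHCStyle, list[SlideParagraph]]:
    """Full structural parse: classify style, segment slides, extract pairs.

    Findings are returned un-normalized (``bn_norm``/``tr_norm`` stay
    ``UNMATCHED``); normalization is a separate pass.
    """
    cfg = cfg or GrammarConfig()
    style = classify_style(report, cfg)
    paragraphs = []
    for header in segment_slide_paragraphs(report, cfg):
        pairs = parse_findings(
            report.text[header.span.start : header.span.end],
            style,
            cfg,
            offset=header.span.start,
        )
        for bn, tr in pairs:
            bn.check_against(report.text)
            tr.check_against(report.text)
        paragraphs.append(
            SlideParagraph(
                ts_id=header.ts_id,
                report_id=report.report_id,
                timestamp=report.timestamp,
                span=header.span,
                findings=tuple(BiomarkerFinding(bn=bn, tr=tr) for bn, tr in pairs),
            )
        )
    return style, paragraphs
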