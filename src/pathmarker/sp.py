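"""Tree-based parsing of surgical-pathology reports.

SP reports are too variable for a grammar, but they follow a layout
tendency rooted in CAP reporting guidelines: the organ of origin appears in
the first few lines, diagnoses follow as numbered items, and the detailed
microscopic findings for a diagnosis are grouped under it with indentation.
The parser turns that layout into a tree — organ at the root, numbered
disease lines as depth-1 children, indented finding lines nested below —
then normalizes the organ and disease names by dictionary look-up with the
combined similarity score, detects negation and metastasis wording with a
user-editable pattern list, and applies the single-organ/single-diagnosis
filter used to select reports safe for merging.
"""

from __future__ import annotations

import enum
import logging
import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Sequence

from pathmarker.model import (
    DictionaryEntry,
    Mention,
    RawReport,
    UNMATCHED,
    UnparseableReport,
    ValidationError,
    mention_from,
)
from pathmarker.normalize import DictionaryMatcher, fold
from pathmarker.similarity import SimilarityWeights

logger = logging.getLogger(__name__)


class NodeKind(enum.Enum):
    ROOT_ORGAN = "root_organ"
    DISEASE = "disease"
    FINDING = "finding"


@dataclass
class SPParseTreeNode:
    kind: NodeKind
    line_index: int
    indent: int
    mention: Mention
    children: list["SPParseTreeNode"] = field(default_factory=list)

    def walk(self):
        yield self
        for child in self.children:
            yield from child.walk()


@dataclass(frozen=True)
class DiagnosisExtraction:
    """One numbered diagnosis line with everything grouped under it."""

    line: Mention  # the diagnosis text with leading numbering stripped
    disease_norm: str
    negated: bool
    metastasis: bool
    findings: tuple[Mention, ...] = ()


@dataclass(frozen=True)
class SPExtraction:
    """Normalized content of one SP report.

    ``ts_id`` is the accession joining this specimen to its IHC slide
    paragraphs; by default it equals the report id.
    """

    report_id: str
    patient_id: str
    timestamp: object  # datetime | None
    ts_id: str
    organ_raw: Mention | None
    organ_norm: str
    diagnoses: tuple[DiagnosisExtraction, ...]


@dataclass(frozen=True)
class SPConfig:
    organ_search_lines: int = 5
    tab_width: int = 8
    numbered_pattern: str = r"^\s*(\d+)[.)]\s+"
    section_stop: frozenset[str] = frozenset(
        {
            "gross description",
            "frozen section",
            "frozen section diagnosis",
            "intraoperative consultation",
            "clinical history",
        }
    )


def _indent_of(line: str, tab_width: int) -> int:
    col = 0
    for ch in line:
        if ch == " ":
            col += 1
        elif ch == "\t":
            col += tab_width - col % tab_width
        else:
            break
    return col


def load_patterns(path) -> list[str]:
    """Read a pattern file: one lowercase pattern or stem per line."""
    lines = []
    for line in open(path, encoding="utf-8"):
        line = line.strip()
        if line and not line.startswith("#"):
            lines.append(line.casefold())
    return lines


def _bundled_patterns(name: str) -> list[str]:
    text = resources.files("pathmarker.data").joinpath(name).read_text(encoding="utf-8")
    return [l.strip().casefold() for l in text.splitlines() if l.strip() and not l.startswith("#")]


def default_negation_patterns() -> list[str]:
    return _bundled_patterns("negation_patterns.txt")


def default_metastasis_patterns() -> list[str]:
    return _bundled_patterns("metastasis_patterns.txt")


def detect_negation_metastasis(
    text: str,
    negation_patterns: Sequence[str] | None = None,
    metastasis_patterns: Sequence[str] | None = None,
) -> tuple[bool, bool]:
    """Flag negation and metastasis wording by case-insensitive pattern match.

    Patterns are plain substrings; a pattern ending in ``-`` is a stem
    (``metasta-`` matches metastasis/metastatic).
    """
    if negation_patterns is None:
        negation_patterns = default_negation_patterns()
    if metastasis_patterns is None:
        metastasis_patterns = default_metastasis_patterns()
    hay = " ".join(text.casefold().split())

    def hit(patterns: Sequence[str]) -> bool:
        return any(p.rstrip("-") in hay for p in patterns)

    return hit(negation_patterns), hit(metastasis_patterns)


class TermRecognizer:
    """Span search over a line against one terminology.

    Candidate spans are comma/semicolon-separated segments and token n-grams
    (n ≤ 4) within them; the best-scoring span wins. Surfaces matched only
    via similarity are registered in a run-scoped learned-term table,
    mirroring incremental terminology-database curation.
    """

    def __init__(
        self,
        entries: Sequence[DictionaryEntry],
        weights: SimilarityWeights | None = None,
        max_ngram: int = 4,
    ):
        self.matcher = DictionaryMatcher(entries, weights)
        self.max_ngram = max_ngram
        self.learned: dict[str, str] = {}

    def _candidate_spans(self, line: str, offset: int) -> list[tuple[int, int]]:
        spans: list[tuple[int, int]] = []
        for seg in re.finditer(r"[^,;:]+", line):
            seg_text = seg.group()
            tokens = list(re.finditer(r"\S+", seg_text))
            n = len(tokens)
            for i in range(n):
                for j in range(i, min(i + self.max_ngram, n)):
                    spans.append(
                        (offset + seg.start() + tokens[i].start(),
                         offset + seg.start() + tokens[j].end())
                    )
        return spans

    def recognize(
        self, line: str, offset: int = 0
    ) -> tuple[str, float, Mention | None]:
        """Return (preferred term or UNMATCHED, score, matched span)."""
        if not line.strip():
            return UNMATCHED, 0.0, None
        best: tuple[float, int, tuple[int, int], str] | None = None
        best_rejected = 0.0
        for start, end in self._candidate_spans(line, offset):
            text = line[start - offset : end - offset]
            preferred, score = self.matcher.lookup(text)
            if preferred == UNMATCHED:
                best_rejected = max(best_rejected, score)
                continue
            # at equal score prefer the longer (maximal) span, then leftmost
            cand = (-score, -(end - start), (start, end), preferred)
            if best is None or cand < best:
                best = cand
        if best is None:
            return UNMATCHED, best_rejected, None
        score, (start, end), preferred = -best[0], best[2], best[3]
        surface = line[start - offset : end - offset]
        if fold(surface) not in self.matcher._exact:
            self.learned.setdefault(surface, preferred)
        return preferred, score, Mention(start, end, surface)


def recognize_organ(
    line: str,
    organ_dictionary: Sequence[DictionaryEntry] | TermRecognizer,
    weights: SimilarityWeights | None = None,
) -> tuple[str, float]:
    """Best organ match over candidate token spans of a line."""
    rec = (
        organ_dictionary
        if isinstance(organ_dictionary, TermRecognizer)
        else TermRecognizer(organ_dictionary, weights)
    )
    preferred, score, _ = rec.recognize(line)
    return preferred, score


def recognize_diagnosis(
    node: SPParseTreeNode,
    disease_dictionary: Sequence[DictionaryEntry] | TermRecognizer,
    weights: SimilarityWeights | None = None,
) -> tuple[str, Mention]:
    """Normalize a DISEASE node; the full raw line is always preserved."""
    if node.kind is not NodeKind.DISEASE:
        raise ValidationError("recognize_diagnosis requires a DISEASE node")
    rec = (
        disease_dictionary
        if isinstance(disease_dictionary, TermRecognizer)
        else TermRecognizer(disease_dictionary, weights)
    )
    line_mention = _strip_numbering(node.mention)
    preferred, _, _ = rec.recognize(line_mention.surface, offset=line_mention.start)
    return preferred, line_mention


_NUM_PREFIX = re.compile(r"^\s*\d+[.)]\s*")


def _strip_numbering(mention: Mention) -> Mention:
    m = _NUM_PREFIX.match(mention.surface)
    cut = m.end() if m else 0
    text = mention.surface[cut:].rstrip()
    if not text:
        return mention
    return Mention(mention.start + cut, mention.start + cut + len(text), text)


def build_parse_tree(
    report: RawReport,
    organ_recognizer: TermRecognizer | None = None,
    config: SPConfig | None = None,
) -> SPParseTreeNode:
    """Build the organ-rooted tree from numbering and indentation.

    The root is the first of the opening lines that matches the organ
    terminology (or simply the first non-empty line when no recognizer is
    given). Numbered lines become depth-1 DISEASE children; deeper-indented
    lines nest as FINDING nodes by indent column. Lines before the organ
    line, and any section from a gross/frozen-section header on, are
    ignored with a warning.
    """
    cfg = config or SPConfig()
    if report.report_type != "SP":
        raise ValidationError(f"report {report.report_id!r} is not an SP report")
    numbered = re.compile(cfg.numbered_pattern)
    lines = report.text.split("\n")
    pos = 0
    spans: list[tuple[int, int, str]] = []
    for line in lines:
        spans.append((pos, pos + len(line), line))
        pos += len(line) + 1
    # truncate at the first stop-section header
    cut = len(spans)
    for i, (_, _, line) in enumerate(spans):
        if fold(line).rstrip(":") in cfg.section_stop:
            cut = i
            break
    spans = spans[:cut]

    root_idx: int | None = None
    non_empty_seen = 0
    for i, (_, _, line) in enumerate(spans):
        if not line.strip():
            continue
        if numbered.match(line):
            break  # numbered lines are diagnoses by layout, never the organ
        non_empty_seen += 1
        if organ_recognizer is None:
            root_idx = i
            break
        preferred, _, _ = organ_recognizer.recognize(line)
        if preferred != UNMATCHED:
            root_idx = i
            break
        if non_empty_seen >= cfg.organ_search_lines:
            break
    if root_idx is None:
        raise UnparseableReport(
            f"report {report.report_id!r}: no organ line in the first "
            f"{cfg.organ_search_lines} lines"
        )
    if any(line.strip() for _, _, line in spans[:root_idx]):
        logger.warning(
            "report %r: ignoring %d line(s) before the organ line",
            report.report_id,
            root_idx,
        )
    start, end, line = spans[root_idx]
    root = SPParseTreeNode(
        kind=NodeKind.ROOT_ORGAN,
        line_index=root_idx,
        indent=_indent_of(line, cfg.tab_width),
        mention=mention_from(report.text, start, end),
    )
    stack: list[SPParseTreeNode] = [root]  # nodes open for attachment, by indent
    for i in range(root_idx + 1, len(spans)):
        start, end, line = spans[i]
        if not line.strip():
            continue
        indent = _indent_of(line, cfg.tab_width)
        mention = mention_from(report.text, start, end)
        if numbered.match(line):
            node = SPParseTreeNode(NodeKind.DISEASE, i, indent, mention)
            root.children.append(node)
            stack = [root, node]
            continue
        node = SPParseTreeNode(NodeKind.FINDING, i, indent, mention)
        while len(stack) > 1 and indent <= stack[-1].indent:
            stack.pop()
        if len(stack) == 1:
            logger.warning(
                "report %r line %d: finding outside any diagnosis", report.report_id, i
            )
        stack[-1].children.append(node)
        stack.append(node)
    return root


def is_single_organ_single_diagnosis(extraction: SPExtraction) -> bool:
    """True iff exactly one matched organ and exactly one diagnosis line."""
    return extraction.organ_norm != UNMATCHED and len(extraction.diagnoses) == 1


def extract_sp(
    report: RawReport,
    organ_recognizer: TermRecognizer,
    disease_recognizer: TermRecognizer,
    config: SPConfig | None = None,
    negation_patterns: Sequence[str] | None = None,
    metastasis_patterns: Sequence[str] | None = None,
    ts_id: str | None = None,
) -> SPExtraction:
    """Parse, recognize and normalize one SP report end to end."""
    tree = build_parse_tree(report, organ_recognizer, config)
    organ_norm, _, organ_mention = organ_recognizer.recognize(
        tree.mention.surface, offset=tree.mention.start
    )
    diagnoses = []
    for node in tree.children:
        if node.kind is not NodeKind.DISEASE:
            continue
        disease_norm, line_mention = recognize_diagnosis(node, disease_recognizer)
        sub_text = " ".join(n.mention.surface.strip() for n in node.walk())
        negated, metastasis = detect_negation_metastasis(
            sub_text, negation_patterns, metastasis_patterns
        )
        diagnoses.append(
            DiagnosisExtraction(
                line=line_mention,
                disease_norm=disease_norm,
                negated=negated,
                metastasis=metastasis,
                findings=tuple(
                    n.mention for n in node.walk() if n.kind is NodeKind.FINDING
                ),
            )
        )
    return SPExtraction(
        report_id=report.report_id,
        patient_id=report.patient_id,
        timestamp=report.timestamp,
        ts_id=ts_id if ts_id is not None else report.report_id,
        organ_raw=organ_mention,
        organ_norm=organ_norm,
        diagnoses=tuple(diagnoses),
    )
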