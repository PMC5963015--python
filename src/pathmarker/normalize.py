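"""Biomarker-name and test-result normalization.

Biomarker names (BN) are normalized by stripping laboratory parentheticals,
exact look-up in an expanded dictionary, and — on a miss — text-similarity
search with the combined look-up score. The dictionary is expanded by five
rule families applied to fixpoint:

1. Roman numerals → Arabic (whole tokens with a preceding word);
2. Greek symbols ↔ spelled letter names (both directions);
3. removal of laboratory-related parentheticals ("(repeat)", "(4)");
4. hyphen / space / joined delimiter variants ("GAL3" = "GAL-3" = "GAL 3");
5. lowercase form.

Test results (TR) are normalized by exact dictionary look-up only, into the
four-category codomain Positive / Focal positive / Negative / Error; fuzzy
matching is deliberately disallowed because assigning a category needs
background knowledge about the assay, not string proximity.
"""

from __future__ import annotations

import enum
import re
import warnings
from itertools import product
from typing import Iterable, Mapping, Sequence

from pathmarker.model import DictionaryEntry, UNMATCHED, ValidationError
from pathmarker.similarity import (
    SimilarityWeights,
    TokenStats,
    similarity_score,
)


class TRCategory(enum.Enum):
    """The four-value test-result codomain."""

    POSITIVE = "Positive"
    FOCAL_POSITIVE = "Focal positive"
    NEGATIVE = "Negative"
    ERROR = "Error"

    @classmethod
    def from_string(cls, value: str) -> "TRCategory":
        folded = " ".join(value.lower().split())
        for cat in cls:
            if cat.value.lower() == folded:
                return cat
        raise ValidationError(f"unknown TR category {value!r}")


DEFAULT_LAB_TERMS = frozenset({"repeat", "recut", "control", "outside"})

_GREEK = {
    "α": "alpha", "β": "beta", "γ": "gamma", "δ": "delta", "ε": "epsilon",
    "ζ": "zeta", "η": "eta", "θ": "theta", "ι": "iota", "κ": "kappa",
    "λ": "lambda", "μ": "mu", "ν": "nu", "ξ": "xi", "ο": "omicron",
    "π": "pi", "ρ": "rho", "σ": "sigma", "τ": "tau", "υ": "upsilon",
    "φ": "phi", "χ": "chi", "ψ": "psi", "ω": "omega",
}
_GREEK_NAME = {v: k for k, v in _GREEK.items()}

_ROMAN_VALUES = {"I": 1, "V": 5, "X": 10, "L": 50, "C": 100, "D": 500, "M": 1000}
_ROMAN_TOKEN = re.compile(r"^[IVXLCDM]+$")
_PAREN_GROUP = re.compile(r"\s*\(([^()]*)\)")


def fold(text: str) -> str:
    """Case-fold and collapse whitespace runs — the exact-look-up key form."""
    return " ".join(text.casefold().split())


def _roman_to_int(token: str) -> int:
    total, prev = 0, 0
    for ch in reversed(token):
        v = _ROMAN_VALUES[ch]
        total = total - v if v < prev else total + v
        prev = max(prev, v)
    return total


def strip_lab_terms(name: str, stop_terms: Iterable[str] = DEFAULT_LAB_TERMS) -> str:
    """Remove parentheticals whose content is numeric or a lab stop term.

    ``"WT-1 (4)"`` and ``"CD10(repeat)"`` become ``"WT-1"`` and ``"CD10"``;
    unbalanced parentheses leave the text unchanged with a warning.
    """
    if name.count("(") != name.count(")"):
        warnings.warn(f"unbalanced parentheses in {name!r}; left unchanged", stacklevel=2)
        return name
    stop = {t.casefold() for t in stop_terms}

    def _maybe_drop(m: re.Match) -> str:
        content = m.group(1).strip().casefold()
        if not content or content.isdigit() or content in stop:
            return ""
        return m.group(0)

    return _PAREN_GROUP.sub(_maybe_drop, name).strip()


def _int_to_roman(n: int) -> str:
    out = []
    for value, sym in (
        (1000, "M"), (900, "CM"), (500, "D"), (400, "CD"), (100, "C"),
        (90, "XC"), (50, "L"), (40, "XL"), (10, "X"), (9, "IX"),
        (5, "V"), (4, "IV"), (1, "I"),
    ):
        while n >= value:
            out.append(sym)
            n -= value
    return "".join(out)


#: largest Roman numeral converted; factor/class numbering stays well below
#: this, and the cap keeps ambiguous letters like D, C, L, M out of the rule
_ROMAN_MAX = 40


def _roman_variants(surface: str) -> set[str]:
    tokens = surface.split(" ")
    out = set()
    for i in range(1, len(tokens)):
        tok = tokens[i]
        if tok == "I" or not _ROMAN_TOKEN.match(tok) or not tokens[i - 1]:
            continue  # "I" alone is ambiguous with the letter
        value = _roman_to_int(tok)
        if value > _ROMAN_MAX or _int_to_roman(value) != tok:
            continue
        out.add(" ".join(tokens[:i] + [str(value)] + tokens[i + 1:]))
    return out


def _greek_variants(surface: str) -> set[str]:
    out = set()
    sym_to_name = surface
    for sym, name in _GREEK.items():
        sym_to_name = sym_to_name.replace(sym, name)
    if sym_to_name != surface:
        out.add(sym_to_name)
    name_to_sym = re.sub(
        r"\b(" + "|".join(_GREEK_NAME) + r")\b",
        lambda m: _GREEK_NAME[m.group(1).lower()],
        surface,
        flags=re.IGNORECASE,
    )
    if name_to_sym != surface:
        out.add(name_to_sym)
    return out


# delimiter variants are generated at letter/digit transitions and at
# existing hyphens; alpha-alpha word spaces stay put ("Wilms Tumor" never
# becomes "WilmsTumor")
_SEGMENT = re.compile(r"[^\W\d_]+|\d+|[ -]|.", re.UNICODE)
_MAX_VARIANT_SLOTS = 5


def _delimiter_variants(surface: str) -> set[str]:
    parts = _SEGMENT.findall(surface)
    template: list[str] = []
    var_positions: list[int] = []
    for i, part in enumerate(parts):
        prev = parts[i - 1] if i > 0 else ""
        nxt = parts[i + 1] if i + 1 < len(parts) else ""
        is_var = part == "-" or (
            part == " "
            and prev[-1:].isalnum()
            and nxt[:1].isalnum()
            and (prev[-1:].isdigit() or nxt[:1].isdigit())
        )
        if is_var:
            var_positions.append(len(template))
        template.append(part)
        # implicit letter|digit boundary gets an empty-delimiter slot
        if part[-1:].isalnum() and nxt[:1].isalnum() and (
            part[-1].isdigit() != nxt[0].isdigit()
        ):
            var_positions.append(len(template))
            template.append("")
    if not var_positions or len(var_positions) > _MAX_VARIANT_SLOTS:
        return set()
    out: set[str] = set()
    for combo in product(["", "-", " "], repeat=len(var_positions)):
        cand = list(template)
        for pos, delim in zip(var_positions, combo):
            cand[pos] = delim
        s = "".join(cand).strip()
        if s and s != surface:
            out.add(s)
    return out


def _rule_variants(surface: str, stop_terms: Iterable[str]) -> set[str]:
    out: set[str] = set()
    out |= _roman_variants(surface)
    out |= _greek_variants(surface)
    stripped = strip_lab_terms(surface, stop_terms)
    if stripped and stripped != surface:
        out.add(stripped)
    out |= _delimiter_variants(surface)
    low = surface.lower()
    if low != surface:
        out.add(low)
    out.discard(surface)
    out.discard("")
    return out


def expand_bn_dictionary(
    entries: Sequence[DictionaryEntry],
    stop_terms: Iterable[str] = DEFAULT_LAB_TERMS,
) -> list[DictionaryEntry]:
    """Close the dictionary under the five expansion rule families.

    Every generated variant maps to its origin entry's preferred term; the
    originals are retained first. Expansion is idempotent: re-expanding an
    expanded dictionary returns it unchanged.
    """
    seen: dict[str, str] = {}
    out: list[DictionaryEntry] = []
    for e in entries:
        if e.surface in seen:
            continue
        seen[e.surface] = e.preferred
        out.append(e)
    frontier = [(e.surface, e.preferred) for e in out]
    while frontier:
        next_frontier: list[tuple[str, str]] = []
        for surface, preferred in frontier:
            for variant in sorted(_rule_variants(surface, stop_terms)):
                if variant in seen:
                    continue
                seen[variant] = preferred
                out.append(DictionaryEntry(variant, preferred, source="expanded"))
                next_frontier.append((variant, preferred))
        frontier = next_frontier
    return out


class DictionaryMatcher:
    """Exact-then-fuzzy look-up against a terminology's surface forms.

    Exact look-up uses case-folded, whitespace-collapsed keys. On a miss the
    combined similarity score ranks all surfaces; ties break by higher score,
    then shorter surface, then lexicographic order.
    """

    def __init__(
        self,
        entries: Sequence[DictionaryEntry],
        weights: SimilarityWeights | None = None,
    ):
        self.entries = list(entries)
        self.weights = weights or SimilarityWeights()
        self._exact: dict[str, str] = {}
        for e in self.entries:
            self._exact.setdefault(fold(e.surface), e.preferred)
        self.stats = TokenStats.from_surfaces(e.surface for e in self.entries)

    def lookup(self, mention: str) -> tuple[str, float]:
        """Return (preferred term or UNMATCHED, score)."""
        key = fold(mention)
        if not key:
            return UNMATCHED, 0.0
        if key in self._exact:
            return self._exact[key], 1.0
        best: tuple[float, int, str, str] | None = None
        for e in self.entries:
            s = similarity_score(key, fold(e.surface), self.weights, self.stats)
            cand = (-s, len(e.surface), e.surface, e.preferred)
            if best is None or cand < best:
                best = cand
        if best is None:
            return UNMATCHED, 0.0
        score = -best[0]
        if score >= self.weights.threshold:
            return best[3], score
        return UNMATCHED, score


def normalize_bn(
    mention: str,
    dictionary: Sequence[DictionaryEntry] | DictionaryMatcher,
    weights: SimilarityWeights | None = None,
    stop_terms: Iterable[str] = DEFAULT_LAB_TERMS,
) -> str:
    """Normalize a biomarker-name mention to its preferred term.

    Pipeline: strip laboratory parentheticals → case-fold → exact look-up →
    similarity search at the configured threshold → ``UNMATCHED``.
    """
    if not mention or not mention.strip():
        warnings.warn("empty biomarker mention", stacklevel=2)
        return UNMATCHED
    matcher = (
        dictionary
        if isinstance(dictionary, DictionaryMatcher)
        else DictionaryMatcher(dictionary, weights)
    )
    preferred, _ = matcher.lookup(strip_lab_terms(mention, stop_terms))
    return preferred


def read_tr_dictionary(entries: Sequence[DictionaryEntry]) -> dict[str, TRCategory]:
    """Turn surface→category dictionary entries into a look-up table."""
    table: dict[str, TRCategory] = {}
    for e in entries:
        table[fold(e.surface)] = TRCategory.from_string(e.preferred)
    return table


def normalize_tr(
    mention: str, tr_dictionary: Mapping[str, TRCategory] | Sequence[DictionaryEntry]
) -> TRCategory | str:
    """Exact-look-up normalization of a test-result mention.

    Returns a :class:`TRCategory` or ``UNMATCHED`` for human triage; no
    similarity search is attempted.
    """
    if not isinstance(tr_dictionary, Mapping):
        tr_dictionary = read_tr_dictionary(tr_dictionary)
    return tr_dictionary.get(fold(mention), UNMATCHED)
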