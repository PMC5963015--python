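"""String-similarity look-up score for terminology matching.

The dictionary look-up score is a weighted linear sum of four component
similarities, each mapped to [0, 1]:

* edit — 1 minus Levenshtein distance normalized by the longer string;
* kernel — cosine-normalized p-spectrum (character 3-gram) kernel;
* jw — Jaro–Winkler similarity;
* soft_tfidf — soft TF-IDF with Jaro–Winkler as the inner token matcher,
  IDF weights taken from a token document-frequency table built over the
  dictionary surfaces.

All components are symmetric except soft TF-IDF, which is evaluated from
the query side. Each equals 1 on identical strings, so the combined score
is 1 exactly when every weighted component is 1.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from typing import Iterable

from pathmarker.model import ValidationError

_TOKEN = re.compile(r"\w+", re.UNICODE)

#: inner-matcher threshold for soft TF-IDF token alignment
SOFT_TFIDF_INNER_THETA = 0.9


@dataclass(frozen=True)
class SimilarityWeights:
    """Component weights (must sum to 1) and the match-acceptance threshold."""

    w_edit: float = 0.25
    w_kernel: float = 0.25
    w_jw: float = 0.25
    w_softtfidf: float = 0.25
    threshold: float = 0.85

    def __post_init__(self) -> None:
        ws = (self.w_edit, self.w_kernel, self.w_jw, self.w_softtfidf)
        if any(w < 0 for w in ws):
            raise ValidationError("similarity weights must be nonnegative")
        if abs(sum(ws) - 1.0) > 1e-9:
            raise ValidationError(f"similarity weights must sum to 1, got {sum(ws)}")
        if not (0 < self.threshold <= 1):
            raise ValidationError("threshold must be in (0, 1]")


def tokenize(text: str) -> list[str]:
    """Lower-cased word tokens; punctuation and hyphens are separators."""
    return _TOKEN.findall(text.lower())


def levenshtein(a: str, b: str) -> int:
    """Unit-cost edit distance (insert / delete / substitute)."""
    if a == b:
        return 0
    if len(a) < len(b):
        a, b = b, a
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        for j, cb in enumerate(b, 1):
            cur.append(min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + (ca != cb)))
        prev = cur
    return prev[-1]


def edit_similarity(a: str, b: str) -> float:
    return 1.0 - levenshtein(a, b) / max(len(a), len(b))


def _ngram_counts(s: str, n: int) -> dict[str, int]:
    counts: dict[str, int] = {}
    for i in range(len(s) - n + 1):
        g = s[i : i + n]
        counts[g] = counts.get(g, 0) + 1
    return counts


def spectrum_kernel(a: str, b: str, p: int = 3) -> float:
    """Cosine-normalized p-spectrum kernel over character n-grams.

    For strings shorter than ``p`` the order drops to the shorter string's
    length so that identical short strings still score 1.
    """
    p_eff = min(p, len(a), len(b))
    ca, cb = _ngram_counts(a, p_eff), _ngram_counts(b, p_eff)
    dot = sum(v * cb.get(g, 0) for g, v in ca.items())
    if dot == 0:
        return 0.0
    na = math.sqrt(sum(v * v for v in ca.values()))
    nb = math.sqrt(sum(v * v for v in cb.values()))
    return dot / (na * nb)


def jaro(a: str, b: str) -> float:
    if a == b:
        return 1.0
    la, lb = len(a), len(b)
    window = max(la, lb) // 2 - 1
    match_a = [False] * la
    match_b = [False] * lb
    matches = 0
    for i, ca in enumerate(a):
        lo, hi = max(0, i - window), min(lb, i + window + 1)
        for j in range(lo, hi):
            if not match_b[j] and b[j] == ca:
                match_a[i] = match_b[j] = True
                matches += 1
                break
    if matches == 0:
        return 0.0
    transpositions = 0
    j = 0
    for i in range(la):
        if match_a[i]:
            while not match_b[j]:
                j += 1
            if a[i] != b[j]:
                transpositions += 1
            j += 1
    t = transpositions / 2
    m = matches
    return (m / la + m / lb + (m - t) / m) / 3


def jaro_winkler(a: str, b: str, prefix_scale: float = 0.1, max_prefix: int = 4) -> float:
    """Jaro similarity boosted by a shared prefix of up to 4 characters."""
    j = jaro(a, b)
    prefix = 0
    for ca, cb in zip(a, b):
        if ca != cb or prefix >= max_prefix:
            break
        prefix += 1
    return j + prefix * prefix_scale * (1 - j)


class TokenStats:
    """Token document frequencies over a terminology's surface forms.

    IDF uses the smoothed form ``log((n_docs + 1) / (df + 1)) + 1`` so that
    unseen tokens get a finite weight and an empty table degrades to uniform
    weighting.
    """

    def __init__(self, doc_freq: dict[str, int] | None = None, n_docs: int = 0):
        self.doc_freq = dict(doc_freq or {})
        self.n_docs = n_docs

    @classmethod
    def from_surfaces(cls, surfaces: Iterable[str]) -> "TokenStats":
        df: dict[str, int] = {}
        n = 0
        for s in surfaces:
            n += 1
            for tok in set(tokenize(s)):
                df[tok] = df.get(tok, 0) + 1
        return cls(df, n)

    def idf(self, token: str) -> float:
        return math.log((self.n_docs + 1) / (self.doc_freq.get(token, 0) + 1)) + 1.0


def _tfidf_vector(tokens: list[str], stats: TokenStats) -> dict[str, float]:
    tf: dict[str, int] = {}
    for t in tokens:
        tf[t] = tf.get(t, 0) + 1
    vec = {t: math.log(c + 1) * stats.idf(t) for t, c in tf.items()}
    norm = math.sqrt(sum(v * v for v in vec.values()))
    return {t: v / norm for t, v in vec.items()}


def soft_tfidf(
    query: str,
    candidate: str,
    stats: TokenStats | None = None,
    theta: float = SOFT_TFIDF_INNER_THETA,
) -> float:
    """Soft TF-IDF similarity with Jaro–Winkler as the inner matcher.

    Query tokens align to their closest candidate token when the inner
    similarity reaches ``theta``; each aligned pair contributes the product
    of the two unit-normalized TF-IDF weights and the inner similarity.
    """
    stats = stats or TokenStats()
    # strings without word characters act as a single opaque token
    q_tokens = tokenize(query) or [query.strip() or query]
    c_tokens = tokenize(candidate) or [candidate.strip() or candidate]
    vq = _tfidf_vector(q_tokens, stats)
    vc = _tfidf_vector(c_tokens, stats)
    score = 0.0
    for qt in vq:
        best_sim, best_ct = 0.0, None
        for ct in vc:
            s = jaro_winkler(qt, ct)
            if s > best_sim:
                best_sim, best_ct = s, ct
        if best_ct is not None and best_sim >= theta:
            score += vq[qt] * vc[best_ct] * best_sim
    return min(score, 1.0)


def similarity_score(
    query: str,
    candidate: str,
    weights: SimilarityWeights | None = None,
    corpus_stats: TokenStats | None = None,
) -> float:
    """Weighted linear sum of the four component similarities, in [0, 1]."""
    if not query or not candidate:
        raise ValidationError("similarity_score requires non-empty strings")
    weights = weights or SimilarityWeights()
    s = (
        weights.w_edit * edit_similarity(query, candidate)
        + weights.w_kernel * spectrum_kernel(query, candidate)
        + weights.w_jw * jaro_winkler(query, candidate)
        + weights.w_softtfidf * soft_tfidf(query, candidate, corpus_stats)
    )
    return min(max(s, 0.0), 1.0)
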