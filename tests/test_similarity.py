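"""Each similarity component against an independent reference implementation.

References: python-edlib for edit distance, scikit-learn character-3-gram
counting with an explicit cosine for the spectrum kernel, and direct
definitional transcriptions for Jaro-Winkler and soft TF-IDF (written
against the published definitions, not by calling the package).
"""

import math
import random
import re

import edlib
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.feature_extraction.text import CountVectorizer

from pathmarker.similarity import (
    SimilarityWeights,
    TokenStats,
    edit_similarity,
    jaro_winkler,
    similarity_score,
    soft_tfidf,
    spectrum_kernel,
)
from pathmarker.synthesis import Vocabulary

TOL = 1e-9


# --- reference implementations -------------------------------------------

def ref_edit_similarity(a: str, b: str) -> float:
    d = edlib.align(a, b, task="distance")["editDistance"]
    return 1.0 - d / max(len(a), len(b))


def ref_spectrum_kernel(a: str, b: str) -> float:
    p = min(3, len(a), len(b))
    vec = CountVectorizer(analyzer="char", ngram_range=(p, p), lowercase=False)
    counts = vec.fit_transform([a, b]).toarray()
    va, vb = counts[0], counts[1]
    dot = float(va @ vb)
    if dot == 0:
        return 0.0
    return dot / (math.sqrt(float(va @ va)) * math.sqrt(float(vb @ vb)))


def ref_jaro(a: str, b: str) -> float:
    if a == b:
        return 1.0
    la, lb = len(a), len(b)
    dist = max(la, lb) // 2 - 1
    a_flags, b_flags = [False] * la, [False] * lb
    m = 0
    for i in range(la):
        for j in range(max(0, i - dist), min(lb, i + dist + 1)):
            if not b_flags[j] and a[i] == b[j]:
                a_flags[i] = b_flags[j] = True
                m += 1
                break
    if m == 0:
        return 0.0
    a_m = [a[i] for i in range(la) if a_flags[i]]
    b_m = [b[j] for j in range(lb) if b_flags[j]]
    t = sum(x != y for x, y in zip(a_m, b_m)) / 2
    return (m / la + m / lb + (m - t) / m) / 3


def ref_jaro_winkler(a: str, b: str) -> float:
    j = ref_jaro(a, b)
    ell = 0
    while ell < min(4, len(a), len(b)) and a[ell] == b[ell]:
        ell += 1
    return j + ell * 0.1 * (1 - j)


def ref_soft_tfidf(query: str, cand: str, surfaces: list[str]) -> float:
    token = re.compile(r"\w+", re.UNICODE)
    docs = [set(token.findall(s.lower())) for s in surfaces]
    n = len(docs)

    def idf(t):
        df = sum(t in d for d in docs)
        return math.log((n + 1) / (df + 1)) + 1.0

    def vec(s):
        toks = token.findall(s.lower()) or [s.strip() or s]
        tf = {t: toks.count(t) for t in set(toks)}
        v = {t: math.log(c + 1) * idf(t) for t, c in tf.items()}
        norm = math.sqrt(sum(x * x for x in v.values()))
        return {t: x / norm for t, x in v.items()}

    vq, vc = vec(query), vec(cand)
    if not vq or not vc:
        return 0.0
    total = 0.0
    for qt, wq in vq.items():
        best, best_ct = 0.0, None
        for ct in vc:
            s = ref_jaro_winkler(qt, ct)
            if s > best:
                best, best_ct = s, ct
        if best_ct is not None and best >= 0.9:
            total += wq * vc[best_ct] * best
    return min(total, 1.0)


# --- fixtures --------------------------------------------------------------

def _string_pairs(n_pairs: int = 60) -> list[tuple[str, str]]:
    rng = random.Random(42)
    vocab = [e.surface.lower() for e in Vocabulary.bundled().bn_entries]
    vocab = [s for s in vocab if s.isascii()]
    pairs = []
    while len(pairs) < n_pairs:
        kind = rng.random()
        if kind < 0.4:
            pairs.append((rng.choice(vocab), rng.choice(vocab)))
        elif kind < 0.7:
            # near-duplicate: one random edit
            s = rng.choice(vocab)
            i = rng.randrange(len(s))
            pairs.append((s, s[:i] + rng.choice("abcxyz019") + s[i + 1 :]))
        else:
            alpha = "abcdefghij -123"
            pairs.append(
                (
                    "".join(rng.choice(alpha) for _ in range(rng.randint(3, 12))).strip() or "abc",
                    "".join(rng.choice(alpha) for _ in range(rng.randint(3, 12))).strip() or "xyz",
                )
            )
    return pairs


PAIRS = _string_pairs()
SURFACES = [e.surface for e in Vocabulary.bundled().bn_entries]


@pytest.mark.parametrize("a,b", PAIRS)
def test_edit_similarity_matches_edlib(a, b):
    assert edit_similarity(a, b) == pytest.approx(ref_edit_similarity(a, b), abs=TOL)


@pytest.mark.parametrize("a,b", PAIRS)
def test_spectrum_kernel_matches_sklearn_cosine(a, b):
    assert spectrum_kernel(a, b) == pytest.approx(ref_spectrum_kernel(a, b), abs=TOL)


@pytest.mark.parametrize("a,b", PAIRS)
def test_jaro_winkler_matches_reference(a, b):
    assert jaro_winkler(a, b) == pytest.approx(ref_jaro_winkler(a, b), abs=TOL)


@pytest.mark.parametrize("a,b", PAIRS)
def test_soft_tfidf_matches_reference(a, b):
    stats = TokenStats.from_surfaces(SURFACES)
    assert soft_tfidf(a, b, stats) == pytest.approx(
        ref_soft_tfidf(a, b, SURFACES), abs=TOL
    )


def test_component_vector_for_wt1_pair():
    """Component values for ('wt-1', 'wt1'), frozen from the references."""
    a, b = "wt-1", "wt1"
    assert edit_similarity(a, b) == pytest.approx(0.75, abs=TOL)
    assert spectrum_kernel(a, b) == pytest.approx(0.0, abs=TOL)
    assert jaro_winkler(a, b) == pytest.approx(ref_jaro_winkler(a, b), abs=TOL)
    assert jaro_winkler(a, b) == pytest.approx(14 / 15, abs=TOL)
    assert soft_tfidf(a, b) == pytest.approx(ref_soft_tfidf(a, b, []), abs=TOL)


def test_identity_scores_one_for_random_strings():
    rng = random.Random(7)
    alphabet = "abcdefghijklmnopqrstuvwxyz0123456789 -α"
    for _ in range(1000):
        s = "".join(rng.choice(alphabet) for _ in range(rng.randint(1, 15))).strip()
        if not s:
            continue
        assert similarity_score(s, s) == pytest.approx(1.0, abs=1e-12)


def test_disjoint_strings_score_zero():
    assert similarity_score("abc", "xyz") == 0.0


@given(
    st.text(alphabet="abcdef012 -", min_size=1, max_size=15).filter(str.strip),
    st.text(alphabet="abcdef012 -", min_size=1, max_size=15).filter(str.strip),
)
@settings(max_examples=200, deadline=None, derandomize=True)
def test_score_bounded_in_unit_interval(a, b):
    s = similarity_score(a, b)
    assert 0.0 <= s <= 1.0


def test_empty_string_rejected():
    with pytest.raises(Exception):
        similarity_score("", "abc")


def test_weights_shift_the_score():
    w_edit_only = SimilarityWeights(1.0, 0.0, 0.0, 0.0)
    assert similarity_score("abcd", "abcx", w_edit_only) == pytest.approx(0.75)
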