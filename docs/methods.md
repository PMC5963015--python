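# Methods

## Data model

A tissue slide is the minimum unit a pathologic finding refers to: IHC
reports open each block of results with the slide's serial number, and a
patient may accumulate several slides, several IHC reports (including
repeat assays of the same slide) and one or more SP reports. The model
therefore keys everything on the **tissue-slide identifier (TS_ID)**. An
IHC report decomposes into **tissue-slide paragraphs (TS_P)** — the
findings for one slide — and each SP report contributes an organ and
diagnosis context. Joining on TS_ID, never on patient-level heuristics,
is what prevents a biomarker result from being attached to another
patient's (or another indication's) pathology.

All character offsets are 0-based, end-exclusive, over LF-normalized
text — the convention of BRAT standoff annotation, which is also the
interchange format for gold and predicted spans. A `Mention` must always
reproduce the document slice at its offsets; this is enforced wherever a
mention meets its document.

## IHC grammar

The two reporting styles are told apart by a columnarity score: a report
is table style when more than half (configurable) of its non-empty,
non-header lines contain at least two column separators; ties go to the
simpler list grammar. The grammars themselves are deliberately minimal —
pathology reports do not follow sentence grammar, but the formatting
determinants `;`, `:` and `|` are stable anchors:

* list style: `finding → BN ':' TR ';'`, tolerant of arbitrary
  whitespace and line breaks inside TR;
* table style: a header row names the BN/TR columns (falling back to
  first-two-columns when unlabeled), each later row yields one pair.

Clauses or rows matching neither production are logged and skipped;
they never abort the paragraph. A report with no slide header at all
cannot be anchored to a slide and is counted and skipped as
unparseable. The default TS_ID pattern is a letter-prefixed accession
(`S12-3456`, optional block suffix); both the pattern and the separator
sets are configurable because accession formats are site-specific.

## Term normalization

Biomarker names are normalized by a pipeline of laboratory-parenthetical
stripping (`WT-1 (4)` → `WT-1`; content must be numeric or in a stop
list — `(repeat)`, `(recut)`, `(control)`, `(outside)` by default, so
meaningful parentheticals like `MIB-1 (Ki-67)` survive), case-folded
exact look-up in the expanded dictionary, then similarity search.

Dictionary expansion closes the entry set under five rule families to a
fixpoint, every variant inheriting its origin's preferred term:

1. Roman → Arabic numerals, for whole canonical-numeral tokens with a
   preceding word. `I` alone is excluded (ambiguous with the letter),
   and values are capped at 40: factor/class numbering never goes
   higher, and the cap keeps single letters like `D` (500) or `C` (100)
   from corrupting names such as `Cyclin D1`.
2. Greek symbol ↔ spelled letter name, both directions (`CD79 α` ↔
   `CD79 alpha`).
3. Laboratory-parenthetical removal (same rule as at query time).
4. Delimiter variants at letter/digit boundaries and existing hyphens:
   `GAL3` = `GAL-3` = `GAL 3`. Alpha–alpha word spaces are left alone
   (`Wilms Tumor` never becomes `WilmsTumor`), and entries with more
   than five variable boundaries are not enumerated.
5. Lowercasing (`DESMIN` → `desmin`).

Expansion is idempotent and order-stable; originals are kept first and
the first surface wins on collisions.

The similarity look-up score is a weighted linear sum of four component
similarities, each in [0, 1]:

* **edit** — 1 − Levenshtein distance / longer-string length;
* **kernel** — cosine-normalized character 3-gram spectrum kernel (the
  order drops to the shorter string's length below 3 characters so
  identity still scores 1);
* **jw** — Jaro–Winkler (prefix scale 0.1, max prefix 4);
* **soft TF-IDF** — token-level TF-IDF cosine with Jaro–Winkler as the
  inner matcher at θ = 0.9; IDF is the smoothed
  `log((N+1)/(df+1)) + 1` over the dictionary's surface forms, and
  strings with no word characters act as a single opaque token.

Defaults are equal weights (0.25 each) and acceptance threshold 0.85,
both configurable: no published values exist for either, so the neutral
prior was chosen once and the correctness claims rest on properties
(bounds, identity, per-component agreement with independent reference
implementations) rather than on a tuned operating point. A consequence
worth knowing: with the 3-gram kernel in the mix, a single typo in a
short word (`Beast`/`breast` scores 0.828) falls below 0.85, so strict
defaults favor precision over typo recall; a threshold of 0.80 recovers
such cases. Candidate ranking breaks ties by higher score, then shorter
surface, then lexicographic order — except in span recognition (below),
where the longer of two equal-scoring spans wins.

Test results are deliberately **not** fuzzy-matched: assigning
`a few positive cells` to *Focal positive* is background knowledge, not
string proximity, so TR normalization is exact look-up in a curated
surface → category table and anything else is returned as `UNMATCHED`
for human triage. The codomain is exactly *Positive*, *Focal positive*,
*Negative*, *Error* (failed assay or an uninterpretable result).

## SP tree parsing

The parser exploits layout: the organ appears in the first few lines
(K = 5 searched, configurable), numbered lines are diagnoses, indented
lines below a diagnosis are its microscopic findings. Indent is measured
in columns with tab = 8. Numbered lines are never considered as the
organ root, and a configurable stop list truncates gross-description /
frozen-section blocks, which otherwise confound the single-root
assumption. Lines before the organ line are ignored with a warning; a
report with no organ match is unparseable.

Organ and disease recognition search candidate spans (comma-separated
segments and token n-grams up to 4) against their terminology with the
combined score, so `multiple gastric carcinoma` normalizes via its
`gastric carcinoma` sub-span while the **full raw diagnosis line is
always preserved** — boundaries of disease terms are genuinely
ambiguous, and keeping the line loses nothing. Surfaces matched only via
similarity are registered in a run-scoped learned-term table, mirroring
incremental terminology curation. Negation (`no evidence of`,
`negative for`, …) and metastasis (`metasta-` stem) are flagged by
case-insensitive substring patterns from user-editable files; the
bundled lists are plain defaults, not a clinically validated set.

Only extractions with exactly one matched organ and exactly one
diagnosis line proceed to merging by default; multi-organ/multi-diagnosis
disambiguation is out of scope and such reports are simply filtered
(the merge can be told to keep them).

## Merging and statistics

Each finding in a paragraph whose TS_ID has a matching extraction yields
one merged record; unmatched paragraphs are returned as orphans, so
`merged + orphaned findings = parsed findings` always holds. A TS_ID
claimed by two patients raises an error. When the same patient has
several SP reports for one TS_ID (addendum scenario), the
latest-timestamped extraction wins by default; `keep_all_extractions`
retains every version with provenance. Missing timestamps are allowed
on real-world input and order last in repeat-test tracing.

Positive rate is `(n_positive + n_focal_positive) / n_total` per
(biomarker, organ, diagnosis); *Error* results stay in the denominator
only, and `UNMATCHED` test results are excluded from the table and
reported separately. Aggregation is order-invariant.

## Synthetic corpus

The generator stands in for a private hospital archive. Defaults: 100
patients, 1–3 slides each (uniform), 2–6 biomarkers per slide (uniform;
the real distributions are unpublished, so uniform is an explicit
arbitrary choice), a 50/50 list/table style mix, a 10% chance per slide
of a later repeat test, and timestamps ordered SP → IHC → repeat. One
specimen per SP report, whose accession doubles as the TS_ID; diseases
are drawn compatibly with the sampled organ. Test-result categories are
planted at 40% positive / 15% focal positive / 40% negative / 5% error.
Vocabulary comes from the bundled sample terminologies (~35 biomarker
surfaces, 18 organs, 21 diseases, 21 test-result phrasings).

Noise dials: per-token single-character typos (confined to word
characters so separators — the grammar anchors — and the TS_ID survive;
dropped slide headers are the dedicated dial for broken joins),
biomarker-variant substitution, appended lab parentheticals, SP indent
jitter, and per-paragraph header omission. Gold offsets are computed on
the final noisy text, so gold is exact by construction at every noise
level.

What passing on this corpus does **not** show: robustness to real
reporting-style drift (site-specific headers, Korean/English mixing,
synoptic CAP checklists, gross descriptions interleaved with
microscopic ones), to terminology coverage gaps at hospital scale, or
to boundary disagreements between human annotators. The corpus
exercises the mechanics — segmentation, offsets, normalization closure,
the join — under controlled corruption, nothing more.

## Evaluation

Predictions are scored per label under exact (identical boundaries) or
overlap (any intersection) span matching; each gold span satisfies at
most one prediction, greedily by position. Overlap can only relax
exact, so overlap-F1 ≥ exact-F1 holds on every dataset — the suite
checks this across twenty noisy corpora.

## Problem sizes and numerical choices

The acceptance script uses a 100-patient noise-free corpus (~340
documents, ~900 findings) for the end-to-end identity and twenty
4-patient noisy corpora for the stochastic properties; these sizes make
every property decidable exactly while keeping a full run in seconds.
Similarity components are compared to independent references at 1e-9;
the combined score is clamped to [0, 1] against floating-point drift;
all generator randomness flows from a single integer seed, and the same
seed yields a byte-identical corpus.

## Known limitations

* Multi-organ / multi-diagnosis SP reports are filtered, not resolved;
  final-vs-intermediate diagnosis discrimination is not attempted.
* TR normalization covers only surfaces present in the curated table;
  numeric results with cell-type-dependent ranges need explicit rows.
* The strict default similarity threshold trades typo recall for
  precision (see above).
* Orphaned paragraphs are not retried against later-arriving SP
  reports; merging is a single batch pass.
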