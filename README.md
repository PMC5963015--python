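# pathmarker

Automated extraction of biomarker profiles from free-text pathology
reports.

Hospitals accumulate two report streams that together describe a tumor's
immunophenotype: **immunohistochemistry (IHC)** reports, which list
biomarker assays and their results per tissue slide, and **surgical
pathology (SP)** reports, which give the organ of origin, the diagnosis,
and the microscopic findings. Both are free text, written in a
keyword-oriented style full of line breaks, abbreviations and typos, so
the biomarker statistics buried in them (e.g. "how often is ErbB-2
positive in gastric adenocarcinoma here?") are inaccessible without
information extraction. `pathmarker` is a small toolkit for pathology
informatics groups who want those statistics from their own archive.

## What it does

* **IHC parsing.** Reports are classified as *list style*
  (`p53 : positive ;`) or *table style* (`| p53 | positive |`) and parsed
  with a minimal grammar anchored on the three formatting determinants
  `;`, `:` and `|`. Each **tissue-slide paragraph** (TS_P) — the set of
  findings for one slide — is keyed by the slide serial number (**TS_ID**)
  printed at its top, giving (biomarker name BN, test result TR) mention
  pairs with exact character offsets.
* **Term normalization.** A biomarker dictionary (surface → preferred
  term, e.g. MeSH heading) is expanded by five variant-rule families
  (Roman↔Arabic numerals, Greek symbol↔letter name, laboratory
  parentheticals, hyphen/space/joined forms, lowercase), so that
  `WT-1`, `WT1 (4)` and `Wilms tumor 1-protein` all resolve to
  `Genes, Wilms Tumor`. Misses fall back to a text-similarity look-up
  score: a weighted linear sum of normalized edit distance, character
  3-gram spectrum kernel, Jaro–Winkler, and soft TF-IDF. Test results are
  normalized by exact dictionary look-up only, into the four-category
  codomain *Positive / Focal positive / Negative / Error*.
* **SP parsing.** Each report becomes an organ-rooted tree: the organ
  line is the root, numbered lines (`1.`, `2.`) are diagnosis nodes, and
  deeper-indented lines nest beneath them as microscopic findings.
  Organ and disease names are recognized by dictionary look-up with the
  same similarity score; negation and metastasis wording is flagged by an
  editable pattern list; reports mentioning more than one organ or
  diagnosis are filtered out before merging.
* **Merging and statistics.** IHC paragraphs join their SP context on
  TS_ID — never across patients — producing merged records from which
  per-(biomarker, organ, diagnosis) positive rates are aggregated, with
  repeat tests of the same slide traceable chronologically.
* **Synthetic corpus + evaluation.** Because real archives are private,
  a generator emits paired IHC/SP corpora with gold BRAT standoff
  annotations and a blueprint join table, with configurable noise
  (typos, name variants, lab parentheticals, indent jitter, dropped
  slide headers). An evaluator scores predictions by exact or overlap
  span matching (precision/recall/F1 per label).

## Worked example

Generate a small noise-free corpus, run the pipeline, and score it:

```sh
pathmarker gen-corpus --out-dir corpus --patients 5 --seed 42
pathmarker extract --in corpus/reports.jsonl --out merged.jsonl --ann-dir pred
pathmarker stats --in merged.jsonl --out stats.tsv
pathmarker eval --pred pred --gold corpus/ann --mode exact
```

which prints

```
wrote 18 reports, gold annotations and blueprint to corpus
merged 38 records; 0 orphan paragraphs; 0 unparseable reports
34 stat rows; 0 records with unmatched TR
label	precision	recall	f1
BN	1.0000	1.0000	1.0000
Diagnosis	1.0000	1.0000	1.0000
Organ	1.0000	1.0000	1.0000
TR	1.0000	1.0000	1.0000
TS_ID	1.0000	1.0000	1.0000
micro	1.0000	1.0000	1.0000
```

Every entity label — slide id, biomarker name, test result, organ,
diagnosis — is recovered with exact boundaries on noise-free input. One
merged record joins a slide's assay to its pathology context:

```json
{"patient_id": "PT0000", "ts_id": "S12-1000", "timestamp": "2012-01-05T00:00:00",
 "bn_norm": "Thymidylate Synthase", "tr_norm": "Focal positive",
 "organ_norm": "Colon", "disease_norm": "Adenocarcinoma",
 "disease_line": "Adenocarcinoma, 1.2 cm", "negated": false, "metastasis": false,
 "ihc_report_id": "IHC00001", "sp_report_id": "S12-1000"}
```

and `stats.tsv` holds the aggregated positive rates
(`positive_rate = (n_pos + n_focal) / n_total`, errors count in the
denominator only):

```
p_bn	organ	disease	n_total	n_pos	n_focal	n_neg	n_err	positive_rate
Actins, Smooth Muscle	Kidney	Carcinoma, Renal Cell	1	1	0	0	0	1.0000
Actins, Smooth Muscle	Prostate	Adenocarcinoma	2	0	0	2	0	0.0000
```

To process real reports, supply your institution's terminologies as
two-column TSVs (`--bn-dict`, `--tr-dict`, `--organs`, `--diseases`);
the bundled sample dictionaries exist to make the toolkit runnable out
of the box, not to cover a hospital's vocabulary.

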