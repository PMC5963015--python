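"""SP tree parsing, organ/disease recognition, negation and filtering."""

import pytest

from pathmarker.model import UNMATCHED, UnparseableReport
from pathmarker.similarity import SimilarityWeights
from pathmarker.sp import (
    NodeKind,
    SPConfig,
    build_parse_tree,
    detect_negation_metastasis,
    extract_sp,
    is_single_organ_single_diagnosis,
    recognize_diagnosis,
    recognize_organ,
)
from tests.conftest import make_report

BREAST_TEXT = (
    "Breast, left, mastectomy:\n"
    "  1. INFILTRATING DUCT CARCINOMA, multiple, residual (see note)\n"
    "       tumor size 2.1 cm\n"
    "       resection margin, clear\n"
    "  2. Fibrocystic change with microcalcification\n"
)


def sp_report(text, **kw):
    return make_report(text, report_type="SP", **kw)


def test_tree_root_is_organ_with_numbered_children(normalizers):
    tree = build_parse_tree(sp_report(BREAST_TEXT), normalizers.organ)
    assert tree.kind is NodeKind.ROOT_ORGAN
    assert tree.mention.surface.startswith("Breast")
    assert [c.kind for c in tree.children] == [NodeKind.DISEASE, NodeKind.DISEASE]
    first = tree.children[0]
    assert first.mention.surface.lstrip().startswith("1. INFILTRATING")
    assert [n.mention.surface.strip() for n in first.children] == [
        "tumor size 2.1 cm",
        "resection margin, clear",
    ]


def test_tree_traversal_preserves_line_order(normalizers):
    tree = build_parse_tree(sp_report(BREAST_TEXT), normalizers.organ)
    indices = [n.line_index for n in tree.walk()]
    assert indices == sorted(indices)
    non_empty_lines = [l for l in BREAST_TEXT.split("\n") if l.strip()]
    assert [n.mention.surface for n in tree.walk()] == non_empty_lines


def test_finding_indent_exceeds_disease_indent(normalizers):
    tree = build_parse_tree(sp_report(BREAST_TEXT), normalizers.organ)
    for disease in tree.children:
        for node in disease.walk():
            if node.kind is NodeKind.FINDING:
                assert node.indent > disease.indent


def test_single_line_report_gives_bare_root(normalizers):
    tree = build_parse_tree(sp_report("Lung\n"), normalizers.organ)
    assert tree.kind is NodeKind.ROOT_ORGAN
    assert tree.children == []


def test_no_organ_in_leading_lines_is_unparseable(normalizers):
    with pytest.raises(UnparseableReport):
        build_parse_tree(
            sp_report("Consultation note\nSee attached.\n"), normalizers.organ
        )


def test_stop_section_truncates_parsing(normalizers):
    text = "Stomach, resection:\n  1. Gastric carcinoma\nGross description:\n  2. spurious\n"
    tree = build_parse_tree(sp_report(text), normalizers.organ)
    assert len(tree.children) == 1


def test_recognize_organ_exact_and_typo(vocab):
    matched, score = recognize_organ("Breast", list(vocab.organ_entries))
    assert (matched, score) == ("Breast", 1.0)
    # the 3-gram kernel penalizes single typos in short words hard, so at
    # the strict default threshold the typo stays unmatched; a laxer
    # threshold recovers it through the similarity search
    matched, score = recognize_organ("Beast", list(vocab.organ_entries))
    assert matched == UNMATCHED and 0.75 < score < 0.85
    lax = SimilarityWeights(threshold=0.80)
    matched, score = recognize_organ("Beast", list(vocab.organ_entries), lax)
    assert matched == "Breast" and score >= 0.80
    matched, _ = recognize_organ("Consultation note", list(vocab.organ_entries))
    assert matched == UNMATCHED


def test_recognize_organ_registers_learned_surface():
    from pathmarker.sp import TermRecognizer
    from pathmarker.synthesis import Vocabulary

    rec = TermRecognizer(
        list(Vocabulary.bundled().organ_entries), SimilarityWeights(threshold=0.80)
    )
    rec.recognize("Beast, left")
    assert rec.learned.get("Beast") == "Breast"


def test_recognize_diagnosis_preserves_full_line(normalizers):
    tree = build_parse_tree(sp_report(BREAST_TEXT), normalizers.organ)
    norm, line = recognize_diagnosis(tree.children[0], normalizers.disease)
    assert norm == "Carcinoma, Ductal, Breast"
    assert line.surface == "INFILTRATING DUCT CARCINOMA, multiple, residual (see note)"
    assert BREAST_TEXT[line.start : line.end] == line.surface


def test_recognize_diagnosis_partial_dictionary_entry(vocab, normalizers):
    text = "Stomach:\n  1. multiple gastric carcinoma\n"
    tree = build_parse_tree(sp_report(text), normalizers.organ)
    norm, line = recognize_diagnosis(tree.children[0], normalizers.disease)
    assert norm == "Carcinoma, Gastric"
    assert line.surface == "multiple gastric carcinoma"


def test_recognize_diagnosis_exotic_line_unmatched(normalizers):
    text = "Lung:\n  1. zzqx unclassifiable lesion-of-interest\n"
    tree = build_parse_tree(sp_report(text), normalizers.organ)
    norm, line = recognize_diagnosis(tree.children[0], normalizers.disease)
    assert norm == UNMATCHED
    assert line.surface == "zzqx unclassifiable lesion-of-interest"


@pytest.mark.parametrize(
    "text,negated,metastasis",
    [
        ("No evidence of malignancy", True, False),
        ("Metastatic carcinoma from stomach", False, True),
        ("INFILTRATING DUCT CARCINOMA", False, False),
        ("negative for tumor cells", True, False),
        ("metastasis to lymph node", False, True),
    ],
)
def test_detect_negation_metastasis(text, negated, metastasis):
    assert detect_negation_metastasis(text) == (negated, metastasis)


def test_single_organ_single_diagnosis_filter(normalizers):
    multi = extract_sp(
        sp_report(BREAST_TEXT), normalizers.organ, normalizers.disease
    )
    assert not is_single_organ_single_diagnosis(multi)

    single = extract_sp(
        sp_report("Lung, biopsy:\n  1. Squamous cell carcinoma\n"),
        normalizers.organ,
        normalizers.disease,
    )
    assert is_single_organ_single_diagnosis(single)
    assert single.organ_norm == "Lung"
    assert single.diagnoses[0].disease_norm == "Carcinoma, Squamous Cell"


def test_extract_sp_flags_metastatic_diagnosis(normalizers):
    ext = extract_sp(
        sp_report("Liver, biopsy:\n  1. Metastatic adenocarcinoma\n"),
        normalizers.organ,
        normalizers.disease,
    )
    assert ext.diagnoses[0].metastasis
    assert not ext.diagnoses[0].negated
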