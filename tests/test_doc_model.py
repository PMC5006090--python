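"""Document model: readers, figure/citation detection, caption splitting."""

import io

import pytest

from scidisc import doc_model as dm


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def test_plain_empty_text_gives_no_sections():
    doc = dm.read_document("", "plain")
    assert doc.sections == [] and doc.figure_refs == [] and doc.citations == []


def test_plain_text_becomes_one_results_section():
    doc = dm.read_document("Binding increased.", "plain")
    assert [s.kind for s in doc.sections] == ["results"]
    assert (doc.sections[0].start, doc.sections[0].end) == (0, len(doc.text))


def test_jsonl_round_trip_is_identity():
    doc = dm.Document(
        "d1",
        "Binding rose (Fig. 2B) as shown [3].\n\nMore text.",
        sections=[dm.Section("results", 0, 36), dm.Section("caption", 38, 48, heading="2")],
        figure_refs=[dm.FigureRef(2, "B", 14, 21)],
        citations=[dm.Citation(32, 35, "numeric-bracket")],
    )
    buf = io.StringIO()
    dm.write_document(doc, buf)
    assert dm.read_document(buf.getvalue(), "jsonl") == doc
    # bit-exact: rewriting the parsed document reproduces the line
    buf2 = io.StringIO()
    dm.write_document(dm.read_document(buf.getvalue(), "jsonl"), buf2)
    assert buf2.getvalue() == buf.getvalue()


BIOC = (
    '<collection><document id="d1"><passage kind="results"><text>'
    'Binding increased <xref type="fig" figure="2" subfigure="B">(Fig. 2B)</xref>'
    ' as shown <xref type="bibr">[3]</xref>.</text></passage></document></collection>'
)


def test_bioc_xref_offsets_hand_counted():
    doc = dm.read_document(BIOC, "bioc-xml-subset")
    assert len(doc.figure_refs) == 1
    ref = doc.figure_refs[0]
    # "Binding increased " is 18 characters; the xref content is "(Fig. 2B)"
    assert (ref.start, ref.end) == (18, 27)
    assert doc.text[ref.start:ref.end] == "(Fig. 2B)"
    assert (ref.figure, ref.subfigure) == (2, "B")
    cite = doc.citations[0]
    assert doc.text[cite.start:cite.end] == "[3]" and cite.style == "markup"


def test_bioc_malformed_xml_raises_parse_error():
    with pytest.raises(dm.ParseError, match="XML"):
        dm.read_document("<collection><document>", "bioc-xml-subset")


def test_unknown_format_is_a_usage_error():
    with pytest.raises(dm.ParseError, match="unknown format"):
        dm.read_document("x", "tsv")


# ---------------------------------------------------------------------------
# figure references
# ---------------------------------------------------------------------------

def test_conjoined_subfigure_list_expands_per_subfigure():
    text = ("They describe results of five separate experiments labeled by "
            "subfigure in Fig. 2 and Fig. 3 (2B, 2C, 2E, 3A, 3B).")
    keys = [r.key for r in dm.detect_figure_refs(text)]
    assert [(2, "B"), (2, "C"), (2, "E"), (3, "A"), (3, "B")] == keys[-5:]


@pytest.mark.parametrize(
    "text,expected",
    [
        ("no figures here", []),
        ("Figure 3", [(3, None)]),
        ("see Fig. 2b for details", [(2, "B")]),  # letters normalize to uppercase
        ("Figs. 1A and 1B overlap", [(1, "A"), (1, "B")]),
        ("Fig. 2B and C", [(2, "B"), (2, "C")]),  # bare letter inherits the figure
        ("see (2B) alone", []),  # bare token without an anchor in the sentence
    ],
)
def test_figure_mention_grammar(text, expected):
    assert [r.key for r in dm.detect_figure_refs(text)] == expected


def test_figure_ref_spans_lie_on_their_tokens():
    text = "As shown in Fig. 12C, binding rose."
    (ref,) = dm.detect_figure_refs(text)
    assert text[ref.start:ref.end] == "12C"


# ---------------------------------------------------------------------------
# citations
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "text,styles",
    [
        ("as shown previously [3,7]", ["numeric-bracket"]),
        ("", []),
        ("(2B)", []),  # figure-like parenthetical is never a citation
        ("(Smith et al., 2004)", ["author-year"]),
        ("earlier work (12) supports this", ["numeric-bracket"]),
    ],
)
def test_citation_patterns(text, styles):
    assert [c.style for c in dm.detect_citations(text)] == styles


@pytest.mark.parametrize(
    "text",
    [
        "Binding rose (Fig. 2B) as reported [12] and (Smith et al., 2004).",
        "Fig. 1 and refs (3) and [4,5] appear together (1A, 1B).",
        "(2B) [7] Figure 2 (2C)",
    ],
)
def test_figure_and_citation_spans_are_disjoint(text):
    figs = [(r.start, r.end) for r in dm.detect_figure_refs(text)]
    cites = [(c.start, c.end) for c in dm.detect_citations(text)]
    for fs, fe in figs:
        for cs, ce in cites:
            assert fe <= cs or ce <= fs


# ---------------------------------------------------------------------------
# caption subfigure extraction
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "caption,expected",
    [
        ("(A) Lysates were blotted. (B) Quantification.",
         [("A", "Lysates were blotted."), ("B", "Quantification.")]),
        ("Overview of the pathway.", []),
        ("(A) x (A) y", [("A", "x"), ("A", "y")]),  # duplicates preserved
        ("(a) lowercase marker.", [("A", "lowercase marker.")]),
    ],
)
def test_caption_subfigure_markers(caption, expected):
    assert dm.extract_caption_subfigures(caption) == expected


@pytest.mark.parametrize(
    "caption",
    ["(A) one. (B) two. trailing", "(A) only", "", "text (B) tail (C) end."],
)
def test_caption_pieces_are_an_ordered_subsequence_of_input(caption):
    pieces = [t for _, t in dm.extract_caption_subfigures(caption)]
    pos = 0
    for piece in pieces:
        found = caption.find(piece, pos)
        assert found >= 0
        pos = found + len(piece)
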