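"""Document model: JATS parsing, subsection typing, sentence segmentation."""

import warnings

import pytest
from lxml import etree

from efip import (Document, classify_subsection, parse_abstract, parse_jats,
                  segment_sentences)

JATS_TEMPLATE = """<?xml version="1.0"?>
<article>
 <front>
  <article-meta>
   <article-id pub-id-type="pmcid">PMC1</article-id>
   <title-group><article-title>Phosphorylation of PLN</article-title></title-group>
  </article-meta>
  <abstract><p>PLN is a small protein.</p></abstract>
 </front>
 <body>
  <sec sec-type="intro"><title>Introduction</title><p>Intro text here.</p></sec>
  <sec>
   <title>Results</title>
   <sec><title>PP1 association with PLN and effect of PKA</title>
    <p>Result text one. Result text two.</p>
    <fig><label>Figure 1</label><caption><p>A caption sentence.</p></caption></fig>
   </sec>
  </sec>
  <sec sec-type="materials|methods"><title>Materials and Methods</title>
   <sec><title>GST pull down assay</title><p>Assay text.</p></sec>
  </sec>
 </body>
</article>
"""


class TestParseJats:
    def test_heading_without_text_yields_no_subsection(self):
        """A heading with no prose before the next heading (here: Results)
        produces no subsection; its child carries it as inherited heading."""
        doc = parse_jats(JATS_TEMPLATE)
        headings = [s.heading for s in doc.subsections]
        assert "Results" not in headings
        child = next(s for s in doc.subsections
                     if s.heading == "PP1 association with PLN and effect of PKA")
        assert "Results" in child.inherited_headings
        assert child.inherited_headings[0] == "Phosphorylation of PLN"

    def test_subsection_inventory_and_types(self):
        doc = parse_jats(JATS_TEMPLATE)
        by_heading = {s.heading: s for s in doc.subsections}
        # abstract + intro + results-child + caption + methods-child
        assert len(doc.subsections) == 5
        assert by_heading["Abstract"].section_type == "abstract"
        assert by_heading["Introduction"].section_type == "introduction"
        assert by_heading["Figure 1"].section_type == "figure"
        assert by_heading["GST pull down assay"].section_type == "methods"

    def test_empty_body_yields_zero_subsections(self):
        xml = ("<article><front><article-meta><title-group>"
               "<article-title>T</article-title></title-group>"
               "</article-meta></front><body></body></article>")
        doc = parse_jats(xml)
        assert doc.subsections == []

    def test_missing_body_warns(self):
        xml = ("<article><front><article-meta><title-group>"
               "<article-title>T</article-title></title-group>"
               "</article-meta></front></article>")
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            doc = parse_jats(xml)
        assert doc.subsections == []
        assert any("body" in str(w.message) for w in caught)

    def test_malformed_xml_names_line(self):
        with pytest.raises(etree.XMLSyntaxError) as err:
            parse_jats("<article>\n<body>\n<sec>\n</article>")
        assert err.value.lineno is not None

    def test_round_trip_json(self):
        doc = parse_jats(JATS_TEMPLATE)
        again = Document.from_json(doc.to_json())
        assert again == doc

    def test_generated_fixture_subsection_count(self):
        """Subsection count equals filled leaf headings + captions (+abstract),
        checked against the generator's own ground truth."""
        from efip import FixtureSpec, generate
        fx = generate(FixtureSpec(seed=11, n_docs=2, n_relations=6))
        for fname, xml in fx.documents.items():
            doc = parse_jats(xml)
            assert len(doc.subsections) == fx.expected_subsections[doc.doc_id]

    def test_offsets_slice_back_to_text(self):
        doc = parse_jats(JATS_TEMPLATE)
        for sub in doc.subsections:
            for sent in sub.sentences:
                assert sub.text[sent.start:sent.end] == sent.text


class TestClassifySubsection:
    @pytest.mark.parametrize("heading,parents,expected", [
        ("Discussion", [], "discussion"),
        ("GST pull down assay", ["Materials and Methods"], "methods"),
        ("Acknowledgements", [], "other"),
        ("Conclusion", [], "conclusions"),
        ("Conclusions", [], "conclusions"),
        ("METHODS", [], "methods"),
        ("Subheading", ["Results"], "results"),
        ("", [], "other"),
    ])
    def test_labels(self, heading, parents, expected):
        assert classify_subsection(heading, parents) == expected

    def test_declared_type_wins(self):
        assert classify_subsection("Weird title", [], "materials|methods") \
            == "methods"

    def test_total_and_pure(self):
        for args in [("Discussion", []), ("??", ["??"]), ("x", None)]:
            assert classify_subsection(*args) == classify_subsection(*args)


class TestSegmentSentences:
    def test_single_sentence(self):
        text = ("These data suggest that Bax Thr167 is phosphorylated in "
                "response to cytokine treatment, and that Thr167 "
                "phosphorylation facilitates Bax binding to Pin1.")
        assert len(segment_sentences(text)) == 1

    def test_empty(self):
        assert segment_sentences("") == []
        assert segment_sentences("   ") == []

    @pytest.mark.parametrize("text,n", [
        ("One sentence. Two sentence. Three sentence.", 3),
        ("Sites Ser-309 Ser-361 are modified. Next one.", 2),
        ("See Fig. 2 for details. Next sentence.", 2),
        ("This occurs, e.g. in cells. Next.", 2),
        ("Values were 3.5 and 2.1 in assays. Next.", 2),
    ])
    def test_protected_tokens(self, text, n):
        assert len(segment_sentences(text)) == n

    def test_joined_template_count(self):
        parts = [f"Sentence number {i} is here" for i in range(7)]
        text = ". ".join(parts) + "."
        assert len(segment_sentences(text)) == 7

    def test_offsets_are_half_open_and_ordered(self):
        text = "First sentence. Second sentence. Third."
        sents = segment_sentences(text)
        for a, b in zip(sents, sents[1:]):
            assert a.end <= b.start
        for s in sents:
            assert s.end > s.start
            assert text[s.start:s.end] == s.text


class TestParseAbstract:
    def test_first_line_is_title(self):
        doc = parse_abstract("A title line\nBody sentence one. Body two.",
                             doc_id="PMID1")
        assert doc.title == "A title line"
        assert len(doc.subsections) == 1
        assert doc.subsections[0].section_type == "abstract"
        assert len(doc.subsections[0].sentences) == 2
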