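"""Document model: JATS full-text and plain abstracts as typed subsections.

Full-length articles are processed subsection by subsection: a *subsection*
is any heading together with the text occurring right after it and before
the next heading.  Headings of ancestor sections (and the article title)
are inherited by each subsection, and each subsection carries one of nine
section-type labels (abstract, introduction, background, methods, results,
discussion, conclusions, figure, other).  A heading with no text of its own
before the next heading produces no subsection.
"""

from __future__ import annotations

import json
import re
import warnings
from dataclasses import dataclass, field, asdict

from lxml import etree

SECTION_TYPES = (
    "abstract", "introduction", "background", "methods", "results",
    "discussion", "conclusions", "figure", "other",
)

# Canonical heading names per label, in priority order of the labels.
_CANONICAL = [
    ("abstract", {"abstract", "summary"}),
    ("introduction", {"introduction", "intro"}),
    ("background", {"background"}),
    ("methods", {
        "methods", "method", "materials and methods", "methods and materials",
        "material and methods", "materials & methods", "experimental procedures",
        "materials", "methods & materials",
    }),
    ("results", {"results", "result", "results and discussion"}),
    ("discussion", {"discussion"}),
    ("conclusions", {"conclusion", "conclusions", "concluding remarks",
                     "conclusion and future work", "conclusions and future work"}),
    ("figure", {"figure", "fig", "figures"}),
]

_PUNCT = re.compile(r"[^\w&\s]")


@dataclass
class Sentence:
    index: int
    text: str
    start: int
    end: int


@dataclass
class Subsection:
    sub_id: str
    heading: str
    inherited_headings: list[str]
    section_type: str
    text: str
    sentences: list[Sentence] = field(default_factory=list)


@dataclass
class Document:
    doc_id: str
    title: str
    subsections: list[Subsection] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(asdict(self), ensure_ascii=False, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "Document":
        raw = json.loads(text)
        subs = [
            Subsection(
                sub_id=s["sub_id"], heading=s["heading"],
                inherited_headings=list(s["inherited_headings"]),
                section_type=s["section_type"], text=s["text"],
                sentences=[Sentence(**t) for t in s["sentences"]],
            )
            for s in raw["subsections"]
        ]
        return cls(doc_id=raw["doc_id"], title=raw["title"], subsections=subs)


def _canon_heading(heading: str) -> str:
    return _PUNCT.sub("", heading).strip().lower()


def classify_subsection(
    heading: str,
    parent_headings: list[str] | None = None,
    declared_type: str | None = None,
) -> str:
    """Assign one of the nine section-type labels.

    A type declared in the source XML (e.g. a JATS ``sec-type`` such as
    ``materials|methods``) wins when it maps onto the label set; otherwise
    the heading, then each parent heading from nearest to furthest, is
    matched case-insensitively against canonical section names.  Anything
    unrecognized is ``other``.
    """
    if declared_type:
        for part in re.split(r"[|,;/]", declared_type.lower()):
            part = part.strip().replace("-", " ")
            if part in SECTION_TYPES:
                return part
            for label, names in _CANONICAL:
                if part in names:
                    return label
    for h in [heading] + list(parent_headings or []):
        canon = _canon_heading(h or "")
        if not canon:
            continue
        for label, names in _CANONICAL:
            if canon in names:
                return label
    return "other"


# --- sentence segmentation -------------------------------------------------

# Tokens that end with "." without ending a sentence, checked against the
# text immediately before a candidate boundary.
_PROTECTED = (
    "e.g", "i.e", "cf", "vs", "ca", "et al", "Fig", "Figs", "fig", "figs",
    "Ref", "refs", "No", "no", "approx", "Dr", "St", "Mr", "Ms", "Prof",
    "Suppl", "suppl", "Eq", "eq", "resp",
)
_BOUNDARY = re.compile(r"[.!?]+(?=\s+\(?[A-Z0-9“\"])")
_DECIMAL = re.compile(r"\d$")


def _protected_at(text: str, dot: int) -> bool:
    before = text[:dot]
    for tok in _PROTECTED:
        if before.endswith(tok) and (len(before) == len(tok)
                                     or not before[-len(tok) - 1].isalnum()):
            return True
    # single capital initial, as in "K. Vijay" — and decimals like "3.1"
    if re.search(r"(?:^|[\s(])[A-Z]$", before):
        return True
    if text[dot:dot + 1] == "." and _DECIMAL.search(before) \
            and re.match(r"\.\d", text[dot:]):
        return True
    return False


def segment_sentences(text: str) -> list[Sentence]:
    """Deterministic rule-based sentence segmentation with offsets.

    Splits on ``. ! ?`` followed by whitespace and a capital or digit,
    with a protected-token list so abbreviations ("e.g.", "Fig.",
    "et al.") and initials do not trigger splits.  Residue tokens such as
    "Ser-309 Ser-361" contain no terminator and never split.
    """
    sentences: list[Sentence] = []
    if not text or not text.strip():
        return sentences
    cuts: list[int] = []
    for m in _BOUNDARY.finditer(text):
        if not _protected_at(text, m.start()):
            cuts.append(m.end())
    prev = 0
    for cut in cuts + [len(text)]:
        chunk = text[prev:cut]
        lead = len(chunk) - len(chunk.lstrip())
        trail = len(chunk) - len(chunk.rstrip())
        if chunk.strip():
            sentences.append(Sentence(
                index=len(sentences),
                text=text[prev + lead:cut - trail],
                start=prev + lead,
                end=cut - trail,
            ))
        prev = cut
    return sentences


# --- JATS parsing ----------------------------------------------------------

_SKIP_TAGS = {"table-wrap", "table", "ref-list", "ref", "xref", "fig",
              "table-wrap-group", "disp-formula", "supplementary-material"}


def _elem_text(elem) -> str:
    """Decoded text of an element, skipping tables/figures/references."""
    parts: list[str] = []

    def walk(e):
        tag = etree.QName(e).localname if isinstance(e.tag, str) else ""
        if tag in _SKIP_TAGS:
            if e.tail:
                parts.append(e.tail)
            return
        if e.text:
            parts.append(e.text)
        for child in e:
            walk(child)
        if e.tail:
            parts.append(e.tail)

    if elem.text:
        parts.append(elem.text)
    for child in elem:
        walk(child)
    from ._text import squeeze
    return squeeze("".join(parts))


def _first(root, path: str):
    hits = root.xpath(path)
    return hits[0] if hits else None


def _make_subsection(sub_id, heading, parents, sec_type, text) -> Subsection:
    sub = Subsection(
        sub_id=sub_id, heading=heading,
        inherited_headings=list(parents),
        section_type=sec_type, text=text,
    )
    sub.sentences = segment_sentences(text)
    return sub


def parse_jats(xml_text: str | bytes) -> Document:
    """Parse a JATS article into a :class:`Document` of typed subsections.

    One subsection is emitted per heading that has prose before the next
    heading; figure captions become subsections of type ``figure``; tables
    and reference lists are skipped.  Malformed XML raises an
    ``lxml.etree.XMLSyntaxError`` naming the offending line.
    """
    if isinstance(xml_text, str):
        xml_text = xml_text.encode("utf-8")
    parser = etree.XMLParser(resolve_entities=True, recover=False)
    root = etree.fromstring(xml_text, parser=parser)

    title_el = _first(root, ".//article-title")
    title = _elem_text(title_el) if title_el is not None else ""
    doc_id = ""
    for pref in ("pmcid", "pmc", "pmid", "doi"):
        el = _first(root, f".//article-id[@pub-id-type='{pref}']")
        if el is not None and el.text:
            doc_id = el.text.strip()
            break
    if not doc_id:
        doc_id = title or "DOC"

    doc = Document(doc_id=doc_id, title=title)
    counter = [0]

    def next_id() -> str:
        counter[0] += 1
        return f"{doc_id}.S{counter[0]}"

    inherited_base = [title] if title else []

    abstract = _first(root, ".//front//abstract")
    if abstract is not None:
        text = _elem_text(abstract)
        if text:
            doc.subsections.append(_make_subsection(
                next_id(), "Abstract", inherited_base, "abstract", text))

    body = _first(root, ".//body")
    if body is None:
        warnings.warn(f"document {doc_id!r} has no <body> element", stacklevel=2)
        return doc

    def emit_figs(scope, parents):
        for fig in scope.iterchildren():
            tag = etree.QName(fig).localname if isinstance(fig.tag, str) else ""
            if tag != "fig":
                continue
            cap = _first(fig, "./caption")
            if cap is None:
                continue
            text = _elem_text(cap)
            if not text:
                continue
            label_el = _first(fig, "./label")
            heading = _elem_text(label_el) if label_el is not None else "Figure"
            doc.subsections.append(_make_subsection(
                next_id(), heading, parents, "figure", text))

    def walk_sec(sec, parents):
        title_el = _first(sec, "./title")
        heading = _elem_text(title_el) if title_el is not None else ""
        declared = sec.get("sec-type")
        paras = [
            _elem_text(p)
            for p in sec.iterchildren()
            if isinstance(p.tag, str) and etree.QName(p).localname == "p"
        ]
        text = " ".join(t for t in paras if t)
        if text:
            sec_type = classify_subsection(heading, list(reversed(parents)),
                                           declared)
            doc.subsections.append(_make_subsection(
                next_id(), heading, parents, sec_type, text))
        emit_figs(sec, parents)
        child_parents = parents + ([heading] if heading else [])
        for child in sec.iterchildren():
            if isinstance(child.tag, str) and \
                    etree.QName(child).localname == "sec":
                walk_sec(child, child_parents)

    # paragraphs directly under <body> (untitled preamble)
    paras = [
        _elem_text(p)
        for p in body.iterchildren()
        if isinstance(p.tag, str) and etree.QName(p).localname == "p"
    ]
    text = " ".join(t for t in paras if t)
    if text:
        doc.subsections.append(_make_subsection(
            next_id(), "", inherited_base, "other", text))
    emit_figs(body, inherited_base)
    for sec in body.iterchildren():
        if isinstance(sec.tag, str) and etree.QName(sec).localname == "sec":
            walk_sec(sec, inherited_base)
    return doc


def parse_abstract(text: str, doc_id: str = "") -> Document:
    """Parse a plain-text abstract file: first line is the title."""
    lines = text.splitlines()
    title = lines[0].strip() if lines else ""
    body = " ".join(l.strip() for l in lines[1:] if l.strip())
    doc = Document(doc_id=doc_id or title or "DOC", title=title)
    if body:
        doc.subsections.append(_make_subsection(
            f"{doc.doc_id}.S1", "Abstract", [title] if title else [],
            "abstract", body))
    return doc
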