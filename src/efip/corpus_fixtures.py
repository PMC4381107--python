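"""Deterministic synthetic corpus generator.

Builds small JATS articles with planted template sentences and the exact
gold tuples they encode, so every pipeline stage and the evaluator can be
exercised without any external corpus.  Templates are data (YAML), cover
the pattern families the extractors implement, and each positive
instantiation plants exactly one gold tuple; distractors include
no-relation sentences, opposite-directionality sentences (PPI event first,
phosphorylation second — the classic false-positive class a directionality
check must reject) and hedged sentences (extracted but tagged).

The same FixtureSpec always yields byte-identical output: one seeded
generator drives every sampling choice.

What the fixtures do NOT emulate: the linguistic variety, anaphora and
nested constructions of real full-text prose.  Perfect scores on fixtures
demonstrate wiring, not corpus-level accuracy.
"""

from __future__ import annotations

import random
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import yaml
from lxml import etree

from .document_model import parse_jats
from .evaluation import GoldAnnotation, GoldTuple, gold_to_json
from .protein_mentions import Lexicon

_FAMILY_FORMS = {
    "binding": {"noun": "binding", "prep": "to", "verb": "bound to"},
    "interaction": {"noun": "interaction", "prep": "with",
                    "verb": "interacted with"},
    "association": {"noun": "association", "prep": "with",
                    "verb": "associated with"},
    "dissociation": {"noun": "dissociation", "prep": "from",
                     "verb": "was dissociated from"},
}

_CUES = ["facilitates", "promotes", "enhances", "increases", "results in",
         "leads to", "prevents", "reduces"]
_RESIDUES = ["Ser", "Thr", "Tyr"]
_SITE_STYLES = ["{res}{pos}", "{res}-{pos}"]

_FILLER = "No signaling events are described here."
_ABSTRACT = "This study examines signaling in cells."


@dataclass
class Template:
    id: str
    text: str
    kind: str  # positive | distractor | hedged
    relation: str | None = None
    families: list[str] = field(default_factory=list)
    siteless: bool = False

    def slots(self) -> set[str]:
        return set(re.findall(r"\{(\w+)\}", self.text))


_KNOWN_SLOTS = {"S", "S2", "K", "I", "site", "cue", "ppi_noun", "ppi_prep",
                "ppi_verb"}


def load_templates(path: str | Path | None = None) -> list[Template]:
    """Load templates from YAML; unknown slots raise at load time."""
    if path is None:
        text = resources.files("efip").joinpath(
            "data/templates.yaml").read_text("utf-8")
    else:
        text = Path(path).read_text(encoding="utf-8")
    raw = yaml.safe_load(text)
    out: list[Template] = []
    for kind in ("positive", "distractor", "hedged"):
        for item in raw.get(kind, []) or []:
            t = Template(id=item["id"], text=item["text"], kind=kind,
                         relation=item.get("relation"),
                         families=list(item.get("families", [])),
                         siteless=bool(item.get("siteless", False)))
            bad = t.slots() - _KNOWN_SLOTS
            if bad:
                raise ValueError(
                    f"template {t.id!r} references unknown slots: {sorted(bad)}")
            out.append(t)
    return out


@dataclass
class FixtureSpec:
    seed: int = 0
    n_docs: int = 3
    n_relations: int = 12
    distractor_rate: float = 0.3
    templates: list[Template] | None = None
    include_abstract: bool = True
    hedged_fraction: float = 0.1  # fraction of planted relations hedged


@dataclass
class PlantedUnit:
    text: str
    gold: GoldTuple | None
    template_id: str
    sub_id: str = ""  # filled after parsing


@dataclass
class GeneratedFixture:
    documents: dict[str, str]  # filename -> XML text
    gold: dict[str, GoldAnnotation]
    lexicon: Lexicon
    lexicon_tsv: str
    planted: list[PlantedUnit]
    expected_subsections: dict[str, int]  # doc_id -> subsection count
    paths: list[Path] = field(default_factory=list)
    gold_path: Path | None = None


def _instantiate(template: Template, rng: random.Random, serial: int,
                 lexicon_rows: list[tuple[str, str]]):
    """Fill a template's slots; returns (sentence text, gold tuple|None)."""
    slots = template.slots()
    values: dict[str, str] = {}

    def new_protein(prefix: str) -> str:
        name = f"{prefix}{serial}"
        lexicon_rows.append((name, f"ACC{len(lexicon_rows) + 1:04d}"))
        return name

    if "S" in slots:
        values["S"] = new_protein("SUB")
    if "S2" in slots:
        values["S2"] = new_protein("SUC")
    if "K" in slots:
        values["K"] = new_protein("KIN")
    if "I" in slots:
        values["I"] = new_protein("INT")
    family = rng.choice(template.families) if template.families else None
    if family:
        forms = _FAMILY_FORMS[family]
        values.update(ppi_noun=forms["noun"], ppi_prep=forms["prep"],
                      ppi_verb=forms["verb"])
    site_canonical = None
    if "site" in slots:
        res = rng.choice(_RESIDUES)
        pos = rng.randint(15, 999)
        values["site"] = rng.choice(_SITE_STYLES).format(res=res, pos=pos)
        site_canonical = f"{res}-{pos}"
    if "cue" in slots:
        values["cue"] = rng.choice(_CUES)
    text = template.text.format(**values)

    gold = None
    if template.kind in ("positive", "hedged"):
        gold = GoldTuple(
            substrate=values["S"],
            interactant=values["I"],
            relation_type=template.relation or "causal",
            kinase=values.get("K"),
            site=None if template.siteless else site_canonical,
            ppi_type=family,
            hedged=template.kind == "hedged",
        )
    return text, gold


# --- JATS assembly ---------------------------------------------------------

def _build_doc_xml(doc_id: str, title: str, buckets: dict[str, list[str]],
                   include_abstract: bool) -> str:
    """Assemble one JATS article.

    ``buckets`` maps layout slot names to sentence lists; the Results
    heading itself carries no text (heading-without-text case) and hosts
    two child subsections plus a figure caption.
    """
    article = etree.Element("article")
    front = etree.SubElement(article, "front")
    meta = etree.SubElement(front, "article-meta")
    aid = etree.SubElement(meta, "article-id", **{"pub-id-type": "pmcid"})
    aid.text = doc_id
    tg = etree.SubElement(meta, "title-group")
    at = etree.SubElement(tg, "article-title")
    at.text = title
    if include_abstract:
        ab = etree.SubElement(front, "abstract")
        p = etree.SubElement(ab, "p")
        p.text = _ABSTRACT
    body = etree.SubElement(article, "body")

    def sec(parent, heading, sentences, sec_type=None):
        el = etree.SubElement(parent, "sec")
        if sec_type:
            el.set("sec-type", sec_type)
        t = etree.SubElement(el, "title")
        t.text = heading
        if sentences:
            p = etree.SubElement(el, "p")
            p.text = " ".join(sentences)
        return el

    sec(body, "Introduction", buckets["introduction"], "intro")
    sec(body, "Background", buckets["background"])
    sec(body, "Materials and Methods", buckets["methods"],
        "materials|methods")
    results = etree.SubElement(body, "sec")
    rt = etree.SubElement(results, "title")
    rt.text = "Results"
    r1 = sec(results, "Phosphorylation analysis", buckets["results_a"])
    fig = etree.SubElement(r1, "fig")
    label = etree.SubElement(fig, "label")
    label.text = "Figure 1"
    caption = etree.SubElement(fig, "caption")
    cp = etree.SubElement(caption, "p")
    cp.text = " ".join(buckets["figure"]) or _FILLER
    sec(results, "Interaction analysis", buckets["results_b"])
    sec(body, "Discussion", buckets["discussion"])
    sec(body, "Conclusions", buckets["conclusions"])
    sec(body, "Additional observations", buckets["other"])
    return etree.tostring(article, pretty_print=True,
                          xml_declaration=True, encoding="UTF-8").decode()


_BUCKET_NAMES = ["introduction", "background", "methods", "results_a",
                 "figure", "results_b", "discussion", "conclusions", "other"]


def generate(spec: FixtureSpec,
             out_dir: str | Path | None = None) -> GeneratedFixture:
    """Generate JATS documents, a gold corpus and a protein lexicon.

    Deterministic: the same spec yields byte-identical files.  When
    ``out_dir`` is given the documents, ``gold.json`` and ``lexicon.tsv``
    are written there.
    """
    rng = random.Random(spec.seed)
    templates = spec.templates or load_templates()
    positives = [t for t in templates if t.kind == "positive"]
    hedged = [t for t in templates if t.kind == "hedged"]
    distractors = [t for t in templates if t.kind == "distractor"]

    lexicon_rows: list[tuple[str, str]] = []
    units: list[PlantedUnit] = []
    serial = 0
    n_hedged = round(spec.n_relations * spec.hedged_fraction) if hedged else 0
    for i in range(spec.n_relations):
        serial += 1
        pool = hedged if i < n_hedged else positives
        t = rng.choice(pool)
        text, gold = _instantiate(t, rng, serial, lexicon_rows)
        units.append(PlantedUnit(text=text, gold=gold, template_id=t.id))
    rate = min(max(spec.distractor_rate, 0.0), 0.9)
    n_distract = round(len(units) * rate / (1.0 - rate)) if distractors else 0
    for _ in range(n_distract):
        serial += 1
        t = rng.choice(distractors)
        text, _ = _instantiate(t, rng, serial, lexicon_rows)
        units.append(PlantedUnit(text=text, gold=None, template_id=t.id))
    rng.shuffle(units)

    # distribute units over documents and buckets, round-robin
    per_doc: list[list[PlantedUnit]] = [[] for _ in range(spec.n_docs)]
    for i, u in enumerate(units):
        per_doc[i % spec.n_docs].append(u)

    documents: dict[str, str] = {}
    gold: dict[str, GoldAnnotation] = {}
    expected: dict[str, int] = {}
    for d in range(spec.n_docs):
        doc_id = f"FIX{spec.seed}D{d + 1}"
        buckets: dict[str, list[str]] = {b: [] for b in _BUCKET_NAMES}
        for i, u in enumerate(per_doc[d]):
            buckets[_BUCKET_NAMES[i % len(_BUCKET_NAMES)]].append(u.text)
        for b in _BUCKET_NAMES:
            if not buckets[b] and b != "figure":
                buckets[b].append(_FILLER)
        xml = _build_doc_xml(doc_id, f"Synthetic phospho-PPI article {d + 1}",
                             buckets, spec.include_abstract)
        documents[f"doc_{d + 1:03d}.xml"] = xml
        # ground truth for the subsection count: filled leaf headings plus
        # captions plus the abstract
        n_leaf = sum(1 for b in _BUCKET_NAMES
                     if b != "figure" and buckets[b])
        expected[doc_id] = n_leaf + 1 + (1 if spec.include_abstract else 0)

        doc = parse_jats(xml)
        for sub in doc.subsections:
            gold.setdefault(sub.sub_id, GoldAnnotation(sub_id=sub.sub_id))
        for u in per_doc[d]:
            host = next(s for s in doc.subsections
                        if u.text.split(".")[0] in s.text)
            u.sub_id = host.sub_id
            if u.gold is not None:
                gold[host.sub_id].tuples.append(u.gold)

    lexicon = Lexicon()
    for name, acc in lexicon_rows:
        lexicon.add(name, acc)
    lexicon_tsv = "".join(f"{n}\t{a}\n" for n, a in lexicon_rows)

    fixture = GeneratedFixture(
        documents=documents, gold=gold, lexicon=lexicon,
        lexicon_tsv=lexicon_tsv, planted=units,
        expected_subsections=expected)

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for fname, xml in documents.items():
            path = out_dir / fname
            path.write_text(xml, encoding="utf-8")
            fixture.paths.append(path)
        fixture.gold_path = out_dir / "gold.json"
        fixture.gold_path.write_text(gold_to_json(gold), encoding="utf-8")
        (out_dir / "lexicon.tsv").write_text(lexicon_tsv, encoding="utf-8")
    return fixture
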