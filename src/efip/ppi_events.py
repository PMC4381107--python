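"""Trigger-based extraction of protein-protein interaction (PPI) events.

Extraction is anchored on a lexicon of eleven trigger families — binding,
interaction, complex, association, dissociation, dimerization, affinity,
precipitation, recruitment, release, sequestering — each with its shipped
morphological variants.  Matching is token-based against the variant
table (a lookup lemmatizer), not raw substring search, so "bound" in
"outbound" never fires.  For every trigger occurrence a small set of
argument patterns fills the two interactant slots; events whose first
slot carries a "phosphorylated" pre-modifier are marked, which downstream
linking uses for temporal relations.

The "complex" trigger requires an adjacent protein pair ("the A-B
complex"); bare adjectival "complex" is ignored.  Dimerization with a
single mention fills both slots with the same protein, marked homodimer.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

from ._match import mention_at, mention_before, conjunct_mentions, DETS
from ._text import tokenize
from .protein_mentions import ProteinMention

PPI_FAMILIES = (
    "binding", "interaction", "complex", "association", "dissociation",
    "dimerization", "affinity", "precipitation", "recruitment", "release",
    "sequestering",
)

_NOMINAL_SUFFIXES = ("tion", "ing", "ity", "ment", "ase", "ex", "exes")
_BE = {"is", "are", "was", "were", "be", "been", "being", "get", "gets",
       "got", "become", "becomes", "became"}
_PREPS = {"with", "to", "from", "by", "for"}


@dataclass
class PPIEvent:
    interactant_a: ProteinMention  # the (potential) phospho-substrate side
    interactant_b: ProteinMention
    ppi_type: str
    trigger: tuple[int, int]
    sentence_ref: tuple[str, int] = ("", 0)
    a_phospho_marked: bool = False
    b_phospho_marked: bool = False
    homodimer: bool = False


class TriggerLexicon:
    """Variant -> family table for the eleven PPI trigger families."""

    def __init__(self, table: dict[str, str] | None = None):
        self._variants: dict[str, str] = {}
        for variant, family in (table or {}).items():
            self.add(variant, family)

    def add(self, variant: str, family: str) -> None:
        variant = variant.strip().lower()
        family = family.strip().lower()
        if family not in PPI_FAMILIES:
            raise ValueError(f"unknown PPI trigger family: {family!r}")
        if not variant:
            raise ValueError("empty trigger variant")
        prior = self._variants.get(variant)
        if prior is not None and prior != family:
            raise ValueError(
                f"variant {variant!r} mapped to both {prior!r} and {family!r}")
        self._variants[variant] = family

    def family_of(self, token: str) -> str | None:
        return self._variants.get(token.lower())

    def variants(self, family: str) -> set[str]:
        if family not in PPI_FAMILIES:
            raise ValueError(f"unknown PPI trigger family: {family!r}")
        return {v for v, f in self._variants.items() if f == family}

    @classmethod
    def from_tsv(cls, path: str | Path) -> "TriggerLexicon":
        lex = cls()
        for line in Path(path).read_text(encoding="utf-8").splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            variant, family = line.split("\t")[:2]
            lex.add(variant, family)
        return lex

    @classmethod
    def default(cls) -> "TriggerLexicon":
        lex = cls()
        text = resources.files("efip").joinpath(
            "data/ppi_triggers.tsv").read_text("utf-8")
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            variant, family = line.split("\t")[:2]
            lex.add(variant, family)
        return lex


_DEFAULT: TriggerLexicon | None = None


def default_triggers() -> TriggerLexicon:
    global _DEFAULT
    if _DEFAULT is None:
        _DEFAULT = TriggerLexicon.default()
    return _DEFAULT


def expand_trigger_variants(family: str) -> set[str]:
    """Shipped morphological surface variants of one trigger family."""
    if not family:
        raise ValueError("empty trigger family")
    return default_triggers().variants(family)


def _phospho_marked(text: str, mention: ProteinMention) -> bool:
    left = text[:mention.start].rstrip()
    return bool(re.search(r"(?:\bphosphorylated|\bphospho)[- ]?$", left,
                          re.IGNORECASE))


def _is_nominal(token: str) -> bool:
    return token.lower().endswith(_NOMINAL_SUFFIXES) or \
        token.lower() in {"complex", "release", "affinity"}


def _word_before(text: str, pos: int):
    m = re.search(r"([\w'-]+)\s*$", text[:pos])
    return (m.group(1), m.start(1)) if m else ("", pos)


def extract_ppi(sentence, mentions, triggers: TriggerLexicon | None = None,
                sub_id: str = "") -> list[PPIEvent]:
    """Extract PPI events from one (possibly simplified) sentence.

    A trigger whose argument slots cannot be filled yields no event.
    """
    if hasattr(sentence, "source_ref"):  # SimpleSentence
        text = sentence.text
        ref = sentence.source_ref
    elif isinstance(sentence, str):
        text, ref = sentence, (sub_id, 0)
    else:
        text, ref = sentence.text, (sub_id, sentence.index)
    triggers = triggers or default_triggers()
    events: list[PPIEvent] = []

    def add(a, b, family, trig, homodimer=False):
        if a is None or b is None:
            return
        if not homodimer and (a.start, a.end) == (b.start, b.end):
            return
        for prior in events:
            if prior.trigger == trig and prior.interactant_a.key == a.key \
                    and prior.interactant_b.key == b.key:
                return
        events.append(PPIEvent(
            interactant_a=a, interactant_b=b, ppi_type=family, trigger=trig,
            sentence_ref=ref,
            a_phospho_marked=_phospho_marked(text, a),
            b_phospho_marked=_phospho_marked(text, b),
            homodimer=homodimer))

    for tok, start, end in tokenize(text):
        family = triggers.family_of(tok)
        if family is None:
            continue
        trig = (start, end)
        nominal = _is_nominal(tok)

        if family == "complex":
            # requires an adjacent pair: "A-B complex" / "A/B complex" /
            # "A B complex"; bare adjectival "complex" is ignored
            b = mention_before(mentions, text, start, skippable=set())
            if b is not None:
                before_b = text[:b.start].rstrip()
                if before_b.endswith(("-", "–", "—", "/")):
                    a = mention_before(mentions, text, len(before_b) - 1,
                                       skippable=set())
                else:
                    a = mention_before(mentions, text, b.start,
                                       skippable=set())
                if a is not None and a.end <= b.start:
                    add(a, b, family, trig)
            continue

        if nominal:
            # "T of A (and A2) (with/to/from/by/for B ...)"
            m_of = re.match(r"\s+of\s+", text[end:])
            if m_of:
                a_list, cur = conjunct_mentions(mentions, text,
                                                end + m_of.end())
                if a_list:
                    m_prep = re.match(r"\s*(with|to|from|by|for)\s+",
                                      text[cur:])
                    if m_prep:
                        b_list, _ = conjunct_mentions(
                            mentions, text, cur + m_prep.end())
                        for a in a_list:
                            for b in b_list:
                                add(a, b, family, trig)
                        if b_list:
                            continue
                    if len(a_list) >= 2:
                        for b in a_list[1:]:
                            add(a_list[0], b, family, trig)
                        continue
                    if family == "dimerization" and len(a_list) == 1:
                        add(a_list[0], a_list[0], family, trig,
                            homodimer=True)
                        continue
            # "T between A and B"
            m_btw = re.match(r"\s+between\s+", text[end:])
            if m_btw:
                pair, _ = conjunct_mentions(mentions, text,
                                            end + m_btw.end())
                if len(pair) >= 2:
                    add(pair[0], pair[1], family, trig)
                    continue
            # "A('s) T with/to B"  (gerund or noun-compound, "Bax binding
            # to Pin1")
            a = mention_before(mentions, text, start,
                               skippable={"own"})
            if a is None:
                pm = re.search(r"[’']s\s*$", text[:start])
                if pm:
                    a = mention_before(mentions, text, pm.start())
            if a is not None:
                m_prep = re.match(r"\s*(with|to|from|by|for)\s+", text[end:])
                if m_prep:
                    b_list, _ = conjunct_mentions(mentions, text,
                                                  end + m_prep.end())
                    for b in b_list:
                        add(a, b, family, trig)
                    if b_list:
                        continue
                if family == "dimerization":
                    add(a, a, family, trig, homodimer=True)
            continue

        # verbal trigger
        w, wpos = _word_before(text, start)
        wl = w.lower()
        hops = 0
        while hops < 2 and (wl.endswith("ly") or wl in {"directly", "also",
                                                        "then", "stably"}):
            w, wpos = _word_before(text, wpos)
            wl = w.lower()
            hops += 1
        passive = wl in _BE
        subj_pos = wpos if passive else start
        a = mention_before(mentions, text, subj_pos,
                           skippable={"phosphorylated", "phospho",
                                      "unphosphorylated"} if passive
                           else set())
        if a is None and passive:
            a = mention_before(mentions, text, subj_pos)
        if a is None:
            a = mention_before(mentions, text, start)
        if a is None:
            continue
        m_prep = re.match(r"\s*(with|to|from|by|for)\s+", text[end:])
        if m_prep:
            b_list, _ = conjunct_mentions(mentions, text, end + m_prep.end())
            for b in b_list:
                add(a, b, family, trig)
            if b_list:
                continue
        # direct object: "A binds B"
        if not passive:
            b = mention_at(mentions, text, end)
            if b is not None:
                add(a, b, family, trig)
                continue
        if family == "dimerization":
            add(a, a, family, trig, homodimer=True)

    return events
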