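"""Decomposition of complex sentences into simple ones.

High-precision argument patterns only fire reliably on simple clauses, so
complex sentences are first broken apart: clause and verb-phrase
coordinations are split with the shared subject copied into each conjunct,
participial adjuncts are promoted to finite clauses, relative clauses and
appositives become stand-alone sentences, and long subject lists are
distributed.  One nesting level is handled (depth 2); anything deeper is
passed through unsplit and flagged.

A deliberate rule concerns mediating event nominals: in a sentence like
"Addition of BSO induced apoptosis via the phosphorylation of A and B,
resulting in their dissociation, and increased the interaction between A
and C", the follow-on conjuncts predicate over the *phosphorylation*, not
over the surface subject.  When the first conjunct contains a
"via/through the <event nominal> of ..." phrase, that nominal becomes the
subject of the remaining conjuncts, which yields the natural reading.

Possessive pronouns ("their"/"its") directly modifying an interaction
nominal are resolved against the nearest preceding conjoined protein noun
phrase — the only coreference case the impact patterns need.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .protein_mentions import Lexicon, detect_mentions, detect_sites

CONSTRUCTS = ("coordination", "list", "relative_clause", "appositive",
              "pronoun_substitution")

_MAX_DEPTH = 2

# Base verbs the splitter recognizes (domain verbs + causal cues + copulas).
_BASE_VERBS = [
    "induce", "increase", "decrease", "reduce", "enhance", "promote",
    "facilitate", "abolish", "prevent", "impair", "inhibit", "disrupt",
    "block", "suppress", "stimulate", "trigger", "cause", "result", "lead",
    "require", "interact", "bind", "associate", "dissociate", "dimerize",
    "precipitate", "recruit", "release", "sequester", "phosphorylate",
    "dephosphorylate", "regulate", "activate", "form", "show", "suggest",
    "demonstrate", "indicate", "reveal", "found", "enable", "contribute",
    "occur", "affect", "modulate", "attenuate", "augment", "diminish",
    "accelerate", "stabilize", "maintain", "disturb", "mediate",
]

_IRREGULAR_PAST = {"bind": "bound", "lead": "led", "found": "found"}


def _third_sg(base: str) -> str:
    if re.search(r"(?:s|sh|ch|x|z)$", base):
        return base + "es"
    if re.search(r"[^aeiou]y$", base):
        return base[:-1] + "ies"
    return base + "s"


def _past(base: str) -> str:
    if base in _IRREGULAR_PAST:
        return _IRREGULAR_PAST[base]
    if base.endswith("e"):
        return base + "d"
    if re.search(r"[^aeiou]y$", base):
        return base[:-1] + "ied"
    return base + "ed"


def _ing(base: str) -> str:
    if base.endswith("e") and not base.endswith(("ee", "ye")):
        return base[:-1] + "ing"
    return base + "ing"


FINITE_VERBS: set[str] = {"is", "are", "was", "were", "has", "have", "had",
                          "becomes", "became", "remains", "remained",
                          "does", "did", "led", "bound", "formed"}
ING_VERBS: set[str] = set()
ING_TO_FINITE: dict[str, str] = {}
for _b in _BASE_VERBS:
    FINITE_VERBS.update({_b, _third_sg(_b), _past(_b)})
    _g = _ing(_b)
    ING_VERBS.add(_g)
    ING_TO_FINITE[_g] = _third_sg(_b)


@dataclass
class SimpleSentence:
    text: str
    source_ref: tuple[str, int] = ("", 0)
    construct_trace: list[str] = field(default_factory=list)
    flagged: bool = False


def _finish(text: str) -> str:
    text = re.sub(r"\s+", " ", text).strip().strip(",;")
    if text and text[0].islower():
        text = text[0].upper() + text[1:]
    if text and text[-1] not in ".!?":
        text += "."
    return text


_MEDIATOR = re.compile(
    r"\b(?:via|through)\s+(the\s+(?:de)?phosphorylation\s+of\s+.+)$",
    re.IGNORECASE)

_MATRIX_THAT = re.compile(
    r"^(?P<matrix>.{0,80}?\b(?:suggest|show|demonstrate|indicate|reveal|"
    r"report|confirm|find|found|note|observe)\w*\s+that)\s+(?P<rest>.+)$",
    re.IGNORECASE)


def _split_that_coordination(text: str):
    """"[matrix] that C1, and that C2" -> [C1, C2]."""
    m = _MATRIX_THAT.match(text)
    if not m:
        return None
    rest = m.group("rest")
    parts = re.split(r",?\s+(?:and|or)\s+that\s+", rest)
    if len(parts) < 2:
        return None
    return [p.rstrip(" .,") for p in parts], "coordination"


def _subject_span(text: str) -> int:
    """End offset of the initial subject NP (start of the first finite verb)."""
    for m in re.finditer(r"\b([\w'-]+)\b", text):
        if m.group(1).lower() in FINITE_VERBS and m.start() > 0:
            return m.start()
    return 0


def _split_vp_coordination(text: str):
    """Split top-level VP coordination and participial adjuncts."""
    subj_end = _subject_span(text)
    if subj_end <= 0:
        return None
    subject = text[:subj_end].rstrip()
    boundaries: list[tuple[int, int, str]] = []  # (cut, verb_start, kind)
    for m in re.finditer(r",?\s+(?:(?:and|or)\s+)?([\w-]+)", text):
        if m.start() < subj_end:
            continue
        tok = m.group(1).lower()
        has_conj = re.search(r"\b(?:and|or)\s+[\w-]+$", m.group(0))
        if has_conj and tok in FINITE_VERBS and tok not in ING_VERBS:
            boundaries.append((m.start(), m.start(1), "coordination"))
        elif not has_conj and tok in ING_VERBS and \
                m.group(0).startswith(","):
            boundaries.append((m.start(), m.start(1), "participial"))
        elif not has_conj and m.group(0).startswith(",") and \
                tok in FINITE_VERBS:
            # serial VP list "V1 ..., V2 ..., and V3 ..." — only real when
            # an "and"-conjoined verb follows
            boundaries.append((m.start(), m.start(1), "serial"))
    if any(kind == "coordination" for _, _, kind in boundaries):
        boundaries = [(c, v, "coordination" if k == "serial" else k)
                      for c, v, k in boundaries]
    else:
        boundaries = [b for b in boundaries if b[2] != "serial"]
    if not boundaries:
        return None
    boundaries.sort()
    segments: list[tuple[str, str]] = []
    prev_cut = 0
    prev_kind = "main"
    for cut, vstart, kind in boundaries:
        segments.append((prev_kind, text[prev_cut:cut].strip(" ,")))
        prev_cut, prev_kind = vstart, kind
    segments.append((prev_kind, text[prev_cut:].strip(" ,")))

    first = segments[0][1]
    med = _MEDIATOR.search(first)
    follow_subject = med.group(1).strip(" .,") if med else subject

    out: list[tuple[str, str]] = [("coordination", first)]
    for kind, seg in segments[1:]:
        if kind == "participial":
            m = re.match(r"([\w-]+)", seg)
            finite = ING_TO_FINITE.get(m.group(1).lower(), m.group(1)) \
                if m else ""
            seg = finite + seg[m.end():] if m else seg
        out.append(("coordination", f"{follow_subject} {seg}"))
    return [s for _, s in out], "coordination"


def _split_relative(text: str, mentions):
    """Non-restrictive ", which VP" clauses -> separate sentence."""
    m = re.search(r",\s+which\s+([\w-]+)", text)
    if not m or m.group(1).lower() not in FINITE_VERBS:
        return None
    end = len(text)
    nxt = re.search(r",", text[m.end():])
    if nxt:
        end = m.end() + nxt.start()
    clause = text[m.start():end]
    head = None
    for men in mentions:
        if men.end <= m.start():
            head = men
    head_text = head.surface if head is not None else \
        " ".join(text[:m.start()].rstrip(" ,").split()[-2:])
    vp = clause[len(","):].strip()
    vp = re.sub(r"^\s*which\s+", "", vp)
    main = (text[:m.start()] + text[end:]).strip(" ,")
    return [main, f"{head_text} {vp}".rstrip(" .,")], "relative_clause"


def _split_appositive(text: str, mentions):
    """Trailing "..., a N that VP" and inner "X, a Y, VP" appositives."""
    m = re.search(r",\s+(a|an|the)\s+([\w-]+)\s+that\s+(.+)$", text)
    if m:
        main = text[:m.start()].rstrip(" .,")
        art = m.group(1).capitalize() if m.group(1) != "the" else "The"
        extra = f"{art} {m.group(2)} {m.group(3)}".rstrip(" .,")
        return [main, extra], "appositive"
    for men in mentions:
        pat = re.compile(re.escape(men.surface) +
                         r",\s+(a|an)\s+([^,]{3,60}?),\s+")
        mm = pat.search(text)
        if mm:
            main = text[:mm.start()] + men.surface + " " + text[mm.end():]
            extra = f"{men.surface} is {mm.group(1)} {mm.group(2)}"
            return [main.strip(" .,"), extra], "appositive"
    return None


def _split_subject_list(text: str, mentions):
    """Distribute a >=3-way subject list: "A, B, and C VP" -> 3 sentences."""
    subj_end = _subject_span(text)
    if subj_end <= 0:
        return None
    subs = [m for m in mentions if m.end <= subj_end]
    if len(subs) < 3:
        return None
    covered = text[subs[0].start:subs[-1].end]
    rest = text[subs[-1].end:subj_end]
    joined = re.fullmatch(r"(?:[\w ,/-]|and|or)*", covered)
    if not joined or rest.strip(" ,"):
        return None
    lead = text[:subs[0].start]
    vp = text[subj_end:].rstrip(" .")
    return [f"{lead}{m.surface} {vp}" for m in subs], "list"


def simplify(sentence, lexicon: Lexicon | None = None,
             sub_id: str = "", _depth: int = 0) -> list[SimpleSentence]:
    """Break a complex sentence into simple sentences (depth <= 2).

    A sentence with no detected construct yields exactly itself with an
    empty trace; a sentence still complex past the nesting limit is passed
    through unsplit and flagged.
    """
    text = sentence if isinstance(sentence, str) else sentence.text
    index = 0 if isinstance(sentence, str) else sentence.index
    ref = (sub_id, index)
    text_clean = text.rstrip()
    body = text_clean.rstrip(".!?")
    mentions = detect_mentions(body, lexicon)

    result = (_split_that_coordination(body)
              or _split_vp_coordination(body)
              or _split_relative(body, mentions)
              or _split_appositive(body, mentions)
              or _split_subject_list(body, mentions))
    if result is None:
        return [SimpleSentence(text=_finish(text_clean), source_ref=ref)]
    if _depth >= _MAX_DEPTH:
        out = [SimpleSentence(text=_finish(text_clean), source_ref=ref,
                              flagged=True)]
        return out

    parts, label = result
    out: list[SimpleSentence] = []
    for part in parts:
        for child in simplify(part, lexicon, sub_id, _depth + 1):
            child.source_ref = ref
            child.construct_trace = [label] + child.construct_trace
            if child.text not in [o.text for o in out]:
                out.append(child)
    return out


# --- possessive pronoun resolution ----------------------------------------

_PPI_NOMINALS = ("dissociation", "interaction", "binding", "association",
                 "complex", "dimerization", "affinity", "precipitation",
                 "recruitment", "release", "sequestration", "sequestering",
                 "phosphorylation")

_POSS = re.compile(r"\b(their|its)\s+(" + "|".join(_PPI_NOMINALS) + r")\b",
                   re.IGNORECASE)


def _antecedent_conjuncts(text: str, pos: int, mentions) -> list:
    """Nearest preceding conjoined protein NP (all conjuncts)."""
    before = [m for m in mentions if m.end <= pos]
    if not before:
        return []
    group = [before[-1]]
    while True:
        head = group[0]
        gap = None
        for m in before:
            if m.end <= head.start:
                gap = m
        if gap is None:
            break
        between = text[gap.end:head.start]
        if re.fullmatch(r"\s*(?:,|,?\s*(?:and|or))?\s*", between):
            group.insert(0, gap)
        else:
            break
    return group


def resolve_possessive(sentences: list[SimpleSentence],
                       lexicon: Lexicon | None = None) -> list[SimpleSentence]:
    """Substitute "their"/"its" before an interaction nominal.

    The pronoun phrase is rewritten as "the <nominal> of <A> and <B>" using
    the nearest preceding conjoined protein noun phrase; unresolvable
    pronouns are left intact and flagged.
    """
    out: list[SimpleSentence] = []
    for sent in sentences:
        text = sent.text
        mentions = detect_mentions(text, lexicon)
        changed = False
        unresolved = False
        while True:
            m = _POSS.search(text)
            if not m:
                break
            ante = _antecedent_conjuncts(text, m.start(), mentions)
            if not ante:
                unresolved = True
                break
            names = " and ".join(a.surface for a in ante)
            repl = f"the {m.group(2)} of {names}"
            text = text[:m.start()] + repl + text[m.end():]
            mentions = detect_mentions(text, lexicon)
            changed = True
        trace = list(sent.construct_trace)
        if changed:
            trace.append("pronoun_substitution")
        out.append(SimpleSentence(
            text=text, source_ref=sent.source_ref, construct_trace=trace,
            flagged=sent.flagged or unresolved))
    return out


__all__ = ["SimpleSentence", "simplify", "resolve_possessive", "CONSTRUCTS",
           "detect_sites"]
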