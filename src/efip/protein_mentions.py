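"""Protein name and phosphosite mention detection, with dictionary normalization.

Protein mentions are found by longest-match lookup against a name lexicon
(two-column TSV: surface name, accession), falling back to a conservative
protein-like token pattern for names absent from the lexicon.  Phosphosite
mentions cover the common surface forms (Ser280, S280, Ser-280, "serine
280", and space-separated lists such as "Ser-309 Ser-361").  Normalization
maps a surface name to its accession(s) by exact lookup after case,
punctuation, Greek-letter and subscript-markup normalization — a dictionary
stand-in for full gene normalization, which is all the downstream pipeline
needs.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

from ._text import norm_name, tokenize

ENTITY_CLASSES = ("protein", "complex", "region", "protein_class")

_REGION_HEADS = {"domain", "motif", "region", "terminus", "tail"}
_CLASS_HEADS = {"family", "proteins", "isoforms"}

_MAX_NAME_TOKENS = 5


@dataclass
class ProteinMention:
    surface: str
    start: int
    end: int
    entity_class: str = "protein"
    accessions: list[str] = field(default_factory=list)
    flagged: bool = False  # unmapped — kept for later manual correction

    @property
    def key(self) -> str:
        """Identity key: first accession when mapped, else normalized surface."""
        return self.accessions[0] if self.accessions else norm_name(self.surface)


_RESIDUES = {"ser": "Ser", "thr": "Thr", "tyr": "Tyr", "his": "His",
             "serine": "Ser", "threonine": "Thr", "tyrosine": "Tyr",
             "histidine": "His",
             "s": "Ser", "t": "Thr", "y": "Tyr", "h": "His"}


@dataclass
class SiteMention:
    residue: str  # Ser | Thr | Tyr | His | other
    position: int | None
    surface: str
    start: int
    end: int

    @property
    def canonical(self) -> str:
        """Canonical "Res-NNN" rendering (or "phosphoX" when unknown)."""
        if self.position is None:
            return "phosphoX"
        return f"{self.residue}-{self.position}"


_SITE = re.compile(
    r"""\b(?:
        (?P<resfull>[Ss]erine|[Tt]hreonine|[Tt]yrosine|[Hh]istidine)
            [- ]?(?P<posfull>\d+)
      | (?P<res3>[Ss]er|[Tt]hr|[Tt]yr|[Hh]is)[- ]?(?P<pos3>\d+)
      | (?P<res1>[STY])(?P<pos1>\d+)
    )\b""",
    re.VERBOSE,
)


def detect_sites(sentence) -> list[SiteMention]:
    """Find phosphosite mentions; space-separated lists yield one per site.

    Single-letter forms cover S/T/Y only: "H3" and friends are histone
    names in practice, and phosphohistidine is essentially never written
    that way.
    """
    text = sentence if isinstance(sentence, str) else sentence.text
    out: list[SiteMention] = []
    for m in _SITE.finditer(text):
        res = m.group("resfull") or m.group("res3") or m.group("res1")
        pos = m.group("posfull") or m.group("pos3") or m.group("pos1")
        out.append(SiteMention(
            residue=_RESIDUES.get(res.lower(), "other"),
            position=int(pos),
            surface=m.group(0),
            start=m.start(),
            end=m.end(),
        ))
    return out


# --- lexicon ---------------------------------------------------------------

class Lexicon:
    """Protein-name lexicon mapping normalized surface names to accessions."""

    def __init__(self, entries: dict[str, list[str]] | None = None):
        # normalized name -> ordered unique accession list
        self._map: dict[str, list[str]] = {}
        for name, accs in (entries or {}).items():
            for acc in accs if isinstance(accs, (list, tuple)) else [accs]:
                self.add(name, acc)

    def add(self, name: str, accession: str) -> None:
        key = norm_name(name)
        if not key:
            return
        bucket = self._map.setdefault(key, [])
        if accession and accession not in bucket:
            bucket.append(accession)

    def lookup(self, name: str) -> list[str]:
        return list(self._map.get(norm_name(name), []))

    def __contains__(self, name: str) -> bool:
        return norm_name(name) in self._map

    def __len__(self) -> int:
        return len(self._map)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "Lexicon":
        """Load a two-column tab-separated (surface_name, accession) file."""
        lex = cls()
        for line in Path(path).read_text(encoding="utf-8").splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            lex.add(parts[0], parts[1] if len(parts) > 1 else "")
        return lex


def _load_words(name: str) -> frozenset[str]:
    text = resources.files("efip").joinpath(f"data/{name}").read_text("utf-8")
    return frozenset(w.strip().lower() for w in text.splitlines()
                     if w.strip() and not w.startswith("#"))


_STOPWORDS: frozenset[str] | None = None


def _stopwords() -> frozenset[str]:
    global _STOPWORDS
    if _STOPWORDS is None:
        _STOPWORDS = _load_words("stopwords.txt")
    return _STOPWORDS


def _protein_like(token: str) -> bool:
    """Heuristic for protein-symbol-looking tokens absent from the lexicon."""
    if len(token) < 2 or not token[0].isalnum():
        return False
    if token.lower().strip("-_/") in _stopwords():
        return False
    if _SITE.fullmatch(token):
        return False
    if any(ch.isdigit() for ch in token):
        return True
    n_upper = sum(1 for ch in token if ch.isupper())
    if n_upper >= 2:
        return True
    # short capitalized symbol such as "Bax" (common words are stoplisted)
    return token[0].isupper() and token[1:].islower() and 2 <= len(token) <= 6


def _split_compound(tok: str, start: int,
                    lexicon: Lexicon) -> list[ProteinMention] | None:
    """Split "A-B"/"A/B" at separators when some part is a lexicon name.

    Names whose hyphens are integral ("14-3-3", "MCL-1") are never split
    because no split part resolves in the lexicon while the whole-token
    lookup (tried first by the caller) does.
    """
    if "-" not in tok and "/" not in tok:
        return None
    pieces = re.split(r"([-–/])", tok)
    if len(pieces) < 3:
        return None
    offs = []
    off = 0
    for p in pieces:
        offs.append(off)
        off += len(p)
    names = [(p, offs[i]) for i, p in enumerate(pieces) if p not in "-–/"]
    kinase_mod = (len(names) == 2 and names[1][0].lower() in
                  {"mediated", "induced", "catalyzed", "catalysed",
                   "dependent"} and _protein_like(names[0][0]))
    if not kinase_mod and not any(lexicon.lookup(p) for p, _ in names):
        return None
    out = []
    for p, o in names:
        accs = lexicon.lookup(p)
        if accs:
            out.append(ProteinMention(surface=p, start=start + o,
                                      end=start + o + len(p),
                                      accessions=accs))
        elif _protein_like(p):
            out.append(ProteinMention(surface=p, start=start + o,
                                      end=start + o + len(p), flagged=True))
    return out or None


def detect_mentions(sentence, lexicon: Lexicon | None = None) -> list[ProteinMention]:
    """Detect protein mentions by longest-first lexicon match plus patterns.

    Returned mentions are non-overlapping; lexicon hits carry all accessions
    their name maps to, pattern-derived mentions carry none and are flagged.
    """
    text = sentence if isinstance(sentence, str) else sentence.text
    lexicon = lexicon or Lexicon()
    tokens = tokenize(text)
    mentions: list[ProteinMention] = []
    i = 0
    while i < len(tokens):
        matched = False
        for j in range(min(i + _MAX_NAME_TOKENS, len(tokens)) - 1, i - 1, -1):
            surface = text[tokens[i][1]:tokens[j][2]]
            accs = lexicon.lookup(surface)
            if accs:
                mentions.append(ProteinMention(
                    surface=surface, start=tokens[i][1], end=tokens[j][2],
                    accessions=accs))
                i = j + 1
                matched = True
                break
        if matched:
            continue
        tok, start, end = tokens[i]
        # hyphen/slash compounds like "BIM_EL-BAX": split when at least one
        # part is a lexicon name, so pair patterns ("A-B complex") see both
        parts = _split_compound(tok, start, lexicon)
        if parts is not None:
            mentions.extend(parts)
        elif _protein_like(tok):
            mentions.append(ProteinMention(
                surface=tok, start=start, end=end, flagged=True))
        i += 1
    # entity-class head nouns immediately after a mention
    for m in mentions:
        rest = text[m.end:].lstrip()
        head = rest.split(" ", 1)[0].strip(".,;:") if rest else ""
        if head.lower() in _REGION_HEADS:
            m.entity_class = "region"
        elif head.lower() in _CLASS_HEADS:
            m.entity_class = "protein_class"
    return mentions


def normalize(mention: ProteinMention, mapping: Lexicon | dict) -> ProteinMention:
    """Fill a mention's accessions by exact normalized-name lookup.

    Unmapped mentions keep an empty accession list and are flagged for
    later manual correction; ambiguous names retain every accession.
    """
    if isinstance(mapping, dict):
        mapping = Lexicon({k: v if isinstance(v, list) else [v]
                           for k, v in mapping.items()})
    accs = mapping.lookup(mention.surface)
    mention.accessions = accs
    mention.flagged = not accs
    return mention
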