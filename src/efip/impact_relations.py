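"""Linking phosphorylation events to PPI events and assembling final tuples.

A relation is only asserted when the phosphorylation chronologically
precedes the PPI:

* temporal — the participial pattern "phosphorylated X" (or "X, when
  phosphorylated,") fills an interactant slot of the PPI; no impact cue
  is present, so the polarity is unspecified;
* causal — a cue from the impact lexicon (facilitates, results in,
  increased, abolishes, ...) connects the phosphorylation nominal or
  clause to the PPI nominal, with the cue's polarity describing the
  change of the stated PPI event itself.

Configurations where the PPI precedes the phosphorylation ("binding of A
to B induces phosphorylation of A") produce no relation — asserting them
would invert the directionality.  Hedged statements ("may", "whether")
are extracted but tagged, preserving recall while exposing uncertainty.

Relation search operates within one simple sentence; each PPI event
yields at most one relation.  Final tuples carry kinase and site slots
completed by subsection-level merging; substrates with no site receive
the "phosphoX" placeholder phosphoform.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path

from ._text import norm_name
from .phospho_events import PhosphoEvent, merge_events
from .ppi_events import PPIEvent

log = logging.getLogger(__name__)

POLARITIES = ("increase", "decrease", "unspecified")
RELATION_TYPES = ("temporal", "causal")

_HEDGE = re.compile(
    r"\b(?:may|might|whether|possibly|potentially|putative|hypothes\w+|"
    r"unclear|unknown|investigated?\s+whether|examined?\s+whether|"
    r"tested\s+whether|asked\s+whether)\b", re.IGNORECASE)


class CueLexicon:
    """Causal impact cue phrases with their polarity."""

    def __init__(self, table: dict[str, str] | None = None):
        self._cues: dict[str, str] = {}
        self._regex = None
        for cue, pol in (table or {}).items():
            self.add(cue, pol)

    def add(self, cue: str, polarity: str) -> None:
        if polarity not in POLARITIES:
            raise ValueError(f"unknown polarity: {polarity!r}")
        self._cues[cue.strip().lower()] = polarity
        self._regex = None

    def polarity(self, cue: str | None) -> str:
        if not cue:
            return "unspecified"
        pol = self._cues.get(cue.strip().lower())
        if pol is None:
            log.info("unknown impact cue %r -> unspecified", cue)
            return "unspecified"
        return pol

    def finditer(self, text: str):
        if self._regex is None:
            alts = sorted(self._cues, key=len, reverse=True)
            self._regex = re.compile(
                r"\b(?:" + "|".join(re.escape(a) for a in alts) + r")\b",
                re.IGNORECASE)
        return self._regex.finditer(text)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "CueLexicon":
        lex = cls()
        for line in Path(path).read_text(encoding="utf-8").splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            cue, pol = line.split("\t")[:2]
            lex.add(cue, pol)
        return lex

    @classmethod
    def default(cls) -> "CueLexicon":
        lex = cls()
        text = resources.files("efip").joinpath(
            "data/impact_cues.tsv").read_text("utf-8")
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            cue, pol = line.split("\t")[:2]
            lex.add(cue, pol)
        return lex


_DEFAULT_CUES: CueLexicon | None = None


def default_cues() -> CueLexicon:
    global _DEFAULT_CUES
    if _DEFAULT_CUES is None:
        _DEFAULT_CUES = CueLexicon.default()
    return _DEFAULT_CUES


def classify_polarity(cue: str | None, ppi_type: str | None = None,
                      cues: CueLexicon | None = None) -> str:
    """Polarity of a causal cue (absent cue -> unspecified).

    The polarity describes the stated PPI event itself regardless of its
    family, so ``ppi_type`` never flips the sign.
    """
    return (cues or default_cues()).polarity(cue)


@dataclass
class ImpactRelation:
    phospho: PhosphoEvent
    ppi: PPIEvent
    relation_type: str
    polarity: str = "unspecified"
    cue: tuple[int, int] | None = None
    cue_text: str | None = None
    evidence: str = ""
    hedged: bool = False

    @property
    def substrate(self):
        return self.phospho.substrate

    @property
    def interactant(self):
        sub_key = self.phospho.substrate_key
        if sub_key is not None and self.ppi.interactant_b.key == sub_key \
                and self.ppi.interactant_a.key != sub_key:
            return self.ppi.interactant_a
        return self.ppi.interactant_b


def link_events(phospho_events: list[PhosphoEvent],
                ppi_events: list[PPIEvent],
                sentence,
                evidence: str | None = None,
                cues: CueLexicon | None = None) -> list[ImpactRelation]:
    """Link phospho and PPI events extracted from one simple sentence.

    Returns at most one relation per PPI event.  The PPI's phospho-side
    interactant must match a phosphorylation substrate; a substrate-less
    phosphorylation nominal ("Thr167 phosphorylation facilitates Bax
    binding...") adopts the phospho-side interactant as its substrate.
    """
    text = sentence if isinstance(sentence, str) else sentence.text
    evidence = evidence if evidence is not None else text
    cues = cues or default_cues()
    hedged = bool(_HEDGE.search(evidence) or _HEDGE.search(text))
    relations: list[ImpactRelation] = []

    cue_hits = list(cues.finditer(text))

    for ppi in ppi_events:
        a_key = ppi.interactant_a.key
        b_key = ppi.interactant_b.key

        def substrate_rank(p: PhosphoEvent) -> int:
            if p.substrate_key == a_key:
                return 0
            if p.substrate_key == b_key:
                return 1
            if p.substrate_key is None:
                return 2
            return 3

        # --- causal: phospho trigger < cue < PPI trigger ----------------
        made = None
        for cm in cue_hits:
            if ppi.trigger[0] < cm.end():
                continue
            cands = [p for p in phospho_events
                     if p.trigger[1] <= cm.start() and substrate_rank(p) < 3]
            if not cands:
                continue
            cands.sort(key=lambda p: (substrate_rank(p), -p.trigger[1]))
            p = cands[0]
            if p.substrate is None:
                p = replace(p, substrate=ppi.interactant_a,
                            provenance=list(p.provenance))
            cue_text = cm.group(0)
            made = ImpactRelation(
                phospho=p, ppi=ppi, relation_type="causal",
                polarity=classify_polarity(cue_text, ppi.ppi_type, cues),
                cue=(cm.start(), cm.end()), cue_text=cue_text,
                evidence=evidence, hedged=hedged)
            break
        if made is not None:
            relations.append(made)
            continue

        # --- temporal: participial "phosphorylated X" fills a slot ------
        part = [p for p in phospho_events
                if p.form == "participial" and substrate_rank(p) < 2]
        if not part and (ppi.a_phospho_marked or ppi.b_phospho_marked):
            part = [p for p in phospho_events if substrate_rank(p) < 2]
        if part:
            part.sort(key=substrate_rank)
            relations.append(ImpactRelation(
                phospho=part[0], ppi=ppi, relation_type="temporal",
                polarity="unspecified", evidence=evidence, hedged=hedged))

    return relations


# --- final tuples ----------------------------------------------------------

@dataclass
class EFIPTuple:
    substrate: str
    interactant: str
    ppi_type: str
    relation_type: str
    polarity: str = "unspecified"
    kinase: str | None = None
    sites: tuple[str, ...] = ()
    substrate_acc: str = ""
    interactant_acc: str = ""
    kinase_acc: str = ""
    hedged: bool = False
    doc_id: str = ""
    sub_id: str = ""
    section_type: str = ""
    evidence: str = ""
    provenance: list = field(default_factory=list)

    def identity(self) -> tuple:
        """Deduplication key after normalization."""
        return (
            self.kinase_acc or (norm_name(self.kinase) if self.kinase else ""),
            self.substrate_acc or norm_name(self.substrate),
            tuple(sorted(self.sites)) or ("phosphoX",),
            self.interactant_acc or norm_name(self.interactant),
            self.ppi_type, self.relation_type, self.polarity,
        )

    def to_dict(self) -> dict:
        return {
            "doc_id": self.doc_id, "sub_id": self.sub_id,
            "section_type": self.section_type,
            "kinase": self.kinase, "kinase_acc": self.kinase_acc,
            "substrate": self.substrate, "substrate_acc": self.substrate_acc,
            "sites": list(self.sites),
            "interactant": self.interactant,
            "interactant_acc": self.interactant_acc,
            "ppi_type": self.ppi_type, "relation_type": self.relation_type,
            "polarity": self.polarity, "hedged": self.hedged,
            "evidence": self.evidence, "provenance": list(self.provenance),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "EFIPTuple":
        return cls(
            substrate=d["substrate"], interactant=d["interactant"],
            ppi_type=d["ppi_type"], relation_type=d["relation_type"],
            polarity=d.get("polarity", "unspecified"),
            kinase=d.get("kinase"), sites=tuple(d.get("sites") or ()),
            substrate_acc=d.get("substrate_acc", ""),
            interactant_acc=d.get("interactant_acc", ""),
            kinase_acc=d.get("kinase_acc", ""),
            hedged=bool(d.get("hedged", False)),
            doc_id=d.get("doc_id", ""), sub_id=d.get("sub_id", ""),
            section_type=d.get("section_type", ""),
            evidence=d.get("evidence", ""),
            provenance=list(d.get("provenance") or ()),
        )


CSV_COLUMNS = ["doc_id", "sub_id", "section_type", "kinase", "substrate",
               "sites", "interactant", "ppi_type", "relation_type",
               "polarity", "evidence"]


def _acc(mention) -> str:
    return mention.accessions[0] if mention is not None and \
        mention.accessions else ""


def assemble_tuples(relations: list[ImpactRelation],
                    subsection=None,
                    merged_events: list[PhosphoEvent] | None = None,
                    doc_id: str = "") -> list[EFIPTuple]:
    """Assemble deduplicated final tuples from linked relations.

    Kinase and site slots are completed from the subsection's merged
    phosphorylation events (``merged_events``); a substrate with no known
    site becomes the "phosphoX" phosphoform.  Duplicate tuples (same
    normalized identity) merge their provenance; assembly is idempotent.
    """
    sub_id = getattr(subsection, "sub_id", "") if subsection else ""
    section_type = getattr(subsection, "section_type", "") if subsection else ""
    by_sub: dict[str, list[PhosphoEvent]] = {}
    for ev in merged_events or []:
        if ev.substrate_key is not None:
            by_sub.setdefault(ev.substrate_key, []).append(ev)

    out: dict[tuple, EFIPTuple] = {}
    for rel in relations:
        sub_m = rel.phospho.substrate
        if sub_m is None:
            continue
        inter_m = rel.interactant
        completions = by_sub.get(rel.phospho.substrate_key) or [rel.phospho]
        for comp in completions:
            kin = comp.kinase if comp.kinase is not None else rel.phospho.kinase
            sites = comp.sites or rel.phospho.sites
            tup = EFIPTuple(
                substrate=sub_m.surface,
                substrate_acc=_acc(sub_m),
                interactant=inter_m.surface,
                interactant_acc=_acc(inter_m),
                kinase=kin.surface if kin is not None else None,
                kinase_acc=_acc(kin),
                sites=tuple(sorted({s.canonical for s in sites}))
                    or ("phosphoX",),
                ppi_type=rel.ppi.ppi_type,
                relation_type=rel.relation_type,
                polarity=rel.polarity,
                hedged=rel.hedged,
                doc_id=doc_id, sub_id=sub_id, section_type=section_type,
                evidence=rel.evidence,
                provenance=[list(r) for r in
                            (rel.phospho.provenance
                             or [rel.phospho.sentence_ref])],
            )
            key = tup.identity()
            if key in out:
                prior = out[key]
                for r in tup.provenance:
                    if r not in prior.provenance:
                        prior.provenance.append(r)
            else:
                out[key] = tup
    return list(out.values())


def dedupe_tuples(tuples: list[EFIPTuple]) -> list[EFIPTuple]:
    """Merge tuples with identical normalized identity (idempotent)."""
    out: dict[tuple, EFIPTuple] = {}
    for tup in tuples:
        key = tup.identity()
        if key in out:
            for r in tup.provenance:
                if r not in out[key].provenance:
                    out[key].provenance.append(r)
        else:
            out[key] = replace(tup, provenance=list(tup.provenance),
                               sites=tuple(tup.sites))
    return list(out.values())
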