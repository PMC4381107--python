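"""End-to-end orchestration: document -> simplified sentences -> events ->
linked relations -> final tuples.

Processing is subsection-scoped: sentences are simplified and possessive
pronouns resolved, phosphorylation and PPI events are extracted per simple
sentence and linked within it, partial phosphorylation events are merged
across the subsection's sentences, and the merged information completes
the kinase/site slots of the final tuples.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .document_model import Document, Subsection
from .impact_relations import (CueLexicon, EFIPTuple, ImpactRelation,
                               assemble_tuples, default_cues, link_events)
from .phospho_events import PhosphoEvent, extract_phospho, merge_events
from .ppi_events import PPIEvent, TriggerLexicon, default_triggers, extract_ppi
from .protein_mentions import Lexicon, detect_mentions, detect_sites
from .sentence_simplification import (SimpleSentence, resolve_possessive,
                                      simplify)


@dataclass
class SubsectionResult:
    subsection: Subsection
    simple_sentences: list[SimpleSentence] = field(default_factory=list)
    phospho_events: list[PhosphoEvent] = field(default_factory=list)
    merged_events: list[PhosphoEvent] = field(default_factory=list)
    ppi_events: list[PPIEvent] = field(default_factory=list)
    relations: list[ImpactRelation] = field(default_factory=list)
    tuples: list[EFIPTuple] = field(default_factory=list)


class Pipeline:
    """The assembled extraction pipeline.

    Parameters
    ----------
    lexicon:
        Protein-name lexicon used for mention detection and normalization.
        Names outside the lexicon are still picked up by the protein-like
        token fallback, with empty accessions.
    triggers, cues:
        PPI trigger and causal-cue lexicons; shipped defaults when omitted.
    """

    def __init__(self, lexicon: Lexicon | None = None,
                 triggers: TriggerLexicon | None = None,
                 cues: CueLexicon | None = None):
        self.lexicon = lexicon or Lexicon()
        self.triggers = triggers or default_triggers()
        self.cues = cues or default_cues()

    def process_subsection(self, sub: Subsection,
                           doc_id: str = "") -> SubsectionResult:
        res = SubsectionResult(subsection=sub)
        for sentence in sub.sentences:
            simples = simplify(sentence, self.lexicon, sub_id=sub.sub_id)
            simples = resolve_possessive(simples, self.lexicon)
            res.simple_sentences.extend(simples)
            for simple in simples:
                mentions = detect_mentions(simple.text, self.lexicon)
                sites = detect_sites(simple.text)
                phospho = extract_phospho(simple.text, mentions, sites,
                                          sub_id=sub.sub_id)
                for ev in phospho:
                    ev.sentence_ref = (sub.sub_id, sentence.index)
                    ev.provenance = [(sub.sub_id, sentence.index)]
                ppi = extract_ppi(simple, mentions, self.triggers,
                                  sub_id=sub.sub_id)
                for ev in ppi:
                    ev.sentence_ref = (sub.sub_id, sentence.index)
                res.phospho_events.extend(phospho)
                res.ppi_events.extend(ppi)
                res.relations.extend(link_events(
                    phospho, ppi, simple.text, evidence=sentence.text,
                    cues=self.cues))
        res.merged_events = merge_events(res.phospho_events)
        res.tuples = assemble_tuples(res.relations, sub, res.merged_events,
                                     doc_id=doc_id)
        return res

    def process_document(self, doc: Document) -> list[SubsectionResult]:
        return [self.process_subsection(sub, doc_id=doc.doc_id)
                for sub in doc.subsections]

    def document_tuples(self, doc: Document) -> list[EFIPTuple]:
        out: list[EFIPTuple] = []
        for res in self.process_document(doc):
            out.extend(res.tuples)
        return out

    def predictions_by_subsection(
            self, doc: Document) -> dict[str, list[EFIPTuple]]:
        """Per-subsection tuples, keyed by sub_id (evaluation input)."""
        return {res.subsection.sub_id: res.tuples
                for res in self.process_document(doc)}

    def run_text(self, text: str, sub_id: str = "text") -> SubsectionResult:
        """Process a plain-text snippet as a single stand-alone subsection."""
        from .document_model import segment_sentences
        sub = Subsection(sub_id=sub_id, heading="", inherited_headings=[],
                         section_type="other", text=text,
                         sentences=segment_sentences(text))
        return self.process_subsection(sub)
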