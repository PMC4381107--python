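# efip

Rule-based text mining of the **functional impact of phosphorylation on
protein–protein interactions** (PPIs), for curators and systems biologists
who need phosphorylation-dependent interaction networks out of the
literature rather than one abstract at a time.

Protein phosphorylation — a kinase adding a phosphate to a substrate at a
Ser/Thr/Tyr residue — can abolish an interaction with one partner or enable
an interaction with another. Sentences stating this follow recognizable
patterns, and this package extracts them end to end:

1. **Documents → subsections.** JATS full-text XML (and plain abstracts) are
   split into subsections — a heading plus the prose before the next
   heading — with inherited ancestor headings and a section type
   (abstract, introduction, background, methods, results, discussion,
   conclusions, figure, other).
2. **Phosphorylation events** `<kinase, substrate, site>` from
   trigger-anchored patterns (passive, nominal, kinase pre-modifier,
   active, participial), with partial events merged across sentences of a
   subsection.
3. **PPI events** `<interactant_a, interactant_b, ppi_type>` from eleven
   trigger families (binding, interaction, complex, association,
   dissociation, dimerization, affinity, precipitation, recruitment,
   release, sequestering) and their morphological variants.
4. **Sentence simplification** of coordinations, lists, relative clauses
   and appositives into simple sentences, plus resolution of possessive
   pronouns over conjoined protein antecedents — high-precision patterns
   then run on the simple sentences.
5. **Impact linking**: a *temporal* relation when the participial
   "phosphorylated X" fills an interactant slot, a *causal* relation when
   a cue (facilitates, results in, increased, abolishes, ...) connects the
   phosphorylation to the PPI, with polarity increase/decrease/unspecified.
   Opposite-directionality statements (PPI first, phosphorylation second)
   are rejected.
6. **Outputs**: `<kinase, substrate, site, interactant, ppi_type,
   relation_type, polarity>` tuples (JSON-lines/CSV), Cytoscape-compatible
   XGMML phosphoform networks, and two-level evaluation (subsection and
   unique-tuple) with P = 100·TP/(TP+FP), R = 100·TP/(TP+FN),
   F = 2PR/(P+R).

Protein names are normalized to accessions by dictionary lookup against a
two-column lexicon after case/punctuation/Greek-letter normalization.
A deterministic synthetic-corpus generator (`efip.corpus_fixtures`)
produces JATS articles with planted tuples and matching gold annotations
so the whole pipeline is testable offline.

## Worked example

```python
from efip import Lexicon, Pipeline

lexicon = Lexicon({"Bax": ["Q07812"], "Pin1": ["Q13526"]})
pipe = Pipeline(lexicon=lexicon)
result = pipe.run_text(
    "These data suggest that Bax Thr167 is phosphorylated in response to "
    "cytokine treatment, and that Thr167 phosphorylation facilitates Bax "
    "binding to Pin1."
)
for t in result.tuples:
    print(t.kinase, t.substrate, t.sites, t.interactant,
          t.ppi_type, t.relation_type, t.polarity)
```

prints

```
None Bax ('Thr-167',) Pin1 binding causal increase
```

meaning: the phosphoform Bax Thr-167 binds Pin1, the phosphorylation
*increases* that binding (cue "facilitates"), and no kinase is stated.
The `examples/` directory has one short script per capability
(extraction, simplification, network export, JATS parsing, synthetic
evaluation), each printing the numbers it computes.

A thin CLI wraps the same functions:

```bash
efip extract article.nxml --lexicon names.tsv --jsonl tuples.jsonl
efip evaluate --gold gold.json --pred tuples.jsonl --level tuple
efip fixtures --seed 7 --out corpus/
efip export-network --tuples tuples.jsonl --xgmml net.xgmml
```

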