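# Methods

This note records what the pipeline computes, the linguistic and numerical
choices behind it, and what its tests do and do not demonstrate.

## Processing model

The unit of processing and evaluation is the **subsection**: a heading plus
the prose before the next heading of a JATS article (abstracts are a single
subsection). Ancestor headings and the article title are inherited, because
a bare subsection heading ("GST pull down assay") is often uninformative
without its parent ("Materials and Methods"). Section types come from the
source's `sec-type` attribute when it maps onto the nine-label set, else
from case-insensitive matching of the heading and its ancestors against
canonical names, else `other`. Tables and reference lists are skipped — the
extractors target prose and figure captions; whether mining table bodies
would add recall is untested here and deliberately out of scope.

Character offsets are 0-based and half-open in entity-decoded text, so any
span slices its sentence exactly. Sentence segmentation is a deterministic
rule list (terminator + following capital/digit, with a protected-token
lexicon for "e.g.", "Fig.", "et al.", initials and decimals) rather than a
statistical segmenter: the pipeline's behavior must be reproducible
byte-for-byte, and the domain's hard cases (residue lists like "Ser-309
Ser-361") contain no terminator at all.

## Event extraction

**Phosphorylation.** Extraction is anchored on phosphorylation triggers and
fills slots by walking left/right over pre-detected protein and site spans:
passive ("X (Site) is phosphorylated by K at S"), nominal ("phosphorylation
of X and Y at S by K", "Site phosphorylation"), kinase pre-modifier
("K-mediated phosphorylation of X"), active ("K phosphorylates X"), and
participial ("phosphorylated X", "X, when phosphorylated,"). Conjoined
substrates yield one event per substrate. Negated triggers ("not
phosphorylated", "unphosphorylated") are dropped: an extracted tuple
asserts that the phosphorylation occurred, and asserting a negated event
would be wrong in the worst way.

Because kinase, substrate and site rarely co-occur in one sentence, partial
events are **merged within the subsection** (never across subsections —
each subsection is processed as an independent short document). Merging
keys on accession when the name is mapped, else on the normalized surface
name. Kinase-only and site-only events donate their slot to the nearest
preceding substrate-bearing event (ties broken by recency — the most recent
preceding event wins; with no stated rule for orphan sites, attaching to
the most recently discussed substrate is the conservative reading).
Conflicting donors multiply: two kinases for one substrate produce two
completed events, never an overwrite. Merging is idempotent and loses no
substrate occurrence.

**PPI.** Eleven trigger families (binding, interaction, complex,
association, dissociation, dimerization, affinity, precipitation,
recruitment, release, sequestering) with shipped morphological variants in
an editable two-column table. Matching is token lookup against the variant
table, not substring search ("outbound" never fires "bound"). Argument
patterns per trigger form: "T of A with/to/from/by/for B", "T between A and
B", "A('s) T with B", "A interacts/binds/was dissociated from B", "A–B
complex" (an adjacent pair is required; bare adjectival "complex" is
ignored), unary dimerization marked homodimer. The variant table is a
superset judgment for the five families whose full variant lists are not
fixed anywhere; being data, it can be trimmed or extended without code
changes. Complexes, protein regions and protein classes are recognized by
head nouns ("domain", "family", "proteins") adjacent to a name.

## Simplification

High-precision patterns only fire reliably on simple clauses, so complex
sentences are decomposed first: "that"-clause coordination under reporting
verbs, verb-phrase coordination and serial VP lists (shared subject copied
into each conjunct), participial adjuncts promoted to finite clauses
("resulting in" → "results in"), non-restrictive relative clauses and
appositives split off, and ≥3-way subject lists distributed. Constructs
nest to depth 2; anything deeper passes through unsplit and flagged, which
trades recall for not mangling sentences the splitter does not understand.

One deliberate rule: when the first conjunct contains a mediating
"via/through the *phosphorylation* of ..." phrase, that event nominal (not
the surface subject) becomes the subject of the following conjuncts. In
"Addition of BSO induced apoptosis via the phosphorylation of A and B,
resulting in their dissociation, and increased the interaction between A
and C", the follow-on predicates are about the phosphorylation, not about
"Addition of BSO"; copying the surface subject would produce truthful but
useless sentences and lose both impact relations. Only the shared subject
(and converted finite verb) is copied into conjuncts; prepositional
adjuncts of the first conjunct are not distributed, since nothing
downstream needs them and blind copying risks ungrammatical or wrong
attachments.

Pronoun resolution is deliberately minimal: only possessives ("their",
"its") directly modifying an interaction nominal, resolved to the nearest
preceding conjoined protein noun phrase (all conjuncts). That is the one
coreference configuration the impact patterns need; general coreference is
out of scope and unresolvable pronouns are left intact and flagged.

## Impact linking

Within one simple sentence, each PPI event yields at most one relation:

* **causal** when a cue from the impact lexicon sits between a
  phosphorylation trigger (before the cue) and the PPI trigger (after it).
  The cue's polarity describes the stated PPI event itself — a facilitated
  *dissociation* is an increase of a dissociation event, not a decrease of
  binding. Neutral cues ("results in", "leads to") and unknown cues give
  `unspecified`; polarity is never guessed.
* **temporal** when the participial "phosphorylated X" (or "X, when
  phosphorylated,") fills an interactant slot — the phosphorylation
  precedes the interaction but no change is asserted, so polarity is
  `unspecified` there too (the graph export shows "+"/"−" only when a
  causal cue states a direction).

Configurations with the PPI before the cue and the phosphorylation after
it ("binding of A to B induces phosphorylation of A") produce no relation:
reversed directionality is the characteristic false-positive class of this
task and is rejected structurally rather than filtered afterwards. When
the phosphorylation expression has no substrate of its own ("Thr167
phosphorylation facilitates Bax binding to Pin1"), the phospho-side
interactant is adopted as substrate, and subsection-level merging then
completes kinase/site. Hedged statements ("may", "whether", "we
investigated whether") are extracted and tagged `hedged` instead of
dropped — the distinction is exposed, the recall kept. Cross-sentence
impact relations are not attempted in this version; relation search is
strictly within one simple sentence.

Final tuples deduplicate on the normalized identity (kinase, substrate,
site-set, interactant, ppi_type, relation_type, polarity), concatenating
provenance. A substrate with no stated site becomes the `phosphoX`
placeholder phosphoform.

## Networks

Tuples merge into a typed graph: one base node per protein, one
**phosphoform** node per distinct site-set (including `phosphoX`),
`phosphoform_of` edges to the base, `phosphorylates` edges from kinases,
and `association`/`dissociation` edges (dashed flag for dissociation) to
interactants carrying polarity symbol, support count and document ids.
Node identity keys on accession when available, else normalized surface
name — the same rule as tuple deduplication, so normalization failures
degrade gracefully to surface identity. XGMML export orders elements by id
and round-trips losslessly through the bundled reader; colors and shapes
are left to Cytoscape.

## Evaluation

Subsection level scores whether a subsection contains at least one tuple
on each side (TP/TN/FP/FN); tuple level scores unique tuples, where a
prediction matches a gold tuple if it agrees on substrate, interactant and
relation type, and on kinase/site/ppi_type **wherever the gold specifies
them**. Gold-absent kinase/site slots are wildcards: the corpus format
leaves them empty when the text does not state them (well under half of
gold tuples carry a kinase or a site), yet full tuples are still scored —
wildcarding is the only consistent reading. A true negative is undefined
at tuple level. Uniqueness keys on the five named slots (kinase,
substrate, site, interactant, relation type); ppi_type and polarity
constrain matching but not uniqueness. Matching is maximum bipartite
matching under the wildcard predicate, so greedy order cannot cost a TP.
Metrics are on the percent scale with one-decimal round-half-up;
zero-denominator cases return 0 and are flagged degenerate.

## Synthetic corpus generator

The generator is first-class, tested code. Templates (YAML data) cover
exactly the pattern families the extractors implement — passive+nominal
causal, kinase pre-modifier with "between", nominal "of ... with" causal,
participial temporal, cross-sentence completion, and conjoined-substrate
pronoun causal — plus distractors: no-relation sentences, phospho-only
sentences, opposite-directionality sentences, and hedged sentences (which
carry gold tuples tagged hedged). Defaults (3 documents, 12 planted
relations, distractor rate 0.3, 10% hedged) give every template and
distractor type a realistic chance to appear in a small corpus while every
document still exercises all nine section types; the acceptance script
scales this to 5 documents / 30 relations / rate 0.4. One seeded generator
drives all sampling, and the same spec yields byte-identical files.
Synthetic protein names (SUBn/KINn/INTn) are unique per planted relation
so that subsection-level merging cannot leak slots between relations.

What fixtures do **not** emulate: the lexical and syntactic variety of
real full-text prose, deep nesting, anaphora beyond possessives,
cross-sentence relations, and annotation noise. Perfect fixture scores
therefore demonstrate that the machinery is wired correctly end to end —
they say nothing about corpus-level accuracy on real articles, which
depends on rule coverage this package does not claim to reproduce in full.

## Numerical and degenerate-input choices

* Name normalization: case-fold, strip subscript markers, unify Greek
  letters with spelled-out forms, drop hyphens/spaces ("MCL-1" = "MCL1",
  "14-3-3σ" = "14-3-3sigma"). Ambiguous names keep all accessions.
* Site canonicalization: every surface form ("S280", "Ser280", "serine
  280") renders as "Ser-280". Single-letter forms are limited to S/T/Y —
  "H3" is a histone name in practice.
* Empty inputs are legal everywhere: empty text → no sentences; empty
  lexicon → pattern-derived mentions only; no trigger → no events; empty
  tuple set → empty network; malformed XML raises with the line number.
* Tie-breaks are deterministic by construction (document order, then
  recency), and all outputs serialize in sorted or insertion order so
  repeated runs are byte-identical.

## Known limitations

Rule coverage is intentionally the high-precision core, not a full
reimplementation of a production phosphorylation extractor; complex
sentences beyond nesting depth 2 pass through unsplit; relation search is
single-sentence; species are not disambiguated; abbreviation definitions
are not detected; and the dictionary normalizer does nothing for names
absent from the lexicon beyond flagging them for manual correction.
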