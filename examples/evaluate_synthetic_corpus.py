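"""Generate a synthetic gold corpus, run the pipeline, and score it.

The generator plants template sentences (with known tuples) into small
JATS articles, together with no-relation distractors, hedged statements
and opposite-directionality sentences ("binding ... induces
phosphorylation") that a correct directionality check must reject.
Scoring follows the two-level scheme: whole subsections, then unique
tuples with gold-absent kinase/site slots as wildcards.
"""

from efip import (FixtureSpec, Pipeline, compute_metrics, generate,
                  match_tuples, parse_jats)

spec = FixtureSpec(seed=7, n_docs=4, n_relations=20, distractor_rate=0.4)
fixture = generate(spec)
n_gold = sum(len(g.tuples) for g in fixture.gold.values())
print(f"{len(fixture.documents)} documents, {n_gold} gold tuples")

pipeline = Pipeline(lexicon=fixture.lexicon)
predicted = {}
for xml in fixture.documents.values():
    predicted.update(pipeline.predictions_by_subsection(parse_jats(xml)))

for level in ("subsection", "tuple"):
    counts = match_tuples(fixture.gold, predicted, level=level)
    m = compute_metrics(counts)
    tn = f" TN={counts.TN}" if counts.TN is not None else ""
    print(f"{level:>10}: P={m.P} R={m.R} F={m.F} "
          f"(TP={counts.TP} FP={counts.FP} FN={counts.FN}{tn})")

# On template-covered fixtures the pipeline recovers every planted tuple
# and fires on no distractor, so both levels score P=R=100 — evidence of
# correct wiring, not of corpus-scale accuracy on real prose.
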