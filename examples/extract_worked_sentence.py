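"""Extract a phospho-dependent interaction from a single sentence.

The sentence states that phosphorylation of Bax at Thr-167 facilitates
its binding to Pin1.  The pipeline segments, simplifies, extracts the
phosphorylation and PPI events, links them with the causal cue, and
completes the site slot by merging across the two clauses.
"""

from efip import Lexicon, Pipeline

sentence = (
    "These data suggest that Bax Thr167 is phosphorylated in response to "
    "cytokine treatment, and that Thr167 phosphorylation facilitates Bax "
    "binding to Pin1."
)

lexicon = Lexicon({"Bax": ["Q07812"], "Pin1": ["Q13526"]})
result = Pipeline(lexicon=lexicon).run_text(sentence)

for t in result.tuples:
    print(f"kinase={t.kinase}  substrate={t.substrate}  sites={t.sites}  "
          f"interactant={t.interactant}  ppi={t.ppi_type}  "
          f"relation={t.relation_type}  polarity={t.polarity}")

# Expected output:
#   kinase=None  substrate=Bax  sites=('Thr-167',)  interactant=Pin1
#   ppi=binding  relation=causal  polarity=increase
# i.e. the phosphoform Bax Thr-167 binds Pin1, and the phosphorylation
# increases that binding ("facilitates"); no kinase is stated.
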