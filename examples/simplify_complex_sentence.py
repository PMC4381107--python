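"""Decompose a complex coordination sentence into simple sentences.

One phosphorylation event here impacts two PPI events (a dissociation
referred to by the pronoun "their", and an interaction), connected in a
verb-phrase coordination.  The simplifier splits the conjuncts, copies
the mediating phosphorylation nominal in as subject, and the pronoun
resolver then rewrites "their dissociation" over its conjoined
antecedents.
"""

from efip import Lexicon, resolve_possessive, simplify

sentence = (
    "Addition of BSO induced mitochondrial injury-mediated apoptosis via "
    "the phosphorylation of BIM_EL and MCL-1, resulting in their "
    "dissociation, and increased the interaction between BIM_EL and BAX."
)

lexicon = Lexicon({"BIM_EL": ["O43521"], "MCL-1": ["Q07820"],
                   "BAX": ["Q07812"]})

simple = simplify(sentence, lexicon)
print("simplified:")
for s in simple:
    print("  ", s.text)

print("after pronoun resolution:")
for s in resolve_possessive(simple, lexicon):
    print("  ", s.text)

# The three simplified sentences isolate (1) the treatment clause,
# (2) the phosphorylation -> dissociation impact and (3) the
# phosphorylation -> interaction impact; resolution turns "their
# dissociation" into "the dissociation of BIM_EL and MCL-1" so the PPI
# argument patterns can fill both interactant slots.
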