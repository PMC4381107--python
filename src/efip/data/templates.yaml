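# Sentence templates for the synthetic fixture generator.
#
# Placeholders: {S} substrate, {S2} second substrate, {K} kinase,
# {I} interactant, {site} phosphosite, {cue} causal cue,
# {ppi_noun}/{ppi_prep}/{ppi_verb} trigger-family surface forms.
# "families" restricts which PPI families a template may draw.
# Each positive/hedged instantiation plants exactly one gold tuple.
positive:
  - id: passive_then_nominal_causal
    text: "{S} is phosphorylated by {K} at {site}, and the phosphorylation of {S} {cue} its {ppi_noun} {ppi_prep} {I}."
    relation: causal
    families: [binding, interaction, association]
  - id: premod_between_causal
    text: "{K}-mediated phosphorylation of {S} at {site} {cue} the {ppi_noun} between {S} and {I}."
    relation: causal
    families: [interaction, association]
  - id: nominal_of_with_causal
    text: "The phosphorylation of {S} at {site} by {K} {cue} the {ppi_noun} of {S} {ppi_prep} {I}."
    relation: causal
    families: [binding, interaction, association, dissociation]
  - id: participial_temporal
    text: "Phosphorylated {S} {ppi_verb} {I}."
    relation: temporal
    families: [interaction, association, binding, dissociation]
  - id: cross_sentence_temporal
    text: "{S} is phosphorylated at {site} by {K}. Phosphorylated {S} {ppi_verb} {I}."
    relation: temporal
    families: [interaction, association]
  - id: conjoined_pronoun_causal
    text: "The phosphorylation of {S} and {I} {cue} their dissociation."
    relation: causal
    families: [dissociation]
    siteless: true
distractor:
  - id: reverse_directionality
    text: "The {ppi_noun} of {S} {ppi_prep} {I} {cue} the phosphorylation of {S}."
    families: [binding, interaction]
  - id: no_event
    text: "{S} regulates the expression of {I} in cells."
  - id: phospho_only
    text: "{S} is phosphorylated by {K} at {site} in cells."
hedged:
  - id: hedged_temporal
    text: "We investigated whether phosphorylated {S} {ppi_verb} {I}."
    relation: temporal
    families: [interaction, association]
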