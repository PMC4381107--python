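import pytest

from efip import Lexicon, Pipeline

# The five printed example sentences the extractors must handle verbatim.
BAX_SENTENCE = (
    "These data suggest that Bax Thr167 is phosphorylated in response to "
    "cytokine treatment, and that Thr167 phosphorylation facilitates Bax "
    "binding to Pin1."
)
CHK1_SENTENCE = (
    "Chk1 is directly phosphorylated by Akt at Ser280, a modification that "
    "results in cytoplasmic sequestration."
)
BSO_SIMPLE_SENTENCE = (
    "BSO induces the interaction of phosphorylated BIM_EL with BAX."
)
TEMPORAL_SENTENCE = (
    "Phosphorylated BIM_EL was dissociated from MCL1 and interacted with "
    "BAX."
)
BSO_COMPLEX_SENTENCE = (
    "Addition of BSO induced mitochondrial injury-mediated apoptosis via "
    "the phosphorylation of BIM_EL and MCL-1, resulting in their "
    "dissociation, and increased the interaction between BIM_EL and BAX."
)

BSO_SIMPLIFIED = [
    "Addition of BSO induced mitochondrial injury-mediated apoptosis via "
    "the phosphorylation of BIM_EL and MCL-1.",
    "The phosphorylation of BIM_EL and MCL-1 results in their dissociation.",
    "The phosphorylation of BIM_EL and MCL-1 increased the interaction "
    "between BIM_EL and BAX.",
]


@pytest.fixture(scope="session")
def lexicon():
    """Protein-name lexicon covering the example sentences (accessions are
    fixture data)."""
    lex = Lexicon()
    for name, acc in [
        ("Bax", "Q07812"), ("BAX", "Q07812"), ("Pin1", "Q13526"),
        ("Chk1", "O14757"), ("Akt", "P31749"), ("BIM_EL", "O43521"),
        ("MCL-1", "Q07820"), ("MCL1", "Q07820"), ("CDC25B", "P30305"),
        ("CDK5", "Q00535"), ("p38 MAPK", "Q16539"), ("MAPKAPK2", "P49137"),
        ("14-3-3sigma", "P31947"), ("COP1", "Q8NHY2"), ("ATM", "Q13315"),
    ]:
        lex.add(name, acc)
    return lex


@pytest.fixture(scope="session")
def pipeline(lexicon):
    return Pipeline(lexicon=lexicon)
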