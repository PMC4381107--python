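"""PPI event extraction via the trigger-family lexicon."""

import pytest

from conftest import BSO_COMPLEX_SENTENCE
from efip import (detect_mentions, expand_trigger_variants, extract_ppi,
                  resolve_possessive, simplify)
from efip.ppi_events import PPI_FAMILIES, TriggerLexicon, default_triggers


def ppis_for(text, lexicon):
    mentions = detect_mentions(text, lexicon)
    return extract_ppi(text, mentions)


def summary(ev):
    return (ev.interactant_a.surface, ev.interactant_b.surface, ev.ppi_type)


class TestTriggerLexicon:
    def test_dissociation_variants(self):
        got = expand_trigger_variants("dissociation")
        assert {"dissociate", "dissociates", "dissociated", "dissociating",
                "dissociation"} <= got
        # every variant shares the family stem after affix stripping
        assert all(v.startswith("dissociat") for v in got)

    def test_binding_includes_irregular_forms(self):
        assert {"bind", "binds", "bound", "binding"} <= \
            expand_trigger_variants("binding")

    @pytest.mark.parametrize("bad", ["", "unknown_family", "phosphorylation"])
    def test_unknown_family_raises(self, bad):
        with pytest.raises(ValueError):
            expand_trigger_variants(bad)

    def test_variant_maps_to_exactly_one_family(self):
        lex = default_triggers()
        seen = {}
        for family in PPI_FAMILIES:
            for v in lex.variants(family):
                assert v not in seen, f"{v} in {seen.get(v)} and {family}"
                seen[v] = family

    def test_conflicting_assignment_rejected(self):
        lex = TriggerLexicon()
        lex.add("docks", "binding")
        with pytest.raises(ValueError):
            lex.add("docks", "association")


class TestExtractPpi:
    @pytest.mark.parametrize("text,expected", [
        ("BSO induces the interaction of phosphorylated BIM_EL with BAX",
         ("BIM_EL", "BAX", "interaction")),
        ("Phosphorylated BIM_EL was dissociated from MCL1",
         ("BIM_EL", "MCL1", "dissociation")),
        ("Bax binding to Pin1", ("Bax", "Pin1", "binding")),
        ("the interaction between BIM_EL and BAX",
         ("BIM_EL", "BAX", "interaction")),
        ("the association of CDC25B with 14-3-3σ",
         ("CDC25B", "14-3-3σ", "association")),
        ("recruitment of Chk1 to Pin1", ("Chk1", "Pin1", "recruitment")),
        ("sequestration of Chk1 by Pin1", ("Chk1", "Pin1", "sequestering")),
        ("the affinity of Bax for Pin1", ("Bax", "Pin1", "affinity")),
        ("co-precipitation of Bax with Pin1",
         ("Bax", "Pin1", "precipitation")),
        ("Chk1 was released from Pin1", ("Chk1", "Pin1", "release")),
        ("the dissociation of BIM_EL and MCL-1",
         ("BIM_EL", "MCL-1", "dissociation")),
        ("Bax interacts with Pin1", ("Bax", "Pin1", "interaction")),
        ("the BIM_EL-BAX complex", ("BIM_EL", "BAX", "complex")),
    ])
    def test_patterns(self, text, expected, lexicon):
        assert expected in {summary(e) for e in ppis_for(text, lexicon)}

    def test_no_trigger_no_event(self, lexicon):
        assert ppis_for("Bax and Pin1 were expressed in cells", lexicon) == []

    def test_token_matching_avoids_substrings(self, lexicon):
        # "outbound" contains "bound" but is not a trigger token
        assert ppis_for("Bax outbound Pin1 traffic was measured",
                        lexicon) == []

    def test_bare_adjectival_complex_ignored(self, lexicon):
        assert ppis_for("This complex question involves Bax", lexicon) == []

    def test_phospho_marked_flag(self, lexicon):
        evs = ppis_for("the interaction of phosphorylated BIM_EL with BAX",
                       lexicon)
        assert evs[0].a_phospho_marked and not evs[0].b_phospho_marked

    def test_homodimer(self, lexicon):
        evs = ppis_for("phosphorylation induces the dimerization of Bax",
                       lexicon)
        assert summary(evs[0]) == ("Bax", "Bax", "dimerization")
        assert evs[0].homodimer

    def test_trigger_family_membership(self, lexicon):
        """Every returned event's trigger surface belongs to exactly one
        lexicon family."""
        lex = default_triggers()
        for text in ["Bax binding to Pin1", "Chk1 was released from Pin1"]:
            for ev in ppis_for(text, lexicon):
                tok = text[ev.trigger[0]:ev.trigger[1]]
                assert lex.family_of(tok) == ev.ppi_type

    def test_stable_under_simplification(self, lexicon):
        """For an already-simple sentence, extract(simplify(s)) covers
        extract(s)."""
        text = "Phosphorylated BIM_EL was dissociated from MCL1."
        direct = {summary(e) for e in ppis_for(text, lexicon)}
        via_simplify = set()
        for simple in simplify(text, lexicon):
            mentions = detect_mentions(simple.text, lexicon)
            via_simplify |= {summary(e)
                             for e in extract_ppi(simple, mentions)}
        assert direct <= via_simplify

    def test_bso_complex_sentence_yields_two_ppi_events(self, lexicon):
        """simplify + resolve + extract finds exactly the dissociation and
        the BIM_EL-BAX interaction in the complex coordination sentence."""
        found = []
        simples = resolve_possessive(
            simplify(BSO_COMPLEX_SENTENCE, lexicon), lexicon)
        for simple in simples:
            mentions = detect_mentions(simple.text, lexicon)
            found.extend(summary(e) for e in extract_ppi(simple, mentions))
        assert sorted(found) == [("BIM_EL", "BAX", "interaction"),
                                 ("BIM_EL", "MCL-1", "dissociation")]
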