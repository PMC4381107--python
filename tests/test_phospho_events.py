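"""Phosphorylation event extraction and cross-sentence merging."""

import pytest

from efip import detect_mentions, detect_sites, extract_phospho, merge_events


def events_for(text, lexicon):
    mentions = detect_mentions(text, lexicon)
    sites = detect_sites(text)
    return extract_phospho(text, mentions, sites)


def summary(ev):
    return (ev.kinase.surface if ev.kinase else None,
            ev.substrate.surface if ev.substrate else None,
            tuple(s.canonical for s in ev.sites))


class TestExtractPhospho:
    def test_passive_with_kinase_and_site(self, lexicon):
        evs = events_for(
            "Chk1 is directly phosphorylated by Akt at Ser280, a "
            "modification that results in cytoplasmic sequestration.",
            lexicon)
        assert summary(evs[0]) == ("Akt", "Chk1", ("Ser-280",))

    def test_nominal_conjoined_substrates(self, lexicon):
        evs = events_for("the phosphorylation of BIM_EL and MCL-1", lexicon)
        assert {summary(e) for e in evs} == {
            (None, "BIM_EL", ()), (None, "MCL-1", ())}

    def test_apposed_site_passive(self, lexicon):
        evs = events_for("Bax Thr167 is phosphorylated", lexicon)
        assert summary(evs[0]) == (None, "Bax", ("Thr-167",))

    def test_site_only_nominal(self, lexicon):
        evs = events_for("Thr167 phosphorylation facilitates Bax binding "
                         "to Pin1", lexicon)
        assert any(e.substrate is None and
                   [s.canonical for s in e.sites] == ["Thr-167"]
                   for e in evs)

    def test_premodifier_kinase(self, lexicon):
        evs = events_for("ATM-mediated phosphorylation of COP1 at S387",
                         lexicon)
        assert summary(evs[0]) == ("ATM", "COP1", ("Ser-387",))

    def test_active_voice(self, lexicon):
        evs = events_for("Akt phosphorylates Chk1 at Ser280", lexicon)
        assert summary(evs[0]) == ("Akt", "Chk1", ("Ser-280",))

    def test_participial(self, lexicon):
        evs = events_for("Phosphorylated BIM_EL interacted with BAX",
                         lexicon)
        assert evs[0].form == "participial"
        assert evs[0].substrate.surface == "BIM_EL"

    def test_reduced_relative(self, lexicon):
        evs = events_for("CDC25B phosphorylated by CDK5 binds 14-3-3σ",
                         lexicon)
        assert summary(evs[0]) == ("CDK5", "CDC25B", ())

    @pytest.mark.parametrize("text", [
        "Bax is not phosphorylated by Akt",
        "unphosphorylated Bax binds Pin1",
        "Bax was never phosphorylated in cells",
    ])
    def test_negated_triggers_dropped(self, text, lexicon):
        assert events_for(text, lexicon) == []

    def test_no_trigger_no_event(self, lexicon):
        assert events_for("Bax binds Pin1 in cells", lexicon) == []


class TestMergeEvents:
    def two_sentence_events(self, lexicon):
        a = events_for("Chk1 is phosphorylated at Ser280", lexicon)
        for e in a:
            e.sentence_ref = ("S1", 0)
            e.provenance = [("S1", 0)]
        b = events_for("Chk1 is phosphorylated by Akt", lexicon)
        for e in b:
            e.sentence_ref = ("S1", 1)
            e.provenance = [("S1", 1)]
        return a + b

    def test_cross_sentence_completion(self, lexicon):
        merged = merge_events(self.two_sentence_events(lexicon))
        assert len(merged) == 1
        assert summary(merged[0]) == ("Akt", "Chk1", ("Ser-280",))
        assert merged[0].merged
        assert len(merged[0].provenance) == 2

    def test_single_complete_event_unchanged(self, lexicon):
        evs = events_for("Chk1 is phosphorylated by Akt at Ser280", lexicon)
        merged = merge_events(evs)
        assert len(merged) == 1
        assert summary(merged[0]) == ("Akt", "Chk1", ("Ser-280",))
        assert not merged[0].merged

    def test_conflicting_kinases_yield_two_tuples(self, lexicon):
        a = events_for("CDC25B is phosphorylated by CDK5 at Ser280", lexicon)
        b = events_for("CDC25B is phosphorylated by MAPKAPK2", lexicon)
        for i, e in enumerate(a + b):
            e.sentence_ref = ("S1", i)
        merged = merge_events(a + b)
        kinases = {e.kinase.surface for e in merged}
        assert kinases == {"CDK5", "MAPKAPK2"}
        assert all(summary(e)[1] == "CDC25B" for e in merged)
        assert all(summary(e)[2] == ("Ser-280",) for e in merged)

    def test_merge_idempotent(self, lexicon):
        once = merge_events(self.two_sentence_events(lexicon))
        twice = merge_events(once)
        assert [summary(e) for e in twice] == [summary(e) for e in once]

    def test_no_substrate_occurrence_lost(self, lexicon):
        evs = self.two_sentence_events(lexicon) + \
            events_for("the phosphorylation of BIM_EL and MCL-1", lexicon)
        merged = merge_events(evs)
        in_subs = {e.substrate.key for e in evs if e.substrate}
        out_subs = {e.substrate.key for e in merged if e.substrate}
        assert in_subs <= out_subs

    def test_single_sentence_equals_merged_when_complete(self, lexicon):
        """When kinase/substrate/site co-occur in one sentence, merging
        changes nothing."""
        evs = events_for("Akt phosphorylates Chk1 at Ser280", lexicon)
        assert [summary(e) for e in merge_events(evs)] == \
            [summary(e) for e in evs]

    def test_site_only_attaches_to_nearest_preceding(self, lexicon):
        a = events_for("Bax is phosphorylated in cells", lexicon)
        b = events_for("Chk1 is phosphorylated in cells", lexicon)
        c = events_for("Ser280 phosphorylation was observed", lexicon)
        for refno, batch in enumerate((a, b, c)):
            for e in batch:
                e.sentence_ref = ("S1", refno)
                e.provenance = [("S1", refno)]
        merged = merge_events(a + b + c)
        by_sub = {summary(e)[1]: e for e in merged if e.substrate}
        assert summary(by_sub["Chk1"])[2] == ("Ser-280",)
        assert summary(by_sub["Bax"])[2] == ()
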