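"""Precision/recall/F-measure and gold-corpus matching."""

import itertools

import pytest
from hypothesis import given, settings, strategies as st

from efip import (ConfusionCounts, EFIPTuple, GoldAnnotation, GoldTuple,
                  compute_metrics, load_gold, match_tuples)
from efip.evaluation import tuple_matches


def pred(substrate="Bax", interactant="Pin1", relation="causal",
         kinase=None, sites=(), ppi="binding", sub_id="S1"):
    return EFIPTuple(substrate=substrate, interactant=interactant,
                     relation_type=relation, kinase=kinase,
                     sites=tuple(sites), ppi_type=ppi, sub_id=sub_id)


class TestComputeMetrics:
    def test_tuple_level_published_counts(self):
        m = compute_metrics(ConfusionCounts(TP=208, FP=17, FN=64))
        assert (m.P, m.R, m.F) == (92.4, 76.5, 83.7)

    def test_subsection_level_published_counts(self):
        m = compute_metrics(ConfusionCounts(TP=89, TN=4, FP=7, FN=0))
        assert (m.P, m.R, m.F) == (92.7, 100.0, 96.2)

    def test_zero_division_convention(self):
        m = compute_metrics(ConfusionCounts(TP=0, FP=0, FN=0))
        assert (m.P, m.R, m.F) == (0.0, 0.0, 0.0)
        assert m.degenerate

    @given(tp=st.integers(0, 500), fp=st.integers(0, 500),
           fn=st.integers(0, 500))
    @settings(max_examples=200, derandomize=True)
    def test_f_between_p_and_r(self, tp, fp, fn):
        m = compute_metrics(ConfusionCounts(TP=tp, FP=fp, FN=fn))
        if m.P > 0 and m.R > 0:
            assert min(m.P, m.R) - 0.1 <= m.F <= max(m.P, m.R) + 0.1

    @given(tp=st.integers(1, 500), err=st.integers(0, 500))
    @settings(max_examples=100, derandomize=True)
    def test_p_equals_r_implies_f(self, tp, err):
        m = compute_metrics(ConfusionCounts(TP=tp, FP=err, FN=err))
        assert m.P == m.R == m.F


class TestTupleMatching:
    def test_identity_match(self):
        gold = {"S1": GoldAnnotation("S1", [GoldTuple(
            substrate="Bax", interactant="Pin1", relation_type="causal",
            site="Thr-167")])}
        predicted = {"S1": [pred(sites=("Thr-167",))]}
        counts = match_tuples(gold, predicted)
        assert (counts.TP, counts.FP, counts.FN) == (1, 0, 0)
        assert counts.TN is None  # undefined at tuple level

    def test_gold_absent_fields_are_wildcards(self):
        """Brute-force the four presence/absence combinations of gold
        kinase/site against a fully specified prediction."""
        p = pred(kinase="Akt", sites=("Ser-280",), substrate="Chk1")
        for has_kinase, has_site in itertools.product([False, True],
                                                      repeat=2):
            g = GoldTuple(substrate="Chk1", interactant="Pin1",
                          relation_type="causal",
                          kinase="Akt" if has_kinase else None,
                          site="Ser-280" if has_site else None)
            assert tuple_matches(g, p)

    def test_gold_specified_fields_constrain(self):
        g = GoldTuple(substrate="Chk1", interactant="Pin1",
                      relation_type="causal", kinase="CDK5")
        assert not tuple_matches(g, pred(substrate="Chk1", kinase="Akt"))
        assert not tuple_matches(g, pred(substrate="Chk1", kinase=None))

    def test_relation_type_must_agree(self):
        g = GoldTuple(substrate="Bax", interactant="Pin1",
                      relation_type="temporal")
        assert not tuple_matches(g, pred(relation="causal"))

    def test_name_normalization_in_matching(self):
        g = GoldTuple(substrate="MCL1", interactant="BIM_EL_",
                      relation_type="causal")
        p = pred(substrate="MCL-1", interactant="BIM_EL")
        assert tuple_matches(g, p)

    def test_counting_identities(self):
        """TP+FN = |unique gold| and TP+FP = |unique predicted| (the
        arithmetic behind 208+64=272 and 208+17=225)."""
        gold = {"S1": GoldAnnotation("S1", [
            GoldTuple(substrate="A1", interactant="B1",
                      relation_type="causal"),
            GoldTuple(substrate="A2", interactant="B2",
                      relation_type="temporal"),
            GoldTuple(substrate="A3", interactant="B3",
                      relation_type="causal"),
        ])}
        predicted = {"S1": [
            pred(substrate="A1", interactant="B1"),
            pred(substrate="A1", interactant="B1"),   # duplicate
            pred(substrate="A9", interactant="B9"),   # false positive
        ]}
        counts = match_tuples(gold, predicted)
        assert counts.TP + counts.FN == 3
        assert counts.TP + counts.FP == 2  # unique predictions
        assert (counts.TP, counts.FP, counts.FN) == (1, 1, 2)

    def test_subsection_level_hand_enumeration(self):
        """10 subsections of known composition: 3 TP, 2 FP, 1 FN, 4 TN."""
        gold = {}
        predicted = {}
        for i, (has_gold, has_pred) in enumerate(
                [(1, 1), (1, 1), (1, 1), (0, 1), (0, 1), (1, 0),
                 (0, 0), (0, 0), (0, 0), (0, 0)]):
            sid = f"S{i}"
            gold[sid] = GoldAnnotation(sid, [GoldTuple(
                substrate="A", interactant="B", relation_type="causal")]
                if has_gold else [])
            predicted[sid] = [pred(sub_id=sid)] if has_pred else []
        counts = match_tuples(gold, predicted, level="subsection")
        assert (counts.TP, counts.TN, counts.FP, counts.FN) == (3, 4, 2, 1)

    def test_conflicting_gold_entries_error(self):
        gold_list = [
            GoldAnnotation("S1", [GoldTuple(substrate="A", interactant="B",
                                            relation_type="causal")]),
            GoldAnnotation("S1", [GoldTuple(substrate="X", interactant="Y",
                                            relation_type="temporal")]),
        ]
        with pytest.raises(ValueError):
            match_tuples(gold_list, {})


class TestGoldIO:
    def test_json_and_tsv_equivalent(self, tmp_path):
        json_text = """{"subsections": [
          {"sub_id": "S1", "tuples": [
            {"substrate": "Bax", "interactant": "Pin1",
             "relation_type": "causal", "site": "Thr-167",
             "ppi_type": "binding"}]},
          {"sub_id": "S2", "tuples": []}
        ]}"""
        tsv_text = ("sub_id\tkinase\tsubstrate\tsite\tinteractant\t"
                    "ppi_type\trelation_type\thedged\n"
                    "S1\t\tBax\tThr-167\tPin1\tbinding\tcausal\t\n"
                    "S2\t\t\t\t\t\t\t\n")
        jp = tmp_path / "gold.json"
        jp.write_text(json_text)
        tp = tmp_path / "gold.tsv"
        tp.write_text(tsv_text)
        gj = load_gold(jp)
        gt = load_gold(tp)
        assert set(gj) == set(gt) == {"S1", "S2"}
        assert gj["S1"].tuples == gt["S1"].tuples
        assert gj["S2"].tuples == gt["S2"].tuples == []
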