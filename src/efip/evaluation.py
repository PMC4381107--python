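"""Gold-corpus reading, prediction matching, and precision/recall/F-measure.

Two evaluation levels are supported, mirroring how a curation-support
system is judged:

* subsection level — a subsection counts as true positive when both the
  gold annotation and the system contain at least one tuple, true
  negative when both are empty, false positive when only the system
  fires, false negative when only the gold does;
* tuple level — unique <kinase, substrate, site, interactant, relation
  type> tuples are matched; gold-absent kinase/site slots are wildcards
  (the corpus format leaves them unannotated when the text does not
  state them, yet full tuples are still scored), and a true negative is
  undefined at this level.

P = 100*TP/(TP+FP), R = 100*TP/(TP+FN), F = 2PR/(P+R); zero denominators
give 0 by convention, flagged as degenerate.  Reported on the percent
scale with one-decimal round-half-up.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path

from ._text import norm_name
from .impact_relations import EFIPTuple
from .protein_mentions import detect_sites


@dataclass
class GoldTuple:
    substrate: str
    interactant: str
    relation_type: str
    kinase: str | None = None
    site: str | None = None  # "Ser-280" or a space-separated list
    ppi_type: str | None = None
    hedged: bool = False


@dataclass
class GoldAnnotation:
    sub_id: str
    tuples: list[GoldTuple] = field(default_factory=list)


@dataclass
class ConfusionCounts:
    TP: int = 0
    TN: int | None = None  # undefined (None) at tuple level
    FP: int = 0
    FN: int = 0


@dataclass
class Metrics:
    P: float
    R: float
    F: float
    degenerate: bool = False


def _round1(x: float) -> float:
    return float(Decimal(repr(x)).quantize(Decimal("0.1"),
                                           rounding=ROUND_HALF_UP))


def compute_metrics(counts: ConfusionCounts) -> Metrics:
    """Percent-scale precision/recall/F with one-decimal round-half-up."""
    tp, fp, fn = counts.TP, counts.FP, counts.FN
    degenerate = False
    if tp + fp > 0:
        p = 100.0 * tp / (tp + fp)
    else:
        p, degenerate = 0.0, True
    if tp + fn > 0:
        r = 100.0 * tp / (tp + fn)
    else:
        r, degenerate = 0.0, True
    if p + r > 0:
        f = 2.0 * p * r / (p + r)
    else:
        f, degenerate = 0.0, True
    return Metrics(P=_round1(p), R=_round1(r), F=_round1(f),
                   degenerate=degenerate)


# --- gold corpus I/O -------------------------------------------------------

def load_gold(path: str | Path) -> dict[str, GoldAnnotation]:
    """Load gold annotations from JSON or TSV.

    Raises ``ValueError`` on duplicate sub_ids carrying conflicting
    entries.
    """
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    if path.suffix.lower() == ".json":
        return parse_gold_json(text)
    return parse_gold_tsv(text)


def _add(gold: dict[str, GoldAnnotation], sub_id: str,
         tuples: list[GoldTuple]) -> None:
    if sub_id in gold:
        prior = gold[sub_id]
        if [t.__dict__ for t in prior.tuples] != [t.__dict__ for t in tuples]:
            raise ValueError(
                f"conflicting gold entries for subsection {sub_id!r}")
        return
    gold[sub_id] = GoldAnnotation(sub_id=sub_id, tuples=tuples)


def parse_gold_json(text: str) -> dict[str, GoldAnnotation]:
    raw = json.loads(text)
    records = raw["subsections"] if isinstance(raw, dict) else raw
    gold: dict[str, GoldAnnotation] = {}
    for rec in records:
        tuples = [GoldTuple(
            substrate=t["substrate"], interactant=t["interactant"],
            relation_type=t["relation_type"], kinase=t.get("kinase"),
            site=t.get("site"), ppi_type=t.get("ppi_type"),
            hedged=bool(t.get("hedged", False)),
        ) for t in rec.get("tuples", [])]
        _add(gold, rec["sub_id"], tuples)
    return gold


_TSV_COLS = ["sub_id", "kinase", "substrate", "site", "interactant",
             "ppi_type", "relation_type", "hedged"]


def parse_gold_tsv(text: str) -> dict[str, GoldAnnotation]:
    by_sub: dict[str, list[GoldTuple]] = {}
    for line in text.splitlines():
        if not line.strip() or line.startswith("#") or \
                line.startswith("sub_id\t"):
            continue
        vals = (line.split("\t") + [""] * len(_TSV_COLS))[:len(_TSV_COLS)]
        row = dict(zip(_TSV_COLS, vals))
        bucket = by_sub.setdefault(row["sub_id"], [])
        if row["substrate"]:
            bucket.append(GoldTuple(
                substrate=row["substrate"], interactant=row["interactant"],
                relation_type=row["relation_type"],
                kinase=row["kinase"] or None, site=row["site"] or None,
                ppi_type=row["ppi_type"] or None,
                hedged=row["hedged"].lower() in ("1", "true", "yes"),
            ))
    gold: dict[str, GoldAnnotation] = {}
    for sub_id, tuples in by_sub.items():
        _add(gold, sub_id, tuples)
    return gold


def gold_to_json(gold: dict[str, GoldAnnotation]) -> str:
    return json.dumps({"subsections": [
        {"sub_id": g.sub_id,
         "tuples": [{k: v for k, v in t.__dict__.items() if v not in
                     (None, False)} for t in g.tuples]}
        for g in gold.values()
    ]}, indent=1, ensure_ascii=False)


# --- matching --------------------------------------------------------------

def _canon_sites(value) -> tuple[str, ...]:
    """Canonical sorted site set from a string, list or tuple."""
    if value is None:
        return ()
    parts = value if isinstance(value, (list, tuple)) else str(value).split()
    out = set()
    for p in parts:
        hits = detect_sites(str(p))
        if hits:
            out.update(h.canonical for h in hits)
        elif p and p != "phosphoX":
            out.add(str(p))
    return tuple(sorted(out))


def _name_eq(gold_name: str, pred_name: str | None, pred_acc: str = "") -> bool:
    if pred_name is None:
        return False
    return norm_name(gold_name) == norm_name(pred_name) or \
        (bool(pred_acc) and gold_name.strip() == pred_acc)


def tuple_matches(gold: GoldTuple, pred: EFIPTuple) -> bool:
    """Match predicate: agree on substrate, interactant and relation type,
    and on kinase/site/ppi_type wherever the gold tuple specifies them."""
    if not _name_eq(gold.substrate, pred.substrate, pred.substrate_acc):
        return False
    if not _name_eq(gold.interactant, pred.interactant, pred.interactant_acc):
        return False
    if gold.relation_type != pred.relation_type:
        return False
    if gold.kinase is not None and not _name_eq(gold.kinase, pred.kinase,
                                                pred.kinase_acc):
        return False
    if gold.site is not None:
        want = set(_canon_sites(gold.site))
        have = set(s for s in pred.sites if s != "phosphoX")
        if not want <= have:
            return False
    if gold.ppi_type is not None and gold.ppi_type != pred.ppi_type:
        return False
    return True


def _unique_gold(tuples: list[GoldTuple]) -> list[GoldTuple]:
    seen = set()
    out = []
    for t in tuples:
        key = (norm_name(t.kinase) if t.kinase else None,
               norm_name(t.substrate), _canon_sites(t.site),
               norm_name(t.interactant), t.relation_type)
        if key not in seen:
            seen.add(key)
            out.append(t)
    return out


def _unique_pred(tuples: list[EFIPTuple]) -> list[EFIPTuple]:
    # uniqueness keys on the five named slots of the tuple
    seen = set()
    out = []
    for t in tuples:
        key = (t.kinase_acc or (norm_name(t.kinase) if t.kinase else None),
               t.substrate_acc or norm_name(t.substrate),
               tuple(sorted(t.sites)),
               t.interactant_acc or norm_name(t.interactant),
               t.relation_type)
        if key not in seen:
            seen.add(key)
            out.append(t)
    return out


def _max_matching(gold: list[GoldTuple], pred: list[EFIPTuple]) -> int:
    """Maximum bipartite matching size under the wildcard predicate
    (augmenting paths; sizes here are small)."""
    adj = [[j for j, p in enumerate(pred) if tuple_matches(g, p)]
           for g in gold]
    match_p = [-1] * len(pred)

    def augment(i, seen):
        for j in adj[i]:
            if j in seen:
                continue
            seen.add(j)
            if match_p[j] < 0 or augment(match_p[j], seen):
                match_p[j] = i
                return True
        return False

    size = 0
    for i in range(len(gold)):
        if augment(i, set()):
            size += 1
    return size


def match_tuples(gold, predicted, level: str = "tuple") -> ConfusionCounts:
    """Score predictions against gold at tuple or subsection level.

    ``gold`` maps sub_id -> GoldAnnotation (an entry with no tuples is an
    annotated-negative subsection); ``predicted`` maps sub_id -> list of
    EFIPTuple.
    """
    if isinstance(gold, list):
        tmp: dict[str, GoldAnnotation] = {}
        for g in gold:
            _add(tmp, g.sub_id, g.tuples)
        gold = tmp
    if level == "subsection":
        counts = ConfusionCounts(TN=0)
        for sub_id in sorted(set(gold) | set(predicted)):
            has_gold = bool(gold.get(sub_id) and gold[sub_id].tuples)
            has_pred = bool(predicted.get(sub_id))
            if has_gold and has_pred:
                counts.TP += 1
            elif has_gold:
                counts.FN += 1
            elif has_pred:
                counts.FP += 1
            else:
                counts.TN += 1
        return counts

    counts = ConfusionCounts(TN=None)
    for sub_id in sorted(set(gold) | set(predicted)):
        gtuples = _unique_gold(gold[sub_id].tuples) if sub_id in gold else []
        ptuples = _unique_pred(predicted.get(sub_id, []))
        tp = _max_matching(gtuples, ptuples)
        counts.TP += tp
        counts.FN += len(gtuples) - tp
        counts.FP += len(ptuples) - tp
    return counts
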