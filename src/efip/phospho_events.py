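"""Extraction of <kinase, substrate, site> phosphorylation events.

The extractor is trigger-anchored and rule-based.  For every occurrence of
a phosphorylation trigger ("phosphorylation", "phosphorylated",
"phosphorylates", the "phospho-" prefix) it applies a small family of
argument patterns:

* passive — "[Chk1] is directly [phosphorylated by] [Akt] at [Ser280]"
* nominal — "phosphorylation of BIM_EL and MCL-1 (at S...) (by K)"
* pre-modifier — "ATM-mediated phosphorylation of COP1 at S387"
* active — "Akt phosphorylates Chk1 at Ser280"
* participial — "phosphorylated BIM_EL", "Bax, when phosphorylated,"
* apposed site — "Bax Thr167 is phosphorylated"
* site nominal — "Thr167 phosphorylation" (substrate filled later)

Conjoined substrates yield one event per substrate.  Negated triggers
("not phosphorylated", "unphosphorylated") are dropped: extracted tuples
assert that phosphorylation occurred.

Because kinase, substrate and site are rarely all in one sentence, partial
events are merged within a subsection: kinase-only and site-only events
donate their slot to substrate-bearing events, and conflicting donors
produce separate completed tuples rather than overwriting one another.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

from ._match import (conjunct_mentions, mention_at, mention_before,
                     negated_before, site_list_at, sites_before)
from ._text import norm_name
from .protein_mentions import ProteinMention, SiteMention

TRIGGER = re.compile(
    r"\b(?P<neg>un|non-?|de)?(?:auto)?"
    r"(?P<stem>phosphorylation|phosphorylated|phosphorylates|phosphorylate|"
    r"phosphorylating)\b"
    r"|\b(?P<prefix>phospho)-(?=\w)",
    re.IGNORECASE,
)

_BE = {"is", "are", "was", "were", "be", "been", "being", "gets", "got",
       "becomes", "became", "remains", "remained"}
_KIN_MOD = re.compile(r"(?:mediated|induced|catalyzed|catalysed|dependent)$",
                      re.IGNORECASE)


@dataclass
class PhosphoEvent:
    substrate: ProteinMention | None
    kinase: ProteinMention | None = None
    sites: list[SiteMention] = field(default_factory=list)
    trigger: tuple[int, int] = (0, 0)
    sentence_ref: tuple[str, int] = ("", 0)
    form: str = "nominal"  # nominal|passive|active|participial|prefix
    merged: bool = False
    negated: bool = False
    provenance: list[tuple[str, int]] = field(default_factory=list)

    @property
    def substrate_key(self) -> str | None:
        return self.substrate.key if self.substrate else None

    @property
    def site_keys(self) -> tuple[str, ...]:
        return tuple(sorted({s.canonical for s in self.sites}))


def _word_before(text: str, pos: int) -> tuple[str, int]:
    m = re.search(r"(\S+)\s*$", text[:pos])
    return (m.group(1), m.start(1)) if m else ("", pos)


def _after_args(text, mentions, sites, pos):
    """Parse trailing "at/on <sites>" and "by <kinase>" in either order."""
    found_sites: list[SiteMention] = []
    kinase = None
    cur = pos
    for _ in range(3):
        m = re.match(r"\s*(?:,\s*)?(at|on|by)\s+", text[cur:])
        if not m:
            break
        word = m.group(1)
        nxt = cur + m.end()
        if word in ("at", "on"):
            got, cur2 = site_list_at(sites, text, nxt)
            if not got:
                break
            found_sites.extend(got)
            cur = cur2
        else:
            k = mention_at(mentions, text, nxt)
            if k is None:
                break
            kinase = k
            cur = k.end
    return found_sites, kinase, cur


def extract_phospho(sentence, mentions, sites,
                    sub_id: str = "") -> list[PhosphoEvent]:
    """Extract phosphorylation events from one sentence.

    ``mentions`` and ``sites`` are the pre-detected protein and site spans
    of the sentence.  Returns partial or complete events; a sentence with
    no trigger returns an empty list.
    """
    text = sentence if isinstance(sentence, str) else sentence.text
    index = 0 if isinstance(sentence, str) else sentence.index
    ref = (sub_id, index)
    events: list[PhosphoEvent] = []

    def add(substrate, kinase, evsites, trig, form):
        ev = PhosphoEvent(
            substrate=substrate, kinase=kinase, sites=list(evsites),
            trigger=trig, sentence_ref=ref, form=form, provenance=[ref])
        for prior in events:
            if (prior.trigger == ev.trigger
                    and prior.substrate_key == ev.substrate_key):
                prior.kinase = prior.kinase or ev.kinase
                seen = {s.canonical for s in prior.sites}
                prior.sites.extend(s for s in ev.sites
                                   if s.canonical not in seen)
                if form == "participial":
                    prior.form = form
                return
        events.append(ev)

    for tm in TRIGGER.finditer(text):
        if tm.group("neg"):
            continue
        if negated_before(text, tm.start()):
            continue
        stem = (tm.group("stem") or "").lower()
        trig = (tm.start(), tm.end())

        if tm.group("prefix"):
            # "phospho-Bax": substrate is the prefixed name
            sub = mention_at(mentions, text, tm.end(), skippable=set())
            if sub is not None:
                s2, kin, _ = _after_args(text, mentions, sites, sub.end)
                add(sub, kin, s2, trig, "participial")
            continue

        if stem == "phosphorylation":
            kinase = None
            # pre-modifier "ATM-mediated phosphorylation"
            w, wpos = _word_before(text, tm.start())
            parts = w.split("-")
            if len(parts) >= 2 and _KIN_MOD.search(parts[-1]):
                head = "-".join(parts[:-1])
                for m in mentions:
                    if m.start == wpos and text[m.start:m.end] == head:
                        kinase = m
                        break
            # site-prefixed nominal "Thr167 phosphorylation"
            pre_sites, spos = sites_before(sites, text, tm.start())
            pre_sub = mention_before(mentions, text, spos) if pre_sites else None
            # possessive "COP1's phosphorylation"
            if pre_sub is None:
                pm = re.search(r"(\S+)[’']s\s*$", text[:tm.start()])
                if pm:
                    pre_sub = mention_before(mentions, text, pm.end(1))
            subs: list[ProteinMention] = []
            of = re.match(r"\s+of\s+", text[tm.end():])
            end_args = tm.end()
            if of:
                subs, end_args = conjunct_mentions(
                    mentions, text, tm.end() + of.end())
                if not subs:
                    # "phosphorylation of Ser10 residue of X"
                    got, cur = site_list_at(sites, text, tm.end() + of.end())
                    if got:
                        pre_sites = pre_sites + got
                        of2 = re.match(r"\s*(?:residues?\s+)?of\s+",
                                       text[cur:])
                        if of2:
                            subs, end_args = conjunct_mentions(
                                mentions, text, cur + of2.end())
            if not subs and pre_sub is not None:
                subs = [pre_sub]
            post_sites, kin2, _ = _after_args(text, mentions, sites, end_args)
            kinase = kinase or kin2
            allsites = pre_sites + post_sites
            if subs:
                for sub in subs:
                    add(sub, kinase, allsites, trig, "nominal")
            elif kinase or allsites:
                add(None, kinase, allsites, trig, "nominal")
            continue

        # verb forms
        w, wpos = _word_before(text, tm.start())
        wl = w.strip(",").lower()
        hops = 0
        be_seen = wl in _BE
        while not be_seen and hops < 2 and (wl.endswith("ly") or wl in
                                            {"directly", "also"}):
            w, wpos = _word_before(text, wpos)
            wl = w.strip(",").lower()
            be_seen = wl in _BE
            hops += 1

        if stem == "phosphorylated" and be_seen:
            # passive: "[X (Site)*] is (directly) phosphorylated (by K)(at S)"
            pre_sites, spos = sites_before(sites, text, wpos)
            sub = mention_before(mentions, text, spos if pre_sites else wpos)
            post_sites, kin, _ = _after_args(text, mentions, sites, tm.end())
            add(sub, kin, pre_sites + post_sites, trig, "passive")
            continue

        if stem == "phosphorylated":
            # ", when phosphorylated," — temporal participial on the subject
            when = re.search(r",\s*(?:when|once|if)\s*$", text[:tm.start()])
            if when:
                sub = mention_before(mentions, text, when.start())
                if sub is not None:
                    post_sites, kin, _ = _after_args(
                        text, mentions, sites, tm.end())
                    add(sub, kin, post_sites, trig, "participial")
                    continue
            # participial pre-modifier: "phosphorylated BIM_EL"
            sub = mention_at(mentions, text, tm.end(), skippable=set())
            if sub is not None:
                add(sub, None, [], trig, "participial")
                continue
            # reduced relative: "CDC25B phosphorylated by p38 (at S)"
            prev = mention_before(mentions, text, tm.start())
            post_sites, kin, _ = _after_args(text, mentions, sites, tm.end())
            if prev is not None and kin is not None:
                add(prev, kin, post_sites, trig, "participial")
            elif prev is not None:
                # active past: "Akt phosphorylated Chk1" needs an object
                obj = mention_at(mentions, text, tm.end())
                if obj is not None:
                    s2, _, _ = _after_args(text, mentions, sites, obj.end)
                    add(obj, prev, s2, trig, "active")
            continue

        # "phosphorylates"/"phosphorylate": active voice
        kin = mention_before(mentions, text, wpos if wl in {"directly", "also"}
                             else tm.start())
        obj = mention_at(mentions, text, tm.end())
        if obj is not None:
            s2, _, _ = _after_args(text, mentions, sites, obj.end)
            add(obj, kin, s2, trig, "active")

    return events


# --- cross-sentence merging ------------------------------------------------

def _order_key(ev: PhosphoEvent):
    return (ev.sentence_ref[1], ev.trigger[0])


def merge_events(events: list[PhosphoEvent], scope=None) -> list[PhosphoEvent]:
    """Complete partial events within one subsection.

    Events sharing a substrate (same accession, or same normalized surface
    when unmapped) pool their kinases and sites; kinase-only and site-only
    events donate their slot to the nearest preceding substrate-bearing
    event (ties broken by recency, i.e. the latest preceding one).  Two
    different kinases for the same substrate produce two completed tuples.
    Merging is idempotent and loses no substrate occurrence.
    """
    ordered = sorted(events, key=_order_key)
    groups: dict[str, dict] = {}
    for ev in ordered:
        key = ev.substrate_key
        if key is None:
            continue
        g = groups.setdefault(key, {
            "substrate": ev.substrate, "kinases": [], "sites": [],
            "events": [], "forms": set(),
        })
        g["events"].append(ev)
        g["forms"].add(ev.form)
        if ev.kinase is not None and ev.kinase.key not in \
                [k.key for k in g["kinases"]]:
            g["kinases"].append(ev.kinase)
        for s in ev.sites:
            if s.canonical not in [x.canonical for x in g["sites"]]:
                g["sites"].append(s)

    leftovers: list[PhosphoEvent] = []
    for ev in ordered:
        if ev.substrate_key is not None:
            continue
        # donate to nearest preceding substrate-bearing event
        candidates = [g for g in groups.values()
                      if any(_order_key(e) <= _order_key(ev)
                             for e in g["events"])]
        if not candidates:
            candidates = list(groups.values())
        if not candidates:
            leftovers.append(ev)
            continue

        def recency(g):
            prior = [_order_key(e) for e in g["events"]
                     if _order_key(e) <= _order_key(ev)]
            return max(prior) if prior else min(_order_key(e)
                                                for e in g["events"])
        target = max(candidates, key=recency)
        target["events"].append(ev)
        if ev.kinase is not None and ev.kinase.key not in \
                [k.key for k in target["kinases"]]:
            target["kinases"].append(ev.kinase)
        for s in ev.sites:
            if s.canonical not in [x.canonical for x in target["sites"]]:
                target["sites"].append(s)

    out: list[PhosphoEvent] = []
    for key, g in groups.items():
        base = g["events"][0]
        was_merged = len(g["events"]) > 1
        prov = []
        for e in g["events"]:
            for r in e.provenance or [e.sentence_ref]:
                if r not in prov:
                    prov.append(r)
        kinases = g["kinases"] or [None]
        for kin in kinases:
            out.append(PhosphoEvent(
                substrate=g["substrate"], kinase=kin, sites=list(g["sites"]),
                trigger=base.trigger, sentence_ref=base.sentence_ref,
                form=base.form, merged=was_merged or base.merged,
                provenance=prov))
    out.extend(replace(ev) for ev in leftovers)
    return out
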