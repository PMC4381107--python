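"""Span-level helpers for anchoring argument patterns on trigger words.

The extractors work procedurally: find a trigger occurrence, then walk left
and right over previously detected protein/site mention spans to fill the
argument slots.  These helpers encapsulate the walking.
"""

from __future__ import annotations

import re

# words that may sit between a preposition and its protein argument
DETS = {"the", "a", "an", "both", "either", "endogenous", "human", "native",
        "activated", "phosphorylated", "unphosphorylated", "phospho",
        "cellular", "total", "free"}

_WORD = re.compile(r"\S+")


def skip_words(text: str, pos: int, skippable: set[str] = DETS) -> int:
    """Advance ``pos`` past whitespace and skippable little words."""
    while True:
        while pos < len(text) and text[pos].isspace():
            pos += 1
        m = _WORD.match(text, pos)
        if m and m.group(0).strip(",.;:").lower() in skippable:
            pos = m.end()
            continue
        return pos


def mention_at(mentions, text: str, pos: int, skippable: set[str] = DETS):
    """Mention starting at ``pos`` after determiners/adjectives, or None."""
    pos = skip_words(text, pos, skippable)
    for m in mentions:
        if m.start == pos:
            return m
    return None


def mention_before(mentions, text: str, pos: int,
                   skippable: set[str] | None = None):
    """Mention ending just before ``pos`` (skipping given trailing words)."""
    skippable = skippable or set()
    while True:
        while pos > 0 and (text[pos - 1].isspace() or text[pos - 1] in ",("):
            pos -= 1
        for m in mentions:
            if m.end == pos:
                return m
        # try to hop over one skippable word to the left
        left = text[:pos]
        mw = re.search(r"(\S+)$", left)
        if mw and mw.group(1).strip(",.;:").lower() in skippable:
            pos = mw.start(1)
            continue
        return None


def conjunct_mentions(mentions, text: str, pos: int):
    """Parse a conjoined mention list ("A", "A and B", "A, B, and C").

    Returns (mentions, end_position); empty list when no mention starts at
    ``pos``.
    """
    out = []
    cur = pos
    sep = re.compile(r"\s*(?:,\s*(?:and\s+|or\s+)?|\s+(?:and|or)\s+)")
    while True:
        m = mention_at(mentions, text, cur)
        if m is None or m in out:
            break
        out.append(m)
        cur = m.end
        sm = sep.match(text, cur)
        if not sm:
            break
        nxt = mention_at(mentions, text, sm.end(), skippable=DETS)
        if nxt is None:
            break
        cur = sm.end()
    return out, cur


def site_list_at(sites, text: str, pos: int):
    """Collect consecutive site mentions from ``pos`` ("Ser-309 Ser-361",
    "Ser280 and Thr290", "S1, S2")."""
    out = []
    cur = pos
    sep = re.compile(r"\s*(?:,\s*(?:and\s+|or\s+)?|\s+(?:and|or)\s+|\s+|/)")
    while True:
        cur2 = skip_words(text, cur, {"the", "residue", "residues"})
        hit = None
        for s in sites:
            if s.start == cur2:
                hit = s
                break
        if hit is None:
            break
        out.append(hit)
        cur = hit.end
        sm = sep.match(text, cur)
        if sm and any(s.start >= sm.end() for s in sites):
            cur = sm.end()
        else:
            break
    return out, cur


def sites_before(sites, text: str, pos: int):
    """Collect contiguous site mentions ending just before ``pos``,
    right-to-left (for "Bax Thr167 is phosphorylated")."""
    out = []
    cur = pos
    while True:
        while cur > 0 and (text[cur - 1].isspace() or text[cur - 1] == ","):
            cur -= 1
        hit = None
        for s in sites:
            if s.end == cur:
                hit = s
                break
        if hit is None:
            break
        out.insert(0, hit)
        cur = hit.start
    return out, cur


_NEG = re.compile(r"\b(?:not|never|cannot|neither|nor|fails?\s+to|failed\s+to"
                  r"|unable\s+to|without\s+being)\s*$")


def negated_before(text: str, pos: int) -> bool:
    """True when the immediately preceding context negates a trigger."""
    left = text[:pos].rstrip()
    # hop over be-verbs/adverbs: "was not directly phosphorylated"
    for _ in range(3):
        if _NEG.search(left):
            return True
        mw = re.search(r"\b(\w+)\s*$", left)
        if mw and (mw.group(1).lower() in
                   {"is", "are", "was", "were", "be", "been", "being",
                    "directly", "rapidly", "readily", "strongly"}
                   or mw.group(1).lower().endswith("ly")):
            left = left[:mw.start(1)].rstrip()
            continue
        return False
    return False
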