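"""Shared text normalization and tokenization helpers.

Protein surface names in articles vary in case ("BAX" vs "Bax"), hyphenation
("MCL1" vs "MCL-1"), Greek-letter rendering ("14-3-3σ" vs "14-3-3sigma") and
JATS subscript styling ("BIM_EL_" for BIM with an EL subscript).  All lexicon
lookup, event merging and tuple deduplication go through :func:`norm_name`
so that these variants collapse onto one key.
"""

from __future__ import annotations

import re

GREEK = {
    "α": "alpha", "β": "beta", "γ": "gamma", "δ": "delta", "ε": "epsilon",
    "ζ": "zeta", "η": "eta", "θ": "theta", "ι": "iota", "κ": "kappa",
    "λ": "lambda", "μ": "mu", "ν": "nu", "ξ": "xi", "π": "pi", "ρ": "rho",
    "σ": "sigma", "τ": "tau", "φ": "phi", "χ": "chi", "ψ": "psi", "ω": "omega",
}

_WS = re.compile(r"\s+")


def unify_greek(text: str) -> str:
    """Replace Greek letters with their spelled-out lower-case forms."""
    return "".join(GREEK.get(ch, GREEK.get(ch.lower(), ch)) for ch in text)


def strip_subscript(text: str) -> str:
    """Normalize subscript markup such as ``BIM_EL_`` to plain ``BIM_EL``."""
    return text.strip("_")


def norm_name(name: str) -> str:
    """Canonical key for a protein surface name.

    Case-insensitive, Greek unified, subscript markers stripped, and
    hyphens/spaces removed so that "MCL-1" and "MCL1" share a key.
    """
    s = unify_greek(strip_subscript(name)).lower()
    s = s.replace("-", "").replace(" ", "")
    return s


def squeeze(text: str) -> str:
    """Collapse runs of whitespace to single spaces and trim."""
    return _WS.sub(" ", text).strip()


# Tokens (with offsets) — words keep internal hyphens/underscores/slashes so
# that names like "14-3-3" and "BIM_EL" stay whole.
_TOKEN = re.compile(r"[A-Za-z0-9Ͱ-Ͽ][\wͰ-Ͽ/'-]*|\S")


def tokenize(text: str) -> list[tuple[str, int, int]]:
    """Split ``text`` into (token, start, end) triples."""
    return [(m.group(0), m.start(), m.end()) for m in _TOKEN.finditer(text)]
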