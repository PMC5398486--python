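"""Small text-normalization helpers for ingesting hand-typed scientific tables.

Tables copied out of PDFs and manuscripts routinely carry typographic dashes
(en/em dashes, non-breaking hyphens) where ASCII minus signs are meant, and
spaces around ``InChI =``.  Every reader in this package funnels free-text
numbers and structure strings through these helpers.
"""

from __future__ import annotations

_DASHES = str.maketrans({
    "‐": "-",  # hyphen
    "‑": "-",  # non-breaking hyphen
    "‒": "-",  # figure dash
    "–": "-",  # en dash
    "—": "-",  # em dash
    "−": "-",  # true minus
})


def normalize_dashes(s: str) -> str:
    """Replace typographic dash variants with ASCII ``-``."""
    return s.translate(_DASHES)


def parse_number(s: str) -> float:
    """Parse a float, tolerating typographic minus signs and surrounding space.

    Raises ValueError with the offending text on failure.
    """
    t = normalize_dashes(s).strip()
    try:
        return float(t)
    except ValueError:
        raise ValueError(f"not a number: {s!r}") from None


def clean_inchi(s: str) -> str:
    """Canonicalize an InChI string for parsing.

    Accepts ``InChI = 1S/...`` / ``InChI=1S/...`` / bare ``1S/...`` and fixes
    dash variants inside the layered formula.
    """
    t = normalize_dashes(s).strip()
    if t.lower().startswith("inchi"):
        t = t.split("=", 1)[1].strip()
    return "InChI=" + t
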