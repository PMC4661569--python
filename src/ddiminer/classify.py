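"""Compound vs protein classification of substance terms.

MEDLINE substance terms mix small molecules with proteins (enzymes,
receptors, transporters).  Results are reported separately for the two
classes — interacting compounds on one hand, proteins that may mediate the
interaction on the other — so every candidate term is assigned a class.

Classification is rule-based and lexical: protein-indicative patterns
(the word "protein", enzyme-name suffixes like "-ase"/"-ases", "Receptor",
"Cytochrome P-450", "CYP" followed by digits, and a small set of enzyme
family names) mark a term as protein; anything else is a compound.  The
rule that fired is recorded for audit.  A user-supplied override map always
wins, so curated corrections never fight the heuristics.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Mapping

from .records import match_key

__all__ = ["SubstanceClass", "classify", "classify_terms", "read_overrides"]

COMPOUND = "compound"
PROTEIN = "protein"
UNKNOWN = "unknown"

# (rule name, compiled pattern) — first match wins, order is cosmetic only
_PROTEIN_RULES: list[tuple[str, re.Pattern[str]]] = [
    ("word-protein", re.compile(r"\bprotein\b", re.IGNORECASE)),
    ("cytochrome-p450", re.compile(r"\bcytochrome p-?450\b", re.IGNORECASE)),
    ("cyp-isoform", re.compile(r"\bCYP\d", re.IGNORECASE)),
    ("word-receptor", re.compile(r"\breceptor(s)?\b", re.IGNORECASE)),
    (
        "enzyme-family",
        re.compile(
            r"\b(hydroxylases?|transferases?|synthases?|transaminases?|"
            r"aminotransferases?|oxygenases?|oxidoreductases?|kinases?|"
            r"peptidases?|cyclooxygenases?)\b",
            re.IGNORECASE,
        ),
    ),
    ("ase-suffix", re.compile(r"[a-z]ases?\b", re.IGNORECASE)),
]


@dataclass(frozen=True)
class SubstanceClass:
    term: str
    klass: str  # compound | protein | unknown
    rule: str  # name of the rule that fired ("override", "default-compound", ...)


def classify(
    term: str, overrides: Mapping[str, str] | None = None
) -> SubstanceClass:
    """Classify one substance term; overrides take precedence over patterns."""
    if overrides:
        folded = {match_key(k): v for k, v in overrides.items()}
        hit = folded.get(match_key(term))
        if hit is not None:
            if hit not in (COMPOUND, PROTEIN, UNKNOWN):
                raise ValueError(f"invalid class in overrides: {hit!r}")
            return SubstanceClass(term, hit, "override")
    for name, pattern in _PROTEIN_RULES:
        if pattern.search(term):
            return SubstanceClass(term, PROTEIN, name)
    return SubstanceClass(term, COMPOUND, "default-compound")


def classify_terms(
    terms: list[str], overrides: Mapping[str, str] | None = None
) -> dict[str, SubstanceClass]:
    """Classify a list of terms, keyed by the original term string."""
    return {t: classify(t, overrides) for t in terms}


def read_overrides(path) -> dict[str, str]:
    """Read a two-column tab-separated term -> class override file.

    Blank lines and ``#`` comments are skipped.
    """
    overrides: dict[str, str] = {}
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(
                    f"{path}:{lineno}: expected two tab-separated columns"
                )
            term, klass = parts[0].strip(), parts[1].strip().lower()
            if klass not in (COMPOUND, PROTEIN, UNKNOWN):
                raise ValueError(f"{path}:{lineno}: unknown class {klass!r}")
            overrides[term] = klass
    return overrides
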