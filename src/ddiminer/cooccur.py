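"""Candidate extraction and term-pair counting.

A *candidate* is any substance term appearing in a Group-A record's
substances field, minus the queried drug and its synonyms.  A *term pair* is
the co-occurrence of a candidate with the queried drug in one record; since
every record of the corpus was retrieved for that drug, co-occurrence is
defined by corpus membership, and the pair count of a candidate over a
record set is simply the number of records whose substances field contains
the candidate (record-level presence; within-record multiplicity ignored).
A stricter reading — require the drug itself to appear in the substances
field — is available via ``require_drug_in_substances`` on the model/CLI.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .records import MedlineRecord, match_key

__all__ = [
    "CandidateSet",
    "PairCount",
    "extract_candidates",
    "count_pairs",
    "apply_frequency_cutoff",
]


@dataclass
class CandidateSet:
    """Candidate substance terms, deduplicated case-insensitively.

    ``terms`` keeps the first-seen casing; ``excluded_terms`` records which
    substances were dropped for matching the queried drug or a synonym.
    """

    terms: list[str] = field(default_factory=list)
    excluded_terms: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.terms)

    def keys(self) -> list[str]:
        return [match_key(t) for t in self.terms]


@dataclass(frozen=True)
class PairCount:
    term: str
    count: int


def extract_candidates(
    group_a: list[MedlineRecord],
    queried_drug: str,
    synonyms: list[str] | None = None,
) -> CandidateSet:
    """Union of substance terms over Group A, minus the drug itself."""
    drug_keys = {match_key(queried_drug)} | {
        match_key(s) for s in (synonyms or [])
    }
    out = CandidateSet()
    seen: set[str] = set()
    excluded_seen: set[str] = set()
    for rec in group_a:
        for term in rec.substances:
            key = match_key(term)
            if key in drug_keys:
                if key not in excluded_seen:
                    excluded_seen.add(key)
                    out.excluded_terms.append(term)
                continue
            if key not in seen:
                seen.add(key)
                out.terms.append(term)
    return out


def count_pairs(
    records: list[MedlineRecord], candidates: CandidateSet
) -> list[PairCount]:
    """Per candidate, the number of records whose substances contain it."""
    rec_keys = [rec.substance_keys() for rec in records]
    counts = []
    for term in candidates.terms:
        key = match_key(term)
        counts.append(PairCount(term, sum(1 for ks in rec_keys if key in ks)))
    return counts


def apply_frequency_cutoff(
    counts: list[PairCount], cutoff: int
) -> list[PairCount]:
    """Keep candidates with count >= cutoff, preserving order.

    Candidates below the cutoff are too rare for the resampling test to say
    anything stable about and are dropped from further analysis.
    """
    if cutoff < 0:
        raise ValueError("cutoff must be >= 0")
    return [pc for pc in counts if pc.count >= cutoff]
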