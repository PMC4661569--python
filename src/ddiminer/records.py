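"""Core record types for MEDLINE-derived corpora.

A MEDLINE record is one bibliographic entry: a PMID, free-text title and
abstract, the MeSH headings assigned by indexers, and the *substances* field
listing the chemical and protein names indexed for the article.  The
substances field is the raw material of the whole pipeline: candidate
drug-drug-interaction partners are substance terms that co-occur with the
queried drug.

Substance terms are stored losslessly (original casing) and compared through
:func:`match_key`, which folds case and collapses whitespace.  MeSH substance
names are controlled vocabulary, so no stemming or fuzzy matching is applied
anywhere.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

__all__ = [
    "MeshHeading",
    "MedlineRecord",
    "Corpus",
    "normalize_term",
    "match_key",
    "DuplicatePmidError",
]

_WS = re.compile(r"\s+")


def normalize_term(term: str) -> str:
    """Trim surrounding whitespace and collapse internal runs; keep case."""
    return _WS.sub(" ", term.strip())


def match_key(term: str) -> str:
    """Canonical comparison key: normalized and case-folded."""
    return normalize_term(term).casefold()


class DuplicatePmidError(ValueError):
    """Two records in one corpus share a PMID."""

    def __init__(self, pmid: str):
        self.pmid = pmid
        super().__init__(f"duplicate PMID in corpus: {pmid!r}")


@dataclass(frozen=True)
class MeshHeading:
    """One MeSH heading: descriptor, optional qualifiers, major-topic flag."""

    descriptor: str
    qualifiers: tuple[str, ...] = ()
    is_major: bool = False

    def __post_init__(self) -> None:
        if not self.descriptor.strip():
            raise ValueError("MeSH descriptor must be non-empty")
        object.__setattr__(self, "qualifiers", tuple(self.qualifiers))


@dataclass
class MedlineRecord:
    """One normalized bibliographic record.

    ``substances`` holds the indexed chemical/protein names; empty strings
    are dropped at construction and the remainder whitespace-normalized.
    Records without MeSH headings are valid here; the cohort split excludes
    them later rather than the parser rejecting them.
    """

    pmid: str
    title: str = ""
    abstract: str = ""
    mesh_headings: list[MeshHeading] = field(default_factory=list)
    substances: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not str(self.pmid).strip():
            raise ValueError("pmid must be non-empty")
        self.pmid = str(self.pmid).strip()
        self.substances = [
            normalize_term(s) for s in self.substances if normalize_term(s)
        ]

    def substance_keys(self) -> frozenset[str]:
        """Comparison keys of this record's substance terms."""
        return frozenset(match_key(s) for s in self.substances)

    def descriptor_keys(self) -> frozenset[str]:
        """Comparison keys of the MeSH descriptors (qualifiers stripped)."""
        return frozenset(match_key(h.descriptor) for h in self.mesh_headings)


@dataclass
class Corpus:
    """A drug-centric record collection: every record was retrieved for
    ``queried_drug``, so the drug co-occurs with each record by membership."""

    queried_drug: str
    records: list[MedlineRecord] = field(default_factory=list)
    drug_synonyms: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.queried_drug.strip():
            raise ValueError("queried_drug must be non-empty")
        seen: set[str] = set()
        for rec in self.records:
            if rec.pmid in seen:
                raise DuplicatePmidError(rec.pmid)
            seen.add(rec.pmid)

    def __len__(self) -> int:
        return len(self.records)

    def drug_keys(self) -> frozenset[str]:
        """Match keys of the queried drug and all synonyms."""
        return frozenset(
            match_key(t) for t in [self.queried_drug, *self.drug_synonyms]
        )
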