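"""Cohort split: DDI-indexed articles (Group A) vs the rest (Group B).

The split is driven entirely by MeSH indexing, never by abstract text.
Records lacking MeSH headings are excluded — they carry no indexing signal
either way.  Matching compares a record's MeSH *descriptors* (qualifiers
stripped) case-insensitively against the configured list of DDI-related
headings, by exact string equality; substring matching would drag in
unrelated headings.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .records import Corpus, MedlineRecord, match_key

__all__ = ["CohortSplit", "default_ddi_mesh_terms", "split_corpus"]

_DDI_MESH_TERMS = (
    "drug interactions",
    "drug agonism",
    "drug partial agonism",
    "drug antagonism",
    "drug inverse agonism",
    "drug synergism",
    "food-drug interactions",
    "herb-drug interactions",
)


def default_ddi_mesh_terms() -> list[str]:
    """The eight MeSH headings that mark an article as DDI-related."""
    return list(_DDI_MESH_TERMS)


@dataclass
class CohortSplit:
    """Partition of a corpus into Group A / Group B / excluded (no MeSH)."""

    group_a: list[MedlineRecord] = field(default_factory=list)
    group_b: list[MedlineRecord] = field(default_factory=list)
    excluded: list[MedlineRecord] = field(default_factory=list)
    ddi_terms_used: list[str] = field(default_factory=list)

    @property
    def sizes(self) -> tuple[int, int, int]:
        return len(self.group_a), len(self.group_b), len(self.excluded)


def split_corpus(
    corpus: Corpus,
    ddi_terms: list[str] | None = None,
    *,
    major_topics_only: bool = False,
) -> CohortSplit:
    """Partition ``corpus`` by the presence of DDI-related MeSH descriptors.

    Parameters
    ----------
    ddi_terms
        Headings marking Group A membership; defaults to
        :func:`default_ddi_mesh_terms`.  Must be non-empty.
    major_topics_only
        If true, only headings flagged as major topics count toward
        Group A membership.
    """
    if ddi_terms is None:
        ddi_terms = default_ddi_mesh_terms()
    if not ddi_terms:
        raise ValueError("ddi_terms must be non-empty")
    term_keys = {match_key(t) for t in ddi_terms}

    split = CohortSplit(ddi_terms_used=list(ddi_terms))
    for rec in corpus.records:
        if not rec.mesh_headings:
            split.excluded.append(rec)
            continue
        headings = (
            [h for h in rec.mesh_headings if h.is_major]
            if major_topics_only
            else rec.mesh_headings
        )
        if any(match_key(h.descriptor) in term_keys for h in headings):
            split.group_a.append(rec)
        else:
            split.group_b.append(rec)
    return split
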