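"""Synthetic MEDLINE-like corpora with known ground truth.

The generator emulates the statistical structure the resampling test
assumes: two latent record groups (DDI-indexed and not) plus a no-MeSH
remainder, and a substance vocabulary in which each term occurs in a record
independently with a group-specific Bernoulli rate.  A configurable subset
of terms is *enriched* — more frequent among DDI-indexed records — and those
terms are the ground truth the pipeline should recover.  Term names are
drawn from compound-like and protein-like templates so the classifier is
exercised end to end, and the compound-class enriched terms double as an
embedded gold standard for the evaluation module.

Real MEDLINE substance occurrences are of course correlated (co-prescribed
drugs, enzyme families); independence is the minimal structure needed to
validate null calibration and ranking power, not a model of the literature.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from .classify import COMPOUND, classify
from .evaluate import GoldStandard
from .io import DIALECTS
from .records import Corpus, MedlineRecord, MeshHeading

__all__ = [
    "SyntheticConfig",
    "generate",
    "write_fixture",
    "null_config",
    "enriched_config",
    "DEFAULT_DRUG",
]

DEFAULT_DRUG = "Examplium"

_COMPOUND_TEMPLATES = (
    "Zaridonol {i}",
    "Fexamivir {i}",
    "Cortaline {i}",
    "Nubrafen {i}",
    "Velpristat {i}",
    "Durotinib {i}",
)
_PROTEIN_TEMPLATES = (
    "Cytochrome P-450 CYP9Z{i}",
    "Xenobiotic Transferase {i}",
    "Receptor, Orphan XR-{i}",
    "Steroid Hydroxylase {i}",
    "ZV-{i} protein, human",
    "Quinone Oxidoreductase {i}",
)


@dataclass(frozen=True)
class SyntheticConfig:
    """Generative parameters of a fixture corpus.

    Defaults are the enrichment scenario used throughout validation:
    100 DDI-indexed records vs 2000 background records, a 200-term
    vocabulary with 10 enriched terms at occurrence rate 0.30 in the DDI
    group against 0.02 elsewhere, and a 0.05 background rate in both groups
    (high enough that background terms clear the pair-frequency cutoff of 3
    and genuinely exercise the null test).
    """

    n_group_a: int = 100
    n_group_b: int = 2000
    n_no_mesh: int = 20
    vocabulary_size: int = 200
    n_enriched: int = 10
    rate_background_a: float = 0.05
    rate_background_b: float = 0.05
    rate_enriched_a: float = 0.30
    rate_enriched_b: float = 0.02
    protein_fraction: float = 0.25
    seed: int = 0
    queried_drug: str = DEFAULT_DRUG

    def __post_init__(self) -> None:
        if self.n_enriched > self.vocabulary_size:
            raise ValueError("n_enriched must be <= vocabulary_size")
        if min(self.n_group_a, self.n_group_b, self.n_no_mesh) < 0:
            raise ValueError("group sizes must be >= 0")
        for name in (
            "rate_background_a",
            "rate_background_b",
            "rate_enriched_a",
            "rate_enriched_b",
        ):
            rate = getattr(self, name)
            if not (0.0 <= rate <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {rate}")
        if not (0.0 <= self.protein_fraction <= 1.0):
            raise ValueError("protein_fraction must be in [0, 1]")

    @property
    def is_null(self) -> bool:
        """True when enriched and background rates coincide across groups."""
        return (
            self.rate_enriched_a == self.rate_enriched_b
            and self.rate_background_a == self.rate_background_b
        )


def null_config(seed: int = 0, **kwargs) -> SyntheticConfig:
    """Null scenario: every term has the same rate in both groups."""
    return SyntheticConfig(
        rate_enriched_a=0.05, rate_enriched_b=0.05, seed=seed, **kwargs
    )


def enriched_config(seed: int = 0, **kwargs) -> SyntheticConfig:
    """Enrichment scenario (the defaults), seed applied."""
    return SyntheticConfig(seed=seed, **kwargs)


def _vocabulary(config: SyntheticConfig) -> list[str]:
    """Deterministic term names: proteins first, then compounds."""
    n_protein = round(config.protein_fraction * config.vocabulary_size)
    names = []
    for i in range(n_protein):
        names.append(_PROTEIN_TEMPLATES[i % len(_PROTEIN_TEMPLATES)].format(i=i))
    for i in range(config.vocabulary_size - n_protein):
        names.append(_COMPOUND_TEMPLATES[i % len(_COMPOUND_TEMPLATES)].format(i=i))
    return names


def generate(
    config: SyntheticConfig,
) -> tuple[Corpus, set[str], GoldStandard]:
    """Draw one corpus; return it with the enriched-term truth and gold set.

    Group-A records carry the MeSH descriptor "Drug Interactions";
    Group-B records carry only non-DDI descriptors; the no-MeSH block has
    empty headings.  Every record lists the queried drug as its first
    substance (articles retrieved for a drug generally index it).  Fully
    determined by ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    vocab = _vocabulary(config)
    enriched_idx = rng.choice(
        config.vocabulary_size, size=config.n_enriched, replace=False
    )
    enriched_mask = np.zeros(config.vocabulary_size, dtype=bool)
    enriched_mask[enriched_idx] = True

    def rates(group: str) -> np.ndarray:
        bg = config.rate_background_a if group == "a" else config.rate_background_b
        en = config.rate_enriched_a if group == "a" else config.rate_enriched_b
        return np.where(enriched_mask, en, bg)

    mesh_a = [
        MeshHeading("Drug Interactions", (), True),
        MeshHeading("Humans"),
    ]
    mesh_b = [MeshHeading("Humans"), MeshHeading("Pharmacokinetics")]

    records: list[MedlineRecord] = []
    pmid = 1_000_000
    blocks = (
        ("a", config.n_group_a, mesh_a),
        ("b", config.n_group_b, mesh_b),
        ("x", config.n_no_mesh, []),
    )
    for group, n, mesh in blocks:
        if n == 0:
            continue
        hits = rng.random((n, config.vocabulary_size)) < (
            rates(group) if group != "x" else rates("b")
        )
        for row in hits:
            pmid += 1
            substances = [config.queried_drug] + [
                vocab[j] for j in np.nonzero(row)[0]
            ]
            records.append(
                MedlineRecord(
                    pmid=str(pmid),
                    title=f"Synthetic article {pmid}",
                    abstract="",
                    mesh_headings=list(mesh),
                    substances=substances,
                )
            )

    truth = {vocab[j] for j in enriched_idx}
    gold = GoldStandard(
        drug=config.queried_drug,
        interactors={t for t in truth if classify(t).klass == COMPOUND},
        source_note="synthetic ground truth: compound-class enriched terms",
    )
    corpus = Corpus(queried_drug=config.queried_drug, records=records)
    return corpus, truth, gold


def write_fixture(corpus: Corpus, path, dialect: str = "jsonl") -> None:
    """Serialize a corpus through the matching dialect writer."""
    if dialect not in DIALECTS:
        raise ValueError(
            f"unknown dialect {dialect!r}; choose from {sorted(DIALECTS)}"
        )
    _, write = DIALECTS[dialect]
    write(Path(path), corpus.records)
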