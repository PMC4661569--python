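import numpy as np
import pytest

from ddiminer.records import Corpus, MedlineRecord, MeshHeading


def make_record(pmid, substances=(), descriptors=(), **kwargs):
    headings = [
        h if isinstance(h, MeshHeading) else MeshHeading(h)
        for h in descriptors
    ]
    return MedlineRecord(
        pmid=str(pmid),
        title=kwargs.get("title", f"Article {pmid}"),
        abstract=kwargs.get("abstract", ""),
        mesh_headings=headings,
        substances=list(substances),
    )


def random_corpus(rng, n_records=50, vocab=None, drug="Warfarin", p=0.2):
    """Small random corpus: each term present in each record w.p. ``p``."""
    vocab = vocab or [f"Substance {i}" for i in range(20)]
    records = []
    for i in range(n_records):
        subs = [t for t in vocab if rng.random() < p]
        desc = ["Drug Interactions"] if rng.random() < 0.3 else ["Humans"]
        if rng.random() < 0.1:
            desc = []
        records.append(make_record(100 + i, subs, desc))
    return Corpus(queried_drug=drug, records=records)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_corpus():
    """Three records: one Group A, one Group B, one MeSH-less."""
    return Corpus(
        queried_drug="Warfarin",
        records=[
            make_record(1, ["Aspirin", "Cytochrome P-450 CYP2C9"],
                        ["Drug Interactions"]),
            make_record(2, ["Aspirin"], ["Humans"]),
            make_record(3, ["Ibuprofen"], []),
        ],
    )
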