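"""Ranking evaluation against a gold standard of known interactors.

Three rankers are compared:

* **sampling** — the resampling test's order (p ascending, ties by x0);
* **cooccurrence_only** — candidates by raw Group-A pair count x0,
  descending (co-occurrence without the random-sampling filter);
* **frequency_only** — candidates by their count over the whole corpus
  (Group A and B together), descending.

Metrics: accuracy in the top fraction of the compound-class ranking
(n_top = ceil(fraction * len(ranking)), so the top list is never empty),
accuracy in a fixed top-n, and ROC AUC of the gold labels against rank
order (the Mann-Whitney identity; computed via scikit-learn with negated
rank positions as scores).  A cutoff sweep re-runs the whole test across
pair-frequency cutoffs with the same seed — draw membership is seed-derived
and candidate-independent, so the null draws are comparable across cutoffs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd
from sklearn.metrics import roc_auc_score

from .classify import COMPOUND, classify
from .cooccur import CandidateSet, count_pairs
from .records import Corpus, match_key
from .sampling import AnalysisConfig, CandidateResult, run_ddi_test

__all__ = [
    "GoldStandard",
    "EvalReport",
    "read_gold",
    "rank_by_pvalue",
    "rank_by_cooccurrence",
    "rank_by_frequency",
    "accuracy_at_fraction",
    "accuracy_at_top_n",
    "roc_auc",
    "cutoff_sweep",
]


@dataclass
class GoldStandard:
    """Known interactors of one drug, names normalized like candidate terms."""

    drug: str
    interactors: set[str] = field(default_factory=set)
    source_note: str = ""

    def keys(self) -> frozenset[str]:
        return frozenset(match_key(t) for t in self.interactors)


@dataclass
class EvalReport:
    method: str  # sampling | cooccurrence_only | frequency_only
    top_fraction: float
    n_top: int
    accuracy: float
    auc: float | None
    hits: list[str] = field(default_factory=list)


def read_gold(path, drug: str = "", source_note: str = "") -> GoldStandard:
    """Read a gold-standard file: one compound name per line, ``#`` comments."""
    interactors: set[str] = set()
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if line:
                interactors.add(line)
    return GoldStandard(drug=drug, interactors=interactors, source_note=source_note)


def rank_by_pvalue(results: list[CandidateResult]) -> list[str]:
    """The sampling ranker's order (results already ranked)."""
    return [r.term for r in sorted(results, key=lambda r: r.rank)]


def rank_by_cooccurrence(results: list[CandidateResult]) -> list[str]:
    """Candidates by Group-A pair count x0 descending, ties lexicographic."""
    return [r.term for r in sorted(results, key=lambda r: (-r.x0, r.term))]


def rank_by_frequency(corpus: Corpus, candidates: CandidateSet) -> list[str]:
    """Candidates by whole-corpus record count descending, ties lexicographic."""
    counts = count_pairs(corpus.records, candidates)
    return [pc.term for pc in sorted(counts, key=lambda pc: (-pc.count, pc.term))]


def restrict_to_compounds(
    ranking: list[str], overrides: dict[str, str] | None = None
) -> list[str]:
    """Keep only compound-class terms, preserving order."""
    return [
        t for t in ranking if classify(t, overrides).klass == COMPOUND
    ]


def accuracy_at_fraction(
    ranking: list[str],
    gold: GoldStandard,
    fraction: float = 0.1,
    method: str = "sampling",
) -> EvalReport:
    """Fraction of the top ceil(fraction * n) ranked terms found in the gold set."""
    if not ranking:
        raise ValueError("ranking is empty")
    if not (0.0 < fraction <= 1.0):
        raise ValueError("fraction must be in (0, 1]")
    n_top = math.ceil(fraction * len(ranking))
    return _report(ranking, gold, n_top, fraction, method)


def accuracy_at_top_n(
    ranking: list[str],
    gold: GoldStandard,
    n_top: int = 10,
    method: str = "sampling",
) -> EvalReport:
    """Accuracy over a fixed-size top list (top-10 style reporting)."""
    if not ranking:
        raise ValueError("ranking is empty")
    n_top = min(n_top, len(ranking))
    return _report(ranking, gold, n_top, n_top / len(ranking), method)


def _report(ranking, gold, n_top, fraction, method) -> EvalReport:
    gold_keys = gold.keys()
    hits = [t for t in ranking[:n_top] if match_key(t) in gold_keys]
    auc = None
    labels = [match_key(t) in gold_keys for t in ranking]
    if any(labels) and not all(labels):
        auc = roc_auc(ranking, gold)
    return EvalReport(
        method=method,
        top_fraction=fraction,
        n_top=n_top,
        accuracy=len(hits) / n_top,
        auc=auc,
        hits=hits,
    )


def roc_auc(ranking: list[str], gold: GoldStandard) -> float:
    """AUC of gold labels against rank order (higher rank = higher score)."""
    if not ranking:
        raise ValueError("ranking is empty")
    gold_keys = gold.keys()
    labels = [1 if match_key(t) in gold_keys else 0 for t in ranking]
    if all(labels) or not any(labels):
        raise ValueError(
            "AUC undefined: ranking is all-positive or all-negative"
        )
    scores = [-i for i in range(len(ranking))]
    return float(roc_auc_score(labels, scores))


def cutoff_sweep(
    corpus: Corpus,
    gold: GoldStandard,
    cutoffs: list[int],
    config: AnalysisConfig | None = None,
    ddi_terms: list[str] | None = None,
    class_overrides: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Re-run the test per cutoff; report candidate counts and compound AUC.

    Higher cutoffs keep fewer but better-supported candidates, trading list
    size against ranking quality.  The seed (hence the draw membership) is
    shared across cutoffs so rows differ only by the filter.
    """
    if not cutoffs:
        raise ValueError("cutoffs must be non-empty")
    config = config or AnalysisConfig()
    rows = []
    for cutoff in cutoffs:
        cfg = AnalysisConfig(
            **{**config.__dict__, "cutoff": cutoff}
        )
        results = run_ddi_test(corpus, cfg, ddi_terms)
        ranking = restrict_to_compounds(rank_by_pvalue(results), class_overrides)
        auc = None
        labels = [match_key(t) in gold.keys() for t in ranking]
        if any(labels) and not all(labels):
            auc = roc_auc(ranking, gold)
        rows.append(
            {"cutoff": cutoff, "n_candidates": len(results), "auc": auc}
        )
    return pd.DataFrame(rows)
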