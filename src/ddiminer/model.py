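"""Model/Results interface to the resampling DDI test.

`RandomSamplingDDI` wraps a drug-centric corpus the way a statsmodels model
wraps an endog/exog pair: construction fixes the data and the analysis
configuration, ``fit(seed)`` runs the resampling and returns a
:class:`DDIResults` carrying the ranked candidates, their null summaries and
p-values, with ``summary()``, a results DataFrame, network construction and
gold-standard evaluation hanging off it.

Example
-------
>>> from ddiminer import RandomSamplingDDI, simulate
>>> corpus, truth, gold = simulate.generate(simulate.enriched_config(seed=7))
>>> res = RandomSamplingDDI(corpus).fit(seed=7)
>>> res.frame().head()         # doctest: +SKIP
>>> res.evaluate(gold).accuracy  # doctest: +SKIP
"""

from __future__ import annotations

from dataclasses import replace

import pandas as pd

from . import evaluate as _evaluate
from .classify import classify_terms
from .cohort import CohortSplit, split_corpus
from .cooccur import CandidateSet, extract_candidates
from .network import (
    SubstanceNetwork,
    build_incidence,
    project,
    select_network_terms,
)
from .records import Corpus
from .sampling import AnalysisConfig, CandidateResult, run_ddi_test

__all__ = ["RandomSamplingDDI", "DDIResults"]


class RandomSamplingDDI:
    """The random-sampling DDI candidate test for one drug corpus.

    Parameters
    ----------
    corpus
        Records retrieved for one queried drug.
    ddi_terms
        MeSH descriptors defining Group A; defaults to the standard eight
        DDI-related headings.
    config
        Full :class:`AnalysisConfig`; keyword arguments below override its
        fields when given.
    cutoff, n_resamples, alpha, pvalue_mode, ...
        Shorthand overrides for the corresponding config fields.
    class_overrides
        term -> class map taking precedence over the lexical classifier.
    """

    def __init__(
        self,
        corpus: Corpus,
        *,
        ddi_terms: list[str] | None = None,
        config: AnalysisConfig | None = None,
        class_overrides: dict[str, str] | None = None,
        **config_overrides,
    ):
        self.corpus = corpus
        self.ddi_terms = ddi_terms
        base = config or AnalysisConfig()
        if config_overrides:
            base = replace(base, **config_overrides)
        self.config = base
        self.class_overrides = class_overrides or {}

    @classmethod
    def from_records(
        cls, records, queried_drug: str, synonyms: list[str] | None = None, **kwargs
    ) -> "RandomSamplingDDI":
        """Build the model directly from a record list."""
        corpus = Corpus(
            queried_drug=queried_drug,
            records=list(records),
            drug_synonyms=list(synonyms or []),
        )
        return cls(corpus, **kwargs)

    def fit(self, seed: int | None = None) -> "DDIResults":
        """Run the full pipeline; ``seed`` overrides the config seed."""
        config = self.config if seed is None else replace(self.config, seed=seed)
        results = run_ddi_test(self.corpus, config, self.ddi_terms)
        split = split_corpus(
            self.corpus, self.ddi_terms, major_topics_only=config.major_topics_only
        )
        candidates = extract_candidates(
            split.group_a, self.corpus.queried_drug, self.corpus.drug_synonyms
        )
        return DDIResults(self, config, split, candidates, results)


class DDIResults:
    """Ranked candidates from one fitted :class:`RandomSamplingDDI`."""

    def __init__(
        self,
        model: RandomSamplingDDI,
        config: AnalysisConfig,
        split: CohortSplit,
        candidates: CandidateSet,
        results: list[CandidateResult],
    ):
        self.model = model
        self.config = config
        self.split = split
        self.candidates = candidates
        self.results = results
        self.classes = {
            term: sc.klass
            for term, sc in classify_terms(
                [r.term for r in results], model.class_overrides
            ).items()
        }

    # -- views -------------------------------------------------------------

    def __len__(self) -> int:
        return len(self.results)

    @property
    def significant(self) -> list[CandidateResult]:
        return [r for r in self.results if r.significant]

    def frame(self) -> pd.DataFrame:
        """Ranked result table, one row per candidate."""
        rows = [
            {
                "rank": r.rank,
                "term": r.term,
                "class": self.classes[r.term],
                "x0": r.x0,
                "null_mean": r.null.mean,
                "null_sd": r.null.sd,
                "p_value": r.p_value,
                "significant": r.significant,
                **({"q_value": r.q_value} if r.q_value is not None else {}),
            }
            for r in self.results
        ]
        return pd.DataFrame(rows).sort_values("rank").reset_index(drop=True)

    def summary(self, top: int = 10) -> str:
        """Plain-text summary: cohort sizes, candidate counts, top candidates."""
        a, b, x = self.split.sizes
        lines = [
            "Random-sampling DDI candidate test",
            "=" * 50,
            f"Queried drug:        {self.model.corpus.queried_drug}",
            f"Records:             {len(self.model.corpus)} "
            f"(Group A: {a}, Group B: {b}, no MeSH: {x})",
            f"Candidates:          {len(self.candidates)} extracted, "
            f"{len(self.results)} at count >= {self.config.cutoff}",
            f"Significant (p<{self.config.alpha:g}): {len(self.significant)}",
            f"Resamples:           {self.config.n_resamples} "
            f"({self.config.pvalue_mode}, seed {self.config.seed})",
            "-" * 50,
        ]
        if self.results:
            head = self.frame().head(top)
            lines.append(
                head.to_string(
                    index=False,
                    float_format=lambda v: f"{v:.4g}",
                )
            )
        else:
            lines.append("(no candidates survived the frequency cutoff)")
        return "\n".join(lines)

    # -- downstream analyses -----------------------------------------------

    def network(
        self,
        alpha: float | None = None,
        min_count: int | None = None,
        min_edge_weight: int = 1,
    ) -> SubstanceNetwork:
        """Build the term-article social network of significant terms."""
        alpha = self.config.alpha if alpha is None else alpha
        min_count = self.config.cutoff if min_count is None else min_count
        terms = select_network_terms(self.results, alpha, min_count)
        if not terms:
            return SubstanceNetwork(
                nodes=[(self.model.corpus.queried_drug, "compound")],
                edges=[],
                metadata={"alpha": alpha, "min_count": min_count},
            )
        matrix = build_incidence(
            self.split.group_a, terms, self.model.corpus.queried_drug
        )
        classes = dict(self.classes)
        classes.setdefault(self.model.corpus.queried_drug, "compound")
        net = project(matrix, min_edge_weight, classes)
        net.metadata.update({"alpha": alpha, "min_count": min_count})
        return net

    def ranking(self, method: str = "sampling") -> list[str]:
        """Term order under one of the three rankers."""
        if method == "sampling":
            return _evaluate.rank_by_pvalue(self.results)
        if method == "cooccurrence_only":
            return _evaluate.rank_by_cooccurrence(self.results)
        if method == "frequency_only":
            return _evaluate.rank_by_frequency(
                self.model.corpus, CandidateSet(terms=[r.term for r in self.results])
            )
        raise ValueError(f"unknown ranking method: {method!r}")

    def evaluate(
        self,
        gold: _evaluate.GoldStandard,
        fraction: float = 0.1,
        method: str = "sampling",
        top_n: int | None = None,
        compounds_only: bool = True,
    ) -> _evaluate.EvalReport:
        """Accuracy of a ranker's top list against a gold standard."""
        ranking = self.ranking(method)
        if compounds_only:
            ranking = [
                t for t in ranking if self.classes.get(t) == "compound"
            ]
        if top_n is not None:
            return _evaluate.accuracy_at_top_n(ranking, gold, top_n, method)
        return _evaluate.accuracy_at_fraction(ranking, gold, fraction, method)
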