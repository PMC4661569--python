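"""The random-sampling null distribution, p-values and ranking.

For each candidate term the observed statistic is x0, its pair count over
Group A.  The null distribution is built by repeatedly drawing |A| records
from Group B uniformly at random (without replacement within a draw,
independent across draws) and counting the candidate over each draw,
yielding x_1..x_R.  Under the null hypothesis that the candidate is no more
associated with DDI-indexed articles than with the rest of the literature,
x0 should look like another draw from this distribution.

The p-value is the upper tail P(x > x0).  By default the null counts are
summarized by a fitted normal (sample mean, sample sd with n-1 denominator)
and the tail is the normal survival function — this is what makes extreme
candidates distinguishable below 1/R resolution.  An empirical mode
(#{x_i > x0}/R) is provided as a cross-check.  Two degenerate cases:

* all null counts zero -> p = 0, and such candidates are ordered among
  themselves by x0 descending;
* sd = 0 with nonzero mean -> step function: p = 0 if x0 > mean else 1
  (the limit of the normal tail).

Ranking sorts by p ascending, ties by x0 descending, remaining ties
lexicographically by term, so results are deterministic.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .cohort import split_corpus
from .cooccur import (
    CandidateSet,
    apply_frequency_cutoff,
    count_pairs,
    extract_candidates,
)
from .records import Corpus, MedlineRecord

__all__ = [
    "AnalysisConfig",
    "NullDistribution",
    "CandidateResult",
    "sample_null",
    "p_value",
    "rank_candidates",
    "run_ddi_test",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AnalysisConfig:
    """Tuning knobs of the resampling test.

    Defaults follow the method's published operating point: pair-frequency
    cutoff 3, 100 resamples, significance level 0.1, parametric-normal
    upper-tail p-values, subsampling without replacement.
    """

    cutoff: int = 3
    n_resamples: int = 100
    alpha: float = 0.1
    seed: int = 0
    pvalue_mode: str = "parametric_normal"  # or "empirical"
    sample_with_replacement: bool = False
    require_drug_in_substances: bool = False
    major_topics_only: bool = False
    fdr_correction: bool = False  # optional Benjamini-Hochberg q-values

    def __post_init__(self) -> None:
        if self.n_resamples < 2:
            raise ValueError("n_resamples must be >= 2")
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must be in (0, 1)")
        if self.cutoff < 0:
            raise ValueError("cutoff must be >= 0")
        if self.pvalue_mode not in ("parametric_normal", "empirical"):
            raise ValueError(f"unknown pvalue_mode: {self.pvalue_mode!r}")


@dataclass
class NullDistribution:
    """Null counts x_1..x_R of one candidate with their normal-fit summary."""

    term: str
    samples: np.ndarray  # shape (R,), non-negative integers
    mean: float
    sd: float  # sample standard deviation, n-1 denominator

    @classmethod
    def from_samples(cls, term: str, samples: np.ndarray) -> "NullDistribution":
        arr = np.asarray(samples)
        return cls(
            term=term,
            samples=arr,
            mean=float(arr.mean()),
            sd=float(arr.std(ddof=1)),
        )

    @property
    def all_zero(self) -> bool:
        return bool((self.samples == 0).all())


@dataclass
class CandidateResult:
    """One ranked candidate: observed count, null summary, p-value."""

    term: str
    x0: int
    null: NullDistribution
    p_value: float
    significant: bool = False
    rank: int = 0
    q_value: float | None = None  # BH-adjusted, only if requested


def _draw_indices(
    seed: int, n_resamples: int, pool_size: int, draw_size: int, replace: bool
) -> np.ndarray:
    """Record indices for each resample draw, shape (R, draw_size).

    Each draw's generator is derived from (seed, draw index) via a spawned
    SeedSequence, so draw membership depends only on the seed, the pool and
    the draw size — never on which candidates are being counted.
    """
    children = np.random.SeedSequence(seed).spawn(n_resamples)
    return np.stack(
        [
            np.random.default_rng(child).choice(
                pool_size, size=draw_size, replace=replace
            )
            for child in children
        ]
    )


def sample_null(
    group_a_size: int,
    group_b: list[MedlineRecord],
    candidates: CandidateSet,
    config: AnalysisConfig,
) -> dict[str, NullDistribution]:
    """Build every candidate's null distribution from Group-B subsamples.

    Draws ``config.n_resamples`` subsamples of ``group_a_size`` records from
    ``group_b`` and counts each candidate over each subsample (the
    vectorized equivalent of running :func:`~ddiminer.cooccur.count_pairs`
    per draw).
    """
    if group_a_size < 1:
        raise ValueError("group_a_size must be >= 1")
    if not config.sample_with_replacement and len(group_b) < group_a_size:
        raise ValueError(
            f"group B has {len(group_b)} records, fewer than the draw size "
            f"{group_a_size}; enable sample_with_replacement or reduce the "
            "group size"
        )

    keys = candidates.keys()
    key_index = {k: j for j, k in enumerate(keys)}
    incidence = np.zeros((len(group_b), len(keys)), dtype=bool)
    for i, rec in enumerate(group_b):
        for k in rec.substance_keys():
            j = key_index.get(k)
            if j is not None:
                incidence[i, j] = True

    draws = _draw_indices(
        config.seed,
        config.n_resamples,
        len(group_b),
        group_a_size,
        config.sample_with_replacement,
    )
    # counts[r, j] = candidate j's pair count in draw r
    counts = incidence[draws].sum(axis=1)
    return {
        term: NullDistribution.from_samples(term, counts[:, j])
        for j, term in enumerate(candidates.terms)
    }


def p_value(x0: int, null: NullDistribution, config: AnalysisConfig) -> float:
    """Upper-tail probability P(x > x0) under the candidate's null."""
    if config.pvalue_mode == "empirical":
        p = float((null.samples > x0).sum()) / len(null.samples)
        return min(max(p, 0.0), 1.0)
    if null.all_zero:
        return 0.0
    if null.sd == 0.0:
        return 0.0 if x0 > null.mean else 1.0
    p = float(stats.norm.sf(x0, loc=null.mean, scale=null.sd))
    return min(max(p, 0.0), 1.0)


def rank_candidates(
    results: list[CandidateResult], config: AnalysisConfig
) -> list[CandidateResult]:
    """Sort by p ascending, ties by x0 descending then term; assign ranks."""
    ordered = sorted(results, key=lambda r: (r.p_value, -r.x0, r.term))
    for i, res in enumerate(ordered, start=1):
        res.rank = i
        res.significant = res.p_value < config.alpha
    if config.fdr_correction and ordered:
        _attach_bh(ordered)
    return ordered


def _attach_bh(ordered: list[CandidateResult]) -> None:
    """Benjamini-Hochberg q-values over the already p-sorted results."""
    n = len(ordered)
    q = math.inf
    for i in range(n - 1, -1, -1):
        q = min(q, ordered[i].p_value * n / (i + 1))
        ordered[i].q_value = min(q, 1.0)


def run_ddi_test(
    corpus: Corpus,
    config: AnalysisConfig | None = None,
    ddi_terms: list[str] | None = None,
) -> list[CandidateResult]:
    """The full three-step pipeline on one corpus.

    Split into Group A / Group B, extract candidates from A, count x0,
    apply the frequency cutoff, resample the null from B, compute p-values
    and rank.  Returns an empty list (with a warning) when Group A is empty
    or no candidate survives the cutoff.
    """
    config = config or AnalysisConfig()
    split = split_corpus(
        corpus, ddi_terms, major_topics_only=config.major_topics_only
    )
    logger.info(
        "cohort split: |A|=%d |B|=%d excluded=%d", *split.sizes
    )
    if not split.group_a:
        logger.warning("Group A is empty; no candidates to test")
        return []

    candidates = extract_candidates(
        split.group_a, corpus.queried_drug, corpus.drug_synonyms
    )
    group_a = split.group_a
    if config.require_drug_in_substances:
        drug_keys = corpus.drug_keys()
        group_a = [
            r for r in group_a if r.substance_keys() & drug_keys
        ]
    counts = count_pairs(group_a, candidates)
    surviving = apply_frequency_cutoff(counts, config.cutoff)
    logger.info(
        "%d candidates, %d at count >= %d", len(counts), len(surviving), config.cutoff
    )
    if not surviving:
        return []

    kept = CandidateSet(terms=[pc.term for pc in surviving])
    nulls = sample_null(len(group_a), split.group_b, kept, config)
    results = [
        CandidateResult(
            term=pc.term,
            x0=pc.count,
            null=nulls[pc.term],
            p_value=p_value(pc.count, nulls[pc.term], config),
        )
        for pc in surviving
    ]
    return rank_candidates(results, config)
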