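"""The resampling null, p-values, ranking and the composed test."""

import math

import numpy as np
import pytest

from ddiminer.cooccur import CandidateSet
from ddiminer.records import Corpus
from ddiminer.sampling import (
    AnalysisConfig,
    CandidateResult,
    NullDistribution,
    p_value,
    rank_candidates,
    run_ddi_test,
    sample_null,
)

from conftest import make_record


def null_from(samples, term="t"):
    return NullDistribution.from_samples(term, np.asarray(samples))


class TestAnalysisConfig:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_resamples": 1},
            {"alpha": 0.0},
            {"alpha": 1.0},
            {"cutoff": -1},
            {"pvalue_mode": "bayes"},
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            AnalysisConfig(**kwargs)


class TestSampleNull:
    def test_absent_term_gives_all_zero_null(self):
        group_b = [make_record(i, ["Aspirin"]) for i in range(30)]
        cs = CandidateSet(terms=["Heparin"])
        nulls = sample_null(10, group_b, cs, AnalysisConfig(seed=1))
        assert nulls["Heparin"].all_zero

    def test_exhaustive_draw_gives_constant_samples(self):
        group_b = [
            make_record(i, ["Aspirin"] if i < 7 else []) for i in range(20)
        ]
        cs = CandidateSet(terms=["Aspirin"])
        nulls = sample_null(20, group_b, cs, AnalysisConfig(seed=1))
        assert set(nulls["Aspirin"].samples.tolist()) == {7}
        assert nulls["Aspirin"].sd == 0.0

    def test_sample_mean_matches_hypergeometric_expectation(self):
        # term in 100 of 200 records, draws of 20 -> mean 10,
        # per-draw sd sqrt(20*0.25*180/199), SE of the mean = sd/10
        group_b = [
            make_record(i, ["Aspirin"] if i < 100 else []) for i in range(200)
        ]
        cs = CandidateSet(terms=["Aspirin"])
        nulls = sample_null(20, group_b, cs, AnalysisConfig(seed=3))
        sd = math.sqrt(20 * 0.25 * 180 / 199)
        assert abs(nulls["Aspirin"].mean - 10.0) < 3 * sd / 10

    def test_insufficient_group_b_without_replacement(self):
        group_b = [make_record(i, []) for i in range(5)]
        cs = CandidateSet(terms=["A"])
        with pytest.raises(ValueError, match="replacement"):
            sample_null(10, group_b, cs, AnalysisConfig())
        nulls = sample_null(
            10, group_b, cs, AnalysisConfig(sample_with_replacement=True)
        )
        assert len(nulls["A"].samples) == 100

    def test_draw_membership_independent_of_candidate_set(self):
        """Adding candidates must not perturb which records are drawn."""
        group_b = [
            make_record(i, ["Aspirin"] if i % 3 == 0 else ["Heparin"])
            for i in range(60)
        ]
        cfg = AnalysisConfig(seed=9)
        solo = sample_null(15, group_b, CandidateSet(terms=["Aspirin"]), cfg)
        both = sample_null(
            15, group_b, CandidateSet(terms=["Heparin", "Aspirin"]), cfg
        )
        np.testing.assert_array_equal(
            solo["Aspirin"].samples, both["Aspirin"].samples
        )

    def test_seeded_reproducibility(self):
        group_b = [
            make_record(i, ["Aspirin"] if i % 2 else []) for i in range(40)
        ]
        cs = CandidateSet(terms=["Aspirin"])
        a = sample_null(10, group_b, cs, AnalysisConfig(seed=5))
        b = sample_null(10, group_b, cs, AnalysisConfig(seed=5))
        c = sample_null(10, group_b, cs, AnalysisConfig(seed=6))
        np.testing.assert_array_equal(a["Aspirin"].samples, b["Aspirin"].samples)
        assert not np.array_equal(a["Aspirin"].samples, c["Aspirin"].samples)


class TestPValue:
    cfg = AnalysisConfig()

    def test_all_zero_null_is_zero(self):
        assert p_value(5, null_from([0] * 100), self.cfg) == 0.0

    def test_x0_at_null_mean_is_half(self):
        assert p_value(2, null_from([1, 2, 3]), self.cfg) == pytest.approx(0.5)

    def test_two_sigma_tail_matches_closed_form(self):
        # samples (1,2,3): mean 2, sd 1; x0=4 is z=2
        # 1 - Phi(2) = 0.0227501319... (independent closed form)
        p = p_value(4, null_from([1, 2, 3]), self.cfg)
        assert p == pytest.approx(0.022750131948, abs=1e-6)

    def test_degenerate_sd_zero_nonzero_mean_is_step(self):
        null = null_from([4] * 10)
        assert p_value(5, null, self.cfg) == 0.0
        assert p_value(4, null, self.cfg) == 1.0
        assert p_value(3, null, self.cfg) == 1.0

    def test_empirical_mode_counts_strictly_greater(self):
        cfg = AnalysisConfig(pvalue_mode="empirical")
        null = null_from([0, 1, 2, 3, 4])
        assert p_value(2, null, cfg) == pytest.approx(2 / 5)
        assert p_value(10, null, cfg) == 0.0
        assert p_value(-1, null, cfg) == 1.0

    def test_p_nonincreasing_in_x0(self):
        null = null_from([1, 3, 2, 5, 4])
        ps = [p_value(x, null, self.cfg) for x in range(0, 12)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))
        assert all(0.0 <= p <= 1.0 for p in ps)

    def test_empirical_and_parametric_agree_on_central_values(self, rng):
        samples = rng.binomial(40, 0.4, size=200)
        null = null_from(samples)
        for x0 in (12, 16, 20):
            par = p_value(x0, null, AnalysisConfig())
            emp = p_value(x0, null, AnalysisConfig(pvalue_mode="empirical"))
            assert abs(par - emp) < 0.15


class TestRankCandidates:
    @staticmethod
    def result(term, x0, p):
        null = null_from([0] * 10 if p == 0 else [1, 2, 3], term)
        return CandidateResult(term=term, x0=x0, null=null, p_value=p)

    def test_zero_p_ties_broken_by_x0_descending(self):
        results = [
            self.result("b", 3, 0.0),
            self.result("c", 9, 0.05),
            self.result("a", 7, 0.0),
        ]
        ranked = rank_candidates(results, AnalysisConfig())
        assert [r.term for r in ranked] == ["a", "b", "c"]
        assert [r.rank for r in ranked] == [1, 2, 3]

    def test_single_candidate_rank_one(self):
        (r,) = rank_candidates([self.result("a", 3, 0.2)], AnalysisConfig())
        assert r.rank == 1 and not r.significant

    def test_full_ties_fall_back_to_lexicographic(self):
        ranked = rank_candidates(
            [self.result("z", 5, 0.0), self.result("a", 5, 0.0)],
            AnalysisConfig(),
        )
        assert [r.term for r in ranked] == ["a", "z"]

    def test_significance_flag_follows_alpha(self):
        ranked = rank_candidates(
            [self.result("a", 5, 0.05), self.result("b", 5, 0.15)],
            AnalysisConfig(alpha=0.1),
        )
        assert [r.significant for r in ranked] == [True, False]

    def test_bh_q_values_monotone_and_bounded(self):
        results = [
            self.result(t, 3, p)
            for t, p in zip("abcde", [0.01, 0.02, 0.2, 0.5, 0.9])
        ]
        ranked = rank_candidates(results, AnalysisConfig(fdr_correction=True))
        qs = [r.q_value for r in ranked]
        assert all(0 <= q <= 1 for q in qs)
        assert qs == sorted(qs)
        assert all(q >= r.p_value for q, r in zip(qs, ranked))


class TestRunDdiTest:
    def test_enriched_term_gets_p_zero_rank_one(self):
        records = [
            make_record(i, ["Phenytoin"] if i < 5 else [], ["Drug Interactions"])
            for i in range(10)
        ] + [make_record(100 + i, ["Heparin"], ["Humans"]) for i in range(200)]
        corpus = Corpus("Warfarin", records)
        results = run_ddi_test(corpus, AnalysisConfig(seed=2))
        assert results[0].term == "Phenytoin"
        assert results[0].p_value == 0.0
        assert results[0].rank == 1
        assert results[0].significant

    def test_empty_group_a_yields_empty_results(self):
        corpus = Corpus(
            "W", [make_record(i, ["A"], ["Humans"]) for i in range(5)]
        )
        assert run_ddi_test(corpus, AnalysisConfig()) == []

    def test_no_candidate_reaches_cutoff(self):
        records = [
            make_record(1, ["Aspirin"], ["Drug Interactions"]),
            make_record(2, ["Aspirin"], ["Drug Interactions"]),
        ] + [make_record(10 + i, [], ["Humans"]) for i in range(10)]
        corpus = Corpus("W", records)
        assert run_ddi_test(corpus, AnalysisConfig(cutoff=3)) == []

    def test_every_result_respects_cutoff_and_rank_permutation(self, rng):
        from conftest import random_corpus

        corpus = random_corpus(rng, n_records=80)
        results = run_ddi_test(corpus, AnalysisConfig(seed=4))
        assert all(r.x0 >= 3 for r in results)
        assert sorted(r.rank for r in results) == list(
            range(1, len(results) + 1)
        )

    def test_determinism_same_seed_identical_results(self, rng):
        from conftest import random_corpus

        corpus = random_corpus(rng, n_records=60)
        cfg = AnalysisConfig(seed=11)
        a = run_ddi_test(corpus, cfg)
        b = run_ddi_test(corpus, cfg)
        assert [(r.term, r.x0, r.p_value, r.rank) for r in a] == [
            (r.term, r.x0, r.p_value, r.rank) for r in b
        ]
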