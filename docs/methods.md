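# Methods

## The statistical model

For a queried drug, every MEDLINE record retrieved for that drug either
carries a DDI-related MeSH heading (Group A, size n_A) or does not
(Group B, size n_B); records without MeSH headings are excluded. For a
candidate substance term t, the observed statistic is

    x0(t) = #{records in A whose substances field contains t}.

The null model asks: if t had nothing to do with DDI indexing, how often
would it appear in an arbitrary set of n_A articles about this drug? The
answer is estimated by resampling: R independent draws of n_A records from
Group B, uniformly without replacement within a draw, give null counts
x_1..x_R. Each draw's count is hypergeometric-like (sampling articles, not
term occurrences), and for the moderate rates involved the counts are well
approximated by a normal. The p-value is the upper tail of that normal fit:

    p(t) = 1 - Phi((x0 - mean(x_i)) / sd(x_i)),   sd with n-1 denominator.

This parametric reading is what resolves candidates far beyond the 1/R
resolution of a purely empirical tail (p-values like 1e-16 are meaningful
as "x0 is many sigmas above anything Group B produces"); the empirical
mode #{x_i > x0}/R is available as a cross-check and the two agree within
0.15 for central x0 on dispersed nulls (property-tested).

Degenerate nulls are handled by explicit rules rather than numerics:

* all x_i = 0 — the term never appears in any draw; p := 0, and all such
  candidates are ordered among themselves by x0 descending (a term seen 40
  times in A against a silent background outranks one seen 3 times);
* sd = 0 with nonzero mean (constant null) — step function: p = 0 if
  x0 > mean, else 1, the limit of the normal tail.

Ranking sorts by p ascending, ties by x0 descending, remaining ties
lexicographically, so output order is a deterministic function of the data
and seed. Significance is p < alpha with alpha = 0.1 by default; no
multiple-testing correction is applied by default (the method is a ranking
procedure, and the significance call mirrors the original operating
point), but Benjamini–Hochberg q-values can be attached via
`fdr_correction=True` for users who want FDR control.

## Parameters and defaults

| parameter | default | meaning |
|---|---|---|
| `cutoff` | 3 | minimum x0 (articles) for a candidate to be tested; below this the null is too sparse to rank stably |
| `n_resamples` | 100 | draws R building each null |
| `alpha` | 0.1 | significance level on the upper-tail p |
| `pvalue_mode` | `parametric_normal` | or `empirical` |
| `sample_with_replacement` | false | enable when n_B < n_A |
| `major_topics_only` | false | restrict the cohort split to major-topic MeSH headings |
| `require_drug_in_substances` | false | stricter co-occurrence: the drug itself must appear in the record's substances field |

Co-occurrence with the queried drug is defined by corpus membership —
every record was retrieved for the drug — not by the drug's presence in
the substances field; the flag above enables the stricter reading.

Raising `cutoff` trades list size for ranking quality (the `sweep`
command measures this as candidates vs AUC); the candidate sets at higher
cutoffs are always nested inside those at lower ones.

## Seeding

One master seed drives everything. Each resampling draw's generator is
spawned from `SeedSequence(seed)` by draw index, so draw membership
depends only on the seed, the pool and the draw size — adding or removing
candidates never perturbs which records are drawn, which makes cutoff
sweeps comparable and runs byte-reproducible. Run manifests therefore
contain no wall-clock timestamp: two runs with the same inputs and seed
produce identical tables, manifests and GraphML.

## Compound/protein classification

MEDLINE's substances field mixes small molecules with proteins, and the
two are reported separately (interaction partners vs candidate
mechanisms). Classification is lexical and auditable: a term is a protein
if it matches one of a small set of patterns (the word "protein",
"Cytochrome P-450", "CYP" + digit, "Receptor", enzyme-family names and
the "-ase(s)" suffix), otherwise a compound; the rule that fired is
recorded on every decision. A user-editable override file always wins over
the patterns. This stands in for the curated chemical/protein typing a
production MeSH lookup would provide, and is deliberately conservative:
no stemming, no external services.

## The social network

Significant terms (p < alpha and x0 ≥ cutoff) plus the queried drug form
the rows of a binary term–article incidence matrix over Group A (the
drug's row is all ones, by the membership convention). The one-mode
projection M·Mᵀ links two terms with weight equal to the number of shared
articles; edges below `min_edge_weight` (default 1 — nothing is dropped by
default) are pruned. The graph is undirected and simple, exported as
GraphML (node attribute `klass`, edge attribute `weight`) or a tab-
separated edge list, both in sorted order for byte stability. Networks
from two drug runs can be merged on shared nodes; a protein significant
for both drugs then forms a drug–protein–drug path, the motif suggesting
a pharmacokinetic interaction through a shared enzyme.

## Evaluation machinery

Three rankers are compared against a user-supplied gold standard of known
interactors (restricted to compound-class terms):

* **sampling** — the p-value ranking above;
* **cooccurrence_only** — x0 descending (no resampling filter);
* **frequency_only** — the candidate's count over the *whole* corpus
  (A and B), descending.

Accuracy@fraction uses n_top = ceil(fraction · n) so the evaluated top
list is never empty; a fixed top-n variant is also provided. ROC AUC is
computed from rank order via the Mann–Whitney identity. The precise
definitions of the two baselines are design choices (the distinction being
"how much does the resampling filter buy over raw counts"): frequency
counts over the full corpus, co-occurrence over Group A only.

## The synthetic generator

`simulate.generate` emulates the statistical structure the test assumes:
n_A records carrying the MeSH descriptor "Drug Interactions", n_B records
with only non-DDI descriptors, a block with no MeSH at all, and a
vocabulary whose terms occur in each record independently with a
group-specific Bernoulli rate. Defaults are the validation operating
point: n_A = 100, n_B = 2000, 20 MeSH-less records, 200 terms of which
10 are enriched at rate 0.30 in Group A vs 0.02 in Group B, background
rate 0.05 in both groups (high enough that background terms clear the
cutoff of 3, so the null machinery is genuinely exercised), 25% of the
vocabulary protein-styled so classification runs end to end. The null
scenario sets all rates equal (0.05). Compound-class enriched terms double
as an embedded gold standard.

What the generator does *not* model: correlated term occurrences
(co-prescribed drug pairs, enzyme families appearing together), realistic
MeSH vocabularies, heavy-tailed term frequencies, or citation growth.
Passing tests therefore demonstrate that the statistics behave as designed
under the independence null and a planted-enrichment alternative — not
that any particular real-world interaction list would be recovered.

Note on the accuracy ceiling: in the default scenario the gold standard
has ~8 compound interactors while the top-10% compound list has ~15
slots, so even a perfect ranker scores ~0.55 accuracy@10%; comparisons
between rankers, not the absolute level, are the meaningful output.

## Validation and problem sizes

The test suite checks: exact agreement of all counting paths (pair counts,
incidence row sums, projection weights) with brute-force enumeration on
randomized fixtures of up to 100 records × 50 terms; the p-value contract
(degenerate rules, the 0.5 point, closed-form normal tails to 1e-6); null
calibration over 20 seeded replicates of the null scenario (mean fraction
of candidates with p < 0.1 stays ≤ 0.25 and the median p is central — the
normal approximation on discrete counts is approximately, not exactly,
calibrated); ranking power over 20 enriched replicates (≥ 90% of the top
10 truly enriched; the sampling ranker's accuracy@10% ≥ both baselines in
≥ 80% of replicates); filter/partition conservation and nesting across
cutoffs; byte-level reproducibility under a fixed seed; and round-trip
identity plus cross-dialect agreement of the three record formats. The
acceptance script reruns the enrichment and null scenarios at 10
replicates each. These sizes keep the full suite under a minute while
giving 3–4 significant digits on the stochastic averages.

## Known limitations

* The normal tail on small discrete counts is an approximation; for
  candidates just above the cutoff the empirical mode is a useful sanity
  check.
* Lexical compound/protein classification will misclassify unusual protein
  names lacking any indicative pattern; the override file is the remedy.
* Substance-field indexing is manual upstream: terms absent from the field
  are invisible to the method, and near-synonymous substance strings are
  kept as distinct candidates by design (no identifier mapping).
* No live PubMed querying or synonym expansion: corpora are supplied as
  files in any of the three dialects.
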