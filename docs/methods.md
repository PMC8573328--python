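# Methods

This note documents the models, parameter choices and numerical conventions
behind `invgsea`, and what the synthetic benchmarks do and do not establish
about real data.

## Differential expression

Input is a gene × sample matrix of non-negative counts (or normalized
expression) and a two-group contrast. Gene identifiers are canonicalized
(upper case, whitespace stripped) and duplicate rows collapsed by summation
at load time. Library-size normalization (counts per million) is available
but optional; the simulated study conditions have equal library sizes by
construction.

Fold change is `log2((mean_treated + 1) / (mean_reference + 1))` on the raw
group means — the pseudocount of 1 avoids division by zero and makes results
bit-reproducible. P-values come from a two-sided location test on
log2(x + 1) values:

* **moderated** (default): an empirical-Bayes moderated t. Per-gene pooled
  variances s² (d = n₁ + n₂ − 2 degrees of freedom) are shrunk towards a
  common prior s₀² with d₀ prior degrees of freedom, both estimated by
  matching the moments of log s² to a scaled inverse-chi-square model
  (digamma/trigamma moment equations, Newton inversion of the trigamma
  function). The statistic uses the posterior variance
  (d₀s₀² + d·s²)/(d₀ + d) with d₀ + d degrees of freedom. With six
  replicates per group, per-gene variance estimates are the binding
  constraint on power; borrowing strength across genes is the standard
  remedy and raises sensitivity on the benchmark design from ≈0.58 (Welch)
  to ≈0.82 while leaving the null calibrated (the measured fraction of null
  genes at p < 0.01 matches the nominal 0.01).
* **welch**: the per-gene Welch t-test, provided for users who prefer a
  strictly per-gene procedure.

A mean-variance-trend prior (lowess fit of log s² on average expression) was
evaluated and not adopted: on the benchmark design it reduced the false
discovery proportion slightly but lost an equal amount of sensitivity, and
the simpler global prior is easier to reason about.

Differential calls use the study criteria — raw *P* < 0.01 **and**
|log₂FC| > 0.2, both strict inequalities. Benjamini–Hochberg adjusted
p-values are computed and reported but do not drive the calls unless the
caller uses them explicitly; the thresholds are configurable.

Degenerate genes (zero variance in both groups) get p = 1 when the means
agree and p = 0 when they differ.

## Ranking

The enrichment substrate is the full ranked list, descending in:

* **signal_to_noise** (default): (μ_t − μ_r)/(σ_t + σ_r) on log2(x + 1)
  values, with the conventional floor σ_used = max(σ, 0.2·|μ|, 0.2) so
  near-constant genes cannot dominate;
* **log2fc**: the signed pseudocounted fold change.

Ties are broken by gene identifier, ascending, making every ranking total
and deterministic; permuting the sample columns leaves all results
unchanged.

## Enrichment statistic and permutation null

The running score accumulates |r_j|^w/Σ|r|^w over set members and
1/(N − N_h) over non-members; the enrichment score is the signed value of
the running score at its first position of maximal magnitude. The weight
exponent defaults to w = 1 and is configurable; at w = 0 the magnitude
equals the two-sample KS statistic between hit and miss ranks (asserted
against `scipy.stats.ks_2samp` in the tests), and the statistic is then
invariant under strictly monotone transforms of the metric. Preconditions:
the set must intersect the list but not cover it, and at w > 0 the hit
weights must not all be zero. The running score provably closes at 0 and
this is asserted on every call. The leading edge contains the set members at
or before the extreme position (at or after it for negative ES).

Two permutation nulls are provided:

* **phenotype** (default, requires expression data): group labels are
  shuffled and the whole ranking recomputed, preserving inter-gene
  correlation. When a collection is tested the permuted rankings are
  computed once and shared by all sets.
* **gene_set**: random same-size sets rescored on the fixed ranking. When
  the number of possible subsets C(N, N_h) does not exceed the requested
  permutation count, all subsets are enumerated and the p-value is exact.

The p-value is the add-one estimator over permutations whose ES sign matches
the observed sign, so p ≥ 1/(1 + #same-sign) and never zero; in the
exhaustive case the observed set is itself part of the enumeration and the
plain proportion is reported. NES divides the observed ES by the mean |ES*|
of same-sign permutations; with fewer than two same-sign permutations NES is
reported as NaN with a warning. The estimator is mildly conservative (the
measured type-I error at nominal 0.05 is ≈0.02–0.04 with 200 permutations),
which is the usual price of the add-one correction at small permutation
counts. Permutation counts default to 1000 and a seed is mandatory.

FDR across a collection is Benjamini–Hochberg over the empirical p-values,
after a set-size filter (default: 5 ≤ N_h ≤ 500).

## Inverted cross-contrast enrichment

Contrast A's up- and down-called genes form the condition-specific set, with
per-gene direction retained. Against contrast B's ranked list, each up-gene
keeps its metric and each down-gene contributes the negated metric; the
modified list is re-ranked and the combined set scored. An unsigned union
set cannot distinguish concordance from inversion — with the signed
statistic, concordant regulation yields positive NES and systematic reversal
negative NES. The unsigned variant (A-up set alone) is computed alongside
for comparison. Counts of outright call flips (A-up ∧ B-down, A-down ∧
B-up) are exact set arithmetic over the intersection universe of the two
contrasts; genes absent from either contrast are dropped and logged, with a
warning when the shared universe covers less than 90% of the set.

The permutation null is phenotype-based when contrast B's expression matrix
is supplied (labels shuffled, ranking and signed scoring recomputed),
otherwise random signed sets (the observed direction multiset assigned to
random genes) on the fixed ranking.

## Interaction networks and MCODE

Edge lists are STRING-export style (node, node, combined score), with both
score dialects accepted — reals in [0, 1] or integers in 0–1000 (detected by
any value above 1 and rescaled by 1/1000). Reciprocal duplicates collapse to
one edge (highest score), self-loops are dropped and counted, and only edges
with combined score **strictly** above the threshold (default 0.4) are
retained. Scores are used solely for thresholding; module detection is
topological.

MCODE follows the classical three phases:

1. *Weighting*: a vertex below the degree cutoff (2) weighs 0; otherwise its
   weight is k_max × density of the k_max-core of its closed neighborhood.
2. *Growth*: from each unassigned seed in descending weight order (ties by
   node id), neighbors are admitted breadth-first when their weight exceeds
   seed_weight × (1 − node_score_cutoff), up to max_depth; each node joins
   at most one complex.
3. *Post-processing*: complexes without a K-core (2-core by default) are
   discarded; haircut reduces a complex to its 2-core (the fixed point of
   iteratively removing members with induced degree < 2); if that
   disconnects the complex, the component containing the seed is kept
   (largest component, ties by smallest member id, if the seed itself was
   trimmed). Fluff is exposed as an off-by-default flag but intentionally
   not implemented.

A module's score is induced density × node count (2E/(n−1)); a
loops-inclusive density variant (2E/(n+1) per node) can be reported
alongside, because published MCODE tables are not always a pure function of
the printed node and edge counts and the variant covers the common
alternative convention. Results are sorted by score, then size, then seed
id, so output is fully deterministic; an independent checker routine
re-validates every returned module (edge counts, connectivity, K-core,
haircut bound, score formula) and is exercised by the tests.

Note that greedy growth can merge two dense regions connected by a single
bridge whenever the bridge endpoints score within the admission window —
e.g. two 4-cliques joined by one edge come back as one complex. This matches
the underlying algorithm; callers who need finer granularity can lower the
node score cutoff.

## Synthetic data generator

The generator emulates the structure of a two-contrast degeneration study:
a shared gene universe, a core of truly differential genes planted in
contrast A, and the same genes re-planted in contrast B with a chosen
fraction of their directions flipped.

* Counts are negative binomial with var = μ + αμ²; gene-wise baseline means
  are log-normal (σ_log = 1, roughly a tenfold interquartile spread) around
  a configurable scale.
* Defaults — 2000 genes, 200 differential genes at |log₂FC| = 1, dispersion
  α = 0.1 (biological CV ≈ 0.32, typical of inbred-mouse bulk RNA-seq),
  baseline mean 200, six replicates per group — are the package's standard
  benchmark conditions, sized so the full suite runs on a laptop in about a
  minute.
* Planted effects multiply the treated-group mean by 2^(±lfc); contrast B
  flips the sign for a deterministic prefix of the planted gene list, so
  exactly round(φ·n_de) genes invert and designs differing only in φ are
  nested (the basis of the monotonicity benchmark).
* Interaction networks are Erdős–Rényi background plus planted blocks whose
  internal edge probability equals the requested density; edge scores are
  drawn strictly above 0.4 so topology tests are decoupled from threshold
  tests.

What the generator does **not** model: library-size variation, gene-length
effects, mean-dependent dispersion trends, correlated co-expression modules,
batch structure, or any mapping/quantification artifacts. Passing the
benchmarks therefore demonstrates correctness of the statistics and
algorithms under a clean, well-specified null and signal model — not
robustness to the full messiness of real RNA-seq, where normalization and
dispersion modelling matter more.

## Benchmarks computed by the acceptance script

`scripts/acceptance.py --seed S --out results/acceptance.json` recomputes,
at the standard conditions: the maximum discrepancy between the w = 0
enrichment statistic and an independent KS routine (100 random instances);
the permutation type-I error at nominal 0.05 under a global null (200 random
sets, 200 permutations); differential-expression sensitivity and
false-discovery proportion against planted truth (mean over ten designs);
the inverted-enrichment NES and p under 80% planted inversion and the
concordant NES at 0% (500 permutations); the cross-contrast flip counts; the
fraction of ten planted-module graphs recovered at Jaccard ≥ 0.8 and the
mean Jaccard; and the score of the K5-plus-pendant fixture. All randomness
derives from `--seed`.

## Known limitations

* "P < 0.01" is applied to raw p-values (with BH values reported
  alongside); on 20–30k-gene universes this implies a nontrivial absolute
  number of false calls, which is visible in the false-discovery proportion
  of ≈0.09 on the benchmark.
* The moderated test assumes variances are exchangeable across genes after
  the log transform; strongly mean-dependent dispersion would call for the
  trend variant of the prior or a count-model test.
* NES values are comparable across sets only under the same permutation
  scheme and count.
* MCODE module membership depends on the input network snapshot; published
  module tables are generally not reproducible without the same interaction
  database version, which is why the benchmarks use planted graphs with
  known truth instead.
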