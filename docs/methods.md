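# Methods

This note records the model the package implements, the choices made where
the design was genuinely open, and what the tests do and do not establish.

## Discretisation model

Expression values are treated as ordinal per gene: only whether a sample
sits in a gene's lower quarter, upper quarter or ambiguous middle matters
downstream. Normalisation is per gene (attribute-wise) min-max scaling to
[0, 1]; constant genes are dropped at this stage because they can never
discern any sample pair. Quartiles are estimated from a grouped-frequency
grid rather than order statistics:

    Q_k = l_c + ((R_k − cfr_{c−1}) / fr_c) · δ,   R_k = k · N_s / 4

with interval width δ = 1/`n_intervals`. `n_intervals` defaults to 10
(δ = 0.1 on the normalised domain), making thresholds deterministic and
cheap; the containing interval is the lowest c with cfr_c ≥ R_k, which
also resolves ranks falling on a boundary shared with an empty interval.
The grouped estimate and the inverse-ECDF sample quantile always lie in
the same interval, so they agree to within δ (property-tested); for very
sparse or gappy data the grouped estimate can sit far from interpolated
order-statistic quantiles — that is inherent to the grouped form, not an
implementation artifact.

Ternarisation applies the rule in order: value ≤ Th_i → `0`, else value ≥
Th_f → `1`, else `*`. With collapsed thresholds (Th_i = Th_f) a boundary
value therefore discretises to `0`. Th_i and Th_f are the k = 1 and k = 3
partition values; with continuous data this leaves roughly half of each
gene's samples in the ambiguous middle, and the ambiguity filter (drop
genes with `*`-count ≥ the mean `*`-count, Th_a) keeps the genes whose
expression is closest to bimodal. The comparison is non-strict (≥), so a
perfectly uniform table (all counts equal) filters to nothing and raises
instead of silently returning an empty table. Single-gene tables skip the
filter: a mean-threshold over one value is vacuous.

## Distinction table

Rows are the inter-class sample pairs, ordered lexicographically by
(class pair, first-sample index, second-sample index) with class labels
sorted, so repeated builds are identical. An entry is 1 iff both symbols
are definite and different; `*` never discerns. All-zero rows (pairs no
gene can discern) are retained — they cap Fit₂ below 1 and dropping them
would overstate a subset's discerning power. The matrix is stored as a
plain boolean array; coverage counting is a vectorised any-reduction, and
exactness of `covered_rows` is the only contract.

Multi-class data is supported by taking every unordered pair of classes;
row count is then the sum of class-size products, which reduces to C₁·C₂
for two classes.

## Objectives

Fit₁ = (N − O_v)/N and Fit₂ = R_v/n_rows, both maximised. Fit₂'s
denominator is the total row count, so the two-class and multi-class forms
coincide. The weighted sum Fit₁·α + Fit₂·(1−α) (0 < α < 1) is provided
only as a scalarisation helper for single-objective baselines; the swarm
itself optimises the pair under Pareto dominance.

## Swarm dynamics

The binary-PSO form is the canonical sigmoid-transfer variant: velocities
follow the inertia + cognitive + social rule and positions are
independent Bernoulli draws with probability sigmoid(v_i). Defaults:
P = 20 particles, G = 50 generations, w = 0.9, c₁ = c₂ = 2, velocity clamp
[−4, 4], initial velocities uniform on [−1, 1], initial bits
Bernoulli(0.5). The clamp matters: sigmoid(±4) ≈ 0.982/0.018 keeps every
bit permanently mutable, which is what lets the archive continue to pick
up front points late in a run.

Open points resolved as package conventions:

- **Personal best under incomparability** — replaced with a seeded fair
  coin. This keeps pbest drifting across the front instead of freezing at
  the first non-dominated point.
- **gbest** — re-drawn uniformly from the current swarm's rank-1 set every
  generation; all rank-1 members have equal priority.
- **Elitist survival** — parents and offspring are pooled (2P), ranked by
  non-dominated sorting, and the best P survive. Within the boundary rank
  the order is descending Fit₂, then descending Fit₁, then first-seen;
  a simple deterministic order rather than a density heuristic.
- **Archive** — every evaluated position enters an external archive pruned
  to mutual non-domination with unique positions; equal objective pairs
  may keep several witness subsets. The population alone can lose front
  points to the 50 % truncation; the archive cannot.

All randomness flows from one `numpy` Generator seeded by the
configuration, so runs are bit-reproducible; re-running any CLI command
with the same inputs and seed reproduces outputs byte for byte.

`exhaustive_pareto` enumerates all 2^N subsets (guarded at N ≤ 20),
finds the best coverage at each cardinality and keeps the strictly
improving ones. It is the exact-optimality oracle in the tests and is
deliberately a different algorithm from the swarm.

## Synthetic data

The generator plants a known minimal covering subset: class-B samples are
split round-robin into m blocks and informative gene i is high exactly in
block i, low in class A and the other blocks; informative genes beyond the
first m duplicate block assignments; noise genes are uniform on [0, 1].
Defaults — 30 genes, 3 informative, m = 3, classes of 5 and 6 samples —
describe a small instance with microarray-scale class sizes.

In ideal mode the low/high states are the extreme intensities 0.0 and 1.0.
This is what makes the ground truth provable: a value of 0 can never
exceed any Th_i ≥ 0 and a value of 1 can never fall below any Th_f ≤ 1,
so informative genes discretise to definite symbols with zero don't-cares
regardless of the thresholds the pipeline derives, gene i discerns exactly
the A x block_i pairs, and the minimal cover over informative genes is
exactly m. A two-cluster gene with *continuously spread* values cannot
guarantee this — its Q1/Q3 land inside the clusters and smear the clusters
across the threshold — so the point-mass construction is the only one that
decouples generator correctness from discretisation detail. Noisy mode
adds Gaussian perturbation (default sd 0.05) and clips to [0, 1],
restoring continuous spread at the cost of exactness guarantees.

What passing tests on this generator do **not** show: robustness to the
mean-variance structure, batch effects, spot artifacts or heavy-tailed
noise of real microarrays, nor behaviour at real dimensionality (thousands
of genes). The real-data path is exercised only through the CLI on
user-supplied matrices.

## Validation

k-NN is the native classifier: Euclidean distance on the selected genes,
odd k (voting ties are impossible for two classes), distance ties broken
by training order, multi-class label ties by the nearest voter. Folds are
stratified per class (shuffled, dealt round-robin) and seeded; a class
smaller than the fold count raises rather than producing empty strata.
Accuracy is reported in percent with two decimals. Other classifier
families plug in through the fit/predict adapter and are external
validation, not part of the method.

Z-scores standardise within a sample across all genes with the population
(divide-by-n) standard deviation; z is reported for the selected genes
only. Within-sample standardisation makes z invariant to per-array shift
and positive scaling, which is the property the report header documents.

## Problem sizes in the checks

The whole-method suite and `scripts/acceptance.py` use: the 7-feature toy
table; 50 random distinction tables with 4–12 features and class sizes
2–4; 500 random populations of ≤ 64 objective pairs for the sorting
oracle; planted datasets of 30 genes with classes (5, 6) for reduct
recovery; and classes (20, 24) for 10-fold cross-validation (stratified
10-fold needs at least 10 samples per class). These sizes make the exact
oracles affordable while leaving the search non-trivial.

## Known limitations

- Post-filter gene counts depend on the interval width δ; different
  `n_intervals` values give different retained-gene sets.
- The swarm is a heuristic: on larger instances the archive approximates
  the front and the exhaustive oracle no longer applies (N > 20).
- Missing intensities are rejected, not imputed.
- With duplicate-free minimal witnesses (a single gene uniquely covering a
  block structure at n_informative = m) and only 50 generations, recovery
  of the exact minimal reduct is unreliable; the default generator plants
  duplicated informative genes, which is also the regime the recovery
  checks run in.
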