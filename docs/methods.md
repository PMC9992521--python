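# Methods

## Problem setting

Gene-expression classification datasets live in the "big p, small n"
regime: thousands to tens of thousands of genes measured on tens to a few
hundred samples, with 2 or more (often imbalanced) phenotype classes. Most
genes carry no class signal; a small panel usually suffices for
classification and is what downstream biology wants. The package implements
a hybrid filter–wrapper selection: cheap filters shrink the search space,
then a population metaheuristic searches subsets with a classifier in the
loop.

## Preprocessing

Missing cells are imputed per gene with the mean of that gene's observed
values; each gene is then mapped affinely onto [0, 1] (min–max
normalization). Both steps are column-wise (per gene): that is the standard
for expression matrices and what the variance filter assumes. Degenerate
cases are explicit:

* a gene with zero observed values has no mean — an error naming the gene;
* a constant gene normalizes to all-zeros (with a warning) rather than
  raising: it is a guaranteed casualty of the variance filter;
* when all observed values of a gene are identical, the imputed value is
  that value *exactly* — naive mean summation can differ in the last bit,
  and min–max normalization would stretch that spurious 1-ulp spread across
  the whole [0, 1] range.

Accepted missing-value spellings: empty field, `NA`, `NaN`, `nan`, `?`.
Matrix orientation (samples-by-genes vs genes-by-samples) is an explicit
flag, never guessed.

## Stage 1 — variance filter

Keeps genes whose **population** variance (divide by m) on the normalized
scale is **strictly** greater than the threshold (default 0.05).
Normalization happens first: on [0, 1] the variance is at most 0.25, so a
fixed threshold is meaningful across datasets. Raising the threshold can
only shrink the retained set (monotonicity is tested).

A consequence worth knowing: for m ≈ 60 samples, an i.i.d. Gaussian noise
gene lands near variance 0.045–0.05 after min–max scaling, so the 0.05
default removes roughly two-thirds of pure-noise genes — and occasionally a
weakly-expressed informative gene whose normalized variance straddles the
threshold. The threshold is a config knob for datasets where this bites.

## Stage 2 — extremely-randomized-tree importance filter

An ensemble (default 100 trees, unlimited depth, `ceil(sqrt(D))` split
candidates per node) is fit on **all** samples without bootstrap;
impurity-based importances (summing to 1 when any split gains) rank the
candidates, and genes with numerically zero importance (≤ 1e-12) are
eliminated. The ensemble parameters are configurable defaults, not derived
quantities. Note that with unlimited depth and only tens of samples, most
candidate genes receive *some* split somewhere in 100 trees, so at small
candidate counts this stage prunes lightly; its value grows with the
gene dimension.

## Stage 3 — binary whale optimization

Whales are continuous positions `X ∈ [0,1]^D` over the D stage-2
candidates. Per iteration t (of T) and whale, with `a = 2 − 2t/T`,
`A = 2a·rand₁ − a`, `C = 2·rand₂`, and `p, l` fresh scalar draws:

* `p ≥ 0.5`: spiral toward the best-known position
  `X ← X_q + |X_q − X| · e^{b·l} cos(2πl)`, `l ~ U[−1,1]`, `b = 1`;
* `p < 0.5`, `|A| < 1`: encircle the best, `X ← X_q − A·|C·X_q − X|`;
* `p < 0.5`, `|A| ≥ 1`: explore against a uniformly chosen *other* whale,
  `X ← X_rand − A·|C·X_rand − X|`.

Scalars are drawn once per whale per move (scalar notation, not
per-dimension); `|·|` in the distance terms is element-wise; updated
positions are clipped into [0, 1], the simplest contract-preserving repair.

Masks are re-binarized at every evaluation (`mask_i = 1` iff a fresh
uniform draw < `x_i`), and the best-ever **mask** — not a re-binarization
of the best position — is archived, so the reported subset is exactly the
one that achieved the best fitness. Ties prefer fewer genes, then the
earlier discovery. The all-zero mask is assigned the attainable maximum
fitness 1.0 rather than repaired, keeping the objective total and the exit
subset nonempty. Fitness uses KNN (k = 5) over stratified 5-fold inner CV
whose folds are frozen once per run so every mask is scored on identical
partitions (and cached by mask). One master seed spawns independent
substreams for initialization, binarization and updates; identical
(data, parameters, seed) reproduce identical masks and traces bit-for-bit.

Fitness is bounded in [0, 1]; the elitist trace is non-increasing by
construction; and on instances small enough to enumerate (D ≤ 12 or so),
the optimizer's best fitness can be compared against the exhaustive minimum
over all 2^D masks evaluated on the same frozen folds — the independent
oracle used in the test suite and the acceptance script.

## External evaluation

Stratified k-fold CV (default tenfold; the fold count drops automatically,
with a warning, when the smallest class is smaller than k) under
decision-tree, SVM (RBF) and logistic-regression classifiers with library
defaults. Metrics from one-vs-rest confusion counts:
`Acc = (TP+TN)/(P+N)`, per-class `Precision = TP/(TP+FP)`,
`Recall = TP/(TP+FN)`, `F1 = 2·P·R/(P+R)`, macro-averaged with equal class
weights. Zero denominators yield 0 for that class metric — tiny test folds
make empty predicted-positive sets routine, and 0 is the conservative
convention. Independent repetitions (default 10, differing only by spawned
seeds) aggregate as mean and sample SD (ddof = 1).

Two protocols: **global** (default) selects once on all samples and then
cross-validates — comparable to the published protocol of this method
family but optimistically biased, since the selected genes have seen the
evaluation samples; **nested** reselects within each training fold for
honest estimates at roughly k× the cost.

## Synthetic data

The generator emulates the statistical shape of public microarray
classification sets: tiny m, huge n, class imbalance (default 60/40), a
handful of informative genes, many noise genes, some degenerate genes, and
a small missing fraction. Noise genes are i.i.d. Gaussian(0, σ²);
informative genes add a per-class mean shift of `effect_size · σ` between
adjacent classes (standardized effect, default 2.5); labels follow the
class proportions deterministically to within one sample; missing cells are
uniform at `missing_rate` (default 2%), with at least one observed value
kept per gene. Defaults: 60 samples × 1,000 genes, 10 informative, 50
near-constant.

Near-constant genes are **exactly constant** columns, modelling dead or
saturated probes. This is deliberate: min–max normalization is
scale-invariant, so a column with any i.i.d. jitter — however small —
normalizes to order-one variance and would not behave like a dead probe at
all; only the exactly-constant column survives preprocessing as the
zero-variance gene the variance filter must remove.

What the generator does *not* model: gene–gene correlation structure, batch
effects, probe-level heteroscedastic noise, heavy-tailed intensities.
Passing tests therefore demonstrate correct stage mechanics and search
behaviour under a clean additive-shift signal, not performance on real
microarray data.

## Behaviour worth knowing: recall is bounded by redundancy

The fitness explicitly rewards compact subsets. When several planted
informative genes are individually strong (standardized effect ≥ 2), two or
three of them already saturate the inner KNN accuracy, and masks that shed
the remaining (redundant) informative genes are fitness-neutral or better.
The optimizer therefore converges toward a *minimal sufficient* subset, not
the complete informative set: measured at the defaults (60 × 1,000, 10
informative at effect 2.5, N = 20 whales, T = 100 iterations),
planted-gene recall averages ≈ 0.5–0.65 and clears 0.6 in roughly half of
seeded runs, while held-out tenfold accuracy (mean over DT/SVM/LR) clears
0.9 in ≈ 90% of runs. Longer searches *lower* recall further (tighter
convergence to the minimal subset). This is a property of size-penalized
wrapper objectives in general: completeness of recovery is bounded by
feature redundancy, not by search quality. Use the filter-stage outputs,
not the wrapper output, when the goal is an exhaustive list of associated
genes.

## Numerical choices and problem sizes

* Variance comparison is strict (`>`); importances count as zero at
  ≤ 1e-12; fitness ties are broken exactly (identical frozen folds make
  equal-fitness masks exactly equal in floating point).
* The test suite and the acceptance script run entirely on generated data
  at deliberately modest sizes — staged instances of 12–1,000 genes and
  30–60 samples, 10–20 seeded repetitions, exhaustive enumeration at
  D ≤ 12 — chosen so the whole suite completes in minutes on one core
  while still exercising every stage at the study's statistical shape.
* All randomness flows from explicit integer seeds; there is no global RNG
  state anywhere in the package.

## Known limitations

* The canonical WOA explores weakly in binary spaces; with thousands of
  candidates and a 2,000-evaluation budget it returns subsets far larger
  than the minimal sufficient set (see the worked example's 133 genes).
* The global protocol's CV scores are optimistic (selection sees the
  evaluation data); nested mode is the honest alternative.
* No correction for gene–gene correlation: importances and KNN fitness both
  treat genes exchangeably.
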