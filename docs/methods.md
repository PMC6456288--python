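# Methods

## Problem and model

The package implements a filter feature-selection procedure for
high-dimensional classification tables — the regime of bulk/single-cell
expression matrices and similar biomedical data, where the number of
features far exceeds the number of instances and many columns are either
irrelevant to the phenotype or near-copies of one another.

All scores derive from discretized columns.  For two integer-coded
variables X, Y the package computes plug-in (maximum-likelihood) entropies
in bits,

    H(X)   = -Σ p(x) log2 p(x)
    H(X,Y) = -Σ p(x,y) log2 p(x,y)
    IG(X;Y) = H(X) + H(Y) - H(X,Y)  =  H(X) - H(X|Y),

and the symmetric uncertainty

    R(X,Y) = 2·IG(X;Y) / (H(X) + H(Y))  ∈ [0, 1].

`R_i,c` (feature vs class) is the *relevance* of feature i; `R_i,j`
(feature vs feature) is the *redundancy* between i and j.

## Selection procedure

1. **Irrelevance filter.**  Features with `R_i,c < τ` are discarded
   (default τ = 0, which keeps everything including weakly relevant
   features; constant columns score R = 0 and are retained at τ = 0, with
   a warning suggesting τ > 0).
2. **Descending sort** by `R_i,c`; ties broken by ascending original
   column index (a determinism choice — any stable rule would do).
3. **Redundancy removal.**  `R̄` is the mean relevance over the
   τ-survivors.  Walking pivots i in sorted order, each surviving
   lower-ranked feature j is removed when either rule fires:
   - *rule 1*: `R_i,c − R_j,c ≤ δ` **and** `R_i,j ≥ R_i,c`;
   - *rule 2*: `δ < R_i,c − R_j,c < α` **and** `R_i,j > (R̄ + R_j,c)/2`.

   Removed features are never revisited, as pivots or as candidates.  The
   count of `R_i,j` evaluations is reported (`pair_evaluations`): n−1 when
   everything is redundant with the first pivot, n(n−1)/2 when nothing is
   removed.

A feature whose `R_i,j` with every pivot stays below both rule thresholds
is never removed, whatever its own relevance: weak pairwise correlation
means no other feature can substitute for it.

### Parameters

| parameter | default | meaning |
|---|---|---|
| τ | 0 | irrelevance threshold on R_i,c (unitless, [0,1] scale) |
| δ | 0.08 | relevance-gap width for rule 1; recommended 0.05–0.13 |
| α | 0.64 | upper gap bound for rule 2 (strict `<`); recommended 0.60–0.66 |
| bins | 10 equal-width | discretization of continuous columns |

Values of δ/α outside the recommended ranges warn but run (the `sweep`
helper deliberately crosses them).  Where the gap conditions carry an
ambiguity between a non-strict and strict bound at α, the strict reading
is used; with continuous scores the two differ only on measure-zero ties.

### Numerical choices

- Probabilities are empirical frequencies; no pseudocounts, no
  bias-corrected estimators.  `0·log 0 = 0`.
- Entropy sums accumulate over *sorted* count tables, which makes
  `IG(X;Y) == IG(Y;X)` exact in floating point, not just to rounding.
- `R` is clipped to [0,1] and `IG` to ≥ 0 to absorb last-ulp excursions;
  with both variables constant, `R` is defined as 0.
- Equal-width binning splits [min, max] into half-open intervals with the
  last interval closed; constant columns map to a single code.  Codes are
  densified (empty bins removed) which changes no entropy.
- `R̄` is computed over the τ-retained features by default
  (`r_bar_scope="all"` switches to all features; identical at τ = 0).
- Missing values are rejected at load with cell locations; the selector
  has no missing-data semantics.

## Evaluation harness

Repeated stratified k-fold cross-validation with three
fixed-hyperparameter classifiers: random forest (10 trees), 1-NN, and a
linear-kernel SVM (other hyperparameters at scikit-learn defaults,
recorded in the report).  Defaults are 10 folds × 5 repeats; the
full-scale protocol of 100 repeats is a config change
(`EvalConfig(n_repeats=100)`), and desk-scale problem sizes throughout the
tests (≤ 500 instances, ≤ 200 features) were chosen so the whole suite
runs in seconds.

By default the selector runs *inside* each training fold, so no held-out
information reaches it; `selection_outside_folds=True` reproduces the
simpler protocol of selecting once on the full table.  Accuracy is
`100·C/(C+I)` over each held-out fold; the report aggregates fold-level
mean/max/min/std (std also reported over repeat-level means, since
conventions differ), the mean number of selected features (`MeanFN`), and
the composite score

    performance = w1·Acc + w2·(1 − n/N),   (w1, w2) = (0.999, 0.001),

which is dominated by accuracy and uses parsimony only to break near-ties.

## Synthetic data

The generator plants known structure: a binary phenotype at a chosen
balance (default 0.5), `informative` features drawn class-conditionally as
N(0,1) vs N(d,1) with d = 2.0 by default (the scale of a strongly
differentially-expressed marker; d is exposed as `effect_size`),
`exact_duplicate` verbatim copies of informative parents,
`noisy_duplicate` copies plus N(0, 0.1) jitter, and `irrelevant` N(0,1)
columns independent of the class.  Ground-truth group membership is
returned with the table, so duplicate elimination and irrelevance handling
are checkable without external data.

What the generator does *not* emulate: probe/batch effects, heavy-tailed
expression distributions, correlated noise blocks, multi-class phenotypes.
Passing tests therefore demonstrate algorithmic correctness and the
expected qualitative behaviour (noise pruning, duplicate elimination,
accuracy preservation under selection), not performance claims about any
particular real dataset.

## Known limitations

- The plug-in MI estimator with 10 bins is biased upward at small sample
  sizes: with tens of instances, the noise floor of `R_i,j` between
  independent continuous features approaches typical relevance values and
  the redundancy rules over-fire.  At microarray-scale instance counts
  (~60) fewer bins or equal-frequency binning is advisable; the default is
  kept at 10 equal-width bins for transparency and configurability.
- Rule 2 can prune a genuinely informative feature whose relevance gap to
  a stronger pivot lands inside (δ, α) while the two share class-driven
  correlation.  That is inherent to the procedure's aggressiveness, and on
  some data draws costs accuracy relative to the full set.
- Selection treats features greedily in relevance order; there is no
  backtracking and no wrapper-style search, by design.
- Only single-label categorical classes are supported.
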