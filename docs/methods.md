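# Methods

## Model

`sylvanreg` estimates a varying-coefficient linear model in two stages.

**Stage 1 — exploration.** A bagged ensemble of linear-model trees. Each
tree is grown on a bootstrap sample (size n, with replacement) by
stack-based depth-first binary splitting. Every node carries an OLS fit of
the standardized outcome on **all** p standardized predictors, regardless
of which features were candidates for splitting; the candidate set of j
features is redrawn uniformly without replacement at every node. A split
at (feature, threshold) sends values ≤ threshold left and is accepted when

1. it minimizes the aggregate of the two child-node MSEs over all
   candidate pairs,
2. `MSE_parent − aggregate > α · E_r` (strict), with `E_r` the MSE of the
   tree's own root fit on its bootstrap sample, and
3. both children have ≥ m samples, bootstrap multiplicity included, and
   neither child fit is degenerate.

After growth, every original sample (in-bag and out-of-bag alike) is
routed down every tree and its ensemble coefficient vector is the
equal-weight mean of the T landed-leaf coefficient vectors. An
`oob_only` switch restricts the average to out-of-bag trees.

**Stage 2 — consolidation.** Per-sample coefficients are plotted against
PC1 of the predictors; drift read off the plots is encoded as centered
piecewise-linear interaction columns `x · g(z)` (`g ∈ {lins, linz, trpz}`,
`g(0) = 0`) and the final model is one OLS fit with classical inference.
Because the shapes are chosen by eye, the interaction model's p-values are
exploratory; its report carries a caution footnote.

## Key choices and their rationale

- **Node MSE denominator is n (the node count), not n − k.** The split
  criterion compares MSEs across nodes of different sizes; "mean squared
  error" is taken literally. Inference in the reported models uses the
  unbiased RSS/(n − k) as usual.
- **Child aggregate is the plain sum `MSE_left + MSE_right`** — the
  literal reading of the splitting rule. Note this is demanding: a split
  qualifies only if the children roughly halve the parent MSE, so under
  mild heterogeneity trees stay shallow. The `weighted_split_mse` switch
  substitutes the size-weighted mean `(n_l·MSE_l + n_r·MSE_r)/n`, the
  common CART-style aggregate, which also splits on mild drift; it is off
  by default.
- **Candidate thresholds** are midpoints of consecutive distinct in-node
  feature values (CART convention, invariant to monotone jitter).
  Tie-breaks on the aggregate (within 1e-12): lowest feature index, then
  lowest threshold.
- **Degenerate (rank-deficient) node fits** are solved by minimum-norm
  least squares and flagged; a candidate split is rejected if either child
  is degenerate, and m ≥ p + 2 is enforced so every leaf fit is
  overdetermined.
- **Split search** runs on prefix Gram matrices (cumulative X'X, X'y along
  the feature order) with batched normal-equation solves — O(n·k²) per
  feature plus one batched solve instead of 2(n−1) refits. Negative RSS
  from cancellation is floored at zero; a grossly negative value (beyond
  1e-6 of the response scale) marks the candidate degenerate. The public
  `evaluate_split` refits children directly by least squares, and the test
  suite checks the sweep against brute-force enumeration.
- **Determinism.** Tree t's rng stream is spawned from (seed, t), so
  sequential and parallel (joblib) builds are bit-identical; all CSV
  outputs are byte-reproducible for a fixed seed.
- **Standardization** uses the sample (n − 1) standard deviation, outcome
  included, so all reported coefficients are standardized βs. Constant
  columns are an error; rows with missing values are dropped with a
  logged count.
- **PC1** is the leading eigenpair of the predictor correlation matrix.
  Reported loadings are correlation-scaled (eigenvector × √eigenvalue),
  i.e. the correlation between each variable and the score; the unit
  eigenvector is also kept. Sign is fixed by making the largest-|loading|
  variable (or a configured anchor variable) load positively.
- **Centering at other moderator values**: every piecewise shape accepts
  `center_at` (default 0), subtracting f(center) instead of f(0), so base
  coefficients can be re-anchored at any PC1 value.
- **Cross-validation** (k = 20 folds, 200 trees per fit by default)
  minimizes held-out ensemble prediction MSE over a grid; ties break
  toward the simpler model (larger α, larger m, smaller j). Folds are
  unstratified simple random splits.

## Defaults

| parameter | default | meaning |
|---|---|---|
| m | 45 | minimum node size (samples, with bootstrap multiplicity) |
| j | 4 | features drawn per split |
| α | 0.02 | required MSE reduction as a fraction of the root MSE `E_r` |
| T | 5000 | trees for final coefficient estimation (200 during CV) |
| k | 20 | cross-validation folds |

These are the operating point of the regional-health analysis the package
is built around (tuned there by the same CV procedure); on other data,
re-tune with `sylvan tune`. The CV grid default brackets that point:
m ∈ {25, 35, 45, 60}, j ∈ {2, 4, 8, p}, α ∈ {0.005, 0.01, 0.02, 0.05, 0.1}.

## Synthetic data

The generators provide ground truth that real regional tables cannot:

- `gen_two_regime` — a hard coefficient switch at a threshold of one
  feature; the cleanest target for tree splitting.
- `gen_varying_coefficient` — coefficients drifting with PC1 through a
  centered piecewise shape; the exact data-generating process of the
  interaction model.
- `gen_municipal_like` — a 544 × 16 surrogate for a Japanese city-level
  statistics table. Predictors follow a single-factor model whose
  loadings are patterned on an urbanization axis (education, income,
  population density, fiscal strength positive; primary industry, elderly
  workforce, car dependence negative); the squared loadings sum to ≈ 6.25
  so PC1 of 16 variables carries ≈ 39% of the variance. The outcome
  combines moderate fixed effects with two mild PC1-drifting coefficients
  (IW via `linz(−3, 1.5)`, TI via `trpz(−2.5, −1, 1, 2.5)`), and the
  noise sd is solved analytically from the realized signal variance so a
  homogeneous OLS fit lands near R² = 0.6.

What the surrogate does **not** emulate: real municipal marginal
distributions (skewness, bounded proportions, heavy-tailed populations),
spatial autocorrelation between neighbouring cities, outcome measurement
error that shrinks with population size, and more than one latent factor.
Tests passing on these generators show the estimator recovers the
structures it models — not that any particular real-world association
holds.

## Problem sizes used in tests and the acceptance script

Simulation sizes were chosen as the smallest that make the checked
contrasts unambiguous: split-search equivalence on 50 random nodes with
n ≤ 200, p ≤ 4; the no-split bagging limit at n = 500, T = 2000; regime
recovery at n = 600, T = 300; interaction-coefficient coverage over 50
replicates of n = 600; CV sanity at k = 5 folds × 50 trees; the
municipal-like surrogate at its natural n = 544 with T = 200–300.

## Known limitations

- The literal unweighted split criterion makes α behave unlike CART's
  complexity penalty: raising α beyond ~1 forbids all splits, while even
  α = 0 still requires the children to halve the parent MSE between them.
- Exhaustive threshold search is O(n·k² + n·k³-batched) per node and
  feature; for p in the hundreds a smarter candidate scheme would be
  needed.
- Piecewise shape parameters are user-chosen, not estimated; the final
  model's inference does not account for that selection.
- No missing-value handling inside trees; rows with missing cells are
  dropped at ingest.
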