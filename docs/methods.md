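# Methods

## The modeling problem

High-dimensional omics tables (metabolite features, OTU counts, proteomic
intensities) typically carry far more variables than observations. Supervised
learning on such tables faces two coupled problems: fitness estimates are
easily inflated by information leaking from test data into training or tuning,
and variable selections driven by leaky estimates accumulate false discoveries.
This package addresses both with repeated double cross-validation (rdCV) and a
resampling-based inference layer.

## Repeated double cross-validation with recursive elimination

Four nested loops:

1. **Repetitions** (`nRep`) re-randomize the CV segmentation to average out
   segmentation noise.
2. **Outer loop** (`nOuter` segments) holds one test segment out of *all*
   training and tuning; the remainder is the calibration set.
3. **Recursive elimination** removes, at each step, the worst-ranked fraction
   of variables so that `floor(n * varRatio)` survive (falling back to `n-1`
   when rounding removes nothing), terminating at 2 — a 1-variable PLS model
   is degenerate.
4. **Inner loop** (`nInner` folds, default `nOuter - 1`) splits the
   calibration set into training and validation folds, providing
   hyperparameter tuning (PLS component count; ties prefer the smaller model)
   and variable-importance estimates.

Importance is VIP (variable influence on projection) for PLS and
validation-fold permutation importance (one permutation per variable per inner
model, scored as MSE increase / accuracy decrease) for random forest. Ranks
are averaged over the inner folds of a calibration set, and hyperparameters
are re-tuned at every elimination step. A variable's final importance is its
average elimination-order rank across the `nRep x nOuter` calibration sets;
kept covariates never enter this ranking and are reported with rank 0.

Fold assignment is stratified: per class for categorical targets (dealing each
shuffled class into the currently least-filled segments), and by sorted-target
blocks for continuous ones, so segment target distributions are balanced and
segment sizes differ by at most one.

### Consensus selections

The validation-fitness curve (one value per calibration model per schedule
count) defines a tolerance band: `best +/- tolerance * (best - worst)` with
`tolerance = 0.05` of the curve's fitness range ("similar prediction
performance" made operational). The smallest and largest counts inside the
band give the minimal-optimal ("min") and all-relevant ("max") selections;
"mid" is the rounded geometric mean. Variable lists are nested by
construction (top-n of one global ranking).

Note an asymmetry that the tests rely on: the *validation* curve inherits
selection bias on the way down the schedule (variables were chosen to please
those same validation folds), while the pooled *hold-out* predictions per
schedule point remain leakage-free. Final reported fitness therefore always
comes from the hold-out predictions, scored per repetition against the full
target mean (Q2) and averaged over repetitions.

## Elastic net engine

Calibration models come from nesting the (alpha, lambda) search inside the
same outer loop: per calibration set, a shared log-spaced lambda path (100
points; ratio 1e-2 when p > n, 1e-4 otherwise, following the usual convention)
is evaluated per alpha on the inner folds, and the pair minimizing pooled
inner MSE (binomial deviance for classification) is refitted on the whole
calibration set. Ties prefer the stronger penalty. The alpha grid defaults to
{0.1, ..., 1.0}; pure ridge (alpha = 0) is excluded because it has no finite
lambda-path anchor. The lambda minimizing CV loss is used directly (no 1-SE
rule). Predictors are standardized per training set; coefficients are
reported on the original scale.

**Importance** is the proportion of the `nRep x nOuter` calibration models in
which a variable's coefficient is non-zero (exact zeros from the coordinate
descent solver; no epsilon). Because CV-min models are dense, ties at
proportion 1.0 are common; ranks therefore use the mean absolute standardized
coefficient as a secondary key.

**Covariate adjustment ("keep").** Kept covariates receive penalty factor
zero. For the gaussian family this is solved exactly through the
Frisch–Waugh identity: project the response and every penalized column onto
the covariates (plus intercept) within the training set, solve the elastic
net on the residuals, then recover the covariate coefficients by least
squares. The penalized problem on residualized data has *identical*
minimizers to the joint problem with unpenalized covariates, which the test
suite verifies against glmnet's `penalty.factor` mechanism. The binomial
family wraps the same weighted step in IRLS. Multinomial targets are not
supported (binary only).

**Selection** is either (a) a LOWESS curve of per-model hold-out fitness
versus non-zero count, after removing outliers by a local IQR rule (10
equal-count bins, multiplier 1.5), with the same tolerance-band min/max logic,
falling back to (b) quantiles (0.25, 0.5, 0.75, linear interpolation, rounded
half-up) of the per-model non-zero counts when the smoothed curve is
unusable.

## Validation strategies and resampling tests

Four strategies share one interface: `fit-predict` (train and test on all
data, hyperparameters from a single CV), `1cv` (fitness from pooled hold-out
predictions with hyperparameters tuned on those same folds — the bias is the
point of the strategy), `2cv` (nested CV) and `muvr2` (nested CV plus
recursive elimination, reported at the "mid" consensus size). For the elastic
net, `muvr2` is identical to `2cv` and is rejected with a message. Actual
fitness defaults to 50 repetitions, null models to 10 (both configurable).

Null targets are drawn either by permutation or by **resampling**: n draws
with replacement from the target's empirical distribution (observed class
probabilities for classification). Resampling gives the null the same excess
variability that model predictions have — a resample may even contain a
single class, in which case BER is computed over the classes present and
AUROC draws are redrawn (at most 100 attempts).

`H0_modeled` re-models each null target with the chosen strategy;
`H0_reference` scores null draws directly against the actual target with no
model anywhere. For Q2 the reference mean is analytically -1 (the expected
null residual sum of squares is twice the total sum of squares); for balanced
binary BER it is 1/2. A gap between `H0_modeled` and `H0_reference` diagnoses
structural overfitting of the strategy — largest for `fit-predict`, small for
nested CV.

P-values (always one-sided toward better-than-null; the tail flips for
minimized metrics) come from (i) rank order, floored at `1/(n_null+1)`,
(ii) a fitted t-distribution (`scipy.stats.t.fit`, df floored at 3), and
(iii) a Gaussian KDE (Silverman bandwidth) integrated over
`[min - 4bw, max + 4bw]` and normalized. A degenerate zero-variance null
yields p = 1 when the actual value does not beat it.

## Synthetic benchmarks

`simulate_causal` realises four causal roles among 100 predictors and 4
covariates, all structural noise standard normal:

| structure | equations |
|---|---|
| confounding | X1 = 2 C1 + e, Y += 2 C1 |
| direct cause + independent covariate | Y += X2, Y += C2 |
| mediation | C3 = X3 + e, Y += C3 |
| weak confounding | X4 = C4 + e, Y += C4 (half the strength of structure 1) |

The confounding arrows default to coefficient 2.0 and all others to 1.0.
This calibration makes the confounded proxy X1 the strongest *marginal*
correlate of Y (population correlations ~0.57 for X1 vs ~0.32 for X2/X3 and
~0.22 for X4) while X1 carries no signal at all once C1 is conditioned on —
exactly the situation where forcing covariates into the model should demote
X1, X3 and X4 and leave X2 untouched. With covariates kept, the elastic net
(which always uses the full covariate information) shows this demotion; PLS
and random forest do not, because latent projections and per-node feature
subsets use kept covariates only partially.

What the generator does *not* emulate: correlated feature blocks, heavy-tailed
intensity distributions, batch effects, missingness. Passing tests show the
machinery behaves correctly under the stated causal structures, not that any
particular real dataset is analyzable without care.

`simulate_signal_noise` plants `n_signal` iid N(0,1) predictors with a common
effect size; note that at n = 60 a planted effect of 3x the noise SD has
sample correlation 0.44 +/- 0.10, which falls below the maximum of 95 noise
correlations in roughly one seed in five — perfect recovery of all five
signals in every seed is not information-theoretically attainable at that
sample size, and the test suite documents the achieved rate.

## Problem sizes used by the test suite and the acceptance script

The causal-benchmark experiment runs 25 simulations at nRep = 5, nOuter = 6.
The PLS arm uses its full defaults (varRatio 0.75). The random-forest arm
uses 30 trees, mtry 10, nInner 2 and varRatio 0.5, and the elastic-net arm an
alpha grid of {0.1, 0.55, 1.0} with a 50-point lambda path — reduced grids
that keep a 4x25-run experiment tractable on a single core while leaving the
median-rank summaries unchanged in repeated runs at full settings. The forest
itself is plain bootstrap bagging of scikit-learn decision trees; the
ensemble wrapper's per-fit overhead dominates at these data sizes.

## Known limitations

* Elastic-net classification is binomial only; no multinomial path.
* No multilevel (paired/dependent-sample) analysis.
* The inner validation curve is selection-biased by design; only hold-out
  fitness should be quoted.
* LOWESS-based EN selection needs enough distinct non-zero counts; sparse
  scatters fall back to the quantile method with a warning.
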