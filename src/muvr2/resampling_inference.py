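"""Resampling tests, null distributions and p-values.

Classical permutation tests shuffle the target; resampling tests instead draw
null targets with replacement from the target's empirical distribution
(regression) or from the observed class probabilities (classification),
giving the null the same extra variability that model predictions have.

Two null distributions are produced:

* ``H0_modeled`` — the fitness of full modeling runs on resampled (or
  permuted) targets; it inherits whatever structural overfitting the chosen
  CV strategy allows.
* ``H0_reference`` — the fitness of the resampled targets scored directly
  against the actual target, with no model anywhere: the random-guessing
  baseline.  A gap between the two distributions diagnoses structural
  overfitting of the modeling strategy.

P-values for the actual fitness against ``H0_modeled`` are computed three
ways: by rank order, from a fitted t-distribution, and from a Gaussian-kernel
smoothed empirical distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .metrics import METRIC_DIRECTIONS, TargetVector, fitness
from .rdcv_core import OmicsDataset, _rng
from .validation_strategies import run_strategy

__all__ = [
    "NullSpec",
    "ResamplingResult",
    "permute_target",
    "resample_target",
    "h0_reference",
    "h0_modeled",
    "p_value",
    "run_resampling_test",
]


@dataclass
class NullSpec:
    mode: str = "resampling"        # "resampling" | "permutation"
    n_null: int = 400               # null targets modeled for H0_modeled
    n_reference: int = 1000         # direct draws for H0_reference
    n_rep_per_null: int = 10        # repetitions averaged per null model
    seed: int = 0

    def __post_init__(self):
        if self.mode not in ("resampling", "permutation"):
            raise ValueError("mode must be 'resampling' or 'permutation'")
        if min(self.n_null, self.n_reference, self.n_rep_per_null) < 1:
            raise ValueError("counts must be >= 1")


@dataclass
class ResamplingResult:
    fitness_actual: float
    h0_modeled: np.ndarray
    h0_reference: np.ndarray
    p_rank: float
    p_t: float
    p_smooth: float
    metric: str
    strategy: str
    per_rep_actual: np.ndarray = field(default_factory=lambda: np.array([]))


def permute_target(y: TargetVector, seed: int = 0) -> TargetVector:
    """A random permutation (identical multiset) of the target."""
    rng = seed if hasattr(seed, "permutation") else _rng(seed, 31)
    return TargetVector(np.asarray(y.values)[rng.permutation(len(y))], y.kind, y.classes)


def resample_target(y: TargetVector, seed: int = 0) -> TargetVector:
    """n independent draws with replacement from the target's empirical
    distribution (regression) or observed class probabilities (classification)."""
    rng = seed if hasattr(seed, "permutation") else _rng(seed, 32)
    idx = rng.integers(0, len(y), len(y))
    return TargetVector(np.asarray(y.values)[idx], y.kind, y.classes)


def _null_target(y, spec_mode, rng):
    return resample_target(y, rng) if spec_mode == "resampling" else permute_target(y, rng)


def h0_reference(y: TargetVector, metric: str, n_reference: int = 1000,
                 seed: int = 0, mode: str = "resampling") -> np.ndarray:
    """Fitness of null targets scored directly against the actual target.

    No model is fitted anywhere: the i-th value treats the i-th null draw as
    if it were the prediction.  Draws whose single represented class makes
    AUROC undefined are redrawn (up to 100 attempts each).
    """
    rng = _rng(seed, 33)
    vals = np.empty(n_reference)
    center = float(np.mean(y.values)) if y.kind == "continuous" else None
    for i in range(n_reference):
        for attempt in range(100):
            draw = _null_target(y, mode, rng)
            try:
                if metric.upper() == "AUROC":
                    scores = (np.asarray(draw.values) == y.classes[1]).astype(float)
                    vals[i] = fitness("AUROC", y.values, scores).value
                else:
                    vals[i] = fitness(metric, y.values, draw.values, center=center).value
                break
            except ValueError:
                if attempt == 99:
                    raise
    return vals


def h0_modeled(dataset: OmicsDataset, learner: str, strategy: str,
               null_spec: NullSpec, **strategy_kwargs) -> np.ndarray:
    """Fitness of full modeling runs on ``n_null`` null targets."""
    rng = _rng(null_spec.seed, 34)
    vals = np.empty(null_spec.n_null)
    for i in range(null_spec.n_null):
        y_null = _null_target(dataset.y, null_spec.mode, rng)
        ds = dataset.with_target(y_null)
        res = run_strategy(ds, learner, strategy, nRep=null_spec.n_rep_per_null,
                           seed=int(rng.integers(2**31)), **strategy_kwargs)
        vals[i] = res.fitness_actual
    return vals


def p_value(fitness_actual: float, h0: np.ndarray, direction: str,
            method: str = "smooth") -> float:
    """One-sided p-value of the actual fitness against a null sample.

    The tail always points toward better-than-null fitness, so for minimized
    metrics (RMSEP, BER, MISS) the comparison flips.  ``method`` is ``rank``
    (non-parametric, floored at 1/(n+1)), ``t`` (fitted t-distribution,
    df >= 3) or ``smooth`` (Gaussian-KDE tail, Silverman bandwidth).
    """
    h0 = np.asarray(h0, dtype=float)
    if h0.size == 0:
        raise ValueError("empty null sample")
    if direction not in ("maximize", "minimize"):
        direction = METRIC_DIRECTIONS[direction.upper()]
    # orient so that larger = better
    a = fitness_actual if direction == "maximize" else -fitness_actual
    h = h0 if direction == "maximize" else -h0
    n = h.size
    if np.ptp(h) == 0:
        return 1.0 if a <= h[0] else 1.0 / (n + 1)
    if method == "rank":
        return (1 + int(np.sum(h >= a))) / (n + 1)
    if method == "t":
        df, loc, scale = stats.t.fit(h)
        df = max(df, 3.0)
        return float(np.clip(stats.t.sf(a, df, loc=loc, scale=scale),
                             np.finfo(float).tiny, 1.0))
    if method == "smooth":
        kde = stats.gaussian_kde(h, bw_method="silverman")
        bw = np.sqrt(kde.covariance[0, 0])
        hi = h.max() + 4 * bw
        if a >= hi:
            return float(np.finfo(float).tiny)
        lo = max(a, h.min() - 4 * bw)
        total = kde.integrate_box_1d(h.min() - 4 * bw, hi)
        return float(np.clip(kde.integrate_box_1d(lo, hi) / total,
                             np.finfo(float).tiny, 1.0))
    raise ValueError("method must be 'rank', 't' or 'smooth'")


def run_resampling_test(dataset: OmicsDataset, learner: str, strategy: str,
                        null_spec: NullSpec | None = None, nRep_actual: int = 50,
                        fitness_metric: str | None = None,
                        **strategy_kwargs) -> ResamplingResult:
    """Actual fitness, both null distributions and the three p-values."""
    null_spec = null_spec or NullSpec()
    if fitness_metric is None:
        fitness_metric = "Q2" if dataset.y.kind == "continuous" else "BER"
    fitness_metric = fitness_metric.upper()
    actual = run_strategy(dataset, learner, strategy, nRep=nRep_actual,
                          fitness_metric=fitness_metric, seed=null_spec.seed,
                          **strategy_kwargs)
    h0m = h0_modeled(dataset, learner, strategy, null_spec,
                     fitness_metric=fitness_metric, **strategy_kwargs)
    h0r = h0_reference(dataset.y, fitness_metric, null_spec.n_reference,
                       null_spec.seed, null_spec.mode)
    direction = METRIC_DIRECTIONS[fitness_metric]
    return ResamplingResult(
        actual.fitness_actual, h0m, h0r,
        p_rank=p_value(actual.fitness_actual, h0m, direction, "rank"),
        p_t=p_value(actual.fitness_actual, h0m, direction, "t"),
        p_smooth=p_value(actual.fitness_actual, h0m, direction, "smooth"),
        metric=fitness_metric, strategy=actual.strategy,
        per_rep_actual=actual.per_rep)
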