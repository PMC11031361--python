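"""Four cross-validation strategies behind one interface.

The strategies differ in how much of the data is held out from training and
tuning, and therefore in how much optimistic bias their fitness estimate
carries:

* ``fit-predict`` — the whole dataset is used for training and testing;
  hyperparameters come from a single CV.  Maximally biased.
* ``1cv`` — single cross-validation: fitness comes from pooled hold-out
  predictions, but hyperparameters are tuned on those same folds.
* ``2cv`` — double (nested) cross-validation: the outer test segments are held
  out from all training and tuning.
* ``muvr2`` — double CV plus recursive variable elimination; for the elastic
  net this is identical to ``2cv`` (no recursive elimination) and is rejected.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .metrics import METRIC_DIRECTIONS, is_better
from .rdcv_core import (OmicsDataset, _PLS, _assign_segments, _fit_rf,
                        _pooled_fitness, _rng, fit_rdcv, make_cv_plan)
from .elastic_net_engine import (DEFAULT_ALPHA_GRID, _GaussianKeepEN,
                                 _lambda_path, _wlstsq, fit_nested_en)

__all__ = ["StrategyResult", "run_strategy", "STRATEGIES"]

STRATEGIES = ("fit-predict", "1cv", "2cv", "muvr2")


@dataclass
class StrategyResult:
    strategy: str
    learner: str
    fitness_actual: float          # mean over repetitions
    per_rep: np.ndarray            # one value per repetition (fit-predict: length 1)
    metric: str
    detail: object = None          # underlying engine result where applicable


def _norm_strategy(s: str) -> str:
    s = s.lower().replace("_", "-")
    aliases = {"fit-predict": "fit-predict", "fitpredict": "fit-predict",
               "1cv": "1cv", "cv1": "1cv", "2cv": "2cv", "cv2": "2cv",
               "muvr2": "muvr2"}
    if s not in aliases:
        raise ValueError(f"unknown strategy {s!r}; choose from {STRATEGIES}")
    return aliases[s]


def run_strategy(dataset: OmicsDataset, learner: str, strategy: str,
                 nRep: int = 50, nOuter: int = 6, nInner: int | None = None,
                 varRatio: float = 0.75, fitness_metric: str | None = None,
                 seed: int = 0, max_comp: int = 5, n_trees: int = 150,
                 alpha_grid=DEFAULT_ALPHA_GRID, n_lambda: int = 100) -> StrategyResult:
    """Run one CV strategy and return its (per-repetition) fitness."""
    learner = learner.upper()
    strategy = _norm_strategy(strategy)
    y = dataset.y
    if fitness_metric is None:
        fitness_metric = "Q2" if y.kind == "continuous" else "BER"
    fitness_metric = fitness_metric.upper()
    if learner == "EN" and strategy == "muvr2":
        raise ValueError("MUVR2-EN does not perform recursive variable elimination; "
                         "its rdCV is identical to '2cv' — run strategy='2cv' instead")

    if strategy == "fit-predict":
        val = _fit_predict(dataset, learner, nOuter, fitness_metric, seed,
                           max_comp, n_trees, alpha_grid, n_lambda)
        return StrategyResult(strategy, learner, val, np.array([val]), fitness_metric)

    if strategy == "1cv":
        per_rep = np.array([
            _cv1_once(dataset, learner, nOuter, fitness_metric,
                      int(_rng(seed, 21, r).integers(2**31)), max_comp, n_trees,
                      alpha_grid, n_lambda)
            for r in range(nRep)
        ])
        return StrategyResult(strategy, learner, float(per_rep.mean()), per_rep,
                              fitness_metric)

    if learner == "EN":  # strategy == "2cv"
        res = fit_nested_en(dataset, nRep=nRep, nOuter=nOuter, nInner=nInner,
                            alpha_grid=alpha_grid, n_lambda=n_lambda,
                            fitness_metric=fitness_metric, seed=seed)
        return StrategyResult(strategy, learner, res.fitness_mean,
                              res.rep_fitness, fitness_metric, res)

    res = fit_rdcv(dataset, learner=learner, nRep=nRep, nOuter=nOuter,
                   nInner=nInner, varRatio=varRatio,
                   fitness_metric=fitness_metric, seed=seed, max_comp=max_comp,
                   n_trees=n_trees, eliminate=(strategy == "muvr2"))
    if strategy == "2cv":
        per_rep = res.rep_fitness[res.schedule[0]]
    else:  # muvr2: fitness of the consensus "mid" model
        per_rep = res.rep_fitness_at(res.selection.n_mid)
    return StrategyResult(strategy, learner, float(np.mean(per_rep)),
                          np.asarray(per_rep), fitness_metric, res)


# ---------------------------------------------------------------------------
# fit-predict and 1CV
# ---------------------------------------------------------------------------

def _pls_fold_fitness(dataset, assign, nFold, metric, max_comp):
    """Pooled hold-out fitness per component count over one segmentation."""
    y = dataset.y
    classes = y.classes
    K = len(classes) if classes else 1
    n = dataset.n_obs
    max_a = max_comp
    for f in range(nFold):
        max_a = min(max_a, int(np.sum(assign != f)) - 1)
    max_a = max(1, min(max_a, dataset.n_vars))
    preds = np.zeros((max_a, n, K))
    for f in range(nFold):
        val = np.flatnonzero(assign == f)
        tr = np.flatnonzero(assign != f)
        m = _PLS(dataset.X[tr], y.subset(tr), max_a)
        for a in range(1, max_a + 1):
            preds[a - 1, val, :] = m.predict_raw(dataset.X[val], a)
    center = float(np.mean(y.values)) if y.kind == "continuous" else None
    fits = [_pooled_fitness(metric, y, preds[a - 1] if classes else preds[a - 1, :, 0],
                            classes, center) for a in range(1, max_a + 1)]
    return fits


def _best(values, metric):
    direction = METRIC_DIRECTIONS[metric]
    best = 0
    for i in range(1, len(values)):
        if is_better(values[i], values[best], direction):
            best = i
    return best


def _fit_predict(dataset, learner, nOuter, metric, seed, max_comp, n_trees,
                 alpha_grid, n_lambda):
    """Train and test on the full data; hyperparameters from a single CV."""
    y = dataset.y
    classes = y.classes
    center = float(np.mean(y.values)) if y.kind == "continuous" else None
    if learner == "PLS":
        assign = _assign_segments(y, nOuter, _rng(seed, 22))
        fits = _pls_fold_fitness(dataset, assign, nOuter, metric, max_comp)
        a = _best(fits, metric) + 1
        m = _PLS(dataset.X, y, a)
        preds = m.predict_raw(dataset.X, a)
        return _pooled_fitness(metric, y, preds if classes else preds[:, 0],
                               classes, center)
    if learner == "RF":
        m = _fit_rf(dataset.X, y, n_trees, int(_rng(seed, 23).integers(2**31)))
        if classes:
            return _pooled_fitness(metric, y, m.predict_proba(dataset.X), classes, center)
        return _pooled_fitness(metric, y, m.predict(dataset.X), classes, center)
    if learner == "EN":
        if y.kind == "categorical":
            raise NotImplementedError("fit-predict EN is implemented for regression targets")
        yv = np.asarray(y.values, float)
        Xf = dataset.X[:, dataset.free_idx]
        C = dataset.X[:, dataset.keep_idx]
        assign = _assign_segments(y, nOuter, _rng(seed, 24))
        alpha, lam = _en_grid_search(Xf, yv, C, assign, nOuter, alpha_grid,
                                     n_lambda, pooled=False)[0]
        solver = _GaussianKeepEN(Xf, yv, C)
        beta = solver.path(alpha, [lam])[:, 0]
        bc = solver.covariate_coefs(beta)
        preds = solver.predict(Xf, C, beta, bc)
        return _pooled_fitness(metric, y, preds, classes, center)
    raise ValueError(f"unknown learner {learner!r}")


def _cv1_once(dataset, learner, nOuter, metric, seed, max_comp, n_trees,
              alpha_grid, n_lambda):
    """Single CV with hyperparameters tuned on the evaluation folds themselves."""
    y = dataset.y
    classes = y.classes
    center = float(np.mean(y.values)) if y.kind == "continuous" else None
    assign = _assign_segments(y, nOuter, _rng(seed, 25))
    if learner == "PLS":
        fits = _pls_fold_fitness(dataset, assign, nOuter, metric, max_comp)
        return fits[_best(fits, metric)]
    if learner == "RF":
        K = len(classes) if classes else 1
        preds = np.zeros((dataset.n_obs, K))
        rng = _rng(seed, 26)
        for f in range(nOuter):
            val = np.flatnonzero(assign == f)
            tr = np.flatnonzero(assign != f)
            m = _fit_rf(dataset.X[tr], y.subset(tr), n_trees, int(rng.integers(2**31)))
            if classes:
                preds[val, :] = m.predict_proba(dataset.X[val])
            else:
                preds[val, 0] = m.predict(dataset.X[val])
        return _pooled_fitness(metric, y, preds if classes else preds[:, 0],
                               classes, center)
    if learner == "EN":
        if y.kind == "categorical":
            raise NotImplementedError("1cv EN is implemented for regression targets")
        yv = np.asarray(y.values, float)
        Xf = dataset.X[:, dataset.free_idx]
        C = dataset.X[:, dataset.keep_idx]
        (_, _), best_mse = _en_grid_search(Xf, yv, C, assign, nOuter, alpha_grid,
                                           n_lambda, pooled=True)
        ss_tot = np.sum((yv - yv.mean()) ** 2)
        if metric == "Q2":
            return 1.0 - best_mse * len(yv) / ss_tot
        return float(np.sqrt(best_mse))
    raise ValueError(f"unknown learner {learner!r}")


def _en_grid_search(Xf, yv, C, assign, nFold, alpha_grid, n_lambda, pooled):
    """Hold-out MSE over the (alpha, lambda) grid for one fold assignment.

    Returns ``((alpha, lambda), best_mse)``; with ``pooled`` the MSE is the
    pooled hold-out loss (the biased 1CV estimate), otherwise it is only used
    to pick the pair.
    """
    base = _GaussianKeepEN(Xf, yv, C)
    best = (np.inf, None, None)
    for alpha in alpha_grid:
        lambdas = _lambda_path(base.Xr, base.yr, alpha, n_lambda)
        sse = np.zeros(len(lambdas))
        for f in range(nFold):
            val = np.flatnonzero(assign == f)
            tr = np.flatnonzero(assign != f)
            sub = _GaussianKeepEN(Xf[tr], yv[tr], C[tr])
            coefs = sub.path(alpha, lambdas)
            bc = _wlstsq(sub.C1, yv[tr][:, None] - sub.Xs @ coefs)
            Xs_val = (Xf[val] - sub.mean) / sub.sd
            C1_val = np.column_stack([np.ones(len(val)), C[val]])
            preds = C1_val @ bc + Xs_val @ coefs
            sse += np.sum((preds - yv[val][:, None]) ** 2, axis=0)
        j = int(np.argmin(sse))
        if sse[j] < best[0]:
            best = (sse[j], alpha, lambdas[j])
    return (best[1], best[2]), best[0] / len(yv)
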