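"""Nested cross-validated elastic net with covariate adjustment.

Calibration-set models are obtained by nesting an inner CV (joint tuning of
the mixing parameter alpha and the penalty strength lambda over a shared
log-spaced path) inside the outer rdCV loop.  Variable importance is the
proportion of calibration models in which a variable's coefficient is
non-zero.  Covariates listed in ``keep_vars`` enter every model with penalty
factor zero: for the gaussian family this is solved exactly through the
Frisch–Waugh partialling-out identity (residualize the response and the
penalized block on the covariates within each training set, solve the
penalized problem on residuals, then recover covariate coefficients by least
squares); the binomial family wraps the same weighted step in IRLS.

Two selection procedures are provided: a fitness-curve method (LOWESS over the
per-model scatter of hold-out fitness versus non-zero count, with local-IQR
outlier removal) and a direct quantile method on the non-zero counts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata
from sklearn.linear_model import ElasticNet, enet_path
from statsmodels.nonparametric.smoothers_lowess import lowess

from .metrics import METRIC_DIRECTIONS, TargetVector, fitness
from .rdcv_core import (ConsensusSelection, OmicsDataset, _assign_segments,
                        _nearest_count, _rng, _round_half_up, make_cv_plan)

__all__ = [
    "ENCalibrationModel",
    "ENImportance",
    "ENResult",
    "fit_nested_en",
    "en_importance",
    "select_by_fitness_curve",
    "select_by_quantiles",
]

DEFAULT_ALPHA_GRID = tuple(np.round(np.arange(0.1, 1.01, 0.1), 2))


# ---------------------------------------------------------------------------
# solver internals
# ---------------------------------------------------------------------------

def _standardize_fit(X):
    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    return mean, sd


def _wlstsq(C1, M, w=None):
    """(Weighted) least-squares coefficients of each column of M on C1."""
    M2 = M if M.ndim > 1 else M[:, None]
    if w is None:
        beta, *_ = np.linalg.lstsq(C1, M2, rcond=None)
    else:
        sw = np.sqrt(w)[:, None]
        beta, *_ = np.linalg.lstsq(C1 * sw, M2 * sw, rcond=None)
    return beta[:, 0] if M.ndim == 1 else beta


def _lambda_path(Xr, yr, alpha, n_lambda, w=None):
    """glmnet-style log-spaced penalty path for one mixing parameter."""
    n = Xr.shape[0]
    if w is None:
        grad = np.abs(Xr.T @ yr) / n
    else:
        grad = np.abs(Xr.T @ (w * yr)) / np.sum(w)
    lam_max = max(grad.max() / max(alpha, 1e-3), 1e-10)
    eps = 1e-2 if n < Xr.shape[1] else 1e-4
    return np.logspace(np.log10(lam_max), np.log10(lam_max * eps), n_lambda)


class _GaussianKeepEN:
    """Elastic net with zero-penalty covariates, gaussian family.

    ``C`` may be empty, in which case only the intercept is unpenalized.
    """

    def __init__(self, X_free, y, C):
        self.mean, self.sd = _standardize_fit(X_free)
        self.Xs = (X_free - self.mean) / self.sd
        self.C1 = np.column_stack([np.ones(len(y)), C])
        self.y = np.asarray(y, dtype=float)
        self.Bx = _wlstsq(self.C1, self.Xs)
        self.by = _wlstsq(self.C1, self.y)
        self.Xr = self.Xs - self.C1 @ self.Bx
        self.yr = self.y - self.C1 @ self.by

    def path(self, alpha, lambdas):
        """Penalized coefficients (standardized scale) along a lambda path."""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            _, coefs, _ = enet_path(self.Xr, self.yr, l1_ratio=alpha,
                                    alphas=np.asarray(lambdas))
        return coefs  # (p, n_lambda)

    def covariate_coefs(self, beta_std):
        """Unpenalized coefficients (intercept first) given penalized ones."""
        return _wlstsq(self.C1, self.y - self.Xs @ beta_std)

    def predict(self, X_free_new, C_new, beta_std, bc):
        Xs = (X_free_new - self.mean) / self.sd
        C1 = np.column_stack([np.ones(len(Xs)), C_new])
        return C1 @ bc + Xs @ beta_std


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.clip(x, -30, 30)))


class _BinomialKeepEN:
    """Binomial elastic net with zero-penalty covariates via IRLS around the
    weighted gaussian partialled-out step."""

    def __init__(self, X_free, y01, C):
        self.mean, self.sd = _standardize_fit(X_free)
        self.Xs = (X_free - self.mean) / self.sd
        self.C1 = np.column_stack([np.ones(len(y01)), C])
        self.y = np.asarray(y01, dtype=float)

    def fit(self, alpha, lam, max_iter=30, tol=1e-5):
        n, p = self.Xs.shape
        beta = np.zeros(p)
        pbar = np.clip(self.y.mean(), 1e-3, 1 - 1e-3)
        bc = np.zeros(self.C1.shape[1])
        bc[0] = np.log(pbar / (1 - pbar))
        for _ in range(max_iter):
            eta = self.C1 @ bc + self.Xs @ beta
            mu = _sigmoid(eta)
            w = np.clip(mu * (1 - mu), 1e-5, None)
            z = eta + (self.y - mu) / w
            Bx = _wlstsq(self.C1, self.Xs, w)
            bz = _wlstsq(self.C1, z, w)
            Xr = self.Xs - self.C1 @ Bx
            zr = z - self.C1 @ bz
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                m = ElasticNet(alpha=lam, l1_ratio=alpha, fit_intercept=False,
                               max_iter=2000)
                m.fit(Xr, zr, sample_weight=w)
            new_beta = m.coef_
            new_bc = _wlstsq(self.C1, z - self.Xs @ new_beta, w)
            delta = max(np.max(np.abs(new_beta - beta)), np.max(np.abs(new_bc - bc)))
            beta, bc = new_beta, new_bc
            if delta < tol:
                break
        return beta, bc

    def predict_proba(self, X_free_new, C_new, beta, bc):
        Xs = (X_free_new - self.mean) / self.sd
        C1 = np.column_stack([np.ones(len(Xs)), C_new])
        return _sigmoid(C1 @ bc + Xs @ beta)


# ---------------------------------------------------------------------------
# result containers
# ---------------------------------------------------------------------------

@dataclass
class ENCalibrationModel:
    rep: int
    outer: int
    alpha: float
    lam: float
    coef: dict                  # variable -> coefficient on the original scale
    coef_std: np.ndarray        # penalized coefficients, standardized scale
    nonzero: tuple              # non-zero free variables (covariates excluded)
    holdout_idx: np.ndarray
    holdout_fitness: float


@dataclass
class ENImportance:
    """Per-variable proportion of calibration models with a non-zero coefficient."""

    var_names: list             # free variables
    proportion: np.ndarray
    mean_abs_coef: np.ndarray   # secondary ranking key (standardized scale)
    rank: np.ndarray            # 1..n_free, mid-ranks on exact ties
    keep_vars: tuple = ()       # flagged separately; non-zero by construction

    def order(self) -> np.ndarray:
        return np.lexsort((np.asarray(self.var_names, dtype=object),
                           -self.mean_abs_coef, -self.proportion))

    def as_dict(self) -> dict:
        d = {v: 0.0 for v in self.keep_vars}
        d.update({v: float(r) for v, r in zip(self.var_names, self.rank)})
        return d


@dataclass
class ENResult:
    models: list
    importance: ENImportance
    holdout: np.ndarray         # (nRep, n_obs[, K]) hold-out predictions/probabilities
    rep_fitness: np.ndarray
    plan: object
    params: dict

    @property
    def fitness_mean(self) -> float:
        return float(np.mean(self.rep_fitness))


def _two_key_ranks(prop, mac):
    """Mid-ranks by (proportion desc, mean |coef| desc)."""
    order = np.lexsort((-mac, -prop))
    n = len(prop)
    rank = np.empty(n)
    pos = 1
    i = 0
    while i < n:
        j = i
        while (j + 1 < n and prop[order[j + 1]] == prop[order[i]]
               and mac[order[j + 1]] == mac[order[i]]):
            j += 1
        mid = (pos + pos + (j - i)) / 2.0
        for t in range(i, j + 1):
            rank[order[t]] = mid
        pos += j - i + 1
        i = j + 1
    return rank


def en_importance(models, var_names, keep_vars=()) -> ENImportance:
    """Importance as the proportion of non-zero coefficients across models."""
    if not models:
        raise ValueError("need at least one calibration model")
    prop = np.zeros(len(var_names))
    mac = np.zeros(len(var_names))
    pos = {v: i for i, v in enumerate(var_names)}
    for m in models:
        for v in m.nonzero:
            prop[pos[v]] += 1
        mac += np.abs(m.coef_std)
    prop /= len(models)
    mac /= len(models)
    return ENImportance(list(var_names), prop, mac, _two_key_ranks(prop, mac),
                        tuple(keep_vars))


# ---------------------------------------------------------------------------
# nested CV fit
# ---------------------------------------------------------------------------

def fit_nested_en(dataset: OmicsDataset, nRep: int = 5, nOuter: int = 6,
                  nInner: int | None = None, alpha_grid=DEFAULT_ALPHA_GRID,
                  n_lambda: int = 100, fitness_metric: str | None = None,
                  seed: int = 0) -> ENResult:
    """Nested cross-validated elastic net over an (alpha, lambda) grid.

    Per calibration set the pair minimizing pooled inner-CV loss (MSE for
    regression, binomial deviance for classification) is chosen and refitted;
    hold-out predictions come from the withheld outer test segment only.
    Ties favour the stronger penalty (larger lambda, earlier alpha).
    """
    alpha_grid = tuple(alpha_grid)
    if not alpha_grid or any(not (0 < a <= 1) for a in alpha_grid):
        raise ValueError("alpha_grid must be non-empty with values in (0, 1]; "
                         "pure ridge (alpha=0) has no finite lambda path")
    y = dataset.y
    if y.kind == "categorical" and y.n_classes != 2:
        raise ValueError("elastic net classification supports binary targets only")
    if fitness_metric is None:
        fitness_metric = "Q2" if y.kind == "continuous" else "BER"
    fitness_metric = fitness_metric.upper()
    if dataset.n_obs < 2 * nOuter:
        raise ValueError("too few observations for the requested nOuter")

    plan = make_cv_plan(dataset, nRep, nOuter, nInner, seed)
    nOuter, nInner = plan.nOuter, plan.nInner
    free_idx, keep_idx = dataset.free_idx, dataset.keep_idx
    free_names = dataset.free_names
    classes = y.classes
    K = len(classes) if classes else 1
    n = dataset.n_obs
    holdout = np.zeros((nRep, n, K))
    models = []
    full_center = float(np.mean(y.values)) if y.kind == "continuous" else None
    y01_full = (np.asarray(y.values) == classes[1]).astype(float) if classes else None

    for rep in range(nRep):
        for o, test, calib in plan.segments(rep):
            Xf_cal = dataset.X[np.ix_(calib, free_idx)]
            C_cal = dataset.X[np.ix_(calib, keep_idx)]
            y_cal = y.subset(calib)
            inner_assign = _assign_segments(y_cal, nInner, _rng(seed, 11, rep, o))
            if classes:
                y01 = y01_full[calib]
                alpha_b, lam_b = _choose_binomial(Xf_cal, y01, C_cal, inner_assign,
                                                  nInner, alpha_grid, n_lambda)
                solver = _BinomialKeepEN(Xf_cal, y01, C_cal)
                beta, bc = solver.fit(alpha_b, lam_b)
                prob = solver.predict_proba(dataset.X[np.ix_(test, free_idx)],
                                            dataset.X[np.ix_(test, keep_idx)], beta, bc)
                holdout[rep, test, 1] = prob
                holdout[rep, test, 0] = 1 - prob
                pred_for_fit = (np.column_stack([1 - prob, prob]))
            else:
                alpha_b, lam_b = _choose_gaussian(Xf_cal, np.asarray(y_cal.values, float),
                                                  C_cal, inner_assign, nInner,
                                                  alpha_grid, n_lambda)
                solver = _GaussianKeepEN(Xf_cal, np.asarray(y_cal.values, float), C_cal)
                beta = solver.path(alpha_b, [lam_b])[:, 0]
                bc = solver.covariate_coefs(beta)
                pred = solver.predict(dataset.X[np.ix_(test, free_idx)],
                                      dataset.X[np.ix_(test, keep_idx)], beta, bc)
                holdout[rep, test, 0] = pred
                pred_for_fit = pred
            nonzero = tuple(free_names[j] for j in np.flatnonzero(beta != 0.0))
            coef = {v: float(b / s) for v, b, s in zip(free_names, beta, solver.sd)}
            coef["(intercept)"] = float(bc[0])
            for v, b in zip(dataset.keep_vars, bc[1:]):
                coef[v] = float(b)
            hf = _slice_fitness(fitness_metric, y.subset(test), pred_for_fit,
                                classes, full_center)
            models.append(ENCalibrationModel(rep, o, float(alpha_b), float(lam_b),
                                             coef, beta.copy(), nonzero, test, hf))

    importance = en_importance(models, free_names, dataset.keep_vars)
    rep_fitness = np.empty(nRep)
    for rep in range(nRep):
        preds = holdout[rep] if classes else holdout[rep, :, 0]
        rep_fitness[rep] = _slice_fitness(fitness_metric, y, preds, classes, full_center)
    out_holdout = holdout if classes else holdout[:, :, 0]
    params = {"learner": "EN", "nRep": nRep, "nOuter": nOuter, "nInner": nInner,
              "alpha_grid": alpha_grid, "n_lambda": n_lambda,
              "fitness_metric": fitness_metric, "seed": seed}
    return ENResult(models, importance, out_holdout, rep_fitness, plan, params)


def _slice_fitness(metric, y_slice: TargetVector, preds, classes, center):
    if classes:
        if metric == "AUROC":
            return fitness(metric, y_slice.values, preds[:, 1]).value
        labels = np.asarray(classes, dtype=object)[np.argmax(preds, axis=1)]
        return fitness(metric, y_slice.values, labels).value
    return fitness(metric, y_slice.values, preds, center=center).value


def _choose_gaussian(Xf, yv, C, inner_assign, nInner, alpha_grid, n_lambda):
    """Pooled inner-CV MSE over the (alpha, lambda) grid; returns the best pair."""
    best = (np.inf, None, None)
    base = _GaussianKeepEN(Xf, yv, C)
    for alpha in alpha_grid:
        lambdas = _lambda_path(base.Xr, base.yr, alpha, n_lambda)
        sse = np.zeros(len(lambdas))
        for f in range(nInner):
            val = np.flatnonzero(inner_assign == f)
            tr = np.flatnonzero(inner_assign != f)
            sub = _GaussianKeepEN(Xf[tr], yv[tr], C[tr])
            coefs = sub.path(alpha, lambdas)  # (p, L)
            bc = _wlstsq(sub.C1, yv[tr][:, None] - sub.Xs @ coefs)
            Xs_val = (Xf[val] - sub.mean) / sub.sd
            C1_val = np.column_stack([np.ones(len(val)), C[val]])
            preds = C1_val @ bc + Xs_val @ coefs
            sse += np.sum((preds - yv[val][:, None]) ** 2, axis=0)
        j = int(np.argmin(sse))  # first = largest lambda on ties
        if sse[j] < best[0]:
            best = (sse[j], alpha, lambdas[j])
    return best[1], best[2]


def _choose_binomial(Xf, y01, C, inner_assign, nInner, alpha_grid, n_lambda):
    """Pooled inner-CV binomial deviance over the grid (IRLS per pair)."""
    n_lambda = min(n_lambda, 30)  # IRLS per (alpha, lambda): keep the path short
    base = _BinomialKeepEN(Xf, y01, C)
    pbar = np.clip(y01.mean(), 1e-3, 1 - 1e-3)
    best = (np.inf, None, None)
    for alpha in alpha_grid:
        grad = np.abs(base.Xs.T @ (y01 - pbar)) / len(y01)
        lam_max = max(grad.max() / max(alpha, 1e-3), 1e-10)
        lambdas = np.logspace(np.log10(lam_max), np.log10(lam_max * 1e-2), n_lambda)
        dev = np.zeros(len(lambdas))
        for f in range(nInner):
            val = np.flatnonzero(inner_assign == f)
            tr = np.flatnonzero(inner_assign != f)
            sub = _BinomialKeepEN(Xf[tr], y01[tr], C[tr])
            for li, lam in enumerate(lambdas):
                beta, bc = sub.fit(alpha, lam, max_iter=15)
                p = sub.predict_proba(Xf[val], C[val], beta, bc)
                p = np.clip(p, 1e-8, 1 - 1e-8)
                dev[li] += -2 * np.sum(y01[val] * np.log(p) + (1 - y01[val]) * np.log(1 - p))
        j = int(np.argmin(dev))
        if dev[j] < best[0]:
            best = (dev[j], alpha, lambdas[j])
    return best[1], best[2]


# ---------------------------------------------------------------------------
# variable selection
# ---------------------------------------------------------------------------

def select_by_quantiles(models, importance: ENImportance,
                        quantiles=(0.25, 0.5, 0.75)) -> ConsensusSelection:
    """Min/mid/max directly from quantiles of the per-model non-zero counts."""
    if len(models) < 2:
        raise ValueError("need at least 2 calibration models")
    counts = np.array([len(m.nonzero) for m in models], dtype=float)
    qs = np.quantile(counts, quantiles, method="linear")
    n_min, n_mid, n_max = (_round_half_up(q) for q in qs)
    order = importance.order()
    names = [importance.var_names[i] for i in order]
    fits = np.array([m.holdout_fitness for m in models])
    return ConsensusSelection(n_min, n_mid, n_max,
                              names[:n_min], names[:n_mid], names[:n_max],
                              float(np.mean(fits)), float(np.mean(fits)),
                              float(np.mean(fits)))


def _local_iqr_mask(counts, fits, n_bins, mult):
    """Boolean mask of non-outliers under a per-bin IQR rule."""
    order = np.argsort(counts, kind="stable")
    keep = np.ones(len(counts), dtype=bool)
    for bin_idx in np.array_split(order, min(n_bins, len(order))):
        if len(bin_idx) < 4:
            continue
        q1, q3 = np.percentile(fits[bin_idx], [25, 75])
        iqr = q3 - q1
        lo, hi = q1 - mult * iqr, q3 + mult * iqr
        keep[bin_idx] &= (fits[bin_idx] >= lo) & (fits[bin_idx] <= hi)
    return keep


def select_by_fitness_curve(models, importance: ENImportance, metric: str,
                            tolerance: float = 0.05, n_bins: int = 10,
                            iqr_mult: float = 1.5,
                            smoother_span: float = 0.6) -> ConsensusSelection:
    """Min/mid/max from a LOWESS curve of hold-out fitness vs non-zero count.

    Points flagged by a local interquartile-range rule are excluded before
    smoothing.  Falls back to the quantile method (with a warning) when the
    smoothed curve has no usable optimum.
    """
    if len(models) < 10:
        raise ValueError("fewer than 10 calibration models; use select_by_quantiles")
    counts = np.array([len(m.nonzero) for m in models], dtype=float)
    fits = np.array([m.holdout_fitness for m in models], dtype=float)
    direction = METRIC_DIRECTIONS[metric.upper()]
    keep = _local_iqr_mask(counts, fits, n_bins, iqr_mult)
    c, f = counts[keep], fits[keep]
    distinct = np.unique(c)
    if len(distinct) < 3:
        warnings.warn("too few distinct non-zero counts for a fitness curve; "
                      "falling back to the quantile method")
        return select_by_quantiles(models, importance)
    sm = lowess(f, c, frac=smoother_span, return_sorted=True)
    smoothed = np.interp(distinct, sm[:, 0], sm[:, 1])
    sign = 1.0 if direction == "maximize" else -1.0
    s = sign * smoothed
    best, worst = np.max(s), np.min(s)
    flat = (best - worst) <= 1e-8 * max(1.0, abs(best))
    if flat:
        in_band = np.ones(len(distinct), dtype=bool)
        best = worst  # treat as constant
    else:
        in_band = s >= best - tolerance * (best - worst)
    i_best = int(np.argmax(s))
    if (i_best in (0, len(distinct) - 1)) and in_band.sum() == 1 and best != worst:
        warnings.warn("smoothed fitness curve has no interior optimum; "
                      "falling back to the quantile method")
        return select_by_quantiles(models, importance)
    n_min = int(distinct[in_band].min())
    n_max = int(distinct[in_band].max())
    n_mid = _round_half_up(np.sqrt(max(n_min, 1) * max(n_max, 1))) if n_min > 0 else \
        _round_half_up(np.sqrt(max(n_max, 1)))
    n_mid = min(max(n_mid, n_min), n_max)
    order = importance.order()
    names = [importance.var_names[i] for i in order]

    def _fit_near(nv):
        i = int(np.argmin(np.abs(distinct - nv)))
        return float(smoothed[i])

    return ConsensusSelection(n_min, n_mid, n_max,
                              names[:n_min], names[:n_mid], names[:n_max],
                              _fit_near(n_min), _fit_near(n_mid), _fit_near(n_max))
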