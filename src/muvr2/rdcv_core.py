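"""Repeated double cross-validation (rdCV) with recursive variable elimination.

The procedure runs four nested loops: repetitions (``nRep``) re-randomize the
cross-validation segmentation; an outer loop (``nOuter``) holds out one test
segment at a time; a recursive elimination loop removes a proportion
(``varRatio``) of the worst-ranked variables; an inner loop (``nInner``)
splits the calibration set into training and validation folds for
hyperparameter tuning and variable-importance estimation.  Test segments are
held out from all training and tuning, so pooled hold-out predictions carry no
leakage.  Three consensus selections are reported: "min" (minimal-optimal),
"max" (all-relevant) and "mid" (their geometric mean).

Supported learners are PLS (regression and PLS-DA classification, importance =
VIP) and random forest (importance = validation-fold permutation importance).
Variables named in ``keep_vars`` are forced into every model and excluded from
elimination and from the reported selections.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata
from sklearn.cross_decomposition import PLSRegression
from sklearn.tree import DecisionTreeClassifier, DecisionTreeRegressor

from .metrics import METRIC_DIRECTIONS, TargetVector, fitness, is_better, one_hot_encode

__all__ = [
    "OmicsDataset",
    "CVPlan",
    "FitnessCurve",
    "ImportanceTable",
    "ConsensusSelection",
    "RDCVResult",
    "make_cv_plan",
    "elimination_schedule",
    "rank_variables_pls",
    "rank_variables_rf",
    "tune_inner",
    "fit_rdcv",
    "select_min_mid_max",
]


def _rng(seed, *key):
    """Deterministic child generator for a (seed, key...) coordinate."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=tuple(key)))


# ---------------------------------------------------------------------------
# data containers
# ---------------------------------------------------------------------------

@dataclass
class OmicsDataset:
    """A predictor matrix with target, names and an optional kept-covariate set."""

    X: np.ndarray
    y: TargetVector
    var_names: list
    obs_ids: list
    keep_vars: tuple = ()
    truth: dict | None = None  # ground-truth variable roles from simulators

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2:
            raise ValueError("X must be a 2-d matrix")
        n, p = self.X.shape
        if p < 2:
            raise ValueError("need at least 2 variables")
        if len(self.y) != n:
            raise ValueError("X and y disagree on the number of observations")
        self.var_names = list(self.var_names)
        self.obs_ids = list(self.obs_ids)
        if len(self.var_names) != p or len(set(self.var_names)) != p:
            raise ValueError("var_names must be unique and match X's columns")
        if len(self.obs_ids) != n or len(set(self.obs_ids)) != n:
            raise ValueError("obs_ids must be unique and match X's rows")
        if np.isnan(self.X).any():
            raise ValueError("missing values in X are not supported; filter or impute upstream")
        self.keep_vars = tuple(self.keep_vars)
        unknown = set(self.keep_vars) - set(self.var_names)
        if unknown:
            raise ValueError(f"keep variables not found: {sorted(unknown)}")

    @property
    def n_obs(self) -> int:
        return self.X.shape[0]

    @property
    def n_vars(self) -> int:
        return self.X.shape[1]

    @property
    def keep_idx(self) -> np.ndarray:
        pos = {v: i for i, v in enumerate(self.var_names)}
        return np.asarray([pos[v] for v in self.keep_vars], dtype=int)

    @property
    def free_idx(self) -> np.ndarray:
        kept = set(self.keep_vars)
        return np.asarray([i for i, v in enumerate(self.var_names) if v not in kept], dtype=int)

    @property
    def free_names(self) -> list:
        kept = set(self.keep_vars)
        return [v for v in self.var_names if v not in kept]

    def with_keep(self, keep_vars) -> "OmicsDataset":
        return OmicsDataset(self.X, self.y, self.var_names, self.obs_ids,
                            tuple(keep_vars), self.truth)

    def with_target(self, y: TargetVector) -> "OmicsDataset":
        return OmicsDataset(self.X, y, self.var_names, self.obs_ids,
                            self.keep_vars, self.truth)


@dataclass
class CVPlan:
    """Per-repetition assignment of observations to outer segments."""

    nRep: int
    nOuter: int
    nInner: int
    outer_assignment: np.ndarray  # (nRep, n_obs) ints in [0, nOuter)
    seed: int

    def segments(self, rep: int):
        """Yield (outer_index, test_idx, calibration_idx) for a repetition."""
        assign = self.outer_assignment[rep]
        for o in range(self.nOuter):
            test = np.flatnonzero(assign == o)
            calib = np.flatnonzero(assign != o)
            yield o, test, calib


def _assign_segments(y: TargetVector, k: int, rng) -> np.ndarray:
    """Stratified segment assignment: by class for categorical targets, by
    sorted-target blocks for continuous ones.  Segment sizes differ by <= 1."""
    n = len(y)
    assign = np.full(n, -1, dtype=int)
    fill = np.zeros(k, dtype=int)
    if y.kind == "categorical":
        for cls in y.classes:
            idx = np.flatnonzero(np.asarray(y.values) == cls)
            rng.shuffle(idx)
            # deal into the currently least-filled segments, random among ties
            for i in idx:
                order = np.lexsort((rng.random(k), fill))
                assign[i] = order[0]
                fill[order[0]] += 1
    else:
        order = np.argsort(y.values, kind="stable")
        for start in range(0, n, k):
            block = order[start:start + k]
            block = rng.permutation(block)
            if len(block) == k:
                segs = np.arange(k)
            else:  # partial final block: spread over least-filled segments
                segs = np.lexsort((rng.random(k), fill))[:len(block)]
            for i, s in zip(block, segs):
                assign[i] = s
                fill[s] += 1
    return assign


def make_cv_plan(dataset: OmicsDataset, nRep: int, nOuter: int,
                 nInner: int | None = None, seed: int = 0) -> CVPlan:
    """Build the outer-segmentation plan for all repetitions (deterministic per seed)."""
    if nOuter < 2:
        raise ValueError("nOuter must be >= 2")
    if nOuter > dataset.n_obs:
        raise ValueError(f"nOuter={nOuter} exceeds the number of observations ({dataset.n_obs})")
    y = dataset.y
    if y.kind == "categorical":
        smallest = min(int(np.sum(np.asarray(y.values) == c)) for c in y.classes)
        if nOuter > smallest:
            warnings.warn(
                f"nOuter={nOuter} exceeds the smallest class size ({smallest}); reducing",
                stacklevel=2,
            )
            nOuter = max(2, smallest)
    if nInner is None:
        nInner = max(2, nOuter - 1)
    if nRep < 1 or nInner < 2:
        raise ValueError("nRep must be >= 1 and nInner >= 2")
    assignment = np.stack([
        _assign_segments(y, nOuter, _rng(seed, 0, rep)) for rep in range(nRep)
    ])
    return CVPlan(nRep, nOuter, nInner, assignment, seed)


def elimination_schedule(n_free_vars: int, varRatio: float) -> list:
    """Strictly decreasing variable counts from ``n_free_vars`` down to 2.

    Each step keeps ``floor(n * varRatio)`` variables, falling back to ``n - 1``
    when rounding would not remove anything.
    """
    if not (0.0 < varRatio < 1.0):
        raise ValueError("varRatio must be in (0, 1)")
    if n_free_vars < 2:
        raise ValueError("need at least 2 free variables")
    counts = [n_free_vars]
    while counts[-1] > 2:
        nxt = min(int(np.floor(counts[-1] * varRatio)), counts[-1] - 1)
        counts.append(max(nxt, 2))
    return counts


# ---------------------------------------------------------------------------
# PLS learner (standardized NIPALS via scikit-learn) and VIP importance
# ---------------------------------------------------------------------------

class _PLS:
    """PLS on internally standardized X (and Y), exposing predictions and VIP
    for every component count up to the fitted maximum."""

    def __init__(self, X, yvec: TargetVector, n_components: int):
        X = np.asarray(X, dtype=float)
        self.x_mean = X.mean(axis=0)
        sd = X.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        self.x_sd = sd
        Xs = (X - self.x_mean) / self.x_sd
        self.classes = yvec.classes if yvec.kind == "categorical" else ()
        if yvec.kind == "categorical":
            Y, _ = one_hot_encode(yvec.values, levels=self.classes)
        else:
            Y = np.asarray(yvec.values, dtype=float)[:, None]
        self.y_mean = Y.mean(axis=0)
        ysd = Y.std(axis=0, ddof=1)
        ysd[ysd == 0] = 1.0
        self.y_sd = ysd
        Ys = (Y - self.y_mean) / self.y_sd
        n_components = max(1, min(n_components, X.shape[0] - 1, X.shape[1]))
        self.n_components = n_components
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            m = PLSRegression(n_components=n_components, scale=False)
            m.fit(Xs, Ys)
        self.W = m.x_weights_          # (p, A)
        self.R = m.x_rotations_        # (p, A)
        self.Q = m.y_loadings_         # (q, A)
        self.T = m.x_scores_           # (n, A)

    def coefficients(self, ncomp: int) -> np.ndarray:
        a = min(ncomp, self.n_components)
        return self.R[:, :a] @ self.Q[:, :a].T  # standardized scale, (p, q)

    def predict_raw(self, X, ncomp: int) -> np.ndarray:
        Xs = (np.asarray(X, dtype=float) - self.x_mean) / self.x_sd
        return Xs @ self.coefficients(ncomp) * self.y_sd + self.y_mean

    def predict(self, X, ncomp: int):
        """Regression values, or (labels, scores) for classification."""
        Yhat = self.predict_raw(X, ncomp)
        if not self.classes:
            return Yhat[:, 0]
        labels = np.asarray(self.classes, dtype=object)[np.argmax(Yhat, axis=1)]
        return labels, Yhat

    def vip(self, ncomp: int) -> np.ndarray:
        """Variable influence on projection for the first ``ncomp`` components."""
        a = min(ncomp, self.n_components)
        ss = np.array([
            (self.T[:, c] @ self.T[:, c]) * (self.Q[:, c] @ self.Q[:, c])
            for c in range(a)
        ])
        wnorm2 = np.sum(self.W[:, :a] ** 2, axis=0)
        wnorm2[wnorm2 == 0] = 1.0
        frac = (self.W[:, :a] ** 2) / wnorm2
        total = ss.sum()
        if total <= 0:
            return np.zeros(self.W.shape[0])
        p = self.W.shape[0]
        return np.sqrt(p * (frac @ ss) / total)


def _ranks_from_scores(scores: np.ndarray) -> np.ndarray:
    """Descending-importance mid-ranks (1 = most important)."""
    return rankdata(-np.asarray(scores, dtype=float), method="average")


def rank_variables_pls(X, y: TargetVector, n_components: int) -> np.ndarray:
    """VIP-based importance ranks (1 = best) for every column of ``X``."""
    model = _PLS(X, y, n_components)
    return _ranks_from_scores(model.vip(n_components))


class _LiteForest:
    """Random forest as plain bootstrap bagging of scikit-learn decision trees.

    Semantically a standard random forest (bootstrap resampling per tree,
    ``mtry`` random candidate features per split) with far lower per-fit
    constant overhead than the ensemble wrapper — rdCV fits thousands of small
    forests, where that overhead dominates.
    """

    def __init__(self, n_trees: int, mtry: int, classes=()):
        self.n_trees = n_trees
        self.mtry = mtry
        self.classes_ = tuple(classes)
        self.trees = []

    def fit(self, X, y, rng):
        X = np.asarray(X, dtype=np.float32)
        n = X.shape[0]
        is_classif = bool(self.classes_)
        if is_classif:
            code = {c: k for k, c in enumerate(self.classes_)}
            y_enc = np.asarray([code[v] for v in y])
        else:
            y_enc = np.asarray(y, dtype=float)
        Tree = DecisionTreeClassifier if is_classif else DecisionTreeRegressor
        self.trees = []
        for _ in range(self.n_trees):
            idx = rng.integers(0, n, n)
            t = Tree(max_features=self.mtry, random_state=int(rng.integers(2**31)))
            t.fit(X[idx], y_enc[idx], check_input=False)
            self.trees.append(t)
        return self

    def predict_matrix(self, X):
        """Mean response (regression) or class-probability matrix (classification)."""
        X = np.asarray(X, dtype=np.float32)
        if self.classes_:
            K = len(self.classes_)
            out = np.zeros((X.shape[0], K))
            for t in self.trees:
                proba = t.predict_proba(X)
                for pos, k in enumerate(t.classes_):
                    out[:, int(k)] += proba[:, pos]
            return out / self.n_trees
        out = np.zeros(X.shape[0])
        for t in self.trees:
            out += t.predict(X, check_input=False)
        return out / self.n_trees

    def predict(self, X):
        m = self.predict_matrix(X)
        if self.classes_:
            return np.asarray(self.classes_, dtype=object)[np.argmax(m, axis=1)]
        return m

    def predict_proba(self, X):
        return self.predict_matrix(X)


def _fit_rf(X, yvec: TargetVector, n_trees: int, seed: int, mtry=None):
    p = X.shape[1]
    if yvec.kind == "categorical":
        mf = mtry if mtry is not None else max(1, int(np.sqrt(p)))
        forest = _LiteForest(n_trees, min(mf, p), yvec.classes)
    else:
        mf = mtry if mtry is not None else max(1, p // 3)
        forest = _LiteForest(n_trees, min(mf, p))
    return forest.fit(X, yvec.values, np.random.default_rng(seed))


def _rf_permutation_scores(model, X_val, y_val: TargetVector, columns, rng) -> np.ndarray:
    """Permutation importance on a validation set, one permutation per column,
    evaluated with a single stacked forest predict."""
    X_val = np.asarray(X_val, dtype=float)
    n = X_val.shape[0]
    stacked = np.repeat(X_val[None, :, :], len(columns), axis=0)
    for s, j in enumerate(columns):
        stacked[s, :, j] = X_val[rng.permutation(n), j]
    stacked = stacked.reshape(len(columns) * n, X_val.shape[1])
    if y_val.kind == "categorical":
        base = np.mean(model.predict(X_val) == y_val.values)
        perm = model.predict(stacked).reshape(len(columns), n)
        acc = np.mean(perm == np.asarray(y_val.values)[None, :], axis=1)
        return base - acc  # mean decrease in accuracy
    yv = np.asarray(y_val.values, dtype=float)
    base = np.mean((model.predict(X_val) - yv) ** 2)
    perm = model.predict(stacked).reshape(len(columns), n)
    mse = np.mean((perm - yv[None, :]) ** 2, axis=1)
    return mse - base  # increase in MSE


def rank_variables_rf(X, y: TargetVector, n_trees: int = 150, mtry=None,
                      X_val=None, y_val=None, seed: int = 0) -> np.ndarray:
    """Permutation-importance ranks (1 = best) for every column of ``X``.

    Importance is scored on ``(X_val, y_val)`` when given, else on the training
    data itself.
    """
    rng = _rng(seed, 901)
    model = _fit_rf(np.asarray(X, float), y, n_trees, int(rng.integers(2**31)), mtry)
    if X_val is None:
        X_val, y_val = X, y
    scores = _rf_permutation_scores(model, X_val, y_val,
                                    np.arange(np.asarray(X).shape[1]), rng)
    return _ranks_from_scores(scores)


# ---------------------------------------------------------------------------
# inner loop: tuning, validation fitness and importance
# ---------------------------------------------------------------------------

def _pooled_fitness(metric, y_slice: TargetVector, preds, classes, center):
    """Score pooled predictions; ``preds`` is values (regression) or a score
    matrix (classification)."""
    if y_slice.kind == "categorical":
        if metric == "AUROC":
            return fitness(metric, y_slice.values, preds[:, 1]).value
        labels = np.asarray(classes, dtype=object)[np.argmax(preds, axis=1)]
        return fitness(metric, y_slice.values, labels).value
    return fitness(metric, y_slice.values, preds, center=center).value


def _inner_eval(X, yvec: TargetVector, cols, rank_cols, inner_assign, nInner,
                learner, metric, cfg, seed_key):
    """One pass over the inner folds of a calibration set.

    Returns (hyperparameters, pooled validation fitness, average ranks over
    ``rank_cols`` positions, per-fold audit records).
    """
    direction = METRIC_DIRECTIONS[metric]
    n = X.shape[0]
    classes = yvec.classes
    K = len(classes) if classes else 1
    rank_pos = [list(cols).index(c) for c in rank_cols]
    audit = []

    if learner == "PLS":
        max_a = cfg["max_comp"]
        for f in range(nInner):
            max_a = min(max_a, int(np.sum(inner_assign != f)) - 1)
        max_a = max(1, min(max_a, len(cols)))
        val_preds = np.zeros((max_a, n, K))
        models = []
        for f in range(nInner):
            val = np.flatnonzero(inner_assign == f)
            train = np.flatnonzero(inner_assign != f)
            m = _PLS(X[np.ix_(train, cols)], yvec.subset(train), max_a)
            models.append(m)
            for a in range(1, max_a + 1):
                val_preds[a - 1, val, :] = m.predict_raw(X[np.ix_(val, cols)], a)
            audit.append(("inner", f, train, val))
        center = float(np.mean(yvec.values)) if yvec.kind == "continuous" else None
        fits = [_pooled_fitness(metric, yvec, val_preds[a - 1] if classes else val_preds[a - 1, :, 0],
                                classes, center) for a in range(1, max_a + 1)]
        best_a = 1
        for a in range(2, max_a + 1):
            if is_better(fits[a - 1], fits[best_a - 1], direction):
                best_a = a
        ranks = np.mean([_ranks_from_scores(m.vip(best_a)[rank_pos]) for m in models], axis=0)
        return {"n_components": best_a}, fits[best_a - 1], ranks, audit

    if learner == "RF":
        rng = _rng(*seed_key)
        val_preds = np.zeros((n, K))
        rank_list = []
        for f in range(nInner):
            val = np.flatnonzero(inner_assign == f)
            train = np.flatnonzero(inner_assign != f)
            m = _fit_rf(X[np.ix_(train, cols)], yvec.subset(train),
                        cfg["n_trees"], int(rng.integers(2**31)), cfg.get("mtry"))
            if classes:
                val_preds[val, :] = m.predict_proba(X[np.ix_(val, cols)])
            else:
                val_preds[val, 0] = m.predict(X[np.ix_(val, cols)])
            scores = _rf_permutation_scores(m, X[np.ix_(val, cols)], yvec.subset(val),
                                            rank_pos, rng)
            rank_list.append(_ranks_from_scores(scores))
            audit.append(("inner", f, train, val))
        center = float(np.mean(yvec.values)) if yvec.kind == "continuous" else None
        fit_val = _pooled_fitness(metric, yvec, val_preds if classes else val_preds[:, 0],
                                  classes, center)
        return {"n_trees": cfg["n_trees"]}, fit_val, np.mean(rank_list, axis=0), audit

    raise ValueError(f"unknown learner {learner!r}")


def tune_inner(X_calib, y_calib: TargetVector, learner: str, inner_assign,
               fitness_metric: str, max_comp: int = 5, n_trees: int = 150,
               seed: int = 0) -> dict:
    """Hyperparameters chosen on the inner folds of one calibration set.

    PLS tunes the number of components (ties favour the smaller model); RF
    returns its fixed defaults (the inner loop is still used for importance).
    """
    inner_assign = np.asarray(inner_assign)
    nInner = int(inner_assign.max()) + 1
    if len(np.unique(inner_assign)) < 2:
        raise ValueError("calibration set smaller than nInner")
    cols = np.arange(np.asarray(X_calib).shape[1])
    hyper, _, _, _ = _inner_eval(np.asarray(X_calib, float), y_calib, cols, cols,
                                 inner_assign, nInner, learner.upper(),
                                 fitness_metric.upper(), {"max_comp": max_comp,
                                 "n_trees": n_trees}, (seed, 77))
    return hyper


# ---------------------------------------------------------------------------
# curve / importance / consensus containers
# ---------------------------------------------------------------------------

@dataclass
class FitnessCurve:
    """Validation fitness as a function of the number of retained variables."""

    counts: list                       # schedule counts, descending
    values: dict                       # count -> (nRep*nOuter,) fitness values
    metric: str

    @property
    def direction(self) -> str:
        return METRIC_DIRECTIONS[self.metric]

    def means(self) -> np.ndarray:
        return np.array([np.mean(self.values[c]) for c in self.counts])


@dataclass
class ImportanceTable:
    """Average elimination-order ranks per variable (lower = more important).

    Kept covariates carry rank 0 and never enter the elimination ranking.
    """

    var_names: list                    # free variables
    avg_rank: np.ndarray               # mean rank across nRep*nOuter models
    rank: np.ndarray                   # final mid-ranked positions, 1..n_free
    keep_vars: tuple = ()

    def order(self) -> np.ndarray:
        """Free-variable indices from most to least important (deterministic)."""
        return np.lexsort((np.asarray(self.var_names, dtype=object), self.avg_rank))

    def as_dict(self) -> dict:
        d = {v: 0.0 for v in self.keep_vars}
        d.update({v: float(r) for v, r in zip(self.var_names, self.rank)})
        return d


@dataclass
class ConsensusSelection:
    n_min: int
    n_mid: int
    n_max: int
    vars_min: list
    vars_mid: list
    vars_max: list
    fitness_min: float = np.nan
    fitness_mid: float = np.nan
    fitness_max: float = np.nan

    def __post_init__(self):
        if not (self.n_min <= self.n_mid <= self.n_max):
            raise ValueError("consensus counts must satisfy min <= mid <= max")
        if not (set(self.vars_min) <= set(self.vars_mid) <= set(self.vars_max)):
            raise ValueError("consensus variable lists must be nested")


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def select_min_mid_max(curve: FitnessCurve, tolerance: float = 0.05,
                       importance: ImportanceTable | None = None) -> ConsensusSelection:
    """Min/mid/max consensus from a fitness curve.

    "min" and "max" are the smallest and largest variable counts whose mean
    fitness lies within ``tolerance`` x (fitness range) of the curve optimum;
    "mid" is the rounded geometric mean of the two.
    """
    if not curve.counts:
        raise ValueError("empty fitness curve")
    counts = np.asarray(curve.counts)
    means = curve.means()
    sign = 1.0 if curve.direction == "maximize" else -1.0
    best = np.max(sign * means)
    worst = np.min(sign * means)
    if best == worst:
        in_band = np.ones(len(counts), dtype=bool)
    else:
        in_band = sign * means >= best - tolerance * (best - worst)
    n_min = int(counts[in_band].min())
    n_max = int(counts[in_band].max())
    n_mid = _round_half_up(np.sqrt(n_min * n_max))
    if importance is not None:
        order = importance.order()
        names = [importance.var_names[i] for i in order]
        vmin, vmid, vmax = names[:n_min], names[:n_mid], names[:n_max]
    else:
        vmin = vmid = vmax = []

    def _fit_at(n):
        c = _nearest_count(counts, n)
        return float(np.mean(curve.values[c]))

    return ConsensusSelection(n_min, n_mid, n_max, vmin, vmid, vmax,
                              _fit_at(n_min), _fit_at(n_mid), _fit_at(n_max))


def _nearest_count(counts, n: int) -> int:
    """Schedule count closest to ``n`` in log-space (ties -> larger count)."""
    counts = np.asarray(sorted(set(int(c) for c in counts), reverse=True))
    d = np.abs(np.log(counts) - np.log(max(n, 1)))
    return int(counts[np.argmin(d)])  # argmin hits the larger count first


# ---------------------------------------------------------------------------
# the full rdCV procedure
# ---------------------------------------------------------------------------

@dataclass
class RDCVResult:
    curve: FitnessCurve
    selection: ConsensusSelection
    importance: ImportanceTable
    holdout: dict                      # count -> (nRep, n_obs[, K]) hold-out predictions
    rep_fitness: dict                  # count -> (nRep,) hold-out fitness per repetition
    schedule: list
    plan: CVPlan
    params: dict
    audit: list | None = None

    def rep_fitness_at(self, n: int) -> np.ndarray:
        return self.rep_fitness[_nearest_count(self.schedule, n)]


def fit_rdcv(dataset: OmicsDataset, learner: str = "PLS", nRep: int = 5,
             nOuter: int = 6, nInner: int | None = None, varRatio: float = 0.75,
             fitness_metric: str | None = None, seed: int = 0, max_comp: int = 5,
             n_trees: int = 150, mtry=None, tolerance: float = 0.05,
             eliminate: bool = True, audit: bool = False) -> RDCVResult:
    """Run repeated double cross-validation with recursive variable elimination.

    With ``eliminate=False`` the schedule collapses to the full variable set
    (plain double cross-validation).
    """
    learner = learner.upper()
    if learner not in ("PLS", "RF"):
        raise ValueError("learner must be 'PLS' or 'RF'")
    y = dataset.y
    if fitness_metric is None:
        fitness_metric = "Q2" if y.kind == "continuous" else "BER"
    fitness_metric = fitness_metric.upper()
    if y.kind == "continuous" and fitness_metric not in ("Q2", "RMSEP"):
        raise ValueError(f"{fitness_metric} is not a regression metric")
    if y.kind == "categorical" and fitness_metric in ("Q2", "RMSEP"):
        raise ValueError(f"{fitness_metric} is not a classification metric")
    if fitness_metric == "AUROC" and y.n_classes != 2:
        raise ValueError("AUROC requires a binary target")

    plan = make_cv_plan(dataset, nRep, nOuter, nInner, seed)
    nOuter, nInner = plan.nOuter, plan.nInner
    keep_idx = dataset.keep_idx
    free_idx = dataset.free_idx
    free_names = dataset.free_names
    n_free = len(free_idx)
    schedule = elimination_schedule(n_free, varRatio) if eliminate else [n_free]

    classes = y.classes
    K = len(classes) if classes else 1
    n = dataset.n_obs
    curve_values = {c: [] for c in schedule}
    holdout = {c: np.zeros((nRep, n, K)) for c in schedule}
    elim_ranks = []                     # one (n_free,) array per (rep, outer)
    audit_log = [] if audit else None
    cfg = {"max_comp": max_comp, "n_trees": n_trees, "mtry": mtry}
    full_center = float(np.mean(y.values)) if y.kind == "continuous" else None

    for rep in range(nRep):
        for o, test, calib in plan.segments(rep):
            y_cal = y.subset(calib)
            inner_assign = _assign_segments(y_cal, nInner, _rng(seed, 1, rep, o))
            surv = np.arange(n_free)    # positions into free_idx
            elim = np.full(n_free, np.nan)
            for si, count in enumerate(schedule):
                cols = np.concatenate([keep_idx, free_idx[surv]]).astype(int)
                rank_cols = free_idx[surv]
                hyper, val_fit, avg_ranks, fold_audit = _inner_eval(
                    dataset.X[calib], y_cal, cols, rank_cols, inner_assign,
                    nInner, learner, fitness_metric, cfg, (seed, 2, rep, o, si))
                curve_values[count].append(val_fit)
                # calibration model on the full calibration set -> hold-out preds
                if learner == "PLS":
                    m = _PLS(dataset.X[np.ix_(calib, cols)], y_cal, hyper["n_components"])
                    pred = m.predict_raw(dataset.X[np.ix_(test, cols)], hyper["n_components"])
                    holdout[count][rep, test, :] = pred
                else:
                    m = _fit_rf(dataset.X[np.ix_(calib, cols)], y_cal, n_trees,
                                int(_rng(seed, 3, rep, o, si).integers(2**31)), mtry)
                    if classes:
                        holdout[count][rep, test, :] = m.predict_proba(dataset.X[np.ix_(test, cols)])
                    else:
                        holdout[count][rep, test, 0] = m.predict(dataset.X[np.ix_(test, cols)])
                if audit:
                    audit_log.append({"rep": rep, "outer": o, "n_vars": count,
                                      "kind": "calibration", "hyper": hyper,
                                      "train_idx": calib.copy(), "eval_idx": test.copy()})
                    for kind, f, tr, va in fold_audit:
                        audit_log.append({"rep": rep, "outer": o, "n_vars": count,
                                          "kind": f"inner-{f}", "hyper": hyper,
                                          "train_idx": calib[tr], "eval_idx": calib[va]})
                # recursive elimination
                order = np.argsort(avg_ranks, kind="stable")  # best first
                if si + 1 < len(schedule):
                    nxt = schedule[si + 1]
                    for pos, j in enumerate(order[nxt:]):
                        elim[surv[j]] = nxt + 1 + pos
                    surv = np.sort(surv[order[:nxt]])
                else:
                    for pos, j in enumerate(order):
                        elim[surv[j]] = 1 + pos
            elim_ranks.append(elim)

    curve = FitnessCurve(schedule, {c: np.asarray(v) for c, v in curve_values.items()},
                         fitness_metric)
    avg_rank = np.mean(elim_ranks, axis=0)
    importance = ImportanceTable(free_names, avg_rank,
                                 rankdata(avg_rank, method="average"),
                                 dataset.keep_vars)
    selection = select_min_mid_max(curve, tolerance, importance)

    rep_fit = {}
    for c in schedule:
        vals = []
        for rep in range(nRep):
            preds = holdout[c][rep] if classes else holdout[c][rep, :, 0]
            vals.append(_pooled_fitness(fitness_metric, y, preds, classes, full_center))
        rep_fit[c] = np.asarray(vals)
    # consensus fitness re-expressed on hold-out predictions
    selection.fitness_min = float(np.mean(rep_fit[_nearest_count(schedule, selection.n_min)]))
    selection.fitness_mid = float(np.mean(rep_fit[_nearest_count(schedule, selection.n_mid)]))
    selection.fitness_max = float(np.mean(rep_fit[_nearest_count(schedule, selection.n_max)]))

    if not classes:
        holdout = {c: h[:, :, 0] for c, h in holdout.items()}
    params = {"learner": learner, "nRep": nRep, "nOuter": nOuter, "nInner": nInner,
              "varRatio": varRatio, "fitness_metric": fitness_metric, "seed": seed,
              "max_comp": max_comp, "n_trees": n_trees, "tolerance": tolerance}
    return RDCVResult(curve, selection, importance, holdout, rep_fit, schedule,
                      plan, params, audit_log)
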