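"""Synthetic benchmark generators.

Two families of fixtures are produced:

* ``simulate_causal`` builds the causal-structure benchmark used to study
  covariate adjustment: 100 predictors and 4 covariates linked to a continuous
  target by linear structural equations with standard-normal noise.  The four
  informative predictors realise distinct causal roles — confounded proxy
  (X1), direct cause (X2), cause acting through a mediator covariate (X3), and
  a weakly confounded proxy (X4) — while X5..X100 are pure noise.
* ``simulate_signal_noise`` builds generic regression/classification fixtures
  with a known set of planted signal variables.

``run_causal_rank_experiment`` repeats the causal simulation and summarises median
variable-importance ranks per engine (PLS, RF, EN) and covariate handling mode
(C_none / C_add / C_keep), together with the size of the "max" selection and
hold-out fitness.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .metrics import TargetVector
from .rdcv_core import OmicsDataset, fit_rdcv, _rng
from .elastic_net_engine import fit_nested_en

__all__ = [
    "CausalSimSpec",
    "simulate_causal",
    "simulate_signal_noise",
    "run_causal_rank_experiment",
]

MODES = ("C_none", "C_add", "C_keep")


@dataclass
class CausalSimSpec:
    """Parameters of the causal-structure benchmark.

    Arrow coefficients default to 1.0 except the confounding pair
    (C1 -> X1 and C1 -> Y), which defaults to 2.0 so that the confounded proxy
    X1 carries the strongest marginal correlation with Y; structure 4 repeats
    the confounding topology at half that strength.  Every structural equation
    adds independent N(0, noise_sd^2) noise.
    """

    n_obs: int = 100
    n_predictors: int = 100
    n_covariates: int = 4
    beta_confounder: float = 2.0   # C1 -> X1 and C1 -> Y
    beta_direct: float = 1.0       # X2 -> Y
    beta_covariate: float = 1.0    # C2 -> Y (independent covariate cause)
    beta_mediator: float = 1.0     # X3 -> C3 and C3 -> Y
    beta_weak: float = field(default=None)  # C4 -> X4 and C4 -> Y; half of confounder
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.n_predictors < 4 or self.n_covariates != 4:
            raise ValueError("the causal benchmark needs >= 4 predictors and exactly 4 covariates")
        if self.beta_weak is None:
            self.beta_weak = self.beta_confounder / 2.0


def simulate_causal(spec: CausalSimSpec | None = None, mode: str = "C_add") -> OmicsDataset:
    """Draw one dataset from the causal-structure benchmark.

    ``mode`` controls covariate handling: ``C_none`` excludes C1..C4 from the
    predictor matrix, ``C_add`` includes them as ordinary predictors and
    ``C_keep`` additionally forces them into every model (the *keep* set).
    Ground-truth roles are attached under ``dataset.truth``.
    """
    spec = spec or CausalSimSpec()
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}")
    rng = _rng(spec.seed, 42)
    n, sd = spec.n_obs, spec.noise_sd

    def eps():
        return rng.normal(0.0, sd, n)

    C1, C2, C4 = eps(), eps(), eps()
    X2, X3 = eps(), eps()
    X1 = spec.beta_confounder * C1 + eps()
    C3 = spec.beta_mediator * X3 + eps()
    X4 = spec.beta_weak * C4 + eps()
    Y = (spec.beta_confounder * C1 + spec.beta_direct * X2 + spec.beta_covariate * C2
         + spec.beta_mediator * C3 + spec.beta_weak * C4 + eps())
    noise = rng.normal(0.0, sd, (n, spec.n_predictors - 4))

    X = np.column_stack([X1, X2, X3, X4, noise])
    x_names = [f"X{i}" for i in range(1, spec.n_predictors + 1)]
    c_names = ["C1", "C2", "C3", "C4"]
    truth = {"X1": "confounded", "X2": "direct", "X3": "mediated", "X4": "weak_confounded"}
    truth.update({v: "noise" for v in x_names[4:]})
    if mode != "C_none":
        X = np.column_stack([X, C1, C2, C3, C4])
        names = x_names + c_names
        truth.update({v: "covariate" for v in c_names})
    else:
        names = x_names
    keep = tuple(c_names) if mode == "C_keep" else ()
    return OmicsDataset(X, TargetVector(Y, "continuous"), names,
                        [f"obs{i}" for i in range(n)], keep, truth)


def simulate_signal_noise(n_obs: int, n_signal: int, n_noise: int,
                          effect_size: float, kind: str = "regression",
                          seed: int = 0) -> OmicsDataset:
    """Generic fixture: iid N(0,1) predictors, the first ``n_signal`` of which
    carry ``effect_size`` each; binary targets come from a logistic transform
    of the same linear predictor."""
    if n_signal < 0 or n_signal + n_noise < 2:
        raise ValueError("need n_signal >= 0 and at least 2 variables in total")
    rng = _rng(seed, 43)
    p = n_signal + n_noise
    X = rng.normal(size=(n_obs, p))
    linear = effect_size * X[:, :n_signal].sum(axis=1) if n_signal else np.zeros(n_obs)
    if kind == "regression":
        y = TargetVector(linear + rng.normal(size=n_obs), "continuous")
    elif kind == "binary":
        prob = 1.0 / (1.0 + np.exp(-linear))
        labels = np.where(rng.random(n_obs) < prob, "case", "control")
        y = TargetVector(labels, "categorical")
    else:
        raise ValueError("kind must be 'regression' or 'binary'")
    names = [f"S{i+1}" for i in range(n_signal)] + [f"N{i+1}" for i in range(n_noise)]
    truth = {v: ("signal" if v.startswith("S") else "noise") for v in names}
    return OmicsDataset(X, y, names, [f"obs{i}" for i in range(n_obs)], (), truth)


def _engine_ranks(dataset: OmicsDataset, engine: str, nRep, nOuter, varRatio,
                  n_trees, rf_mtry, rf_nInner, rf_varRatio, alpha_grid,
                  n_lambda, seed):
    """Per-variable final importance ranks plus nVar(max) and hold-out Q2."""
    if engine == "EN":
        res = fit_nested_en(dataset, nRep=nRep, nOuter=nOuter,
                            alpha_grid=alpha_grid, n_lambda=n_lambda, seed=seed)
        ranks = res.importance.as_dict()
        from .elastic_net_engine import select_by_quantiles
        sel = select_by_quantiles(res.models, res.importance)
        return ranks, sel.n_max, res.fitness_mean
    if engine == "RF":
        res = fit_rdcv(dataset, learner="RF", nRep=nRep, nOuter=nOuter,
                       nInner=rf_nInner, varRatio=rf_varRatio, n_trees=n_trees,
                       mtry=rf_mtry, seed=seed)
    else:
        res = fit_rdcv(dataset, learner=engine, nRep=nRep, nOuter=nOuter,
                       varRatio=varRatio, seed=seed)
    return res.importance.as_dict(), res.selection.n_max, res.selection.fitness_mid


def run_causal_rank_experiment(n_simulations: int = 25, engines=("PLS", "RF", "EN"),
                          modes=MODES, seed: int = 0,
                          spec: CausalSimSpec | None = None, nRep: int = 5,
                          nOuter: int = 6, varRatio: float = 0.75,
                          n_trees: int = 30, rf_mtry: int = 10,
                          rf_nInner: int = 2, rf_varRatio: float = 0.5,
                          alpha_grid=(0.1, 0.55, 1.0),
                          n_lambda: int = 50) -> pd.DataFrame:
    """Median importance ranks of X1..X4 and C1..C4 over repeated causal simulations.

    Returns a DataFrame with a row per summarised quantity (variable ranks,
    nVar of the "max" selection, hold-out Q2) and a (engine, mode) column
    MultiIndex.  Covariate rows are NaN under C_none (covariates absent) and
    0 under C_keep (kept variables are excluded from ranking).
    """
    if not engines or not modes:
        raise ValueError("engines and modes must be non-empty")
    base = spec or CausalSimSpec()
    rows = ["X1", "X2", "X3", "X4", "C1", "C2", "C3", "C4", "nVar", "Q2"]
    out = {}
    for engine in engines:
        for mode in modes:
            per_sim = {r: [] for r in rows}
            for s in range(n_simulations):
                d = dict(base.__dict__)
                d["seed"] = int(_rng(seed, 5, s).integers(2**31))
                ds = simulate_causal(CausalSimSpec(**d), mode)
                ranks, nvar, q2v = _engine_ranks(
                    ds, engine, nRep, nOuter, varRatio, n_trees, rf_mtry,
                    rf_nInner, rf_varRatio, alpha_grid, n_lambda,
                    int(_rng(seed, 6, s).integers(2**31)))
                for v in rows[:8]:
                    per_sim[v].append(ranks.get(v, np.nan))
                per_sim["nVar"].append(nvar)
                per_sim["Q2"].append(q2v)
            out[(engine, mode)] = {r: float(np.nanmedian(per_sim[r]))
                                   if not all(np.isnan(per_sim[r])) else np.nan
                                   for r in rows}
    cols = pd.MultiIndex.from_tuples(out.keys(), names=["engine", "mode"])
    return pd.DataFrame({k: pd.Series(v) for k, v in out.items()},
                        columns=cols).reindex(rows)
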