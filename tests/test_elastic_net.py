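"""Nested elastic net: keep contract, importance, selection procedures."""

import subprocess

import numpy as np
import pytest

from muvr2.elastic_net_engine import (ENCalibrationModel, ENImportance,
                                      _GaussianKeepEN, en_importance,
                                      fit_nested_en, select_by_fitness_curve,
                                      select_by_quantiles)
from muvr2.synthetic_data import simulate_signal_noise


def test_keep_covariates_always_nonzero():
    ds = simulate_signal_noise(50, 3, 27, 2.0, "regression", seed=1)
    ds = ds.with_keep(("N1", "N2"))
    res = fit_nested_en(ds, nRep=2, nOuter=4, alpha_grid=(0.5, 1.0),
                        n_lambda=30, seed=1)
    for m in res.models:
        assert m.coef["N1"] != 0.0 and m.coef["N2"] != 0.0
        assert "N1" not in m.nonzero and "N2" not in m.nonzero
    assert res.importance.keep_vars == ("N1", "N2")


def test_dominant_signal_importance_is_one():
    ds = simulate_signal_noise(60, 1, 19, 2.0, "regression", seed=2)
    res = fit_nested_en(ds, nRep=2, nOuter=4, alpha_grid=(0.5, 1.0),
                        n_lambda=30, seed=2)
    prop = dict(zip(res.importance.var_names, res.importance.proportion))
    assert prop["S1"] == 1.0
    assert res.importance.as_dict()["S1"] == 1.0


def test_fit_deterministic_per_seed():
    ds = simulate_signal_noise(40, 2, 18, 2.0, "regression", seed=3)
    r1 = fit_nested_en(ds, nRep=2, nOuter=4, alpha_grid=(0.5, 1.0), n_lambda=25, seed=3)
    r2 = fit_nested_en(ds, nRep=2, nOuter=4, alpha_grid=(0.5, 1.0), n_lambda=25, seed=3)
    for m1, m2 in zip(r1.models, r2.models):
        assert (m1.alpha, m1.lam) == (m2.alpha, m2.lam)
        assert np.array_equal(m1.coef_std, m2.coef_std)


def test_huge_lambda_zeroes_penalized_but_not_kept():
    rng = np.random.default_rng(4)
    Xf = rng.normal(size=(40, 10))
    C = rng.normal(size=(40, 1))
    y = 2 * C[:, 0] + Xf[:, 0] + rng.normal(size=40)
    solver = _GaussianKeepEN(Xf, y, C)
    beta = solver.path(1.0, [1e6])[:, 0]
    bc = solver.covariate_coefs(beta)
    assert np.all(beta == 0.0)
    assert bc[1] != 0.0  # the kept covariate keeps its (unpenalized) coefficient


def test_alpha_grid_validation():
    ds = simulate_signal_noise(40, 2, 18, 2.0, "regression", seed=5)
    with pytest.raises(ValueError, match="ridge"):
        fit_nested_en(ds, alpha_grid=(0.0, 0.5))


def test_keep_solution_matches_glmnet_penalty_factors(tmp_path):
    """Independent oracle: glmnet with penalty.factor=0 on the covariates.

    glmnet rescales penalty factors to average one and scales its L2 term by
    1/sd(y); the test maps (alpha, lambda) through both conventions so the two
    solvers face the identical objective.
    """
    rng = np.random.default_rng(7)
    n, p, k = 40, 8, 2
    C = rng.normal(size=(n, k))
    Xf = rng.normal(size=(n, p))
    y = 1.5 * C[:, 0] - C[:, 1] + 2 * Xf[:, 0] + 0.5 * Xf[:, 1] + rng.normal(size=n)
    Xs = (Xf - Xf.mean(0)) / Xf.std(0)  # pre-standardized for both solvers
    lam, a = 0.1, 0.5
    solver = _GaussianKeepEN(Xs, y, C)
    beta = solver.path(a, [lam])[:, 0]
    bc = solver.covariate_coefs(beta)

    sy = y.std()
    A, B = lam * a, lam * (1 - a) * sy
    lam_r, a_r = (A + B) * p / (p + k), A / (A + B)
    np.savetxt(tmp_path / "X.csv", np.column_stack([C, Xs]), delimiter=",")
    np.savetxt(tmp_path / "y.csv", y, delimiter=",")
    script = tmp_path / "cmp.R"
    script.write_text(f"""
suppressMessages(library(glmnet))
X <- as.matrix(read.csv("{tmp_path}/X.csv", header=FALSE))
y <- scan("{tmp_path}/y.csv", quiet=TRUE)
fit <- glmnet(X, y, alpha={a_r}, lambda={lam_r}, penalty.factor=c(0,0,rep(1,{p})),
              standardize=FALSE, thresh=1e-14, maxit=1e7)
cat(paste(as.numeric(coef(fit)), collapse=","), "\\n")
""")
    out = subprocess.run(["Rscript", str(script)], capture_output=True, text=True,
                         timeout=120)
    assert out.returncode == 0, out.stderr
    co = np.array([float(v) for v in out.stdout.strip().split(",")])
    assert np.abs(co[1 + k:] - beta).max() < 1e-4
    assert np.abs(np.r_[co[0], co[1:1 + k]] - bc).max() < 1e-4


def test_en_importance_counting():
    imp_names = ["a", "b", "c"]

    def model(nonzero, coef_std):
        return ENCalibrationModel(0, 0, 1.0, 0.1, {}, np.asarray(coef_std),
                                  tuple(nonzero), np.arange(2), 0.0)

    models = [model(("a",), [1.0, 0.0, 0.0]), model(("a", "b"), [0.5, 0.2, 0.0])]
    imp = en_importance(models, imp_names)
    assert imp.proportion.tolist() == [1.0, 0.5, 0.0]
    assert imp.rank.tolist() == [1.0, 2.0, 3.0]


def _fake_models(counts, fits):
    out = []
    for c, f in zip(counts, fits):
        nz = tuple(f"v{i}" for i in range(int(c)))
        out.append(ENCalibrationModel(0, 0, 1.0, 0.1, {}, np.zeros(60), nz,
                                      np.arange(2), float(f)))
    return out


def _fake_importance(n=60):
    names = [f"v{i}" for i in range(n)]
    prop = np.linspace(1, 0, n)
    return ENImportance(names, prop, prop.copy(), np.arange(1, n + 1).astype(float))


def test_select_by_quantiles_linear_interpolation():
    models = _fake_models([10, 20, 30, 40], [0.5] * 4)
    sel = select_by_quantiles(models, _fake_importance())
    assert (sel.n_min, sel.n_mid, sel.n_max) == (18, 25, 33)
    allsame = _fake_models([30] * 4, [0.5] * 4)
    sel2 = select_by_quantiles(allsame, _fake_importance())
    assert (sel2.n_min, sel2.n_mid, sel2.n_max) == (30, 30, 30)
    assert set(sel.vars_min) <= set(sel.vars_max)


def test_select_by_fitness_curve_brackets_known_optimum():
    rng = np.random.default_rng(8)
    counts = np.repeat(np.arange(5, 55, 5), 4)
    fits = 0.8 - ((counts - 30) / 30.0) ** 2 + rng.normal(0, 0.01, len(counts))
    sel = select_by_fitness_curve(_fake_models(counts, fits), _fake_importance(),
                                  "Q2")
    assert sel.n_min <= 30 <= sel.n_max
    assert sel.n_min >= 10 and sel.n_max <= 50


def test_select_by_fitness_curve_flat_scatter_spans_range():
    counts = np.repeat(np.arange(5, 35, 5), 3)
    sel = select_by_fitness_curve(_fake_models(counts, [0.5] * len(counts)),
                                  _fake_importance(), "Q2")
    assert (sel.n_min, sel.n_max) == (5, 30)


def test_select_by_fitness_curve_outlier_robust():
    rng = np.random.default_rng(9)
    counts = np.repeat(np.arange(5, 55, 5), 4)
    fits = 0.8 - ((counts - 30) / 30.0) ** 2 + rng.normal(0, 0.01, len(counts))
    base = select_by_fitness_curve(_fake_models(counts, fits), _fake_importance(), "Q2")
    fits_out = fits.copy()
    fits_out[3] = -5.0  # one wild outlier
    pert = select_by_fitness_curve(_fake_models(counts, fits_out),
                                   _fake_importance(), "Q2")
    assert (pert.n_min, pert.n_max) == (base.n_min, base.n_max)


def test_select_by_fitness_curve_needs_enough_models():
    with pytest.raises(ValueError, match="quantile"):
        select_by_fitness_curve(_fake_models([5, 10], [0.1, 0.2]),
                                _fake_importance(), "Q2")


def test_duplicated_column_importance_spreads():
    diffs = []
    for s in range(5):
        rng = np.random.default_rng(200 + s)
        n = 50
        base = rng.normal(size=n)
        X = np.column_stack([base, base + 1e-9 * rng.normal(size=n),
                             rng.normal(size=(n, 18))])
        from muvr2.metrics import TargetVector
        from muvr2.rdcv_core import OmicsDataset
        y = TargetVector(base + 0.5 * rng.normal(size=n), "continuous")
        ds = OmicsDataset(X, y, [f"v{i}" for i in range(20)],
                          [f"o{i}" for i in range(n)])
        res = fit_nested_en(ds, nRep=2, nOuter=4, alpha_grid=(0.3,), n_lambda=25,
                            seed=s)
        prop = res.importance.proportion
        diffs.append(abs(prop[0] - prop[1]))
    assert np.mean(diffs) <= 0.25


def test_selection_stability_across_seeds():
    ds = simulate_signal_noise(60, 5, 45, 3.0, "regression", seed=6)
    sels = []
    for seed in (101, 202):
        res = fit_nested_en(ds, nRep=2, nOuter=5, alpha_grid=(0.5, 1.0),
                            n_lambda=30, seed=seed)
        sels.append(set(select_by_quantiles(res.models, res.importance).vars_min))
    jaccard = len(sels[0] & sels[1]) / len(sels[0] | sels[1])
    assert jaccard >= 0.6


def test_covariate_adjustment_shifts_ranks(causal_rank_summaries):
    """Keeping the covariates must push the confounded/mediated predictors
    (X1, X3, X4) toward noise ranks while X2 stays at least as good."""
    en = causal_rank_summaries["EN"]
    add, keep = en[("EN", "C_add")], en[("EN", "C_keep")]
    for v in ("X1", "X3", "X4"):
        assert keep[v] > add[v]
    assert keep["X2"] <= add["X2"]
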