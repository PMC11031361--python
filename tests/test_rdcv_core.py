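"""Repeated double cross-validation core: plans, schedules, ranking, fitting."""

import numpy as np
import pytest

from muvr2.metrics import TargetVector
from muvr2.rdcv_core import (FitnessCurve, OmicsDataset, elimination_schedule,
                             fit_rdcv, make_cv_plan, rank_variables_pls,
                             rank_variables_rf, select_min_mid_max, tune_inner)
from muvr2.synthetic_data import simulate_signal_noise


def brute_force_schedule(n, ratio):
    counts = [n]
    while counts[-1] > 2:
        nxt = int(np.floor(counts[-1] * ratio))
        if nxt >= counts[-1]:
            nxt = counts[-1] - 1
        counts.append(max(nxt, 2))
    return counts


@pytest.mark.parametrize("ratio", [0.5, 0.75, 0.9])
def test_elimination_schedule_matches_brute_force(ratio):
    for n in range(2, 501):
        assert elimination_schedule(n, ratio) == brute_force_schedule(n, ratio)


def test_elimination_schedule_examples():
    assert elimination_schedule(100, 0.75) == [100, 75, 56, 42, 31, 23, 17, 12,
                                               9, 6, 4, 3, 2]
    assert elimination_schedule(2, 0.5) == [2]
    assert elimination_schedule(4, 0.9) == [4, 3, 2]
    with pytest.raises(ValueError):
        elimination_schedule(100, 1.2)


def _tiny_dataset(n=12, p=6, seed=0, kind="regression"):
    return simulate_signal_noise(n, 2, p - 2, 2.0, kind, seed=seed)


def test_cv_plan_segment_sizes_and_determinism():
    ds = _tiny_dataset(n=12)
    plan = make_cv_plan(ds, nRep=3, nOuter=6, seed=4)
    for rep in range(3):
        sizes = np.bincount(plan.outer_assignment[rep], minlength=6)
        assert sizes.tolist() == [2] * 6
    plan2 = make_cv_plan(ds, nRep=3, nOuter=6, seed=4)
    assert np.array_equal(plan.outer_assignment, plan2.outer_assignment)
    with pytest.raises(ValueError):
        make_cv_plan(ds, nRep=1, nOuter=13)


def test_cv_plan_classification_stratified():
    y = TargetVector(np.array(["a"] * 6 + ["b"] * 6), "categorical")
    X = np.random.default_rng(0).normal(size=(12, 3))
    ds = OmicsDataset(X, y, ["v1", "v2", "v3"], [f"o{i}" for i in range(12)])
    plan = make_cv_plan(ds, nRep=2, nOuter=6, seed=0)
    for rep in range(2):
        for seg in range(6):
            labels = y.values[plan.outer_assignment[rep] == seg]
            assert set(labels) == {"a", "b"}


def test_cv_plan_reduces_nouter_for_small_classes():
    y = TargetVector(np.array(["a"] * 3 + ["b"] * 9), "categorical")
    X = np.random.default_rng(0).normal(size=(12, 3))
    ds = OmicsDataset(X, y, ["v1", "v2", "v3"], [f"o{i}" for i in range(12)])
    with pytest.warns(UserWarning, match="reduc"):
        plan = make_cv_plan(ds, nRep=1, nOuter=6, seed=0)
    assert plan.nOuter == 3


def test_cv_plan_regression_stratifies_target():
    # sorted-block dealing: every segment's mean target close to the global mean
    ds = simulate_signal_noise(60, 1, 4, 1.0, "regression", seed=2)
    plan = make_cv_plan(ds, nRep=1, nOuter=6, seed=2)
    y = np.asarray(ds.y.values, float)
    seg_means = [y[plan.outer_assignment[0] == s].mean() for s in range(6)]
    assert np.ptp(seg_means) < 0.8 * y.std()


def test_pls_ranking_finds_dominant_predictor():
    rng = np.random.default_rng(3)
    X = rng.normal(size=(40, 11))
    y = TargetVector(X[:, 0] + 0.05 * rng.normal(size=40), "continuous")
    ranks = rank_variables_pls(X, y, 2)
    assert ranks[0] == 1.0


def test_pls_ranking_duplicated_column_tie():
    rng = np.random.default_rng(4)
    X = rng.normal(size=(30, 5))
    X[:, 1] = X[:, 0]
    y = TargetVector(X[:, 0] + 0.1 * rng.normal(size=30), "continuous")
    ranks = rank_variables_pls(X, y, 2)
    assert ranks[0] == ranks[1] == 1.5  # mid-rank of the duplicated pair


def test_rf_ranking_finds_dominant_predictor():
    rng = np.random.default_rng(5)
    X = rng.normal(size=(60, 11))
    y = TargetVector(X[:, 0] + 0.1 * rng.normal(size=60), "continuous")
    ranks = rank_variables_rf(X, y, n_trees=80, seed=5)
    assert ranks[0] == 1.0


def test_rf_ranking_pure_noise_has_no_consistent_winner():
    wins = np.zeros(8)
    for s in range(12):
        rng = np.random.default_rng(100 + s)
        X = rng.normal(size=(40, 8))
        y = TargetVector(rng.normal(size=40), "continuous")
        ranks = rank_variables_rf(X, y, n_trees=40, seed=s)
        wins[np.argmin(ranks)] += 1
    assert wins.max() <= 0.4 * 12


def test_tune_inner_low_rank_selects_enough_components():
    rng = np.random.default_rng(6)
    n = 48
    t1, t2 = rng.normal(size=n), rng.normal(size=n)
    X = np.column_stack([t1, t1, t2, t2, rng.normal(size=(n, 4))])
    y = TargetVector(t1 + t2 + 0.05 * rng.normal(size=n), "continuous")
    assign = np.repeat(np.arange(4), n // 4)
    hyper = tune_inner(X, y, "PLS", assign, "Q2", max_comp=5)
    assert hyper["n_components"] >= 2


def test_tune_inner_rf_returns_fixed_defaults():
    ds = _tiny_dataset(n=20, p=5)
    assign = np.tile(np.arange(4), 5)
    hyper = tune_inner(ds.X, ds.y, "RF", assign, "Q2", n_trees=33)
    assert hyper == {"n_trees": 33}


def test_fit_rdcv_deterministic():
    ds = _tiny_dataset(n=24, p=8, seed=7)
    r1 = fit_rdcv(ds, "PLS", nRep=2, nOuter=4, seed=9)
    r2 = fit_rdcv(ds, "PLS", nRep=2, nOuter=4, seed=9)
    for c in r1.schedule:
        assert np.array_equal(r1.curve.values[c], r2.curve.values[c])
        assert np.array_equal(r1.holdout[c], r2.holdout[c])
    assert r1.selection.vars_min == r2.selection.vars_min


def test_fit_rdcv_leakage_audit_and_submodel_count():
    ds = _tiny_dataset(n=24, p=10, seed=8)
    res = fit_rdcv(ds, "PLS", nRep=2, nOuter=4, nInner=3, seed=8, audit=True)
    for rec in res.audit:
        assert not set(rec["train_idx"]) & set(rec["eval_idx"])
    expected = 2 * 4 * len(res.schedule) * (3 + 1)
    assert len(res.audit) == expected


def test_fit_rdcv_pure_noise_holdout_stays_near_zero():
    # hold-out (outer test) fitness must show no systematic fit on pure noise;
    # the inner validation curve may drift upward from selection bias, the
    # leakage-guarded hold-out predictions must not
    ds = simulate_signal_noise(30, 0, 20, 0.0, "regression", seed=9)
    res = fit_rdcv(ds, "PLS", nRep=2, nOuter=5, seed=9)
    holdout_means = [np.mean(res.rep_fitness[c]) for c in res.schedule]
    assert np.all(np.asarray(holdout_means) <= 0.2)


def test_fit_rdcv_keep_excluded_from_ranking_and_selection():
    ds = _tiny_dataset(n=24, p=8, seed=10).with_keep(("N1",))
    res = fit_rdcv(ds, "PLS", nRep=1, nOuter=4, seed=10)
    assert "N1" not in res.importance.var_names
    assert "N1" not in res.selection.vars_max
    assert res.importance.as_dict()["N1"] == 0.0
    assert res.schedule[0] == ds.n_vars - 1


def test_fit_rdcv_classification():
    ds = simulate_signal_noise(36, 2, 6, 3.0, "binary", seed=11)
    res = fit_rdcv(ds, "RF", nRep=1, nOuter=3, n_trees=40, seed=11,
                   fitness_metric="BER")
    assert 0.0 <= res.selection.fitness_mid <= 1.0
    res2 = fit_rdcv(ds, "PLS", nRep=1, nOuter=3, seed=11, fitness_metric="MISS")
    assert res2.selection.fitness_mid >= 0
    with pytest.raises(ValueError, match="not a classification metric"):
        fit_rdcv(ds, "PLS", fitness_metric="Q2")


def test_consensus_nesting_and_geometric_mid(signal_dataset):
    res = fit_rdcv(signal_dataset, "PLS", nRep=2, nOuter=6, seed=3)
    sel = res.selection
    assert set(sel.vars_min) <= set(sel.vars_mid) <= set(sel.vars_max)
    assert sel.n_min <= sel.n_mid <= sel.n_max
    assert sel.n_mid == int(np.floor(np.sqrt(sel.n_min * sel.n_max) + 0.5))


def test_select_min_mid_max_edge_cases():
    flat = FitnessCurve([20, 10, 5, 2], {c: np.array([0.5]) for c in [20, 10, 5, 2]},
                        "Q2")
    sel = select_min_mid_max(flat)
    assert (sel.n_min, sel.n_max) == (2, 20)
    mono = FitnessCurve([20, 10, 5, 2],
                        {20: np.array([0.9]), 10: np.array([0.6]),
                         5: np.array([0.4]), 2: np.array([0.2])}, "Q2")
    sel = select_min_mid_max(mono)
    assert sel.n_max == 20 and sel.n_min == 20
    single = FitnessCurve([7], {7: np.array([0.3])}, "Q2")
    sel = select_min_mid_max(single)
    assert sel.n_min == sel.n_mid == sel.n_max == 7
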