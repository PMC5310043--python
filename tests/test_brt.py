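"""Boosted-tree fitting, influence, simplification, threshold and forecast."""

import warnings

import numpy as np
import pandas as pd
import pytest

from reefcarb.brt import (
    BRTConfig,
    build_design,
    fit_brt,
    forecast_scenario,
    optimal_threshold,
    partial_dependence,
    reef_predictor_table,
    simplify_predictors,
)
from reefcarb.budget import build_trajectory_panel

FAST = BRTConfig(learning_rate=0.05, max_trees=400, n_folds=5,
                 step_size=25, seed=0)


def _separable_design(seed=0, n_reefs=40, flip=0.0):
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_reefs):
        y = i % 2
        for s in range(5):
            resp = y ^ (rng.random() < flip)
            rows.append({"reef_id": f"R{i:02d}", "site_id": f"S{s}",
                         "response": int(resp),
                         "sep": y + rng.normal(0, 0.01),
                         "noise1": rng.normal(), "noise2": rng.normal()})
    return pd.DataFrame(rows)


def test_config_invariants():
    with pytest.raises(ValueError):
        BRTConfig(learning_rate=0.5)
    with pytest.raises(ValueError):
        BRTConfig(bag_fraction=0.0)
    with pytest.raises(ValueError):
        BRTConfig(n_folds=1)


def test_influence_sums_to_100_and_nonnegative():
    m = fit_brt(_separable_design(flip=0.05), FAST)
    assert m.relative_influence.sum() == pytest.approx(100.0, abs=1e-9)
    assert (m.relative_influence >= 0).all()


def test_perfect_separator_dominates_influence():
    m = fit_brt(_separable_design(), FAST)
    assert m.relative_influence["sep"] > 95.0


def test_row_permutation_invariance():
    d = _separable_design(flip=0.05)
    shuffled = d.sample(frac=1.0, random_state=9).reset_index(drop=True)
    a = fit_brt(d, FAST).relative_influence
    b = fit_brt(shuffled, FAST).relative_influence
    assert float((a - b).abs().max()) <= 1e-9


def test_single_class_response_raises():
    d = _separable_design()
    d["response"] = 1
    with pytest.raises(ValueError, match="single class"):
        fit_brt(d, FAST)


def test_still_decreasing_cv_raises():
    cramped = BRTConfig(learning_rate=0.005, max_trees=50, n_folds=5,
                        step_size=25, seed=0)
    with pytest.raises(RuntimeError, match="max_trees"):
        fit_brt(_separable_design(), cramped)


def test_simplify_drops_pure_noise_predictors():
    m = fit_brt(_separable_design(flip=0.05), FAST)
    reduced, removed = simplify_predictors(m)
    assert set(removed) == {"noise1", "noise2"}
    assert reduced.predictors == ["sep"]


def test_partial_dependence_monotone_fixture():
    m = fit_brt(_separable_design(), FAST)
    curve = partial_dependence(m, "sep")
    assert curve["probability"].between(0, 1).all()
    assert curve["probability"].iloc[0] < 0.5 < curve["probability"].iloc[-1]
    with pytest.raises(KeyError):
        partial_dependence(m, "not_a_predictor")
    with pytest.warns(UserWarning, match="extrapolation"):
        partial_dependence(m, "sep", grid=np.array([-5.0, 5.0]))


# -- design construction ---------------------------------------------------------

def test_build_design_reef_level_predictors(panel_bundle):
    ds, rates, _ = panel_bundle
    panel = build_trajectory_panel(ds, rates)
    design = build_design(panel, predictor_year=2005)
    resp2014 = panel.sites[panel.sites["year"] == 2014]
    assert len(design) == len(resp2014)
    # all sites of a reef share the reef's predictor values
    per_reef = design.groupby("reef_id")["cover_massive"].nunique()
    assert (per_reef == 1).all()


def test_build_design_1994_macroalgae_presence_absence(panel_bundle):
    ds, rates, _ = panel_bundle
    panel = build_trajectory_panel(ds, rates)
    design = build_design(panel, predictor_year=1994)
    assert set(design["cover_macroalgae"].unique()) <= {0.0, 1.0}


def test_build_design_drops_zero_variance(panel_bundle):
    ds, rates, _ = panel_bundle
    panel = build_trajectory_panel(ds, rates)
    reefs = panel.reefs.copy()
    reefs.loc[reefs["year"] == 2005, "depth_m"] = 8.0
    panel.reefs = reefs
    with pytest.warns(UserWarning, match="zero-variance"):
        design = build_design(panel, predictor_year=2005)
    assert "depth_m" not in design.columns


# -- threshold -------------------------------------------------------------------

def test_threshold_midpoint_example():
    res = optimal_threshold(np.array([0.1, 0.4, 0.6, 0.9]),
                            np.array([0, 0, 1, 1]))
    assert res.threshold == pytest.approx(0.5)
    assert res.achieved_prevalence_gap == 0.0


def test_threshold_boundary_cases():
    with pytest.warns(UserWarning, match="no observed positives"):
        res = optimal_threshold(np.array([0.2, 0.8]), np.array([0, 0]))
    assert res.threshold > 0.8
    with pytest.warns(UserWarning, match="all observations positive"):
        res = optimal_threshold(np.array([0.2, 0.8]), np.array([1, 1]))
    assert res.threshold <= 0.2


def test_threshold_rejects_nonprobabilities():
    with pytest.raises(ValueError):
        optimal_threshold(np.array([0.5, 1.5]), np.array([0, 1]))


def test_threshold_handles_ties():
    p = np.array([0.7, 0.7, 0.7, 0.2])
    res = optimal_threshold(p, np.array([1, 0, 0, 0]))
    # ties straddle the cut: threshold falls on the tied value
    assert res.threshold == pytest.approx(0.7)
    assert res.achieved_prevalence_gap == pytest.approx(abs(3 / 4 - 1 / 4))


# -- forecasting -----------------------------------------------------------------

def test_forecast_same_inputs_same_probability(panel_bundle):
    ds, rates, _ = panel_bundle
    panel = build_trajectory_panel(ds, rates)
    design = build_design(panel, predictor_year=1994)
    model = fit_brt(design, BRTConfig(learning_rate=0.02, max_trees=800,
                                      n_folds=5, step_size=25, seed=0))
    prob = model.predict_proba(design)
    thr = optimal_threshold(prob, design["response"].to_numpy())
    tbl = reef_predictor_table(panel, 1994, macroalgae_presence_absence=True)
    fc = forecast_scenario(model, tbl, thr)
    assert fc["probability_positive"].between(0, 1).all()
    # reapplying the model to its own training predictors reproduces the
    # per-reef hindcast probabilities
    hind = (design.assign(p=prob).groupby("reef_id")["p"].mean()
            .sort_index())
    got = fc.set_index("reef_id")["probability_positive"].sort_index()
    np.testing.assert_allclose(got.to_numpy(), hind.to_numpy(), rtol=1e-9)
    # and is invariant to reef ordering
    fc2 = forecast_scenario(model, tbl.iloc[::-1], thr)
    pd.testing.assert_frame_equal(fc, fc2)


def test_forecast_missing_predictor_named(panel_bundle):
    ds, rates, _ = panel_bundle
    panel = build_trajectory_panel(ds, rates)
    design = build_design(panel, predictor_year=1994)
    model = fit_brt(design, BRTConfig(learning_rate=0.05, max_trees=400,
                                      n_folds=5, step_size=25, seed=0))
    tbl = reef_predictor_table(panel, 1994).drop(columns=["cover_massive"])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        thr = optimal_threshold(np.array([0.5]), np.array([1]))
    with pytest.raises(KeyError, match="cover_massive"):
        forecast_scenario(model, tbl, thr)
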