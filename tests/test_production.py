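"""Production-engine arithmetic, loadings factorization and hindcast fit."""

import numpy as np
import pandas as pd
import pytest

from reefcarb.census import ValidationError
from reefcarb.production import (
    HindcastModel,
    build_hindcast_pairs,
    colony_production,
    fit_hindcast,
    hindcast_production,
    production_by_site,
    production_loadings,
    transect_production,
)
from reefcarb.simulate import simulate_hindcast_pairs

KEY1 = {"reef_id": "R01", "year": 2014, "site_id": "S01"}


def _intercepts(rows):
    return pd.DataFrame([KEY1 | r for r in rows])


def test_colony_production_hand_chain():
    assert colony_production(50.0, 1000.0, 1.0, 1.5, 1.0) == pytest.approx(
        0.75, abs=1e-12)


def test_colony_production_zero_surface():
    assert colony_production(0.0, 1000.0, 1.0, 1.5) == 0.0


def test_colony_production_monotone_in_growth():
    lo = colony_production(50.0, 1000.0, 0.8, 1.5)
    mean = colony_production(50.0, 1000.0, 1.0, 1.5)
    assert lo < mean


def test_colony_production_input_errors():
    with pytest.raises(ValueError):
        colony_production(50.0, 0.0, 1.0, 1.5)
    with pytest.raises(ValueError):
        colony_production(-1.0, 1000.0, 1.0, 1.5)


def test_transect_production_sums_colonies(oracle_rates):
    inter = _intercepts([
        {"genus": "Acropora", "morphology": "branching",
         "surface_length_cm": 50.0, "linear_length_cm": 25.0,
         "transect_length_cm": 1000.0},
        {"genus": "Acropora", "morphology": "branching",
         "surface_length_cm": 30.0, "linear_length_cm": 15.0,
         "transect_length_cm": 1000.0},
    ])
    res = transect_production(inter, oracle_rates)
    assert res.coral_production == pytest.approx(0.75 + 0.45, rel=1e-12)
    assert res.cca_production == 0.0
    assert res.total == res.coral_production


def test_transect_production_cca_contribution(oracle_rates):
    inter = _intercepts([
        {"genus": "CCA", "morphology": "encrusting",
         "surface_length_cm": 100.0, "linear_length_cm": 100.0,
         "transect_length_cm": 1000.0},
    ])
    res = transect_production(inter, oracle_rates)
    # 10% planar cover at the configured rate per percent cover
    assert res.cca_production == pytest.approx(10.0 * oracle_rates.cca_rate,
                                               rel=1e-12)
    assert res.coral_production == 0.0


def test_transect_production_unknown_taxon_falls_back(oracle_rates):
    inter = _intercepts([
        {"genus": "Unratedus", "morphology": "submassive",
         "surface_length_cm": 100.0, "linear_length_cm": 80.0,
         "transect_length_cm": 1000.0},
    ])
    res = transect_production(inter, oracle_rates)
    # OtherCoral fallback row: 10 * 0.5 * 1.6 * 0.1
    assert res.coral_production == pytest.approx(0.8, rel=1e-12)


def test_transect_production_empty_is_flagged(oracle_rates):
    res = transect_production(_intercepts([]).reindex(
        columns=["reef_id", "year", "site_id", "genus", "morphology",
                 "surface_length_cm", "linear_length_cm",
                 "transect_length_cm"]), oracle_rates)
    assert res.no_census
    assert np.isnan(res.coral_production)


def test_transect_production_rejects_mixed_sites(oracle_rates):
    inter = pd.concat([
        _intercepts([{"genus": "Acropora", "morphology": "branching",
                      "surface_length_cm": 10.0, "linear_length_cm": 5.0,
                      "transect_length_cm": 1000.0}]),
        _intercepts([{"genus": "Acropora", "morphology": "branching",
                      "surface_length_cm": 10.0, "linear_length_cm": 5.0,
                      "transect_length_cm": 1000.0}]).assign(site_id="S02"),
    ])
    with pytest.raises(ValueError, match="more than one site"):
        transect_production(inter, oracle_rates)


def test_unknown_rate_variant_raises(oracle_rates):
    inter = _intercepts([{"genus": "Acropora", "morphology": "branching",
                          "surface_length_cm": 10.0, "linear_length_cm": 5.0,
                          "transect_length_cm": 1000.0}])
    with pytest.raises(ValueError, match="rate variant"):
        transect_production(inter, oracle_rates, which_rate="median")


def test_loadings_factorization_matches_site_production(panel_bundle):
    ds, rates, _ = panel_bundle
    prod = production_by_site(ds, rates, "mean", year=2014)
    site_keys, L, coral = production_loadings(ds, rates, year=2014)
    g = coral["growth_mean_cm_yr"].to_numpy(float)
    merged = site_keys.assign(via_loadings=L @ g).merge(
        prod, on=["reef_id", "year", "site_id"], validate="1:1")
    np.testing.assert_allclose(merged["via_loadings"],
                               merged["coral_production"], rtol=1e-10)


def test_production_by_site_matches_transect_engine(panel_bundle):
    ds, rates, _ = panel_bundle
    prod = production_by_site(ds, rates, "mean", year=2014)
    row = prod.iloc[0]
    inter = ds.intercepts[
        (ds.intercepts["reef_id"] == row["reef_id"])
        & (ds.intercepts["year"] == row["year"])
        & (ds.intercepts["site_id"] == row["site_id"])]
    res = transect_production(inter, rates)
    assert row["production"] == pytest.approx(res.total, rel=1e-10)


# -- hindcast ------------------------------------------------------------------

def test_fit_hindcast_requires_enough_sites(rng):
    pairs = simulate_hindcast_pairs(rng, n_sites=5)
    with pytest.raises(ValueError, match="at least"):
        fit_hindcast(pairs)


def test_fit_hindcast_missing_column(rng):
    pairs = simulate_hindcast_pairs(rng).drop(columns=["cover_massive"])
    with pytest.raises(ValueError, match="missing"):
        fit_hindcast(pairs)


def test_fit_hindcast_rank_deficiency(rng):
    pairs = simulate_hindcast_pairs(rng)
    pairs["cover_table"] = 0.0
    with pytest.raises(np.linalg.LinAlgError):
        fit_hindcast(pairs)


def test_fit_hindcast_noiseless_recovery(rng):
    beta = {"branching": 0.12, "encrusting": 0.02,
            "massive": 0.05, "table": 0.15}
    pairs = simulate_hindcast_pairs(rng, beta=beta, noise_sd=0.0)
    m = fit_hindcast(pairs)
    for k, v in m.coef.items():
        assert v == pytest.approx(beta[k], rel=1e-10)
    assert m.r2 == pytest.approx(1.0, abs=1e-12)


def test_hindcast_production_bounds_check():
    m = HindcastModel(coef={"branching": 0.1}, resid_se=0.1, r2=0.9, n_sites=20)
    bad = pd.DataFrame({"cover_branching": [120.0]})
    with pytest.raises(ValidationError):
        hindcast_production(bad, m)


def test_hindcast_model_rejects_nonfinite_coef():
    with pytest.raises(ValidationError):
        HindcastModel(coef={"branching": np.nan}, resid_se=0.1, r2=0.9,
                      n_sites=20)


def test_panel_hindcast_explains_census_production(panel_bundle):
    ds, rates, _ = panel_bundle
    pairs = build_hindcast_pairs(ds, rates)
    m = fit_hindcast(pairs)
    assert m.r2 > 0.95
    assert m.n_sites == len(pairs)
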