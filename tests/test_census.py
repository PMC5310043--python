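"""Schema, validation, IO round-trip and elementary-conversion tests."""

import numpy as np
import pandas as pd
import pytest

from reefcarb.census import (
    DEFAULT_POINT_COUNT_RADIUS_M,
    EndolithicRates,
    LookupError_,
    SchemaError,
    SurveyDataset,
    ValidationError,
    assign_functional_group,
    attach_fish_biomass,
    biomass_from_length,
    group_biomass_kg_ha,
    point_count_area,
    read_survey,
)


def _tiny_dataset():
    key = {"reef_id": "R01", "year": 2014, "site_id": "S01"}
    sites = pd.DataFrame([key | {
        "habitat": "carbonate", "depth_m": 8.0, "rugosity_class": 3,
        "wave_exposure_jm3": 0.2, "reserve": False,
        "regime_status": "recovered"}])
    benthic = pd.DataFrame([key | {
        "cover_branching": 20.0, "cover_encrusting": 4.0,
        "cover_massive": 6.0, "cover_table": 5.0, "cover_macroalgae": 0.0,
        "cover_soft": 2.0, "cover_sand": 10.0, "cover_rubble": 12.0,
        "cover_rock": 30.0, "cover_cca": 1.0}])
    intercepts = pd.DataFrame([key | {
        "genus": "Acropora", "morphology": "branching",
        "surface_length_cm": 40.0, "linear_length_cm": 20.0,
        "transect_length_cm": 1000.0}])
    fish = pd.DataFrame([key | {
        "species": "Chlorurus sordidus", "total_length_cm": 25.0, "count": 2}])
    urchins = pd.DataFrame([key | {
        "species": "Echinometra mathaei", "test_size_cm": 4.0, "count": 1,
        "belt_area_m2": 20.0}])
    return SurveyDataset(sites=sites, benthic=benthic, intercepts=intercepts,
                         fish=fish, urchins=urchins)


# -- elementary conversions --------------------------------------------------

def test_point_count_area_default_radius():
    assert point_count_area() == pytest.approx(
        np.pi * DEFAULT_POINT_COUNT_RADIUS_M**2, rel=1e-12)


def test_point_count_area_rejects_nonpositive_radius():
    with pytest.raises(ValueError):
        point_count_area(0.0)


def test_biomass_from_length_power_law():
    assert biomass_from_length(20.0, 0.01, 3.0) == pytest.approx(80.0)
    with pytest.raises(ValueError):
        biomass_from_length(-5.0, 0.01, 3.0)
    with pytest.raises(ValueError):
        biomass_from_length(20.0, -0.01, 3.0)


def test_assign_functional_group(oracle_rates):
    assert assign_functional_group(
        "Chlorurus sordidus", oracle_rates.length_weight) == "excavator"
    with pytest.raises(LookupError_):
        assign_functional_group("Nemo", oracle_rates.length_weight)


def test_attach_fish_biomass_values(oracle_rates):
    fish = _tiny_dataset().fish
    out = attach_fish_biomass(fish, oracle_rates.length_weight)
    expected = 2 * 0.015 * 25.0**3.04
    assert out["biomass_g"].iloc[0] == pytest.approx(expected, rel=1e-12)
    assert out["functional_group"].iloc[0] == "excavator"


def test_attach_fish_biomass_unknown_species(oracle_rates):
    fish = _tiny_dataset().fish.assign(species="Unknown fish")
    with pytest.raises(LookupError_):
        attach_fish_biomass(fish, oracle_rates.length_weight)


def test_group_biomass_unit_conversion(oracle_rates):
    fish = attach_fish_biomass(_tiny_dataset().fish,
                               oracle_rates.length_weight)
    out = group_biomass_kg_ha(fish, area_m2=100.0)
    # grams per 100 m^2 -> kg per hectare multiplies by 10/area
    expected = fish["biomass_g"].iloc[0] * 10.0 / 100.0
    assert out["excavator_kg_ha"].iloc[0] == pytest.approx(expected, rel=1e-12)
    assert (out[["browser_kg_ha", "scraper_kg_ha"]].to_numpy() == 0).all()


# -- rate tables -------------------------------------------------------------

def test_endolithic_rugosity_map_must_be_monotone():
    with pytest.raises(ValidationError):
        EndolithicRates(rugosity_map={0: 1.0, 1: 0.9})
    with pytest.raises(ValidationError):
        EndolithicRates(rugosity_map={0: 1.5, 1: 1.2})


def test_endolithic_unknown_class_raises():
    with pytest.raises(ValidationError):
        EndolithicRates().multiplier(7)


def test_rate_tables_validate_growth_ci(oracle_rates):
    import dataclasses
    bad_coral = oracle_rates.coral.copy()
    bad_coral.loc[0, "growth_lo95_cm_yr"] = 2.0  # above the mean
    bad = dataclasses.replace(oracle_rates, coral=bad_coral)
    with pytest.raises(ValidationError):
        bad.validate()


def test_default_rates_pass_validation(default_rates):
    default_rates.validate()


# -- dataset validation and IO -----------------------------------------------

def test_tiny_dataset_is_valid():
    _tiny_dataset().validate()


def test_missing_column_is_schema_error():
    ds = _tiny_dataset()
    ds.sites = ds.sites.drop(columns=["depth_m"])
    with pytest.raises(SchemaError):
        ds.validate()


@pytest.mark.parametrize("table,column,value", [
    ("sites", "depth_m", -1.0),
    ("sites", "rugosity_class", 9),
    ("sites", "year", 2001),
    ("sites", "habitat", "lagoon"),
    ("benthic", "cover_branching", 120.0),
    ("intercepts", "linear_length_cm", 0.0),
    ("intercepts", "transect_length_cm", -10.0),
    ("fish", "total_length_cm", 0.0),
    ("fish", "count", 0),
    ("urchins", "belt_area_m2", 0.0),
])
def test_row_level_invariants(table, column, value):
    ds = _tiny_dataset()
    df = getattr(ds, table).copy()
    df.loc[0, column] = value
    setattr(ds, table, df)
    with pytest.raises(ValidationError):
        ds.validate()


def test_linear_length_cannot_exceed_surface_length():
    ds = _tiny_dataset()
    ds.intercepts.loc[0, "linear_length_cm"] = 50.0  # surface is 40
    with pytest.raises(ValidationError):
        ds.validate()


def test_cover_sum_cannot_exceed_100():
    ds = _tiny_dataset()
    ds.benthic.loc[0, "cover_sand"] = 90.0
    with pytest.raises(ValidationError):
        ds.validate()


def test_orphan_records_are_rejected():
    ds = _tiny_dataset()
    ds.fish.loc[0, "site_id"] = "S99"
    with pytest.raises(ValidationError, match="unknown sites"):
        ds.validate()


def test_duplicate_site_keys_are_rejected():
    ds = _tiny_dataset()
    ds.sites = pd.concat([ds.sites, ds.sites], ignore_index=True)
    with pytest.raises(ValidationError, match="duplicate"):
        ds.validate()


def test_write_read_round_trip(tmp_path):
    ds = _tiny_dataset()
    ds.write(tmp_path / "census")
    back = read_survey(tmp_path / "census")
    for name in ("sites", "benthic", "intercepts", "fish", "urchins"):
        a, b = getattr(ds, name), getattr(back, name)
        pd.testing.assert_frame_equal(
            a.reset_index(drop=True), b.reset_index(drop=True),
            check_dtype=False)


def test_read_missing_table_raises(tmp_path):
    with pytest.raises(FileNotFoundError):
        SurveyDataset.read(tmp_path)


def test_subset_year(panel_bundle):
    ds, _, _ = panel_bundle
    sub = ds.subset_year(2014)
    assert set(sub.sites["year"]) == {2014}
    assert len(sub.sites) < len(ds.sites)
    sub.validate()
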