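"""Domain model, CSV readers/writers, validation and elementary conversions.

All census tables are plain pandas DataFrames joined on the composite key
``(reef_id, year, site_id)``.  A :class:`SurveyDataset` bundles the five
census tables (sites, benthic visual cover, line-intercept colony records,
parrotfish observations, urchin observations); a :class:`RateTables` bundles
the taxon-specific rate inputs (coral growth/density, parrotfish feeding and
erosion, length-weight constants, urchin erosion, endolithic erosion).

Percent covers are stored on the 0-100 scale throughout; fractions appear
only inside formulas.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

KEY = ["reef_id", "year", "site_id"]

SURVEY_YEARS = (1994, 2005, 2008, 2011, 2014)
HABITATS = ("carbonate", "granitic", "patch")
MORPHOLOGIES = ("branching", "encrusting", "massive", "table",
                "foliose", "submassive", "other")
HINDCAST_MORPHOLOGIES = ("branching", "encrusting", "massive", "table")
FUNCTIONAL_GROUPS = ("browser", "scraper", "excavator")
REGIME_STATUSES = ("recovered", "regime_shifted", "unassigned")

COVER_COLUMNS = [
    "cover_branching", "cover_encrusting", "cover_massive", "cover_table",
    "cover_macroalgae", "cover_soft", "cover_sand", "cover_rubble",
    "cover_rock", "cover_cca",
]

#: documented CSV schemas: table name -> required columns
SCHEMAS = {
    "sites": KEY + ["habitat", "depth_m", "rugosity_class",
                    "wave_exposure_jm3", "reserve", "regime_status"],
    "benthic": KEY + COVER_COLUMNS,
    "intercepts": KEY + ["genus", "morphology", "surface_length_cm",
                         "linear_length_cm", "transect_length_cm"],
    "fish": KEY + ["species", "total_length_cm", "count"],
    "urchins": KEY + ["species", "test_size_cm", "count", "belt_area_m2"],
}

#: default planar transect length for a 10 m line intercept, in cm
DEFAULT_TRANSECT_CM = 1000.0
#: default point-count radius, m
DEFAULT_POINT_COUNT_RADIUS_M = 7.0
#: default urchin belt transect area (10 m x 2 m), m^2
DEFAULT_BELT_AREA_M2 = 20.0


class SchemaError(ValueError):
    """A CSV is missing mandatory columns."""


class ValidationError(ValueError):
    """Row-level values violate a dataset invariant."""


class LookupError_(KeyError):
    """A species / genus has no entry in the relevant rate table."""


# ---------------------------------------------------------------------------
# elementary conversions
# ---------------------------------------------------------------------------

def point_count_area(radius: float = DEFAULT_POINT_COUNT_RADIUS_M) -> float:
    """Planar area (m^2) of a circular point count of the given radius (m)."""
    if radius <= 0:
        raise ValueError(f"point-count radius must be positive, got {radius}")
    return float(np.pi * radius**2)


def biomass_from_length(length_cm: float, a: float, b: float) -> float:
    """Individual wet mass (g) from total length (cm) via B = a * L**b."""
    if length_cm <= 0:
        raise ValueError(f"fish length must be positive, got {length_cm}")
    if a <= 0 or b <= 0:
        raise ValueError("length-weight constants a and b must be positive")
    return float(a * length_cm**b)


def assign_functional_group(species: str, length_weight: pd.DataFrame) -> str:
    """Look up the feeding functional group (browser/scraper/excavator).

    Unknown species raise rather than silently defaulting: a mis-keyed
    species name would otherwise corrupt the group biomass sums.
    """
    if not species:
        raise LookupError_("empty species identifier")
    hit = length_weight.loc[length_weight["species"] == species, "group"]
    if hit.empty:
        raise LookupError_(f"species {species!r} absent from length-weight table")
    return str(hit.iloc[0])


def attach_fish_biomass(fish: pd.DataFrame,
                        length_weight: pd.DataFrame) -> pd.DataFrame:
    """Return fish records with derived biomass_g and functional_group columns.

    ``biomass_g`` is the per-record total, i.e. count * a * L**b.
    """
    lw = length_weight.set_index("species")
    unknown = sorted(set(fish["species"]) - set(lw.index))
    if unknown:
        raise LookupError_(f"species missing from length-weight table: {unknown}")
    out = fish.copy()
    a = lw.loc[out["species"], "a"].to_numpy(float)
    b = lw.loc[out["species"], "b"].to_numpy(float)
    out["functional_group"] = lw.loc[out["species"], "group"].to_numpy()
    out["biomass_g"] = out["count"].to_numpy(float) * a * out["total_length_cm"].to_numpy(float) ** b
    if (out["biomass_g"] <= 0).any():
        raise ValidationError("derived fish biomass must be positive")
    return out


def group_biomass_kg_ha(fish_with_biomass: pd.DataFrame,
                        area_m2: float | None = None) -> pd.DataFrame:
    """Per-site biomass (kg ha^-1) of each parrotfish functional group.

    Sums record biomass within (site, functional_group) and scales by the
    census area (default: the 7 m radius point count).
    """
    if area_m2 is None:
        area_m2 = point_count_area()
    g = (fish_with_biomass.groupby(KEY + ["functional_group"], sort=True)["biomass_g"]
         .sum().unstack("functional_group", fill_value=0.0))
    for grp in FUNCTIONAL_GROUPS:
        if grp not in g.columns:
            g[grp] = 0.0
    g = g[list(FUNCTIONAL_GROUPS)]
    # g per point count -> kg per hectare: /1000 * (10000 / area)
    out = g * (10.0 / area_m2)
    out.columns = [f"{c}_kg_ha" for c in out.columns]
    return out.reset_index()


# ---------------------------------------------------------------------------
# rate tables
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EndolithicRates:
    """Endolithic (micro + macro borer) erosion parameters.

    Rates are kg CaCO3 m-2 yr-1 per unit of accessible substrate fraction;
    ``rugosity_map`` converts the 6-point visual rugosity class into a
    linear surface multiplier (monotone non-decreasing, >= 1).
    """

    micro_rate: float = 0.24
    macro_rate: float = 0.07
    rugosity_map: dict[int, float] = field(default_factory=lambda: {
        0: 1.0, 1: 1.2, 2: 1.5, 3: 1.9, 4: 2.4, 5: 3.0})

    def __post_init__(self) -> None:
        if self.micro_rate < 0 or self.macro_rate < 0:
            raise ValidationError("endolithic rates must be non-negative")
        classes = sorted(self.rugosity_map)
        vals = [self.rugosity_map[c] for c in classes]
        if any(v < 1 for v in vals) or any(b < a for a, b in zip(vals, vals[1:])):
            raise ValidationError(
                "rugosity multipliers must be >= 1 and non-decreasing in class")

    def multiplier(self, rugosity_class: int) -> float:
        try:
            return self.rugosity_map[int(rugosity_class)]
        except KeyError:
            raise ValidationError(
                f"no rugosity multiplier configured for class {rugosity_class}") from None


@dataclass
class RateTables:
    """All taxon-specific rate inputs, loaded from editable CSV tables."""

    coral: pd.DataFrame          # genus x morphology growth / density / geometry
    parrotfish: pd.DataFrame     # group x size class feeding and scar parameters
    length_weight: pd.DataFrame  # species a, b, functional group
    urchin: pd.DataFrame         # species x test-size class -> kg ind-1 yr-1
    endolithic: EndolithicRates = field(default_factory=EndolithicRates)
    cca_rate: float = 0.0105     # kg m-2 yr-1 per percent CCA intercept cover
    other_coral_genus: str = "OtherCoral"  # fallback genus for unrated taxa
    min_eroding_length_cm: float = 10.0

    def validate(self) -> None:
        c = self.coral
        bad = c[(c["growth_lo95_cm_yr"] > c["growth_mean_cm_yr"])
                | (c["growth_mean_cm_yr"] > c["growth_hi95_cm_yr"])]
        if len(bad):
            raise ValidationError(
                f"coral growth CI must bracket the mean; offending rows: {list(bad.index)}")
        if (c["density_g_cm3"] <= 0).any():
            raise ValidationError("skeletal density must be positive")
        if (c["geometry_multiplier"] < 0).any():
            raise ValidationError("geometry multiplier must be >= 0")
        p = self.parrotfish
        if ((p["scar_fraction"] < 0) | (p["scar_fraction"] > 1)).any():
            raise ValidationError("scar_fraction must lie in [0, 1]")
        rate_cols = ["bite_rate_h", "feeding_hours", "scar_volume_cm3",
                     "substrate_density_g_cm3"]
        if (p[rate_cols] < 0).any().any():
            raise ValidationError("parrotfish rates must be non-negative")
        lw = self.length_weight
        if ((lw["a"] <= 0) | (lw["b"] <= 0)).any():
            raise ValidationError("length-weight constants must be positive")
        if not set(lw["group"]).issubset(FUNCTIONAL_GROUPS):
            raise ValidationError("unknown functional group in length-weight table")


def _data_path(name: str) -> Path:
    return Path(str(importlib.resources.files("reefcarb") / "data" / name))


def load_default_rates() -> RateTables:
    """Load the packaged default rate tables.

    These are synthetic stand-in values (see each table's ``provenance``
    column) with realistic magnitudes; studies with calibrated regional
    rates should replace them.
    """
    rt = RateTables(
        coral=pd.read_csv(_data_path("coral_rates.csv")),
        parrotfish=pd.read_csv(_data_path("parrotfish_rates.csv")),
        length_weight=pd.read_csv(_data_path("length_weight.csv")),
        urchin=pd.read_csv(_data_path("urchin_rates.csv")),
    )
    rt.validate()
    return rt


# ---------------------------------------------------------------------------
# survey dataset
# ---------------------------------------------------------------------------

@dataclass
class SurveyDataset:
    """The five census tables of one survey panel, keyed on (reef_id, year, site_id)."""

    sites: pd.DataFrame
    benthic: pd.DataFrame
    intercepts: pd.DataFrame
    fish: pd.DataFrame
    urchins: pd.DataFrame

    # -- validation ---------------------------------------------------------

    def validate(self, cover_sum_tolerance: float = 1e-6) -> None:
        """Raise on the first invariant violation, naming offending rows."""
        for name in SCHEMAS:
            df = getattr(self, name)
            missing = [c for c in SCHEMAS[name] if c not in df.columns]
            if missing:
                raise SchemaError(f"table {name!r} missing columns {missing}")

        s = self.sites
        _check(s, "sites", (s["depth_m"] > 0), "depth_m must be > 0")
        _check(s, "sites", s["rugosity_class"].between(0, 5),
               "rugosity_class must lie in [0, 5]")
        _check(s, "sites", s["year"].isin(SURVEY_YEARS),
               f"year must be one of {SURVEY_YEARS}")
        _check(s, "sites", s["habitat"].isin(HABITATS),
               f"habitat must be one of {HABITATS}")
        _check(s, "sites", s["regime_status"].isin(REGIME_STATUSES),
               f"regime_status must be one of {REGIME_STATUSES}")
        if s.duplicated(KEY).any():
            dup = s.loc[s.duplicated(KEY), KEY]
            raise ValidationError(f"duplicate site keys: {dup.values.tolist()}")

        b = self.benthic
        for col in COVER_COLUMNS:
            _check(b, "benthic", b[col].between(0, 100),
                   f"{col} must lie in [0, 100]")
        total = b[COVER_COLUMNS].sum(axis=1)
        _check(b, "benthic", total <= 100 + cover_sum_tolerance,
               "summed covers exceed 100%")

        i = self.intercepts
        if len(i):
            _check(i, "intercepts", i["linear_length_cm"] > 0,
                   "linear_length_cm must be > 0")
            _check(i, "intercepts",
                   i["linear_length_cm"] <= i["surface_length_cm"] + 1e-9,
                   "linear length cannot exceed surface length")
            _check(i, "intercepts", i["morphology"].isin(MORPHOLOGIES),
                   f"morphology must be one of {MORPHOLOGIES}")
            _check(i, "intercepts", i["transect_length_cm"] > 0,
                   "transect_length_cm must be > 0")

        f = self.fish
        if len(f):
            _check(f, "fish", f["total_length_cm"] > 0,
                   "total_length_cm must be > 0")
            _check(f, "fish", f["count"] >= 1, "count must be >= 1")

        u = self.urchins
        if len(u):
            _check(u, "urchins", u["test_size_cm"] > 0,
                   "test_size_cm must be > 0")
            _check(u, "urchins", u["belt_area_m2"] > 0,
                   "belt_area_m2 must be > 0")

        # record tables must not reference unknown sites
        site_keys = set(map(tuple, s[KEY].itertuples(index=False)))
        for name in ("benthic", "intercepts", "fish", "urchins"):
            df = getattr(self, name)
            if not len(df):
                continue
            keys = set(map(tuple, df[KEY].itertuples(index=False)))
            orphans = keys - site_keys
            if orphans:
                raise ValidationError(
                    f"table {name!r} references unknown sites: {sorted(orphans)[:5]}")

    def summary(self) -> dict:
        return {name: int(len(getattr(self, name))) for name in SCHEMAS} | {
            "n_reefs": int(self.sites["reef_id"].nunique()),
            "years": sorted(int(y) for y in self.sites["year"].unique()),
        }

    # -- IO -----------------------------------------------------------------

    def write(self, directory: str | Path) -> dict[str, Path]:
        """Write the five tables as CSV into ``directory`` (created if absent)."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        paths = {}
        for name in SCHEMAS:
            p = directory / f"{name}.csv"
            df = getattr(self, name)
            df.to_csv(p, index=False, float_format="%.10g")
            paths[name] = p
        return paths

    @classmethod
    def read(cls, directory: str | Path, validate: bool = True) -> "SurveyDataset":
        directory = Path(directory)
        tables = {}
        for name in SCHEMAS:
            p = directory / f"{name}.csv"
            if not p.exists():
                raise FileNotFoundError(f"expected census table {p}")
            tables[name] = pd.read_csv(p)
        ds = cls(**tables)
        if validate:
            ds.validate()
        return ds

    def subset_year(self, year: int) -> "SurveyDataset":
        return SurveyDataset(*(getattr(self, n)[getattr(self, n)["year"] == year]
                               .reset_index(drop=True) for n in SCHEMAS))


def _check(df: pd.DataFrame, table: str, ok: pd.Series, message: str) -> None:
    if not ok.all():
        rows = list(df.index[~ok][:10])
        raise ValidationError(f"{table}: {message}; offending rows {rows}")


def read_survey(directory: str | Path) -> SurveyDataset:
    """Read and validate a census dataset from a directory of CSV tables."""
    return SurveyDataset.read(directory, validate=True)
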