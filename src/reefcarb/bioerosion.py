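"""Gross bioerosion from parrotfish, urchin and endolithic agents.

All components are reported as positive magnitudes in kg CaCO3 m-2 yr-1;
the sign convention (erosion subtracts) is applied only at net-budget
assembly.  Urchin erosion is computed but excluded from totals by default:
in the study system urchins are too rare to move the budget balance and
were not censused consistently across years, so between-year comparisons
must not depend on them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from reefcarb.census import (
    KEY,
    EndolithicRates,
    LookupError_,
    RateTables,
    SurveyDataset,
    attach_fish_biomass,
    point_count_area,
)

log = logging.getLogger(__name__)

#: benthic categories whose summed cover is substrate accessible to borers
DEFAULT_ACCESSIBLE_CATEGORIES = ("cover_rock", "cover_rubble", "cover_cca")


@dataclass
class ErosionResult:
    """Gross erosion at one site-year, by agent (positive magnitudes)."""

    site_key: tuple
    parrotfish_erosion: float
    urchin_erosion: float
    endolithic_erosion: float
    include_urchins: bool = False

    @property
    def total(self) -> float:
        t = self.parrotfish_erosion + self.endolithic_erosion
        if self.include_urchins:
            t += self.urchin_erosion
        return t


def parrotfish_individual_erosion(length_cm: float,
                                  functional_group: str,
                                  rates: RateTables) -> float:
    """Substrate removed by one fish, kg CaCO3 yr-1.

    Browsers feed on macroalgae and erode negligibly: they contribute 0 by
    definition.  Fish below the smallest rated size class (and below
    ``rates.min_eroding_length_cm``) contribute 0 and are logged.
    """
    if functional_group == "browser":
        return 0.0
    if length_cm < rates.min_eroding_length_cm:
        log.debug("fish of %.1f cm below minimum eroding length; contributes 0",
                  length_cm)
        return 0.0
    tbl = rates.parrotfish
    hit = tbl[(tbl["species_or_group"] == functional_group)
              & (tbl["size_min_cm"] <= length_cm)
              & (length_cm < tbl["size_max_cm"])]
    if hit.empty:
        in_group = tbl[tbl["species_or_group"] == functional_group]
        if in_group.empty:
            raise LookupError_(
                f"no parrotfish rate entries for group {functional_group!r}")
        if length_cm < in_group["size_min_cm"].min():
            log.debug("fish of %.1f cm below smallest rated size class; 0",
                      length_cm)
            return 0.0
        # above the largest class: use the largest class's rates
        hit = in_group[in_group["size_max_cm"] == in_group["size_max_cm"].max()]
    r = hit.iloc[0]
    return float(r["bite_rate_h"] * r["feeding_hours"] * 365.0
                 * r["scar_fraction"] * r["scar_volume_cm3"]
                 * r["substrate_density_g_cm3"] * 1e-3)


def individual_erosion_rates(fish: pd.DataFrame, rates: RateTables) -> np.ndarray:
    """Vectorized per-individual erosion (kg yr-1) for a fish record table.

    Same contract as :func:`parrotfish_individual_erosion`, applied
    column-wise via size-class binning per functional group.
    """
    L = fish["total_length_cm"].to_numpy(float)
    group = fish["functional_group"].to_numpy()
    out = np.zeros(len(fish))
    tbl = rates.parrotfish
    for g in pd.unique(group):
        if g == "browser":
            continue
        sub = (tbl[tbl["species_or_group"] == g]
               .sort_values("size_min_cm").reset_index(drop=True))
        if sub.empty:
            raise LookupError_(f"no parrotfish rate entries for group {g!r}")
        mask = group == g
        per_class = (sub["bite_rate_h"] * sub["feeding_hours"] * 365.0
                     * sub["scar_fraction"] * sub["scar_volume_cm3"]
                     * sub["substrate_density_g_cm3"] * 1e-3).to_numpy()
        edges = sub["size_min_cm"].to_numpy(float)
        idx = np.searchsorted(edges, L[mask], side="right") - 1
        vals = np.where(idx < 0, 0.0, per_class[np.clip(idx, 0, None)])
        # above the largest class: the largest class's rate (idx already last)
        vals = np.where(L[mask] < rates.min_eroding_length_cm, 0.0, vals)
        out[mask] = vals
    return out


def site_parrotfish_erosion(fish: pd.DataFrame,
                            rates: RateTables,
                            area_m2: float | None = None) -> float:
    """Parrotfish erosion over one point count, kg CaCO3 m-2 yr-1.

    ``fish`` must carry a ``functional_group`` column (see
    :func:`reefcarb.census.attach_fish_biomass`).
    """
    if area_m2 is None:
        area_m2 = point_count_area()
    if area_m2 <= 0:
        raise ValueError("census area must be positive")
    total = 0.0
    for rec in fish.itertuples(index=False):
        total += rec.count * parrotfish_individual_erosion(
            rec.total_length_cm, rec.functional_group, rates)
    return total / area_m2


def urchin_erosion(urchins: pd.DataFrame, rates: RateTables) -> float:
    """Urchin erosion over the belt transect, kg CaCO3 m-2 yr-1."""
    if not len(urchins):
        return 0.0
    tbl = rates.urchin
    total = 0.0
    area = float(urchins["belt_area_m2"].iloc[0])
    for rec in urchins.itertuples(index=False):
        hit = tbl[(tbl["species"] == rec.species)
                  & (tbl["test_min_cm"] <= rec.test_size_cm)
                  & (rec.test_size_cm < tbl["test_max_cm"])]
        if hit.empty:
            raise LookupError_(
                f"no urchin rate for {rec.species!r} at test size "
                f"{rec.test_size_cm} cm")
        total += rec.count * float(hit["erosion_kg_ind_yr"].iloc[0])
    return total / area


def endolithic_erosion(benthic_row: pd.Series,
                       rugosity_class: int,
                       rates: EndolithicRates,
                       accessible_categories: tuple[str, ...] = DEFAULT_ACCESSIBLE_CATEGORIES
                       ) -> float:
    """Micro- + macro-borer erosion, kg CaCO3 m-2 yr-1.

    Scales the combined boring rate by the fraction of the benthos that is
    bare carbonate substrate (rock + rubble + CCA by default) and by the
    linear rugosity multiplier for the site's visual rugosity class.
    """
    accessible = float(sum(benthic_row[c] for c in accessible_categories)) / 100.0
    return ((rates.micro_rate + rates.macro_rate)
            * accessible * rates.multiplier(rugosity_class))


def site_erosion(site_row: pd.Series,
                 benthic_row: pd.Series,
                 fish: pd.DataFrame,
                 urchins: pd.DataFrame,
                 rates: RateTables,
                 area_m2: float | None = None,
                 include_urchins: bool = False) -> ErosionResult:
    """All erosion components for one site-year."""
    key = (site_row["reef_id"], site_row["year"], site_row["site_id"])
    return ErosionResult(
        site_key=key,
        parrotfish_erosion=site_parrotfish_erosion(fish, rates, area_m2),
        urchin_erosion=urchin_erosion(urchins, rates),
        endolithic_erosion=endolithic_erosion(
            benthic_row, int(site_row["rugosity_class"]), rates.endolithic),
        include_urchins=include_urchins,
    )


def erosion_by_site(dataset: SurveyDataset,
                    rates: RateTables,
                    area_m2: float | None = None,
                    include_urchins: bool = False) -> pd.DataFrame:
    """Erosion components for every site in the dataset (tidy, one row per site-year)."""
    if area_m2 is None:
        area_m2 = point_count_area()
    fish = attach_fish_biomass(dataset.fish, rates.length_weight) \
        if len(dataset.fish) else dataset.fish.assign(functional_group=[], biomass_g=[])

    # vectorized parrotfish erosion: per-record individual rate via size-class join
    if len(fish):
        per_ind = individual_erosion_rates(fish, rates)
        pf = (fish.assign(erosion=fish["count"].to_numpy(float) * per_ind)
              .groupby(KEY, sort=True)["erosion"].sum() / area_m2)
    else:
        pf = pd.Series(dtype=float)

    urch = {}
    for key, grp in dataset.urchins.groupby(KEY, sort=True):
        urch[key] = urchin_erosion(grp, rates)

    out = (dataset.sites.sort_values(KEY)
           .merge(dataset.benthic, on=KEY, validate="1:1")
           .reset_index(drop=True))
    endo_rates = rates.endolithic
    accessible = sum(out[c] for c in DEFAULT_ACCESSIBLE_CATEGORIES) / 100.0
    mult = out["rugosity_class"].astype(int).map(endo_rates.rugosity_map)
    if mult.isna().any():
        bad = sorted(out.loc[mult.isna(), "rugosity_class"].unique())
        raise ValueError(f"no rugosity multiplier configured for classes {bad}")
    keys = list(map(tuple, out[KEY].itertuples(index=False)))
    out["parrotfish_erosion"] = [float(pf.get(k, 0.0)) for k in keys]
    out["urchin_erosion"] = [float(urch.get(k, 0.0)) for k in keys]
    out["endolithic_erosion"] = ((endo_rates.micro_rate + endo_rates.macro_rate)
                                 * accessible * mult.to_numpy(float))
    out["erosion"] = (out["parrotfish_erosion"] + out["endolithic_erosion"]
                      + (out["urchin_erosion"] if include_urchins else 0.0))
    return out[KEY + ["parrotfish_erosion", "urchin_erosion",
                      "endolithic_erosion", "erosion"]]
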