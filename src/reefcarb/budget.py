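"""Net carbonate budgets, the reef x year trajectory panel, and the
growth-rate sensitivity analysis.

The net budget of a site is gross production minus gross bioerosion
(kg CaCO3 m-2 yr-1).  A site or reef is in the *positive* budget state only
when net G is strictly greater than zero: a reef producing exactly as much
carbonate as it loses is not accreting.

For the census year the production side comes from the line-intercept
engine; for visual-estimate years it is hindcast from morphology covers via
the through-origin regression fitted on the census year.  Erosion comes
from the fish census in every year.  Urchins are excluded from trajectory
totals by default (see :mod:`reefcarb.bioerosion`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from reefcarb.census import (
    KEY,
    COVER_COLUMNS,
    RateTables,
    SurveyDataset,
    ValidationError,
    attach_fish_biomass,
    group_biomass_kg_ha,
)
from reefcarb.bioerosion import erosion_by_site
from reefcarb.production import (
    HindcastModel,
    build_hindcast_pairs,
    fit_hindcast,
    hindcast_production,
    production_by_site,
    production_loadings,
)


@dataclass(frozen=True)
class BudgetComponents:
    """Net budget for one site-year."""

    site_key: tuple
    gross_production: float
    gross_erosion: float
    net_G: float
    state: str           # "positive" | "negative"
    rate_variant: str = "mean"


def classify_state(net_G: float) -> str:
    """Strict-sign classification: net G must exceed zero to count as accreting."""
    return "positive" if net_G > 0 else "negative"


def net_budget(production: float, erosion: float,
               site_key: tuple = (), rate_variant: str = "mean") -> BudgetComponents:
    """Assemble one site's net budget from gross production and gross erosion."""
    net = production - erosion
    return BudgetComponents(site_key, float(production), float(erosion),
                            float(net), classify_state(net), rate_variant)


def budget_by_site(dataset: SurveyDataset, rates: RateTables,
                   which_rate="mean", include_urchins: bool = False,
                   year: int | None = None) -> pd.DataFrame:
    """Census-based site budgets (production engine + erosion engine)."""
    prod = production_by_site(dataset, rates, which_rate, year=year)
    eros = erosion_by_site(dataset, rates, include_urchins=include_urchins)
    if year is not None:
        eros = eros[eros["year"] == year]
    out = prod.merge(eros, on=KEY, how="inner", validate="1:1")
    if len(out) != len(prod):
        missing = set(map(tuple, prod[KEY].itertuples(index=False))) - \
            set(map(tuple, out[KEY].itertuples(index=False)))
        raise ValidationError(f"no erosion inputs for sites {sorted(missing)[:5]}")
    out["net_G"] = out["production"] - out["erosion"]
    out["state"] = np.where(out["net_G"] > 0, "positive", "negative")
    out["rate_variant"] = which_rate if isinstance(which_rate, str) else "custom"
    return out


# ---------------------------------------------------------------------------
# trajectory panel
# ---------------------------------------------------------------------------

@dataclass
class TrajectoryPanel:
    """Site- and reef-level budget trajectories across survey years."""

    sites: pd.DataFrame        # one row per site-year
    reefs: pd.DataFrame        # one row per reef-year (means over sites)
    hindcast: HindcastModel
    census_year: int = 2014

    def positive_reef_counts(self) -> pd.Series:
        """Number of reefs whose mean net G is strictly positive, per year."""
        ok = self.reefs.dropna(subset=["net_G"])
        return (ok.assign(pos=ok["net_G"] > 0)
                  .groupby("year")["pos"].sum().astype(int))


def site_budget_trajectories(dataset: SurveyDataset, rates: RateTables,
                             hindcast: HindcastModel,
                             which_rate="mean",
                             census_year: int = 2014,
                             include_urchins: bool = False) -> pd.DataFrame:
    """Per-site-year net budgets: census production in the census year,
    hindcast production elsewhere, erosion from the fish census throughout."""
    eros = erosion_by_site(dataset, rates, include_urchins=include_urchins)

    benthic = dataset.benthic.sort_values(KEY).reset_index(drop=True)
    pred = hindcast_production(benthic, hindcast)
    prod = benthic[KEY].assign(production=pred, production_source="hindcast")

    census = production_by_site(dataset, rates, which_rate, year=census_year)
    census = census[KEY + ["production"]].assign(production_source="census")
    prod = (pd.concat([census,
                       prod[~prod.set_index(KEY).index.isin(
                           census.set_index(KEY).index)]])
            .sort_values(KEY).reset_index(drop=True))

    out = prod.merge(eros, on=KEY, how="inner", validate="1:1")
    out["net_G"] = out["production"] - out["erosion"]
    out["state"] = np.where(out["net_G"] > 0, "positive", "negative")
    return out


def build_trajectory_panel(dataset: SurveyDataset, rates: RateTables,
                           hindcast: HindcastModel | None = None,
                           which_rate="mean",
                           census_year: int = 2014,
                           include_urchins: bool = False) -> TrajectoryPanel:
    """Assemble the reef x year panel of budgets, covers and fish biomasses.

    Reefs missing a survey year keep a flagged (all-NaN) row rather than
    being dropped, so panel shape is stable across inputs.
    """
    if hindcast is None:
        pairs = build_hindcast_pairs(dataset, rates, which_rate, year=census_year)
        hindcast = fit_hindcast(pairs)

    sites = site_budget_trajectories(dataset, rates, hindcast, which_rate,
                                     census_year, include_urchins)
    fish = attach_fish_biomass(dataset.fish, rates.length_weight)
    groups = group_biomass_kg_ha(fish)
    full = (sites
            .merge(dataset.sites, on=KEY, how="left", validate="1:1")
            .merge(dataset.benthic, on=KEY, how="left", validate="1:1")
            .merge(groups, on=KEY, how="left", validate="1:1"))
    for c in ("browser_kg_ha", "scraper_kg_ha", "excavator_kg_ha"):
        full[c] = full[c].fillna(0.0)

    num_cols = (["production", "erosion", "parrotfish_erosion",
                 "endolithic_erosion", "urchin_erosion", "net_G",
                 "depth_m", "rugosity_class", "wave_exposure_jm3"]
                + COVER_COLUMNS
                + ["browser_kg_ha", "scraper_kg_ha", "excavator_kg_ha"])
    agg = (full.groupby(["reef_id", "year"], sort=True)
           .agg(**{c: (c, "mean") for c in num_cols},
                n_sites=("site_id", "nunique"),
                n_positive_sites=("state", lambda s: int((s == "positive").sum())),
                regime_status=("regime_status", "first"),
                habitat=("habitat", "first"),
                reserve=("reserve", "first"))
           .reset_index())

    # flag reef-years absent from the survey instead of dropping them
    years = sorted(full["year"].unique())
    grid = pd.MultiIndex.from_product(
        [sorted(full["reef_id"].unique()), years], names=["reef_id", "year"])
    agg = agg.set_index(["reef_id", "year"]).reindex(grid).reset_index()
    agg["surveyed"] = agg["n_sites"].notna()
    agg["net_state"] = np.where(agg["net_G"] > 0, "positive", "negative")
    agg.loc[~agg["surveyed"], "net_state"] = "missing"
    return TrajectoryPanel(sites=full, reefs=agg, hindcast=hindcast,
                           census_year=census_year)


# ---------------------------------------------------------------------------
# growth-rate sensitivity
# ---------------------------------------------------------------------------

@dataclass
class SensitivityDistribution:
    """Census-year budgets under growth-rate uncertainty.

    ``endpoint`` holds the lo95 / mean / hi95 site budgets;
    ``draws`` the per-site net G for every permutation draw (sites x n);
    ``hindcast_coefs`` the refitted through-origin coefficients per draw.
    """

    site_keys: pd.DataFrame
    endpoint: pd.DataFrame               # columns lo95, mean, hi95 (net G)
    draws: np.ndarray = field(repr=False)
    hindcast_coefs: pd.DataFrame = field(repr=False)
    n_permutations: int = 9999
    seed: int = 0
    mode: str = "rates"

    def reef_summary(self) -> pd.DataFrame:
        """Per-reef mean net G across draws and the fraction of draws positive."""
        reef = self.site_keys["reef_id"].to_numpy()
        df = pd.DataFrame(self.draws)
        df["reef_id"] = reef
        means = df.groupby("reef_id", sort=True).mean()
        frac_pos = (means > 0).mean(axis=1)
        out = pd.DataFrame({
            "reef_id": means.index,
            "mean_net_G": means.mean(axis=1).to_numpy(),
            "frac_draws_positive": frac_pos.to_numpy(),
        })
        for v in ("lo95", "mean", "hi95"):
            e = pd.DataFrame({"reef_id": reef, "g": self.endpoint[v].to_numpy()})
            out[f"net_G_{v}"] = e.groupby("reef_id", sort=True)["g"].mean().to_numpy()
        return out

    def positive_reef_counts(self) -> dict[str, int]:
        s = self.reef_summary()
        return {v: int((s[f"net_G_{v}"] > 0).sum())
                for v in ("lo95", "mean", "hi95")}


def sensitivity_analysis(dataset: SurveyDataset, rates: RateTables,
                         n: int = 9999, seed: int = 0,
                         census_year: int = 2014,
                         include_urchins: bool = False,
                         mode: str = "rates") -> SensitivityDistribution:
    """Propagate coral growth-rate uncertainty into census-year budgets.

    mode="rates" (default): each draw samples every coral rate-table row's
    growth rate independently and uniformly within its 95% CI, then
    recomputes all site budgets and refits the hindcast regression.
    mode="sites": each draw resamples sites with replacement within reefs
    at mean growth rates (a nonparametric alternative).
    """
    coral = rates.coral.reset_index(drop=True)
    if (coral["growth_lo95_cm_yr"] > coral["growth_hi95_cm_yr"]).any():
        raise ValidationError("coral rate table has lo95 > hi95")

    site_keys, L, _ = production_loadings(dataset, rates, year=census_year)
    eros = erosion_by_site(dataset, rates, include_urchins=include_urchins)
    eros = eros[eros["year"] == census_year]
    eros = site_keys.merge(eros, on=KEY, validate="1:1")["erosion"].to_numpy()
    # CCA production is growth-rate independent; add it back per site
    cca = (site_keys.merge(production_by_site(dataset, rates, "mean",
                                              year=census_year),
                           on=KEY, how="left", validate="1:1")
           ["cca_production"].fillna(0.0).to_numpy())

    lo = coral["growth_lo95_cm_yr"].to_numpy(float)
    mid = coral["growth_mean_cm_yr"].to_numpy(float)
    hi = coral["growth_hi95_cm_yr"].to_numpy(float)
    endpoint = pd.DataFrame({v: L @ g + cca - eros
                             for v, g in (("lo95", lo), ("mean", mid), ("hi95", hi))})

    benthic = dataset.benthic[dataset.benthic["year"] == census_year]
    X = (site_keys.merge(benthic, on=KEY, validate="1:1")
         [[f"cover_{m}" for m in ("branching", "encrusting", "massive", "table")]]
         .to_numpy(float))
    Xpinv = np.linalg.pinv(X)

    rng = np.random.default_rng(seed)
    if mode == "rates":
        G = rng.uniform(lo[:, None], hi[:, None], size=(len(coral), n))
        prod_draws = L @ G + cca[:, None]          # sites x n
        draws = prod_draws - eros[:, None]
        coefs = (Xpinv @ prod_draws).T             # n x 4
    elif mode == "sites":
        prod_mean = L @ mid + cca
        net_mean = prod_mean - eros
        reef = site_keys["reef_id"].to_numpy()
        draws = np.empty((len(site_keys), n))
        for j in range(n):
            idx = np.concatenate([
                rng.choice(np.flatnonzero(reef == r),
                           size=(reef == r).sum(), replace=True)
                for r in pd.unique(reef)])
            draws[:, j] = net_mean[idx]
        coefs = (Xpinv @ (draws + eros[:, None])).T
    else:
        raise ValueError(f"unknown sensitivity mode {mode!r}")

    coef_df = pd.DataFrame(
        coefs, columns=[f"beta_{m}" for m in
                        ("branching", "encrusting", "massive", "table")])
    return SensitivityDistribution(site_keys=site_keys, endpoint=endpoint,
                                   draws=draws, hindcast_coefs=coef_df,
                                   n_permutations=n, seed=seed, mode=mode)
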