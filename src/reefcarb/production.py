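"""Gross carbonate production from line-intercept census, and its hindcast.

The census engine converts each colony intercepted by a 10 m line transect
into an annual carbonate production contribution from its rugose (surface)
intercept length, the genus-specific linear extension rate (cm yr-1) and
skeletal density (g cm-3), and a dimensionless geometry multiplier:

    G_colony = 10 * growth * density * (surface_length / transect_length) * r

The factor 10 converts g cm-2 yr-1 into kg CaCO3 m-2 yr-1.  Site production
is the sum over colonies; crustose coralline algae (CCA) contribute through
their own rate entry.

For survey years with visual cover estimates only, production is hindcast
from a multiple regression of census production on the cover of the four
coral morphology classes, fitted *through the origin* on the paired census
year: with no coral there is no coral carbonate production.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from reefcarb.census import (
    KEY,
    HINDCAST_MORPHOLOGIES,
    LookupError_,
    RateTables,
    SurveyDataset,
    ValidationError,
)

log = logging.getLogger(__name__)

RATE_VARIANTS = ("lo95", "mean", "hi95")
_GROWTH_COL = {"lo95": "growth_lo95_cm_yr",
               "mean": "growth_mean_cm_yr",
               "hi95": "growth_hi95_cm_yr"}

#: genus identifier reserved for crustose coralline algae intercept records
CCA_GENUS = "CCA"


def colony_production(surface_length_cm: float,
                      transect_length_cm: float,
                      growth_cm_yr: float,
                      density_g_cm3: float,
                      geometry_multiplier: float = 1.0) -> float:
    """Annual production of one colony, kg CaCO3 m-2 yr-1 of transect."""
    if transect_length_cm <= 0:
        raise ValueError("transect length must be positive")
    if surface_length_cm < 0:
        raise ValueError("surface length cannot be negative")
    return float(10.0 * growth_cm_yr * density_g_cm3
                 * (surface_length_cm / transect_length_cm)
                 * geometry_multiplier)


@dataclass
class ProductionResult:
    """Gross production at one site-year, with the per-colony breakdown."""

    site_key: tuple
    coral_production: float          # kg CaCO3 m-2 yr-1
    cca_production: float            # kg CaCO3 m-2 yr-1
    per_colony: pd.DataFrame = field(repr=False, default=None)
    no_census: bool = False          # True when the site has no intercept data

    @property
    def total(self) -> float:
        return self.coral_production + self.cca_production


def _growth_vector(coral: pd.DataFrame, which_rate) -> np.ndarray:
    """Growth rates per rate-table row; which_rate is a variant name or an
    explicit array of per-row rates (used by the sensitivity permutations)."""
    if isinstance(which_rate, str):
        if which_rate not in RATE_VARIANTS:
            raise ValueError(f"unknown rate variant {which_rate!r}")
        return coral[_GROWTH_COL[which_rate]].to_numpy(float)
    arr = np.asarray(which_rate, float)
    if arr.shape != (len(coral),):
        raise ValueError("explicit growth vector length must match rate table")
    return arr


def _match_rate_rows(intercepts: pd.DataFrame, rates: RateTables) -> np.ndarray:
    """Index into the coral rate table for every intercept record.

    Unknown genus x morphology combinations fall back to the configured
    "other coral" entry (logged); if no fallback exists, raise.
    """
    coral = rates.coral.reset_index(drop=True)
    idx = {(g, m): i for i, (g, m) in
           enumerate(zip(coral["genus"], coral["morphology"]))}
    fallback = None
    for i, (g, m) in enumerate(zip(coral["genus"], coral["morphology"])):
        if g == rates.other_coral_genus:
            fallback = i
            break
    out = np.empty(len(intercepts), dtype=int)
    missing = []
    for j, (g, m) in enumerate(zip(intercepts["genus"], intercepts["morphology"])):
        k = idx.get((g, m))
        if k is None:
            if fallback is None:
                missing.append((g, m))
                continue
            log.warning("no rate entry for %s/%s; using %s fallback",
                        g, m, rates.other_coral_genus)
            k = fallback
        out[j] = k
    if missing:
        raise LookupError_(
            f"no rate entry (and no fallback) for genus/morphology: {sorted(set(missing))}")
    return out


def transect_production(intercepts: pd.DataFrame,
                        rates: RateTables,
                        which_rate="mean") -> ProductionResult:
    """Gross production for one site's line-intercept census.

    ``intercepts`` holds the colony records of a single site-year; rows with
    genus equal to :data:`CCA_GENUS` are treated as crustose coralline algae
    and contribute via ``rates.cca_rate`` (kg m-2 yr-1 per percent planar
    cover) rather than the coral rate table.
    """
    key = _single_site_key(intercepts)
    if not len(intercepts):
        return ProductionResult(key, np.nan, np.nan, None, no_census=True)

    is_cca = (intercepts["genus"] == CCA_GENUS).to_numpy()
    coral_rows = intercepts.loc[~is_cca].reset_index(drop=True)
    cca_rows = intercepts.loc[is_cca]

    coral = rates.coral.reset_index(drop=True)
    growth = _growth_vector(coral, which_rate)
    if len(coral_rows):
        rate_idx = _match_rate_rows(coral_rows, rates)
        contrib = (10.0 * growth[rate_idx]
                   * coral.loc[rate_idx, "density_g_cm3"].to_numpy(float)
                   * coral.loc[rate_idx, "geometry_multiplier"].to_numpy(float)
                   * coral_rows["surface_length_cm"].to_numpy(float)
                   / coral_rows["transect_length_cm"].to_numpy(float))
        per_colony = coral_rows.assign(production_kg_m2_yr=contrib)
        coral_g = float(contrib.sum())
    else:
        per_colony = coral_rows
        coral_g = 0.0

    cca_cover_pct = 0.0
    if len(cca_rows):
        cca_cover_pct = float((cca_rows["linear_length_cm"]
                               / cca_rows["transect_length_cm"]).sum() * 100.0)
    cca_g = rates.cca_rate * cca_cover_pct

    return ProductionResult(key, coral_g, cca_g, per_colony)


def _single_site_key(df: pd.DataFrame) -> tuple:
    if not len(df):
        return ()
    keys = df[KEY].drop_duplicates()
    if len(keys) > 1:
        raise ValueError("records from more than one site passed to a "
                         "single-transect operation")
    return tuple(keys.iloc[0])


def production_by_site(dataset: SurveyDataset,
                       rates: RateTables,
                       which_rate="mean",
                       year: int | None = None) -> pd.DataFrame:
    """Census production for every site that has intercept records.

    Returns one row per site-year with ``coral_production``,
    ``cca_production`` and ``production`` (their sum), kg CaCO3 m-2 yr-1.
    """
    site_keys, L, coral = production_loadings(dataset, rates, year=year)
    growth = _growth_vector(coral, which_rate)
    out = site_keys.copy()
    out["coral_production"] = L @ growth

    inter = dataset.intercepts
    if year is not None:
        inter = inter[inter["year"] == year]
    cca_rows = inter[inter["genus"] == CCA_GENUS]
    pct_of: dict[tuple, float] = {}
    if len(cca_rows):
        pct = (cca_rows.assign(pct=100.0 * cca_rows["linear_length_cm"]
                               / cca_rows["transect_length_cm"])
               .groupby(KEY)["pct"].sum() * rates.cca_rate)
        pct_of = {k: float(v) for k, v in pct.items()}
        # sites with only CCA records are absent from the loadings table
        only_cca = sorted(set(pct_of)
                          - set(map(tuple, out[KEY].itertuples(index=False))))
        if only_cca:
            extra = pd.DataFrame(only_cca, columns=KEY)
            extra["coral_production"] = 0.0
            out = pd.concat([out, extra], ignore_index=True)
    out["cca_production"] = [pct_of.get(k, 0.0)
                             for k in map(tuple, out[KEY].itertuples(index=False))]
    out["production"] = out["coral_production"] + out["cca_production"]
    return out.sort_values(KEY).reset_index(drop=True)


def production_loadings(dataset: SurveyDataset,
                        rates: RateTables,
                        year: int | None = None
                        ) -> tuple[pd.DataFrame, np.ndarray, pd.DataFrame]:
    """Factorize census production as  G = L @ growth.

    ``L[s, e]`` is the production at site ``s`` per unit growth rate of
    coral rate-table row ``e`` (i.e. 10 * density * geometry * intercept
    fraction, summed over that row's colonies).  The factorization lets the
    growth-rate sensitivity analysis evaluate thousands of growth-rate draws
    as a single matrix product.  CCA production is excluded (growth-rate
    uncertainty applies to corals).
    """
    inter = dataset.intercepts
    if year is not None:
        inter = inter[inter["year"] == year]
    inter = inter[inter["genus"] != CCA_GENUS].reset_index(drop=True)
    coral = rates.coral.reset_index(drop=True)
    site_keys = inter[KEY].drop_duplicates().sort_values(KEY).reset_index(drop=True)
    site_pos = {tuple(r): i for i, r in enumerate(site_keys.itertuples(index=False))}
    L = np.zeros((len(site_keys), len(coral)))
    rate_idx = _match_rate_rows(inter, rates)
    weights = (10.0 * coral.loc[rate_idx, "density_g_cm3"].to_numpy(float)
               * coral.loc[rate_idx, "geometry_multiplier"].to_numpy(float)
               * inter["surface_length_cm"].to_numpy(float)
               / inter["transect_length_cm"].to_numpy(float))
    rows = np.array([site_pos[tuple(r)] for r in inter[KEY].itertuples(index=False)])
    np.add.at(L, (rows, rate_idx), weights)
    return site_keys, L, coral


# ---------------------------------------------------------------------------
# hindcast regression
# ---------------------------------------------------------------------------

@dataclass
class HindcastModel:
    """Through-origin regression of census production on morphology covers.

    ``coef[m]`` is kg CaCO3 m-2 yr-1 per percent cover of morphology ``m``.
    """

    coef: dict[str, float]
    resid_se: float
    r2: float
    n_sites: int

    def __post_init__(self) -> None:
        if not all(np.isfinite(list(self.coef.values()))):
            raise ValidationError("hindcast coefficients must be finite")
        negative = [m for m, b in self.coef.items() if b < 0]
        if negative:
            log.warning("hindcast fitted negative coefficients for %s; "
                        "inspect the 2014 pairing", negative)


def fit_hindcast(pairs: pd.DataFrame,
                 production_col: str = "production",
                 morphologies: tuple[str, ...] = HINDCAST_MORPHOLOGIES
                 ) -> HindcastModel:
    """Fit the visual-cover -> production hindcast on paired census sites.

    ``pairs`` carries one row per site with the four morphology cover
    columns (percent) and the census production estimate.  The regression
    has no intercept: zero coral cover implies zero coral production.
    """
    cols = [f"cover_{m}" for m in morphologies]
    missing = [c for c in cols + [production_col] if c not in pairs.columns]
    if missing:
        raise ValueError(f"pairs table missing columns {missing}")
    X = pairs[cols].to_numpy(float)
    y = pairs[production_col].to_numpy(float)
    if len(pairs) < 2 * len(cols):
        raise ValueError(
            f"need at least {2 * len(cols)} sites to fit {len(cols)} covers, "
            f"got {len(pairs)}")
    rank = np.linalg.matrix_rank(X)
    if rank < len(cols):
        sd = X.std(axis=0)
        degenerate = [c for c, s in zip(cols, sd) if s == 0 and X[:, cols.index(c)].sum() == 0]
        raise np.linalg.LinAlgError(
            f"rank-deficient design (rank {rank} < {len(cols)}); "
            f"all-zero or collinear columns: {degenerate or 'collinear mix'}")
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    dof = max(len(y) - len(cols), 1)
    resid_se = float(np.sqrt(resid @ resid / dof))
    tss = float(y @ y)  # uncentred, as appropriate for a through-origin fit
    r2 = float(1.0 - (resid @ resid) / tss) if tss > 0 else np.nan
    return HindcastModel(coef=dict(zip(morphologies, map(float, beta))),
                         resid_se=resid_se, r2=r2, n_sites=len(pairs))


def hindcast_production(benthic: pd.DataFrame, model: HindcastModel) -> np.ndarray:
    """Predicted production (kg m-2 yr-1) from visual morphology covers."""
    cols = [f"cover_{m}" for m in model.coef]
    X = benthic[cols].to_numpy(float)
    if ((X < 0) | (X > 100)).any():
        raise ValidationError("cover values outside [0, 100]")
    beta = np.array(list(model.coef.values()))
    return X @ beta


def build_hindcast_pairs(dataset: SurveyDataset, rates: RateTables,
                         which_rate="mean", year: int = 2014) -> pd.DataFrame:
    """Pair census production with visual covers for the census year."""
    prod = production_by_site(dataset, rates, which_rate, year=year)
    benthic = dataset.benthic[dataset.benthic["year"] == year]
    pairs = prod.merge(benthic, on=KEY, how="inner", validate="1:1")
    if not len(pairs):
        raise ValueError(f"no paired census/visual sites in {year}")
    return pairs
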