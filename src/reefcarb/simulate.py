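"""Synthetic survey panels with known ground truth.

The generator emulates the statistical structure of a multi-decade
inner-island survey panel: 21 reefs split across three habitat types,
surveyed in 1994, 2005, 2008, 2011 and 2014 with 8-16 sites per reef, hit
by a >90%-mortality bleaching event between the first two surveys, after
which 12 reefs rebound toward coral dominance while 9 shift to a
macroalgae-dominated regime.  Within the recovered reefs a subset rebounds
only weakly (low massive coral, high excavator biomass) and ends the series
with a negative carbonate budget, reproducing the dissociation between
ecological and geomorphic recovery that the downstream classifiers are
meant to detect.

Everything downstream has ground truth: morphology covers are drawn at
reef level and observed with multiplicative site/visual noise; the coral
rate table is constructed so that census production is exactly
``sum_m beta_m * cover_m`` for a configurable ``true_beta``; fish are drawn
to hit per-site functional-group biomass targets; and the bleaching,
recovery and regime-shift signatures (massive coral, macroalgae, excavator
biomass) are encoded in the covariates so classifier-structure recovery can
be scored against the generating archetypes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from reefcarb.census import (
    DEFAULT_BELT_AREA_M2,
    DEFAULT_TRANSECT_CM,
    HINDCAST_MORPHOLOGIES,
    RateTables,
    SurveyDataset,
    load_default_rates,
    point_count_area,
)

YEARS = (1994, 2005, 2008, 2011, 2014)

#: rugose-surface-to-planar length factor of generated colonies, per morphology
SURFACE_FACTORS = {"branching": 2.0, "encrusting": 1.1,
                   "massive": 1.5, "table": 1.3}
#: skeletal densities used for the generated rate table, g cm-3
DENSITIES = {"branching": 1.5, "encrusting": 1.6, "massive": 1.8, "table": 1.4}
GENUS_OF = {"branching": "Acropora", "encrusting": "Montipora",
            "massive": "Porites", "table": "Acropora"}


@dataclass(frozen=True)
class GeneratorConfig:
    """Study-design parameters of the synthetic panel (defaults = the
    emulated survey conditions)."""

    n_reefs: int = 21
    n_recovered: int = 12            # remainder regime-shifted
    n_budget_recovered: int = 8      # recovered reefs that regain a positive budget
    years: tuple[int, ...] = YEARS
    sites_min: int = 8
    sites_max: int = 16
    true_beta: dict = field(default_factory=lambda: {
        "branching": 0.12, "encrusting": 0.02, "massive": 0.05, "table": 0.15})
    growth_ci_rel: float = 0.20      # half-width of growth 95% CI, relative
    bleach_mortality: float = 0.92   # coral cover fraction lost 1994 -> 2005
    noise_sd: float = 0.25           # site-level lognormal sigma on true covers
    visual_noise_sd: float = 0.10    # extra lognormal sigma on visual estimates
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.bleach_mortality <= 1):
            raise ValueError("bleach_mortality must lie in [0, 1]")
        if self.n_recovered > self.n_reefs:
            raise ValueError("n_recovered cannot exceed n_reefs")
        if self.n_budget_recovered > self.n_recovered:
            raise ValueError("n_budget_recovered cannot exceed n_recovered")
        if self.sites_min > self.sites_max or self.sites_min < 1:
            raise ValueError("invalid sites_per_reef range")


@dataclass
class GroundTruth:
    """Latent values behind one generated panel."""

    config: GeneratorConfig
    reef_table: pd.DataFrame         # archetypes and reef-level covariates
    site_covers: pd.DataFrame        # true (pre-noise-free observation) covers
    true_beta: dict
    rates: RateTables = field(repr=False)

    def true_site_production(self) -> pd.Series:
        """Production implied by true covers and the generating coefficients."""
        beta = self.true_beta
        c = self.site_covers
        return sum(beta[m] * c[f"cover_{m}"] for m in beta)


def coral_rates_for_beta(true_beta: dict, ci_rel: float = 0.20) -> pd.DataFrame:
    """Coral rate table whose engine arithmetic reproduces ``true_beta``.

    With colonies generated at surface factor s_m, production per percent
    planar cover is 0.1 * growth * density * geometry * s_m, so the growth
    rate is back-computed from the target coefficient.
    """
    rows = []
    for m, beta in true_beta.items():
        d, s = DENSITIES[m], SURFACE_FACTORS[m]
        g = beta / (0.1 * d * s)
        rows.append({"genus": GENUS_OF[m], "morphology": m,
                     "growth_mean_cm_yr": g,
                     "growth_lo95_cm_yr": g * (1 - ci_rel),
                     "growth_hi95_cm_yr": g * (1 + ci_rel),
                     "density_g_cm3": d, "geometry_multiplier": 1.0,
                     "provenance": "synthetic (constructed for true_beta)"})
    return pd.DataFrame(rows)


# trajectory multipliers on 1994 coral cover, per archetype and year
_REBOUND = {
    "budget_recovered": {1994: 1.0, 2005: None, 2008: 0.35, 2011: 0.70, 2014: 1.00},
    "eco_recovered":    {1994: 1.0, 2005: None, 2008: 0.20, 2011: 0.35, 2014: 0.50},
    "regime_shifted":   {1994: 1.0, 2005: None, 2008: 0.15, 2011: 0.18, 2014: 0.22},
}
# massive coral rebounds far less on the weakly recovering and shifted reefs
_MASSIVE_EXTRA = {"budget_recovered": 1.0, "eco_recovered": 0.15,
                  "regime_shifted": 0.10}

# excavator biomass growth multipliers on the reef's 1994 level
# (system-wide increase over time, weakest on the reefs that keep a
# positive budget)
_EXC_MULT = {
    "budget_recovered": {1994: 1.0, 2005: 1.3, 2008: 1.4, 2011: 1.5, 2014: 1.6},
    "eco_recovered":    {1994: 1.0, 2005: 1.6, 2008: 2.0, 2011: 2.4, 2014: 2.8},
    "regime_shifted":   {1994: 1.0, 2005: 1.5, 2008: 1.8, 2011: 2.2, 2014: 2.5},
}
_SCRAPER_RECOVERED = {1994: 20, 2005: 25, 2008: 35, 2011: 50, 2014: 60}
_SCRAPER_SHIFTED = {1994: 20, 2005: 21, 2008: 22, 2011: 25, 2014: 28}
# mean excavator/scraper total length, cm (size spectrum shifts up with time)
_MEAN_LENGTH = {1994: 16, 2005: 20, 2008: 23, 2011: 26, 2014: 28}

_MACROALGAE_SHIFTED = {1994: 3, 2005: 10, 2008: 20, 2011: 30, 2014: 35}

_EXC_SPECIES = ("Chlorurus sordidus", "Chlorurus strongylocephalus")
_SCR_SPECIES = ("Scarus ghobban", "Scarus frenatus",
                "Scarus rubroviolaceus", "Hipposcarus harid")
_BRW_SPECIES = ("Calotomus carolinus", "Leptoscarus vaigiensis")
_URCHIN_SPECIES = ("Echinometra mathaei", "Diadema setosum")


def generate_panel(config: GeneratorConfig = GeneratorConfig()
                   ) -> tuple[SurveyDataset, RateTables, GroundTruth]:
    """Generate one synthetic survey panel.

    Returns the dataset (five census tables), the coral/fish/urchin rate
    tables consistent with the generator's coefficients, and the ground
    truth needed to score parameter recovery.
    """
    rng = np.random.default_rng(config.seed)
    base = load_default_rates()
    rates = RateTables(coral=coral_rates_for_beta(config.true_beta,
                                                  config.growth_ci_rel),
                       parrotfish=base.parrotfish,
                       length_weight=base.length_weight,
                       urchin=base.urchin,
                       endolithic=base.endolithic,
                       other_coral_genus="__none__")
    lw = base.length_weight.set_index("species")

    reefs = _reef_archetypes(config, rng)
    area = point_count_area()

    sites_rows, benthic_rows, truth_rows = [], [], []
    fish_rows, intercept_rows, urchin_rows = [], [], []

    for reef in reefs.itertuples(index=False):
        n_sites = int(rng.integers(config.sites_min, config.sites_max + 1))
        for year in config.years:
            covers = _reef_year_covers(reef, year, config, rng)
            for s in range(n_sites):
                site_id = f"S{s + 1:02d}"
                key = {"reef_id": reef.reef_id, "year": year, "site_id": site_id}
                true_cov = {k: v * rng.lognormal(-config.noise_sd**2 / 2,
                                                 config.noise_sd)
                            if config.noise_sd > 0 else v
                            for k, v in covers.items()}
                true_cov = _cap_total(true_cov)
                coral_total = sum(true_cov[f"cover_{m}"]
                                  for m in HINDCAST_MORPHOLOGIES)
                rug = int(np.clip(round(coral_total / 7.0
                                        + rng.normal(0, 0.4)), 0, 5))
                sites_rows.append(key | {
                    "habitat": reef.habitat, "depth_m": reef.depth_m,
                    "rugosity_class": rug,
                    "wave_exposure_jm3": reef.wave_exposure_jm3,
                    "reserve": bool(reef.reserve),
                    "regime_status": reef.regime_status})
                visual = {k: v * rng.lognormal(-config.visual_noise_sd**2 / 2,
                                               config.visual_noise_sd)
                          if config.visual_noise_sd > 0 else v
                          for k, v in true_cov.items()}
                benthic_rows.append(key | _cap_total(visual))
                truth_rows.append(key | true_cov
                                  | {"archetype": reef.archetype})

                fish_rows += _site_fish(key, reef, year, config, lw, area, rng)
                if year == max(config.years):
                    intercept_rows += _site_intercepts(key, true_cov, rng)
                    urchin_rows += _site_urchins(key, rng)

    dataset = SurveyDataset(
        sites=pd.DataFrame(sites_rows),
        benthic=pd.DataFrame(benthic_rows),
        intercepts=pd.DataFrame(
            intercept_rows, columns=["reef_id", "year", "site_id", "genus",
                                     "morphology", "surface_length_cm",
                                     "linear_length_cm", "transect_length_cm"]),
        fish=pd.DataFrame(
            fish_rows, columns=["reef_id", "year", "site_id", "species",
                                "total_length_cm", "count"]),
        urchins=pd.DataFrame(
            urchin_rows, columns=["reef_id", "year", "site_id", "species",
                                  "test_size_cm", "count", "belt_area_m2"]),
    )
    truth = GroundTruth(config=config, reef_table=reefs,
                        site_covers=pd.DataFrame(truth_rows),
                        true_beta=dict(config.true_beta), rates=rates)
    return dataset, rates, truth


def _reef_archetypes(config: GeneratorConfig, rng: np.random.Generator
                     ) -> pd.DataFrame:
    """Reef-level covariates, then outcome archetypes.

    1994 covariates are drawn first with overlapping distributions; which
    recovered reefs also regain a positive *budget* is decided by a latent
    resilience score combining massive coral cover, macroalgae absence and
    (negatively) excavator biomass — so each driver carries partial, not
    individually sufficient, information about the census-year state.
    """
    n = config.n_reefs
    status = np.array(["recovered"] * config.n_recovered
                      + ["regime_shifted"] * (n - config.n_recovered))
    rng.shuffle(status)

    rows = []
    for i in range(n):
        shifted = status[i] == "regime_shifted"
        # regime-shifted reefs: lower pre-bleaching massive coral (hence
        # structural complexity) and more frequent macroalgae
        massive = rng.normal(3.8, 1.8) if shifted else rng.normal(5.5, 2.2)
        p_algae = 0.85 if shifted else 0.35
        macro94 = rng.uniform(1, 6) if rng.random() < p_algae else 0.0
        excav94 = float(np.clip(rng.normal(36, 5) if shifted
                                else rng.normal(31, 5), 18, 50))
        rows.append({
            "reef_id": f"R{i + 1:02d}",
            "habitat": ("carbonate", "granitic", "patch")[i % 3],
            "regime_status": status[i],
            # depth and exposure are recorded to field precision (0.5 m /
            # 0.05 J m-3), as survey metadata would be
            "depth_m": float(rng.integers(6, 21)) / 2.0,
            "wave_exposure_jm3": float(rng.integers(1, 9)) * 0.05,
            "reserve": bool(rng.random() < 0.3),
            "branching_1994": float(np.clip(rng.normal(20, 3.5), 12, 32)),
            "table_1994": float(np.clip(rng.normal(5, 1.5), 1, 10)),
            "encrusting_1994": float(np.clip(rng.normal(4, 1.2), 0.5, 8)),
            "massive_1994": float(np.clip(massive, 0.3, 16)),
            "macroalgae_1994": macro94,
            "excavator_1994_kg_ha": excav94,
            "sand": float(rng.uniform(5, 15)),
            "soft": float(rng.uniform(0, 4)),
            "biomass_factor": float(rng.lognormal(0, 0.12)),
        })
    reefs = pd.DataFrame(rows)

    # latent geomorphic-resilience score -> budget-recovery archetype
    rec = reefs[status == "recovered"]
    score = (1.0 * (rec["massive_1994"] - rec["massive_1994"].mean())
             / max(rec["massive_1994"].std(), 1e-9)
             + 2.0 * (rec["macroalgae_1994"] <= 0).astype(float)
             - 0.8 * (rec["excavator_1994_kg_ha"]
                      - rec["excavator_1994_kg_ha"].mean())
             / max(rec["excavator_1994_kg_ha"].std(), 1e-9)
             + rng.normal(0, 0.7, len(rec)))
    top = score.nlargest(config.n_budget_recovered).index
    archetype = pd.Series("regime_shifted", index=reefs.index, dtype=object)
    archetype[rec.index] = "eco_recovered"
    archetype[top] = "budget_recovered"
    reefs["archetype"] = archetype
    return reefs


def _reef_year_covers(reef, year: int, config: GeneratorConfig,
                      rng: np.random.Generator) -> dict:
    arch = reef.archetype
    if year == min(config.years):
        f = 1.0
    elif year == sorted(config.years)[1]:
        f = 1.0 - config.bleach_mortality
    else:
        f = _REBOUND[arch][year]
    coral = {m: getattr(reef, f"{m}_1994") * f for m in HINDCAST_MORPHOLOGIES}
    if year not in sorted(config.years)[:2]:
        coral["massive"] *= _MASSIVE_EXTRA[arch]

    if arch == "regime_shifted":
        macro = reef.macroalgae_1994 if year == min(config.years) \
            else _MACROALGAE_SHIFTED[year] * float(rng.lognormal(0, 0.1))
    else:
        macro = reef.macroalgae_1994 if year == min(config.years) \
            else (rng.uniform(0, 4) if rng.random() < 0.2 else 0.0)

    rubble = 10.0 + (8.0 if year > min(config.years) else 0.0)
    covers = {f"cover_{m}": coral[m] for m in HINDCAST_MORPHOLOGIES}
    covers |= {"cover_macroalgae": macro, "cover_soft": reef.soft,
               "cover_sand": reef.sand, "cover_rubble": rubble,
               "cover_cca": float(rng.uniform(0, 1.0))}
    used = sum(covers.values())
    covers["cover_rock"] = max(0.0, (100.0 - used) * 0.75)
    return covers


def _cap_total(covers: dict, cap: float = 99.5) -> dict:
    total = sum(covers.values())
    if total > cap:
        covers = {k: v * cap / total for k, v in covers.items()}
    return covers


def _site_fish(key: dict, reef, year: int, config: GeneratorConfig,
               lw: pd.DataFrame, area_m2: float,
               rng: np.random.Generator) -> list[dict]:
    arch = reef.archetype
    targets = {
        "excavator": (reef.excavator_1994_kg_ha * _EXC_MULT[arch][year],
                      _EXC_SPECIES, _MEAN_LENGTH[year]),
        "scraper": ((_SCRAPER_RECOVERED if arch != "regime_shifted"
                     else _SCRAPER_SHIFTED)[year], _SCR_SPECIES,
                    _MEAN_LENGTH[year] - 2),
        "browser": (0.0 if rng.random() < (0.8 if arch != "regime_shifted"
                                           else 0.6)
                    else (3.0 if arch != "regime_shifted" else 5.0),
                    _BRW_SPECIES, 20),
    }
    rows = []
    for group, (kg_ha, species_pool, mean_len) in targets.items():
        if kg_ha <= 0:
            continue
        target_kg = (kg_ha * reef.biomass_factor
                     * float(rng.lognormal(-0.3**2 / 2, 0.3))
                     * area_m2 / 10000.0)
        rows += _fish_to_target(key, target_kg, species_pool, mean_len,
                                lw, rng)
    return rows


def _fish_to_target(key: dict, target_kg: float, species_pool, mean_len: float,
                    lw: pd.DataFrame, rng: np.random.Generator) -> list[dict]:
    """Draw fish until the group's biomass target is met; the last fish's
    length is solved so the site total closes on the target (within the
    10-60 cm plausible range)."""
    rows, total = [], 0.0
    while total < target_kg and len(rows) < 200:
        sp = species_pool[rng.integers(len(species_pool))]
        a, b = float(lw.loc[sp, "a"]), float(lw.loc[sp, "b"])
        remaining = target_kg - total
        L = float(np.clip(rng.lognormal(np.log(mean_len), 0.22), 10, 60))
        mass = a * L**b / 1000.0
        if mass >= remaining:  # close the gap with a solved final length
            L = float(np.clip((remaining * 1000.0 / a) ** (1.0 / b), 10, 60))
            mass = a * L**b / 1000.0
            rows.append(key | {"species": sp,
                               "total_length_cm": round(L, 1), "count": 1})
            total += mass
            break
        rows.append(key | {"species": sp,
                           "total_length_cm": round(L, 1), "count": 1})
        total += mass
    return rows


def _site_intercepts(key: dict, true_cov: dict,
                     rng: np.random.Generator) -> list[dict]:
    """Colonies whose planar intercepts sum exactly to the site's true cover."""
    rows = []
    for m in HINDCAST_MORPHOLOGIES:
        target_cm = true_cov[f"cover_{m}"] / 100.0 * DEFAULT_TRANSECT_CM
        if target_cm < 0.5:
            continue
        s = SURFACE_FACTORS[m]
        placed = 0.0
        while placed < target_cm - 1e-9:
            linear = float(rng.uniform(5, 35)) if m == "branching" \
                else float(rng.uniform(4, 22))
            linear = min(linear, target_cm - placed)
            if target_cm - placed - linear < 0.5:  # avoid sliver colonies
                linear = target_cm - placed
            rows.append(key | {
                "genus": GENUS_OF[m], "morphology": m,
                "surface_length_cm": linear * s,
                "linear_length_cm": linear,
                "transect_length_cm": DEFAULT_TRANSECT_CM})
            placed += linear
    return rows


def _site_urchins(key: dict, rng: np.random.Generator) -> list[dict]:
    rows = []
    for _ in range(rng.poisson(0.6)):
        sp = _URCHIN_SPECIES[rng.integers(len(_URCHIN_SPECIES))]
        size = float(rng.uniform(1.5, 8)) if sp == "Echinometra mathaei" \
            else float(rng.uniform(2, 11))
        rows.append(key | {"species": sp, "test_size_cm": round(size, 1),
                           "count": 1, "belt_area_m2": DEFAULT_BELT_AREA_M2})
    return rows


# ---------------------------------------------------------------------------
# focused simulators for the statistical modules
# ---------------------------------------------------------------------------

def simulate_lmm_panel(rng: np.random.Generator, n_reefs: int = 21,
                       years: tuple[int, ...] = YEARS,
                       status_effect: float = 0.0,
                       reef_sd: float = 1.0,
                       group_sds: dict | None = None,
                       base_sd: float = 1.0,
                       n_shifted: int = 9) -> pd.DataFrame:
    """Reef x year panel from the weighted-LMM generating model.

    Response = year effect + status effect + reef random intercept +
    heteroscedastic noise whose SD varies by (year, status) cell.
    ``status_effect`` is expressed in units of ``base_sd``.
    """
    rows = []
    year_effects = {y: 0.5 * i for i, y in enumerate(years)}
    reef_int = rng.normal(0, reef_sd, n_reefs)
    for i in range(n_reefs):
        status = "regime_shifted" if i < n_shifted else "recovered"
        for y in years:
            sd = base_sd
            if group_sds:
                sd = group_sds.get((y, status), base_sd)
            mu = (year_effects[y]
                  + (status_effect * base_sd if status == "regime_shifted" else 0.0)
                  + reef_int[i])
            rows.append({"reef_id": f"R{i + 1:02d}", "year": y,
                         "regime_status": status,
                         "response": mu + rng.normal(0, sd)})
    return pd.DataFrame(rows)


def simulate_zip(rng: np.random.Generator, n: int = 400,
                 lam: float = 3.0, pi0: float = 0.4) -> np.ndarray:
    """Draws from a zero-inflated Poisson."""
    structural = rng.random(n) < pi0
    y = rng.poisson(lam, n)
    y[structural] = 0
    return y


def simulate_hindcast_pairs(rng: np.random.Generator, n_sites: int = 168,
                            beta: dict | None = None,
                            noise_sd: float = 0.3) -> pd.DataFrame:
    """Visual covers with production from a known through-origin regression."""
    if beta is None:
        beta = {"branching": 0.12, "encrusting": 0.02,
                "massive": 0.05, "table": 0.15}
    covers = {
        "cover_branching": rng.uniform(0, 30, n_sites),
        "cover_encrusting": rng.uniform(0, 10, n_sites),
        "cover_massive": rng.uniform(0, 15, n_sites),
        "cover_table": rng.uniform(0, 10, n_sites),
    }
    df = pd.DataFrame(covers)
    prod = sum(beta[m] * df[f"cover_{m}"] for m in beta)
    df["production"] = prod + rng.normal(0, noise_sd, n_sites)
    return df


def simulate_brt_panel(rng: np.random.Generator, n_reefs: int = 21,
                       n_positive: int = 8, site_flip: float = 0.05,
                       excav_ranks: tuple[int, int] = (2, 6),
                       null_design: bool = False) -> tuple[pd.DataFrame, np.ndarray]:
    """Site-level classification design generated from known reef drivers.

    The census-year budget state of each reef is determined by three 1994
    covariates with a fixed division of labour, mirroring the ecological
    reading of the hindcast model (macroalgae strongest, massive coral
    second, excavator biomass third):

    - macroalgae presence marks every negative reef except two "ambiguous"
      ones and no positive reef, so one clean split resolves most of the
      panel;
    - massive coral ranks the algae-free reefs high-to-low with the two
      ambiguous negatives interleaved mid-rank, so it sharpens but cannot
      purify the algae-free group;
    - excavator biomass is high on exactly the two ambiguous reefs
      (descending ranks ``excav_ranks``) and its remaining values are dealt
      across the classes in proportion, so its only systematic signal is
      resolving what the first two drivers leave open.

    Every other predictor varies at site level independently of state.
    Site responses flip with probability ``site_flip`` (observation noise).
    With ``null_design`` all three drivers are drawn independently of
    state, giving a pure-noise design for baseline checks.

    Returns the design table (one row per site, columns as consumed by
    :func:`reefcarb.brt.fit_brt`) and the true per-reef states.
    """
    state = np.zeros(n_reefs, int)
    state[:n_positive] = 1
    state = state[rng.permutation(n_reefs)]
    pos = np.flatnonzero(state == 1)
    neg = np.flatnonzero(state == 0)

    if null_design:
        algae = (rng.random(n_reefs) < 0.5).astype(float)
        massive = np.maximum(rng.normal(5, 2, n_reefs), 0.3)
        excav = np.maximum(rng.normal(33, 6, n_reefs), 5)
    else:
        amb = rng.choice(neg, 2, replace=False)
        algae = np.zeros(n_reefs)
        algae[np.setdiff1d(neg, amb)] = 1.0

        vals = np.sort(rng.normal(5, 2, n_reefs))[::-1]
        grp = list(rng.permutation(pos))
        grp.insert(3, amb[0])
        grp.insert(6, amb[1])
        massive = np.empty(n_reefs)
        massive[grp] = vals[:len(grp)]
        massive[np.setdiff1d(neg, amb)] = rng.permutation(vals[len(grp):])
        massive = np.maximum(massive, 0.3)

        ev = np.sort(np.maximum(rng.normal(33, 6, n_reefs), 5))[::-1]
        excav = np.empty(n_reefs)
        excav[list(amb)] = ev[list(excav_ranks)]
        rest_vals = np.delete(ev, list(excav_ranks))  # descending
        rest_pos = list(rng.permutation(pos))
        rest_neg = list(rng.permutation(np.setdiff1d(neg, amb)))
        frac = np.argsort(np.concatenate([
            (np.arange(len(rest_pos)) + 0.5) / len(rest_pos),
            (np.arange(len(rest_neg)) + 0.5) / len(rest_neg)]), kind="stable")
        seq = rest_pos + rest_neg
        for v, reef in zip(rest_vals, (seq[i] for i in frac)):
            excav[reef] = v

    rows = []
    for i in range(n_reefs):
        for s in range(int(rng.integers(8, 17))):
            resp = state[i] ^ (rng.random() < site_flip)
            rows.append({
                "reef_id": f"R{i + 1:02d}", "site_id": f"S{s + 1:02d}",
                "response": int(resp),
                "cover_macroalgae": algae[i], "cover_massive": massive[i],
                "excavator_kg_ha": excav[i],
                "browser_kg_ha": float(rng.lognormal(1.0, 0.6)),
                "scraper_kg_ha": float(rng.lognormal(3.0, 0.4)),
                "cover_branching": float(np.clip(rng.normal(20, 4), 5, 35)),
                "cover_encrusting": float(np.clip(rng.normal(4, 1.2), 0.5, 8)),
                "depth_m": float(rng.integers(6, 21)) / 2.0,
                "wave_exposure_jm3": float(rng.integers(1, 9)) * 0.05,
                "rugosity_class": int(rng.integers(1, 6)),
                "reserve": float(rng.random() < 0.3),
                "habitat": float(rng.integers(0, 3))})
    return pd.DataFrame(rows), state
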