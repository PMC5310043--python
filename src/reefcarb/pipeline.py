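"""End-to-end orchestration: generate -> budget -> panel -> stats -> BRT -> forecast.

A single YAML (or dict) configuration drives every stage; all randomness
descends from one master seed through named substreams, and every output
CSV is written with a fixed float format so that identical configurations
produce byte-identical files.  A JSON run manifest records config and
output checksums, the seed registry and stage timings.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from reefcarb import brt as brt_mod
from reefcarb import stats as stats_mod
from reefcarb.budget import (
    build_trajectory_panel,
    budget_by_site,
    sensitivity_analysis,
)
from reefcarb.census import RateTables, SurveyDataset
from reefcarb.simulate import GeneratorConfig, generate_panel

STAGES = ("simulate", "validate", "budget", "panel", "stats",
          "sensitivity", "brt", "forecast")
_SUBSTREAM = {"simulate": 0, "sensitivity": 1, "brt": 2, "stats": 3}
FLOAT_FMT = "%.10g"


def substream_seed(master: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the master seed."""
    ss = np.random.SeedSequence([int(master), _SUBSTREAM[stage]])
    return int(ss.generate_state(1)[0] % (2**31))


def default_config() -> dict:
    return {
        "seed": 0,
        "generator": {},
        "budget": {"rate_variant": "mean", "include_urchins": False,
                   "census_year": 2014},
        "sensitivity": {"n": 999, "mode": "rates"},
        "stats": {"responses": ["net_G", "production", "erosion",
                                "excavator_kg_ha", "scraper_kg_ha"],
                  "zip_responses": ["browser_kg_ha", "cover_macroalgae"]},
        "brt": {"predictor_years": [1994, 2005], "learning_rate": 0.01,
                "tree_complexity": 3, "bag_fraction": 0.75, "n_folds": 10,
                "step_size": 50, "max_trees": 1500, "simplify": True},
        "forecast": {"forecast_year": 2030, "predictor_year_model": 1994},
    }


def load_config(path: str | Path | None = None, **overrides) -> dict:
    cfg = default_config()
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        for k, v in user.items():
            if isinstance(v, dict) and isinstance(cfg.get(k), dict):
                cfg[k] = cfg[k] | v
            else:
                cfg[k] = v
    for k, v in overrides.items():
        if v is not None:
            cfg[k] = v
    return cfg


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_csv(df: pd.DataFrame, path: Path) -> Path:
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format=FLOAT_FMT)
    return path


def _write_rates(rates: RateTables, outdir: Path) -> list[Path]:
    out = []
    for name in ("coral", "parrotfish", "length_weight", "urchin"):
        out.append(_write_csv(getattr(rates, name), outdir / f"rates_{name}.csv"))
    return out


def _read_rates(outdir: Path) -> RateTables:
    tables = {name: pd.read_csv(outdir / f"rates_{name}.csv")
              for name in ("coral", "parrotfish", "length_weight", "urchin")}
    return RateTables(**tables)


def run_pipeline(config: dict | str | Path | None = None,
                 stages: tuple[str, ...] | list[str] = STAGES,
                 outdir: str | Path = "results/run",
                 seed: int | None = None) -> dict:
    """Run the selected stages in dependency order; returns the manifest.

    Stage outputs are written under ``outdir``; a stage run without its
    upstream outputs present raises a dependency error naming the stage to
    run first.
    """
    if not isinstance(config, dict):
        config = load_config(config)
    if seed is not None:
        config = config | {"seed": int(seed)}
    master = int(config["seed"])
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stages = [s for s in STAGES if s in set(stages)]

    manifest = {
        "config": config,
        "config_checksum": hashlib.sha256(
            json.dumps(config, sort_keys=True).encode()).hexdigest(),
        "seed_registry": {s: substream_seed(master, s) for s in _SUBSTREAM},
        "stages": stages,
        "stage_seconds": {},
        "outputs": {},
    }

    state: dict = {}
    for stage in stages:
        t0 = time.perf_counter()
        outputs = _STAGE_FUNCS[stage](config, outdir, state)
        manifest["stage_seconds"][stage] = round(time.perf_counter() - t0, 3)
        manifest["outputs"][stage] = {p.name: _sha256(p) for p in outputs}

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def _require(outdir: Path, relpath: str, needed_by: str, produced_by: str):
    p = outdir / relpath
    if not p.exists():
        raise FileNotFoundError(
            f"stage {needed_by!r} needs {p}; run stage {produced_by!r} first")
    return p


def _get_dataset(config, outdir, state) -> tuple[SurveyDataset, RateTables]:
    if "dataset" not in state:
        _require(outdir, "data/sites.csv", "budget", "simulate")
        state["dataset"] = SurveyDataset.read(outdir / "data")
        state["rates"] = _read_rates(outdir / "data")
    return state["dataset"], state["rates"]


def _stage_simulate(config, outdir, state):
    gcfg = GeneratorConfig(**(config.get("generator") or {}),
                           seed=substream_seed(config["seed"], "simulate"))
    dataset, rates, truth = generate_panel(gcfg)
    paths = list(dataset.write(outdir / "data").values())
    paths += _write_rates(rates, outdir / "data")
    paths.append(_write_csv(truth.reef_table, outdir / "data" / "truth_reefs.csv"))
    paths.append(_write_csv(truth.site_covers, outdir / "data" / "truth_site_covers.csv"))
    tp = outdir / "data" / "truth.json"
    tp.write_text(json.dumps(
        {"true_beta": truth.true_beta, "generator": asdict(gcfg)},
        indent=2, default=str))
    paths.append(tp)
    state.update(dataset=dataset, rates=rates, truth=truth)
    return paths


def _stage_validate(config, outdir, state):
    dataset, _ = _get_dataset(config, outdir, state)
    dataset.validate()
    p = outdir / "validation.json"
    p.write_text(json.dumps(dataset.summary() | {"valid": True}, indent=2))
    return [p]


def _stage_budget(config, outdir, state):
    dataset, rates = _get_dataset(config, outdir, state)
    b = config["budget"]
    site = budget_by_site(dataset, rates, b["rate_variant"],
                          include_urchins=b["include_urchins"],
                          year=b["census_year"])
    state["site_budgets"] = site
    return [_write_csv(site, outdir / "site_budgets.csv")]


def _stage_panel(config, outdir, state):
    dataset, rates = _get_dataset(config, outdir, state)
    b = config["budget"]
    panel = build_trajectory_panel(dataset, rates,
                                   which_rate=b["rate_variant"],
                                   census_year=b["census_year"],
                                   include_urchins=b["include_urchins"])
    state["panel"] = panel
    paths = [_write_csv(panel.sites, outdir / "panel_sites.csv"),
             _write_csv(panel.reefs, outdir / "panel_reefs.csv"),
             _write_csv(panel.positive_reef_counts().reset_index()
                        .rename(columns={"pos": "n_positive_reefs"}),
                        outdir / "positive_reef_counts.csv")]
    hp = outdir / "hindcast.json"
    hp.write_text(json.dumps({
        "coefficients": panel.hindcast.coef,
        "resid_se": panel.hindcast.resid_se, "r2": panel.hindcast.r2,
        "n_sites": panel.hindcast.n_sites}, indent=2))
    paths.append(hp)
    return paths


def _get_panel(config, outdir, state):
    if "panel" not in state:
        _require(outdir, "panel_reefs.csv", "stats", "panel")
        dataset, rates = _get_dataset(config, outdir, state)
        _stage_panel(config, outdir, state)
    return state["panel"]


def _stage_stats(config, outdir, state):
    panel = _get_panel(config, outdir, state)
    reefs = panel.reefs[panel.reefs["surveyed"]
                        & panel.reefs["regime_status"].isin(
                            ["recovered", "regime_shifted"])].copy()
    scfg = config["stats"]
    tables = []
    for resp in scfg["responses"]:
        w = stats_mod.group_weights(reefs, resp)
        fit = stats_mod.fit_weighted_lmm(reefs, resp, weights=w)
        tables.append(stats_mod.coefficient_table(
            fit.coefficients(), response=resp, model="weighted_lmm"))
        years = sorted(reefs["year"].unique())
        pairs = [({"year": y, "regime_status": "recovered"},
                  {"year": y, "regime_status": "regime_shifted"})
                 for y in years]
        tables.append(stats_mod.coefficient_table(
            stats_mod.posthoc_contrasts(fit, pairs),
            response=resp, model="posthoc_recovered_vs_shifted"))
    coef = pd.concat(tables, ignore_index=True)

    zrows = []
    for resp in scfg["zip_responses"]:
        try:
            z = stats_mod.fit_zip(reefs, resp)
        except ValueError:
            continue
        zrows.append({"response": resp, "llf": z.llf,
                      "llf_no_interaction": z.llf_no_interaction,
                      "lrt_stat": z.lrt_stat, "lrt_df": z.lrt_df,
                      "lrt_pvalue": z.lrt_pvalue, "pi0": z.pi0,
                      "converged": z.converged})
    paths = [_write_csv(coef, outdir / "coefficients.csv")]
    if zrows:
        paths.append(_write_csv(pd.DataFrame(zrows), outdir / "zip_models.csv"))
    return paths


def _stage_sensitivity(config, outdir, state):
    dataset, rates = _get_dataset(config, outdir, state)
    n = config["sensitivity"]["n"]
    sens = sensitivity_analysis(
        dataset, rates, n=n,
        seed=substream_seed(config["seed"], "sensitivity"),
        census_year=config["budget"]["census_year"],
        mode=config["sensitivity"]["mode"])
    summary = sens.reef_summary()
    counts = pd.DataFrame([sens.positive_reef_counts()])
    return [_write_csv(summary, outdir / "sensitivity_summary.csv"),
            _write_csv(counts, outdir / "sensitivity_positive_counts.csv")]


def _brt_config(config, master_seed: int) -> brt_mod.BRTConfig:
    b = config["brt"]
    return brt_mod.BRTConfig(
        learning_rate=b["learning_rate"], tree_complexity=b["tree_complexity"],
        bag_fraction=b["bag_fraction"], n_folds=b["n_folds"],
        step_size=b["step_size"], max_trees=b["max_trees"],
        seed=substream_seed(master_seed, "brt"))


def _stage_brt(config, outdir, state):
    panel = _get_panel(config, outdir, state)
    bcfg = _brt_config(config, config["seed"])
    paths = []
    state["brt_models"] = {}
    for py in config["brt"]["predictor_years"]:
        design = brt_mod.build_design(panel, predictor_year=py)
        model = brt_mod.fit_brt(design, bcfg)
        removed: list[str] = []
        if config["brt"].get("simplify", True):
            model, removed = brt_mod.simplify_predictors(model)
        state["brt_models"][py] = model

        infl = (model.relative_influence.sort_values(ascending=False)
                .rename_axis("predictor")
                .reset_index(name="relative_influence"))
        paths.append(_write_csv(infl, outdir / f"brt_influence_{py}.csv"))
        pd_frames = []
        for pred in infl.loc[infl["relative_influence"] > 10, "predictor"]:
            c = brt_mod.partial_dependence(model, pred)
            pd_frames.append(c.assign(predictor=pred))
        if pd_frames:
            paths.append(_write_csv(pd.concat(pd_frames, ignore_index=True),
                                    outdir / f"brt_partial_dependence_{py}.csv"))
        summary = outdir / f"brt_summary_{py}.json"
        summary.write_text(json.dumps({
            "predictor_year": py, "n_trees": model.n_trees,
            "cv_deviance": model.cv_deviance,
            "predictors": model.predictors, "removed": removed,
            "relative_influence": model.relative_influence.round(6).to_dict(),
        }, indent=2))
        paths.append(summary)
        paths.append(_write_csv(model.cv_curve, outdir / f"brt_cv_curve_{py}.csv"))
    return paths


def _stage_forecast(config, outdir, state):
    panel = _get_panel(config, outdir, state)
    if "brt_models" not in state:
        raise FileNotFoundError("stage 'forecast' needs fitted BRT models; "
                                "run stage 'brt' first")
    py = config["forecast"]["predictor_year_model"]
    model = state["brt_models"][py]

    design = brt_mod.build_design(panel, predictor_year=py)
    prob = model.predict_proba(design)
    thr = brt_mod.optimal_threshold(prob, design["response"].to_numpy())

    # hindcast validation: reef-level predictions vs observed census states
    hind = (design.assign(prob=prob)
            .groupby("reef_id", sort=True)
            .agg(probability_positive=("prob", "mean"),
                 observed_positive=("response", "mean")))
    hind["predicted_positive"] = hind["probability_positive"] >= thr.threshold
    hind["observed_positive"] = hind["observed_positive"] > 0.5
    hind = hind.reset_index()

    current = brt_mod.reef_predictor_table(
        panel, year=panel.census_year,
        macroalgae_presence_absence=(py == 1994))
    fc = brt_mod.forecast_scenario(model, current, thr)

    paths = [_write_csv(hind, outdir / "brt_hindcast_validation.csv"),
             _write_csv(fc, outdir / f"forecast_{config['forecast']['forecast_year']}.csv")]
    tp = outdir / "threshold.json"
    tp.write_text(json.dumps({
        "threshold": thr.threshold, "rule": thr.rule,
        "achieved_prevalence_gap": thr.achieved_prevalence_gap,
        "hindcast_accuracy_reefs": int(
            (hind["predicted_positive"] == hind["observed_positive"]).sum()),
        "n_reefs": int(len(hind)),
        "n_forecast_positive": int((fc["predicted_state"] == "positive").sum()),
    }, indent=2))
    paths.append(tp)
    return paths


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "validate": _stage_validate,
    "budget": _stage_budget,
    "panel": _stage_panel,
    "stats": _stage_stats,
    "sensitivity": _stage_sensitivity,
    "brt": _stage_brt,
    "forecast": _stage_forecast,
}
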