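"""Boosted regression trees for budget-state classification and forecasting.

A stagewise gradient-boosting classifier (Bernoulli deviance, shallow
trees) relates the *sign* of each site's net carbonate budget in the census
year to reef-level ecological predictors measured in an earlier year.  Tree
count is chosen by k-fold cross-validated predictive deviance evaluated in
blocks of ``step_size`` trees, folds stratified by reef so sites of one reef
never straddle a train/test split.  Model summaries follow boosted-tree
practice in ecology: relative influence per predictor (summing to 100),
partial dependence curves for the influential predictors, and backward
predictor simplification within one standard error of the best
cross-validated deviance.

Classification probabilities are cut at the prevalence-matching threshold
(predicted prevalence = observed prevalence), and the fitted
past -> census-year transition model is reapplied to current predictors to
forecast budget state one bleaching cycle ahead.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingClassifier

from reefcarb.budget import TrajectoryPanel

log = logging.getLogger(__name__)

#: the twelve reef-level predictors offered to the classifier
PREDICTORS = [
    "browser_kg_ha", "scraper_kg_ha", "excavator_kg_ha",
    "cover_macroalgae", "cover_branching", "cover_massive",
    "cover_encrusting", "depth_m", "wave_exposure_jm3",
    "rugosity_class", "reserve", "habitat",
]


@dataclass(frozen=True)
class BRTConfig:
    learning_rate: float = 0.005
    tree_complexity: int = 3
    bag_fraction: float = 0.75
    n_folds: int = 10
    step_size: int = 50
    max_trees: int = 2000
    min_obs_in_node: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.learning_rate <= 0.1):
            raise ValueError("learning_rate must lie in (0, 0.1]")
        if not (0 < self.bag_fraction <= 1):
            raise ValueError("bag_fraction must lie in (0, 1]")
        if self.n_folds < 2:
            raise ValueError("need at least 2 CV folds")


@dataclass
class BRTModel:
    """A fitted boosted-tree ensemble with its CV curve and summaries."""

    estimator: GradientBoostingClassifier = field(repr=False)
    n_trees: int
    predictors: list[str]
    relative_influence: pd.Series
    cv_curve: pd.DataFrame = field(repr=False)
    cv_deviance: float               # CV deviance at the selected tree count
    cv_deviance_se: float
    config: BRTConfig
    design: pd.DataFrame = field(repr=False)
    response: np.ndarray = field(repr=False)

    def predict_proba(self, X: pd.DataFrame) -> np.ndarray:
        """Probability of a positive budget state for each row."""
        return self.estimator.predict_proba(X[self.predictors])[:, 1]


@dataclass(frozen=True)
class ThresholdResult:
    threshold: float
    rule: str = "PredPrev=Obs"
    achieved_prevalence_gap: float = 0.0


# ---------------------------------------------------------------------------
# design construction
# ---------------------------------------------------------------------------

def build_design(panel: TrajectoryPanel, predictor_year: int,
                 response_year: int = 2014,
                 macroalgae_presence_absence: bool | None = None
                 ) -> pd.DataFrame:
    """Site-level response, reef-level predictors.

    Rows are the ``response_year`` sites; the response is the sign of each
    site's net budget.  Predictors are reef means from ``predictor_year``.
    For 1994 predictors macroalgal cover is reduced to presence/absence
    (most reefs had none, so percent cover carries almost no signal).
    Zero-variance predictors are dropped with a warning.
    """
    if macroalgae_presence_absence is None:
        macroalgae_presence_absence = predictor_year == 1994

    reefs = panel.reefs[(panel.reefs["year"] == predictor_year)
                        & panel.reefs["surveyed"]].copy()
    if not len(reefs):
        raise ValueError(f"panel has no surveyed reefs in {predictor_year}")
    reefs["reserve"] = reefs["reserve"].astype(float)
    reefs["habitat"] = pd.Categorical(
        reefs["habitat"], categories=sorted(reefs["habitat"].unique())).codes.astype(float)
    if macroalgae_presence_absence:
        reefs["cover_macroalgae"] = (reefs["cover_macroalgae"] > 0).astype(float)
    pred = reefs[["reef_id"] + PREDICTORS]

    resp = panel.sites[panel.sites["year"] == response_year]
    if not len(resp):
        raise ValueError(f"panel has no sites in {response_year}")
    resp = resp[["reef_id", "site_id", "net_G"]].copy()
    resp["response"] = (resp["net_G"] > 0).astype(int)

    design = resp.drop(columns="net_G").merge(pred, on="reef_id", how="inner",
                                              validate="m:1")
    keep, dropped = [], []
    for c in PREDICTORS:
        if design[c].nunique() <= 1:
            dropped.append(c)
        else:
            keep.append(c)
    if dropped:
        warnings.warn(f"dropping zero-variance predictors: {dropped}",
                      stacklevel=2)
    return design[["reef_id", "site_id", "response"] + keep]


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def _bernoulli_deviance(y: np.ndarray, margin: np.ndarray) -> float:
    """Mean Bernoulli deviance from log-odds margins (numerically stable)."""
    return float(2.0 * np.mean(np.logaddexp(0.0, margin) - y * margin))


def _reef_folds(reefs: np.ndarray, n_folds: int, seed: int) -> dict:
    """Deterministic reef -> fold assignment (stratifying folds by reef)."""
    uniq = np.array(sorted(pd.unique(reefs)))
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(uniq))
    fold_of = {}
    for i, j in enumerate(order):
        fold_of[uniq[j]] = i % n_folds
    return fold_of


def _make_gbc(config: BRTConfig, n_trees: int) -> GradientBoostingClassifier:
    return GradientBoostingClassifier(
        n_estimators=n_trees,
        learning_rate=config.learning_rate,
        max_depth=config.tree_complexity,
        subsample=config.bag_fraction,
        min_samples_leaf=config.min_obs_in_node,
        random_state=config.seed,
    )


def fit_brt(design: pd.DataFrame, config: BRTConfig = BRTConfig(),
            predictors: list[str] | None = None) -> BRTModel:
    """Fit the ensemble with CV-selected tree count.

    Rows are canonicalized (sorted by reef and site) before fitting so the
    result is invariant to input row order under a fixed seed.
    """
    design = design.sort_values(["reef_id", "site_id"]).reset_index(drop=True)
    if predictors is None:
        predictors = [c for c in design.columns
                      if c not in ("reef_id", "site_id", "response")]
    y = design["response"].to_numpy(int)
    if len(np.unique(y)) < 2:
        raise ValueError("response has a single class; nothing to classify")
    X = design[predictors]

    fold_of = _reef_folds(design["reef_id"].to_numpy(), config.n_folds, config.seed)
    fold = design["reef_id"].map(fold_of).to_numpy()
    blocks = np.arange(config.step_size, config.max_trees + 1, config.step_size)

    # per-fold held-out deviance at each block of trees
    dev = np.full((config.n_folds, len(blocks)), np.nan)
    for k in range(config.n_folds):
        tr, te = fold != k, fold == k
        if te.sum() == 0 or len(np.unique(y[tr])) < 2:
            continue
        gbc = _make_gbc(config, config.max_trees)
        gbc.fit(X[tr], y[tr])
        stages = gbc.staged_decision_function(X[te])
        for i, margin in enumerate(stages):
            stage = i + 1
            if stage % config.step_size == 0:
                dev[k, stage // config.step_size - 1] = \
                    _bernoulli_deviance(y[te], margin.ravel())

    valid = ~np.isnan(dev).all(axis=1)
    curve = np.nanmean(dev[valid], axis=0)
    curve_se = np.nanstd(dev[valid], axis=0, ddof=1) / np.sqrt(valid.sum())
    best = int(np.argmin(curve))
    if best == len(blocks) - 1 and len(blocks) > 1 and curve[-1] < curve[-2]:
        raise RuntimeError(
            "CV deviance still decreasing at max_trees="
            f"{config.max_trees}; increase max_trees or lower learning_rate")
    n_trees = int(blocks[best])

    final = _make_gbc(config, n_trees)
    final.fit(X, y)
    infl = pd.Series(final.feature_importances_ * 100.0, index=predictors)

    cv_curve = pd.DataFrame({"n_trees": blocks, "cv_deviance": curve,
                             "cv_deviance_se": curve_se})
    return BRTModel(estimator=final, n_trees=n_trees,
                    predictors=list(predictors), relative_influence=infl,
                    cv_curve=cv_curve, cv_deviance=float(curve[best]),
                    cv_deviance_se=float(curve_se[best]), config=config,
                    design=design, response=y)


def _cv_deviance_at(design: pd.DataFrame, config: BRTConfig,
                    predictors: list[str], n_trees: int
                    ) -> tuple[float, float]:
    """Held-out Bernoulli deviance (mean, SE over folds) at a fixed tree count."""
    y = design["response"].to_numpy(int)
    X = design[predictors]
    fold_of = _reef_folds(design["reef_id"].to_numpy(), config.n_folds,
                          config.seed)
    fold = design["reef_id"].map(fold_of).to_numpy()
    devs = []
    for k in range(config.n_folds):
        tr, te = fold != k, fold == k
        if te.sum() == 0 or len(np.unique(y[tr])) < 2:
            continue
        gbc = _make_gbc(config, n_trees)
        gbc.fit(X[tr], y[tr])
        margin = gbc.decision_function(X[te])
        devs.append(_bernoulli_deviance(y[te], np.asarray(margin).ravel()))
    devs = np.asarray(devs)
    return float(devs.mean()), float(devs.std(ddof=1) / np.sqrt(len(devs)))


def simplify_predictors(model: BRTModel, design: pd.DataFrame | None = None,
                        config: BRTConfig | None = None
                        ) -> tuple[BRTModel, list[str]]:
    """Backward predictor elimination within one SE of the best CV deviance.

    Repeatedly drops the lowest-influence predictor; a drop is kept while
    cross-validated deviance, re-estimated at the parent model's selected
    tree count, does not exceed the current best deviance plus one standard
    error.  The surviving predictor set is then refit with a full
    tree-count search.  Returns the reduced model and the ordered list of
    removed predictors.
    """
    if design is None:
        design = model.design
    if config is None:
        config = model.config
    design = design.sort_values(["reef_id", "site_id"]).reset_index(drop=True)
    best_dev, best_se = model.cv_deviance, model.cv_deviance_se
    preds = list(model.predictors)
    infl = model.relative_influence
    removed: list[str] = []
    while len(preds) > 1:
        weakest = infl[preds].idxmin()
        reduced = [p for p in preds if p != weakest]
        dev, se = _cv_deviance_at(design, config, reduced, model.n_trees)
        if dev <= best_dev + best_se:
            removed.append(weakest)
            log.info("dropped predictor %s (CV deviance %.4f -> %.4f)",
                     weakest, best_dev, dev)
            preds = reduced
            if dev < best_dev:
                best_dev, best_se = dev, se
        else:
            break
    if not removed:
        return model, []
    return fit_brt(design, config, predictors=preds), removed


def partial_dependence(model: BRTModel, predictor: str,
                       grid: np.ndarray | None = None,
                       n_grid: int = 25) -> pd.DataFrame:
    """Partial dependence of P(positive budget) on one predictor.

    For each grid value the predictor column is clamped to that value across
    the training design and the ensemble predictions averaged — the standard
    Friedman recipe, returned on the probability scale.
    """
    if predictor not in model.predictors:
        raise KeyError(f"{predictor!r} is not a model predictor")
    col = model.design[predictor].to_numpy(float)
    if grid is None:
        grid = np.linspace(col.min(), col.max(), n_grid)
    else:
        grid = np.asarray(grid, float)
        if grid.min() < col.min() or grid.max() > col.max():
            warnings.warn("partial-dependence grid extends beyond the "
                          "observed predictor range (extrapolation)",
                          stacklevel=2)
    X = model.design[model.predictors].copy()
    probs = np.empty(len(grid))
    for i, v in enumerate(grid):
        X[predictor] = v
        probs[i] = model.estimator.predict_proba(X)[:, 1].mean()
    return pd.DataFrame({"value": grid, "probability": probs})


# ---------------------------------------------------------------------------
# threshold and forecasting
# ---------------------------------------------------------------------------

def optimal_threshold(predictions: np.ndarray,
                      observed: np.ndarray) -> ThresholdResult:
    """Prevalence-matching cut-off: predicted prevalence = observed prevalence.

    The threshold is placed at the midpoint between the k-th and (k+1)-th
    largest predictions, where k is the observed positive count; ties can
    make exact matching unachievable, in which case the achieved gap is
    reported.
    """
    p = np.asarray(predictions, float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("predictions must be probabilities in [0, 1]")
    yobs = np.asarray(observed, int)
    n, k = len(p), int(yobs.sum())
    srt = np.sort(p)[::-1]
    if k == 0:
        warnings.warn("no observed positives; threshold set above the "
                      "largest prediction", stacklevel=2)
        thr = min((srt[0] + 1.0) / 2.0, 1.0 - 1e-12)
    elif k == n:
        warnings.warn("all observations positive; threshold set below the "
                      "smallest prediction", stacklevel=2)
        thr = max(srt[-1] / 2.0, 1e-12)
    else:
        thr = (srt[k - 1] + srt[k]) / 2.0
        if srt[k - 1] == srt[k]:   # tied predictions straddle the cut
            thr = srt[k]
    gap = abs(float((p >= thr).mean()) - k / n)
    return ThresholdResult(threshold=float(thr),
                           achieved_prevalence_gap=gap)


def forecast_scenario(model: BRTModel, predictor_table: pd.DataFrame,
                      threshold: ThresholdResult) -> pd.DataFrame:
    """Reapply the fitted transition model to current predictors.

    ``predictor_table`` must carry ``reef_id`` plus every model predictor
    (reef-level means, with macroalgae on the same presence/absence coding
    used in training).  Returns per-reef probability of a positive budget
    one bleaching-recovery cycle ahead, thresholded and ranked.
    """
    missing = [c for c in model.predictors if c not in predictor_table.columns]
    if missing:
        raise KeyError(f"predictor table missing model variables: {missing}")
    tbl = predictor_table.sort_values("reef_id").reset_index(drop=True)
    prob = model.predict_proba(tbl)
    out = pd.DataFrame({
        "reef_id": tbl["reef_id"],
        "probability_positive": prob,
        "predicted_state": np.where(prob >= threshold.threshold,
                                    "positive", "negative"),
    })
    return out.sort_values("probability_positive",
                           ascending=False).reset_index(drop=True)


def reef_predictor_table(panel: TrajectoryPanel, year: int,
                         macroalgae_presence_absence: bool = True
                         ) -> pd.DataFrame:
    """Reef-level predictor means for ``year``, coded as in :func:`build_design`."""
    reefs = panel.reefs[(panel.reefs["year"] == year)
                        & panel.reefs["surveyed"]].copy()
    reefs["reserve"] = reefs["reserve"].astype(float)
    reefs["habitat"] = pd.Categorical(
        reefs["habitat"], categories=sorted(reefs["habitat"].unique())).codes.astype(float)
    if macroalgae_presence_absence:
        reefs["cover_macroalgae"] = (reefs["cover_macroalgae"] > 0).astype(float)
    return reefs[["reef_id"] + PREDICTORS]
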