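"""Statistical contrasts of budget components across years and regime states.

Three tools, mirroring how reef trajectory panels are usually analysed:

* variance-weighted linear mixed models with a reef random intercept, where
  each observation is weighted by the reciprocal of its (year x regime
  status) group variance — inference is CI-based (standardized coefficients
  with Wald 95% CIs), not p-value based;
* least-squares-means style post hoc group contrasts with Tukey-adjusted
  intervals;
* zero-inflated Poisson regression for responses with excess zeros
  (browser biomass, macroalgae and some coral covers), with a likelihood
  ratio test for the year x status interaction.

The weighted mixed model is fitted by profiled REML over the single
variance ratio (reef variance / residual variance); with observation
weights ``w`` the marginal covariance is ``sigma^2 (diag(1/w) + lambda ZZ')``.
statsmodels' MixedLM does not accept observation weights, hence the direct
implementation here; with all-equal weights the two agree (covered by the
test suite).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import patsy
from scipy import optimize, stats
from statsmodels.discrete.count_model import ZeroInflatedPoisson

log = logging.getLogger(__name__)

Z95 = stats.norm.ppf(0.975)


@dataclass(frozen=True)
class CoefficientCI:
    """One standardized coefficient with its Wald 95% CI."""

    term: str
    estimate: float
    lo95: float
    hi95: float

    @property
    def significant(self) -> bool:
        """CI excludes zero."""
        return (self.lo95 > 0) or (self.hi95 < 0)


# ---------------------------------------------------------------------------
# weights
# ---------------------------------------------------------------------------

def group_weights(data: pd.DataFrame, response: str,
                  group_cols: tuple[str, ...] = ("year", "regime_status")
                  ) -> pd.Series:
    """Reciprocal-of-group-variance weights, aligned with ``data``'s index.

    Groups are the year x regime-status cells; every observation in a cell
    gets weight 1 / var(cell).  Cells with fewer than two observations or
    zero variance are an error — a silently infinite weight would dominate
    the fit, so the caller must pool or drop such cells explicitly.
    """
    g = data.groupby(list(group_cols))[response]
    var = g.transform("var")
    n = g.transform("count")
    if (n < 2).any():
        bad = data.loc[n < 2, list(group_cols)].drop_duplicates()
        raise ValueError(f"groups with < 2 observations: {bad.values.tolist()}; "
                         "pool groups before weighting")
    if (var <= 0).any():
        bad = data.loc[var <= 0, list(group_cols)].drop_duplicates()
        raise ValueError(f"zero-variance groups {bad.values.tolist()}; "
                         "pool groups before weighting")
    return 1.0 / var


# ---------------------------------------------------------------------------
# weighted random-intercept model
# ---------------------------------------------------------------------------

@dataclass
class WeightedLMMFit:
    """A fitted variance-weighted random-intercept model."""

    terms: list[str]
    beta: np.ndarray
    cov_beta: np.ndarray = field(repr=False)
    sigma2: float
    lambda_: float                  # var(reef intercept) / residual variance
    response_sd: float              # scale used to standardize the response
    design_info: object = field(repr=False, default=None)
    n_obs: int = 0
    n_groups: int = 0
    singular: bool = False
    reml_neg2ll: float = np.nan
    term_df: np.ndarray = field(default=None, repr=False)

    def coefficients(self) -> list[CoefficientCI]:
        """Wald t-intervals with inner-outer degrees of freedom.

        Terms constant within every reef (between-reef effects such as
        regime status) are tested against the number of reefs, not the
        number of observations; within-reef terms use residual df.
        """
        se = np.sqrt(np.diag(self.cov_beta))
        if self.term_df is None:
            crit = np.full(len(self.terms), Z95)
        else:
            crit = stats.t.ppf(0.975, self.term_df)
        return [CoefficientCI(t, float(b), float(b - c * s), float(b + c * s))
                for t, b, s, c in zip(self.terms, self.beta, se, crit)]

    def predict_row(self, factor_values: dict) -> np.ndarray:
        """Design row for one factor combination (population level)."""
        (m,) = patsy.build_design_matrices([self.design_info],
                                           pd.DataFrame([factor_values]))
        return np.asarray(m)[0]


def _reml_neg2ll(loglam: float, X: np.ndarray, y: np.ndarray,
                 Dinv_diag: np.ndarray, Z: np.ndarray) -> tuple:
    lam = np.exp(loglam)
    n, p = X.shape
    V = np.diag(Dinv_diag) + lam * (Z @ Z.T)
    try:
        c = np.linalg.cholesky(V)
    except np.linalg.LinAlgError:
        return np.inf, None
    logdetV = 2.0 * np.log(np.diag(c)).sum()
    Vinv_X = np.linalg.solve(V, X)
    Vinv_y = np.linalg.solve(V, y)
    XtVinvX = X.T @ Vinv_X
    beta = np.linalg.solve(XtVinvX, X.T @ Vinv_y)
    r = y - X @ beta
    quad = float(r @ np.linalg.solve(V, r))
    sigma2 = quad / (n - p)
    sign, logdetXtVX = np.linalg.slogdet(XtVinvX)
    neg2ll = (n - p) * np.log(sigma2) + logdetV + logdetXtVX
    return neg2ll, (beta, sigma2, XtVinvX)


def fit_weighted_lmm(data: pd.DataFrame, response: str,
                     formula: str = "C(year) * C(regime_status)",
                     group: str = "reef_id",
                     weights: pd.Series | np.ndarray | None = None,
                     standardize: bool = True,
                     sqrt_transform: bool | str = "auto") -> WeightedLMMFit:
    """Fit the variance-weighted random-intercept model by profiled REML.

    ``sqrt_transform="auto"`` square-root transforms the (non-negative)
    response when a Breusch-Pagan check on unweighted OLS residuals rejects
    homoscedasticity at alpha = 0.05; pass True/False to force.
    """
    data = data.reset_index(drop=True)
    y_raw = data[response].to_numpy(float)

    if sqrt_transform == "auto":
        sqrt_transform = (y_raw.min() >= 0) and _breusch_pagan_rejects(
            data, response, formula)
    if sqrt_transform:
        if y_raw.min() < 0:
            raise ValueError("cannot sqrt-transform a response with negatives")
        y_raw = np.sqrt(y_raw)
        log.info("response %s square-root transformed", response)

    sd = float(np.std(y_raw, ddof=1)) if standardize else 1.0
    if sd == 0:
        sd = 1.0
    y = y_raw / sd

    ymat, X = patsy.dmatrices(f"__y__ ~ {formula}",
                              data.assign(__y__=y), return_type="dataframe")
    terms = list(X.columns)
    Xm = X.to_numpy(float)
    groups, _ = pd.factorize(data[group], sort=True)
    Z = np.zeros((len(data), groups.max() + 1))
    Z[np.arange(len(data)), groups] = 1.0

    if weights is None:
        w = np.ones(len(data))
    else:
        w = np.asarray(weights, float)
        if (w <= 0).any():
            raise ValueError("weights must be positive")
        w = w / w.mean()   # scale-free: only relative weights matter
    Dinv = 1.0 / w

    obj = lambda ll: _reml_neg2ll(ll, Xm, y, Dinv, Z)[0]
    res = optimize.minimize_scalar(obj, bounds=(-12.0, 8.0), method="bounded",
                                   options={"xatol": 1e-8})
    loglam = res.x
    neg2ll, (beta, sigma2, XtVinvX) = _reml_neg2ll(loglam, Xm, y, Dinv, Z)
    lam = float(np.exp(loglam))
    singular = loglam <= -11.5
    if singular:
        warnings.warn("random-intercept variance estimated at the zero "
                      "boundary; fit reduces to weighted least squares",
                      stacklevel=2)
    cov_beta = sigma2 * np.linalg.inv(XtVinvX)

    # inner-outer denominator df (as in nlme): a column constant within
    # every group is a between-group effect and is tested against the
    # group count; other columns against residual df
    group_means = Z @ (Z.T @ Xm / Z.sum(axis=0)[:, None])
    between = np.abs(Xm - group_means).max(axis=0) < 1e-10
    q_between = int(between.sum())
    df_between = max(Z.shape[1] - q_between, 1)
    df_within = max(len(data) - Z.shape[1] - int((~between).sum()) + 1, 1)
    term_df = np.where(between, df_between, df_within).astype(float)

    return WeightedLMMFit(terms=terms, beta=beta, cov_beta=cov_beta,
                          sigma2=float(sigma2), lambda_=lam, response_sd=sd,
                          design_info=X.design_info, n_obs=len(data),
                          n_groups=Z.shape[1], singular=singular,
                          reml_neg2ll=float(neg2ll), term_df=term_df)


def _breusch_pagan_rejects(data: pd.DataFrame, response: str,
                           formula: str, alpha: float = 0.05) -> bool:
    """Breusch-Pagan-style check of residual variance against fitted values."""
    y, X = patsy.dmatrices(f"{response} ~ {formula}", data,
                           return_type="dataframe")
    yv = y.to_numpy(float).ravel()
    Xm = X.to_numpy(float)
    beta, *_ = np.linalg.lstsq(Xm, yv, rcond=None)
    resid = yv - Xm @ beta
    u = resid**2 / resid.var()
    fitted = Xm @ beta
    A = np.column_stack([np.ones_like(fitted), fitted])
    g, *_ = np.linalg.lstsq(A, u, rcond=None)
    ess = float(((A @ g - u.mean())**2).sum())
    pval = stats.chi2.sf(ess / 2.0, 1)
    return bool(pval < alpha)


def posthoc_contrasts(fit: WeightedLMMFit,
                      pairs: list[tuple[dict, dict]],
                      adjust: str = "tukey",
                      n_groups: int | None = None) -> list[CoefficientCI]:
    """Estimated-marginal-mean differences for pairs of factor combinations.

    Each pair is two dicts of factor values, e.g.
    ``({"year": 2014, "regime_status": "recovered"},
       {"year": 2005, "regime_status": "recovered"})``.
    Intervals use a Tukey (studentized-range) multiplier across the implied
    family of groups by default; pass adjust="none" for plain Wald.
    """
    if n_groups is None:
        combos = {tuple(sorted(d.items())) for pair in pairs for d in pair}
        n_groups = max(len(combos), 2)
    df = max(fit.n_obs - len(fit.terms), 1)
    if adjust == "tukey":
        crit = stats.studentized_range.ppf(0.95, n_groups, df) / np.sqrt(2)
    elif adjust == "none":
        crit = Z95
    else:
        raise ValueError(f"unknown adjustment {adjust!r}")
    out = []
    for a, b in pairs:
        L = fit.predict_row(a) - fit.predict_row(b)
        est = float(L @ fit.beta)
        se = float(np.sqrt(L @ fit.cov_beta @ L))
        name = f"{_fmt(a)} - {_fmt(b)}"
        out.append(CoefficientCI(name, est, est - crit * se, est + crit * se))
    return out


def _fmt(d: dict) -> str:
    return "/".join(str(v) for _, v in sorted(d.items()))


def coefficient_table(coefs: list[CoefficientCI], **extra) -> pd.DataFrame:
    """Tidy one-row-per-term table, forest-plot ready."""
    return pd.DataFrame([{
        "term": c.term, "estimate": c.estimate, "lo95": c.lo95,
        "hi95": c.hi95, "significant": c.significant, **extra} for c in coefs])


# ---------------------------------------------------------------------------
# zero-inflated Poisson
# ---------------------------------------------------------------------------

@dataclass
class ZIPFit:
    """Zero-inflated Poisson fit with the year x status interaction test."""

    count_params: pd.Series
    inflate_params: pd.Series
    llf: float
    llf_no_interaction: float
    lrt_stat: float
    lrt_df: int
    lrt_pvalue: float
    converged: bool

    @property
    def pi0(self) -> float:
        """Implied structural-zero probability at the inflation intercept."""
        return float(1.0 / (1.0 + np.exp(-self.inflate_params.iloc[0])))


def to_counts(x: np.ndarray | pd.Series, scale: float = 1.0) -> np.ndarray:
    """Round a continuous non-negative response to integers after scaling.

    Zero-inflated Poisson needs counts; biomass (kg ha-1) and percent cover
    are continuous, so they are scaled (documented, default 1) and rounded.
    """
    arr = np.asarray(x, float) * scale
    if (arr < 0).any():
        raise ValueError("ZIP responses must be non-negative")
    return np.rint(arr).astype(int)


def fit_zip(data: pd.DataFrame, response: str,
            formula: str = "C(year) * C(regime_status)",
            reduced_formula: str = "C(year) + C(regime_status)",
            scale: float = 1.0,
            maxiter: int = 500) -> ZIPFit:
    """Fit ZIP with a logit zero model and LRT for the interaction.

    The zero-inflation component is intercept-only (a single structural-zero
    probability), which keeps the model identifiable at panel sizes of a
    couple of hundred observations.
    """
    y = to_counts(data[response], scale)
    if (y == 0).all():
        raise ValueError("all-zero response: nothing to model")
    if not (y == 0).any():
        warnings.warn("response has no zeros; plain Poisson regression is "
                      "more appropriate", stacklevel=2)

    def _fit(fml: str):
        X = patsy.dmatrix(fml, data, return_type="dataframe")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            m = ZeroInflatedPoisson(y, X, exog_infl=np.ones((len(y), 1)),
                                    inflation="logit")
            return m.fit(method="bfgs", maxiter=maxiter, disp=0), X

    full, Xf = _fit(formula)
    red, Xr = _fit(reduced_formula)
    lrt = max(2.0 * (full.llf - red.llf), 0.0)
    df = Xf.shape[1] - Xr.shape[1]
    pval = float(stats.chi2.sf(lrt, df)) if df > 0 else np.nan

    names = list(Xf.columns)
    params = np.asarray(full.params)
    # statsmodels orders inflation parameters first
    infl = pd.Series(params[:1], index=["inflate_intercept"])
    count = pd.Series(params[1:], index=names)
    return ZIPFit(count_params=count, inflate_params=infl,
                  llf=float(full.llf), llf_no_interaction=float(red.llf),
                  lrt_stat=float(lrt), lrt_df=int(df), lrt_pvalue=pval,
                  converged=bool(full.mle_retvals.get("converged", True)))
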