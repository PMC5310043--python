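"""Weighted mixed model, post hoc contrasts and zero-inflated Poisson."""

import numpy as np
import pandas as pd
import pytest

from reefcarb.simulate import simulate_lmm_panel, simulate_zip
from reefcarb.stats import (
    coefficient_table,
    fit_weighted_lmm,
    fit_zip,
    group_weights,
    posthoc_contrasts,
    to_counts,
)


def _panel(seed=0, **kw):
    return simulate_lmm_panel(np.random.default_rng(seed), **kw)


# -- weights -------------------------------------------------------------------

def test_group_weights_are_reciprocal_variances():
    d = _panel()
    w = group_weights(d, "response")
    cell = d[(d["year"] == 2014) & (d["regime_status"] == "recovered")]
    expected = 1.0 / cell["response"].var()
    assert w.loc[cell.index].unique() == pytest.approx(expected)


def test_group_weights_reject_small_groups():
    d = _panel().iloc[:6]  # several cells left with a single observation
    with pytest.raises(ValueError, match="< 2 observations"):
        group_weights(d, "response")


def test_group_weights_reject_zero_variance():
    d = _panel()
    d.loc[(d["year"] == 1994) & (d["regime_status"] == "recovered"),
          "response"] = 5.0
    with pytest.raises(ValueError, match="zero-variance"):
        group_weights(d, "response")


# -- weighted LMM ----------------------------------------------------------------

def test_equal_weight_fit_matches_statsmodels_mixedlm():
    import statsmodels.formula.api as smf
    d = _panel(seed=3, status_effect=1.0)
    fit = fit_weighted_lmm(d, "response", formula="C(year) + C(regime_status)",
                           standardize=False, sqrt_transform=False)
    sm = smf.mixedlm("response ~ C(year) + C(regime_status)", d,
                     groups=d["reef_id"]).fit(reml=True)
    ours = dict(zip(fit.terms, fit.beta))
    for term, est in ours.items():
        assert est == pytest.approx(sm.params[term], abs=1e-5)
    assert fit.sigma2 == pytest.approx(sm.scale, rel=1e-3)
    assert fit.lambda_ * fit.sigma2 == pytest.approx(
        float(sm.cov_re.iloc[0, 0]), rel=1e-2)


def test_between_reef_terms_use_reef_level_df():
    d = _panel(seed=1)
    fit = fit_weighted_lmm(d, "response", formula="C(year) + C(regime_status)",
                           sqrt_transform=False)
    df = dict(zip(fit.terms, fit.term_df))
    # status never varies within a reef: tested against reefs, not rows
    assert df["C(regime_status)[T.regime_shifted]"] == 21 - 2
    # year varies within every reef: tested against residual rows
    assert df["C(year)[T.2005]"] > 21


def test_standardization_scales_coefficients():
    d = _panel(seed=2, status_effect=2.0)
    raw = fit_weighted_lmm(d, "response", standardize=False,
                           sqrt_transform=False)
    std = fit_weighted_lmm(d, "response", standardize=True,
                           sqrt_transform=False)
    i = std.terms.index("C(regime_status)[T.regime_shifted]")
    assert std.beta[i] * std.response_sd == pytest.approx(raw.beta[i],
                                                          rel=1e-8)


def test_sqrt_transform_rejects_negative_response():
    d = _panel(seed=4)
    with pytest.raises(ValueError, match="sqrt"):
        fit_weighted_lmm(d, "response", sqrt_transform=True)


def test_nonpositive_weights_rejected():
    d = _panel(seed=5)
    with pytest.raises(ValueError, match="positive"):
        fit_weighted_lmm(d, "response", weights=np.zeros(len(d)),
                         sqrt_transform=False)


def test_zero_reef_variance_warns_singular():
    d = _panel(seed=6, reef_sd=0.0)
    with pytest.warns(UserWarning, match="boundary"):
        fit = fit_weighted_lmm(d, "response", sqrt_transform=False)
    assert fit.singular


def test_posthoc_contrasts_wider_with_tukey():
    d = _panel(seed=7, status_effect=1.5)
    fit = fit_weighted_lmm(d, "response", formula="C(year) + C(regime_status)",
                           sqrt_transform=False)
    pairs = [({"year": 2014, "regime_status": "recovered"},
              {"year": 2014, "regime_status": "regime_shifted"})]
    tukey = posthoc_contrasts(fit, pairs, adjust="tukey", n_groups=10)[0]
    plain = posthoc_contrasts(fit, pairs, adjust="none")[0]
    assert tukey.estimate == pytest.approx(plain.estimate)
    assert (tukey.hi95 - tukey.lo95) > (plain.hi95 - plain.lo95)
    with pytest.raises(ValueError, match="adjustment"):
        posthoc_contrasts(fit, pairs, adjust="bonferroni")


def test_coefficient_table_shape():
    d = _panel(seed=8)
    fit = fit_weighted_lmm(d, "response", sqrt_transform=False)
    tbl = coefficient_table(fit.coefficients(), response="net_G")
    assert list(tbl.columns) == ["term", "estimate", "lo95", "hi95",
                                 "significant", "response"]
    assert len(tbl) == len(fit.terms)


# -- zero-inflated Poisson -------------------------------------------------------

def test_to_counts_rejects_negative():
    with pytest.raises(ValueError):
        to_counts(np.array([-1.0, 2.0]))
    np.testing.assert_array_equal(to_counts(np.array([1.4, 2.6])), [1, 3])


def test_fit_zip_rejects_all_zero():
    d = pd.DataFrame({"count": np.zeros(50)})
    with pytest.raises(ValueError, match="all-zero"):
        fit_zip(d, "count", formula="1", reduced_formula="1")


def test_fit_zip_warns_without_zeros():
    d = pd.DataFrame({"count": np.ones(50)})
    with pytest.warns(UserWarning, match="no zeros"):
        fit_zip(d, "count", formula="1", reduced_formula="1")


def test_fit_zip_single_replicate_recovery():
    rng = np.random.default_rng(11)
    y = simulate_zip(rng, n=2000, lam=4.0, pi0=0.3)
    f = fit_zip(pd.DataFrame({"count": y}), "count",
                formula="1", reduced_formula="1")
    assert np.exp(f.count_params.iloc[0]) == pytest.approx(4.0, rel=0.1)
    assert f.pi0 == pytest.approx(0.3, abs=0.05)
    assert f.lrt_df == 0 and np.isnan(f.lrt_pvalue)


def test_fit_zip_interaction_lrt_nonnegative():
    rng = np.random.default_rng(12)
    d = _panel(seed=12)
    d["count"] = simulate_zip(rng, n=len(d), lam=3.0, pi0=0.4)
    f = fit_zip(d, "count")
    assert f.lrt_stat >= 0
    assert f.lrt_df == 4
    assert 0 <= f.lrt_pvalue <= 1
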