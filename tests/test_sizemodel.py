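"""Zero-truncated Poisson herd-size regression and selection rules."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import poisson

from herddens.formula import Term
from herddens.sizemodel import (
    fit_ztp,
    observed_ranges,
    predict_group_size,
    residual_fit_check,
    size_bias_test,
    stepwise_select,
    ztp_logpmf,
    ztp_mean,
    ztp_mu_from_mean,
    ztp_variance,
)


def _rztp(rng, mu):
    mu = np.asarray(mu, dtype=float)
    u = rng.uniform(np.exp(-mu), 1.0)
    return np.maximum(poisson.ppf(u, mu), 1).astype(int)


def test_logpmf_closed_form_and_normalization():
    assert ztp_logpmf(1.0, 1) == pytest.approx(
        np.log(np.exp(-1) / (1 - np.exp(-1))), abs=1e-12
    )
    for mu in (0.3, 1.0, 5.0, 20.0):
        total = np.exp(ztp_logpmf(mu, np.arange(1, 201))).sum()
        assert total == pytest.approx(1.0, abs=1e-9)


def test_pmf_recurrence():
    mu = 2.7
    k = np.arange(1, 30)
    ratio = np.exp(ztp_logpmf(mu, k + 1) - ztp_logpmf(mu, k))
    np.testing.assert_allclose(ratio, mu / (k + 1), rtol=1e-12)


def test_logpmf_rejects_zero():
    with pytest.raises(ValueError):
        ztp_logpmf(1.0, 0)


@pytest.mark.parametrize(
    "mu, expected",
    [(1e-10, 1.0), (1.0, 1 / (1 - np.exp(-1))), (10.0, 10.0 / (1 - np.exp(-10.0)))],
)
def test_ztp_mean_closed_forms(mu, expected):
    assert ztp_mean(mu) == pytest.approx(expected, rel=1e-9)


def test_ztp_mean_exceeds_mu_and_increases():
    mus = np.linspace(0.05, 8, 50)
    m = np.asarray(ztp_mean(mus))
    assert np.all(m > np.maximum(1.0, mus))
    assert np.all(np.diff(m) > 0)


def test_intercept_only_mle_matches_root_of_mean_equation():
    rng = np.random.default_rng(10)
    k = _rztp(rng, np.full(300, 2.5))
    fit = fit_ztp(pd.DataFrame({"size": k}))
    mu_root = ztp_mu_from_mean(k.mean())
    assert np.exp(fit.coef[0]) == pytest.approx(mu_root, abs=1e-8)
    # fitted truncated mean equals the sample mean
    assert ztp_mean(np.exp(fit.coef[0])) == pytest.approx(k.mean(), abs=1e-8)


def test_fit_matches_statsmodels_truncated_poisson():
    """Independent cross-check of coefficients, SEs and loglik."""
    from statsmodels.discrete.truncated_model import TruncatedLFPoisson

    rng = np.random.default_rng(2)
    n = 300
    x = rng.normal(size=n)
    z = (x - x.mean()) / x.std()
    k = _rztp(rng, np.exp(0.8 + 0.4 * z))
    df = pd.DataFrame({"size": k, "x": x})
    fit = fit_ztp(df, (Term("x"),))
    sm_fit = TruncatedLFPoisson(
        k, np.column_stack([np.ones(n), z]), truncation=0
    ).fit(disp=0)
    np.testing.assert_allclose(fit.coef, sm_fit.params, atol=1e-6)
    np.testing.assert_allclose(fit.se, sm_fit.bse, atol=1e-5)
    assert fit.loglik == pytest.approx(sm_fit.llf, abs=1e-6)


def test_parameter_recovery_coverage():
    """95% Wald intervals cover the truth at roughly nominal rate."""
    rng = np.random.default_rng(5)
    beta = np.array([0.9, 0.5])
    R, n = 200, 500
    hit = np.zeros((R, 2))
    x = rng.normal(size=n)
    z = (x - x.mean()) / x.std()
    for r in range(R):
        k = _rztp(rng, np.exp(beta[0] + beta[1] * z))
        fit = fit_ztp(pd.DataFrame({"size": k, "x": x}), (Term("x"),))
        hit[r] = (np.abs(fit.coef - beta) <= 1.96 * fit.se).astype(float)
    cov = hit.mean(axis=0)
    assert np.all(cov >= 0.92) and np.all(cov <= 0.98)


def test_constant_zero_covariate_leaves_loglik_unchanged():
    rng = np.random.default_rng(3)
    k = _rztp(rng, np.full(200, 2.0))
    df = pd.DataFrame({"size": k, "null": np.zeros(200)})
    base = fit_ztp(df, ())
    # a zero-variance covariate standardizes to the zero column
    aug = fit_ztp(df, (Term("null"),))
    assert aug.loglik == pytest.approx(base.loglik, abs=1e-6)


def test_all_ones_response_flagged():
    fit = fit_ztp(pd.DataFrame({"size": np.ones(20, dtype=int)}))
    assert fit.all_ones


def test_size_bias_filter_triggers_on_strong_effect():
    rng = np.random.default_rng(8)
    n = 200
    dist = np.round(rng.uniform(0, 300, n), -1)
    dist[:40] = 0.0
    k = _rztp(rng, np.exp(0.3 + 0.006 * dist))
    d = pd.DataFrame({"distance_m": dist, "size": k})
    p, kept = size_bias_test(d)
    assert p < 0.15
    assert (kept["distance_m"] == 0).all()
    assert len(kept) == (dist == 0).sum()


def test_size_bias_keeps_all_when_independent():
    rng = np.random.default_rng(9)
    n = 400
    d = pd.DataFrame(
        {"distance_m": rng.uniform(0, 300, n), "size": _rztp(rng, np.full(n, 3.0))}
    )
    p, kept = size_bias_test(d, statistic="lr")
    if p >= 0.15:
        assert len(kept) == n


def test_size_bias_error_when_no_online_herds():
    rng = np.random.default_rng(12)
    dist = np.linspace(10, 300, 120)
    k = _rztp(rng, np.exp(0.1 + 0.01 * dist))
    with pytest.raises(ValueError, match="no herds"):
        size_bias_test(pd.DataFrame({"distance_m": dist, "size": k}))


def test_stepwise_retains_strong_term_drops_noise():
    rng = np.random.default_rng(4)
    n = 400
    df = pd.DataFrame({f"n{i}": rng.normal(size=n) for i in range(3)})
    df["x"] = rng.normal(size=n)
    z = (df["x"] - df["x"].mean()) / df["x"].std(ddof=0)
    df["size"] = _rztp(rng, np.exp(0.8 + 0.8 * z))
    cands = (Term("x"), Term("n0"), Term("n1"), Term("n2"))
    sel = stepwise_select(df, cands)
    names = {t.name for t in sel["terms"]}
    assert "x" in names
    assert sel["forward_disagreement"] == ()


def test_stepwise_empty_candidates_gives_intercept_only():
    rng = np.random.default_rng(6)
    df = pd.DataFrame({"size": _rztp(rng, np.full(50, 2.0))})
    sel = stepwise_select(df, ())
    assert sel["terms"] == ()
    assert sel["fit"].n_params == 1


def test_residual_check_near_zero_under_truth():
    rng = np.random.default_rng(7)
    x = rng.normal(size=600)
    z = (x - x.mean()) / x.std()
    k = _rztp(rng, np.exp(0.7 + 0.5 * z))
    fit = fit_ztp(pd.DataFrame({"size": k, "x": x}), (Term("x"),))
    res = residual_fit_check(fit)
    assert res["p_intercept"] > 0.01
    assert res["p_slope"] > 0.01


def test_residual_check_needs_three_obs():
    fit = fit_ztp(pd.DataFrame({"size": [2, 3]}))
    with pytest.raises(ValueError):
        residual_fit_check(fit)


def test_variance_formula_against_moments():
    mu = 1.7
    k = np.arange(1, 400)
    p = np.exp(ztp_logpmf(mu, k))
    m1 = (k * p).sum()
    v = ((k - m1) ** 2 * p).sum()
    assert ztp_mean(mu) == pytest.approx(m1, rel=1e-10)
    assert ztp_variance(mu) == pytest.approx(v, rel=1e-8)


def test_predict_group_size_masking():
    rng = np.random.default_rng(11)
    x = rng.uniform(0, 10, 200)
    z = (x - x.mean()) / x.std()
    df = pd.DataFrame({"size": _rztp(rng, np.exp(0.5 + 0.3 * z)), "x": x})
    fit = fit_ztp(df, (Term("x"),))
    ranges = observed_ranges(df, fit.terms)
    new = pd.DataFrame({"x": [x.min(), x.mean(), x.max() * 1.01]})
    pred = predict_group_size(fit, new, ranges)
    assert not pred["masked"][0] and not pred["masked"][1]
    assert pred["masked"][2] and np.isnan(pred["mean_size"][2])
    # a fitted row reproduces its fitted mean
    row = predict_group_size(fit, df.iloc[[5]], ranges)
    assert row["mean_size"].iloc[0] == pytest.approx(
        float(ztp_mean(fit.fitted_mu[5])), rel=1e-10
    )


def test_filtering_never_increases_sample(small_survey):
    p, kept = size_bias_test(small_survey)
    assert len(kept) <= len(small_survey)
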