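"""Hierarchical distance-sampling likelihood, fitting, prediction, GOF."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit, gammaln

from herddens import TruthParams, generate_design, simulate_survey
from herddens.formula import Term
from herddens.hds import (
    HDSModelSpec,
    build_hds_data,
    default_cutpoints,
    deviance_gof,
    expected_counts,
    fit_hds,
    hds_negloglik,
    predict_hds,
    saturated_loglik,
)


def _toy_segments(n=3, length=1.0):
    return pd.DataFrame(
        {
            "segment_id": np.arange(1, n + 1),
            "length_km": np.full(n, length),
            "region": ["park_west"] * n,
            "u": np.linspace(-1, 1, n),
        }
    )


def test_default_cutpoints_bin_width():
    np.testing.assert_allclose(default_cutpoints(300.0), np.arange(0, 301, 50))
    assert len(default_cutpoints(400.0)) == 9


def test_negloglik_matches_hand_summed_poisson():
    """Brute-force term-by-term Poisson log-pmf on a tiny instance."""
    segs = _toy_segments(3)
    det = pd.DataFrame(
        {
            "segment_id": [1, 1, 2, 3, 3, 3],
            "occasion": [1, 2, 1, 1, 2, 2],
            "distance_m": [10.0, 140.0, 260.0, 30.0, 60.0, 290.0],
            "size": [1] * 6,
        }
    )
    spec = HDSModelSpec((Term("u"),), (), (), "half-normal")
    cut = [0.0, 150.0, 300.0]
    data = build_hds_data(segs, det, spec, w=300.0, cutpoints=cut, n_occasions=2)
    theta = np.array([0.2, 0.3, -0.4, np.log(110.0)])

    # independent oracle: loop over cells, standard Poisson log-pmf
    from herddens.detection import cell_probabilities

    u = segs["u"].to_numpy()
    z = (u - u.mean()) / u.std()
    lam = np.exp(0.2 + 0.3 * z)
    phi = expit(-0.4)
    pi = cell_probabilities("half-normal", cut, 300.0, sigma=110.0)
    area = 2 * 0.3 * 1.0
    ll = 0.0
    for s in range(3):
        for t in range(2):
            for j in range(2):
                y = data.y[s, t, j]
                m = lam[s] * area * phi * pi[j]
                ll += y * np.log(m) - m - gammaln(y + 1)
    assert hds_negloglik(theta, data) == pytest.approx(-ll, abs=1e-10)


def test_negloglik_simple_values():
    """One cell with mean 1 and y=1 contributes exactly 1; all-zero y gives sum of means."""
    segs = _toy_segments(1)
    spec = HDSModelSpec((), None, (), "uniform")
    det = pd.DataFrame(
        {"segment_id": [1], "occasion": [1], "distance_m": [100.0], "size": [1]}
    )
    data = build_hds_data(segs, det, spec, w=300.0, cutpoints=[0.0, 300.0], n_occasions=1)
    # lambda * area = 1 when lambda = 1/area
    area = 2 * 0.3 * 1.0
    theta = np.array([np.log(1 / area)])
    assert hds_negloglik(theta, data) == pytest.approx(1.0, abs=1e-12)

    empty = det.iloc[:0]
    data0 = build_hds_data(
        segs, empty, spec, w=300.0, cutpoints=[0.0, 150.0, 300.0], n_occasions=2
    )
    m = 0.7
    theta0 = np.array([np.log(m / (area * 0.5))])
    # four cells each with mean m/... mean per cell = lam*area*pi = 2m*0.5 = m
    assert hds_negloglik(theta0, data0) == pytest.approx(4 * m, abs=1e-10)


def test_uniform_phi1_closed_form_mle():
    """With g=1 and phi=1 the density MLE is total herds / total strip area."""
    d = generate_design(4, 5, seed=21, n_occasions=6)
    truth = TruthParams(
        lam_intercept=np.log(2.5), phi_intercept=40.0, size_intercept=0.0,
        det_key="uniform", w=300.0,
    )
    det = simulate_survey(d, truth, seed=22)
    spec = HDSModelSpec((), None, (), "uniform")
    data = build_hds_data(d.segments, det, spec, w=300.0, occasions=d.occasions)
    fit = fit_hds(data, tol=1e-14)
    analytic = len(det) / (data.area.sum() * 6)
    assert np.exp(fit.theta[0]) == pytest.approx(analytic, rel=1e-7)


def test_duplicating_data_doubles_loglik(small_design, small_survey):
    spec = HDSModelSpec((Term("area", "cat"),), (Term("survey_day"),), (), "half-normal")
    data = build_hds_data(
        small_design.segments, small_survey, spec, w=300.0,
        occasions=small_design.occasions,
    )
    fit = fit_hds(data)
    data2 = build_hds_data(
        small_design.segments, small_survey, spec, w=300.0,
        occasions=small_design.occasions,
    )
    data2.y = np.concatenate([data2.y, data2.y], axis=1)
    Xr = data2.X_phi.reshape(data.n_segments, data.n_occasions, -1)
    data2.X_phi = np.concatenate([Xr, Xr], axis=1).reshape(-1, Xr.shape[2])
    rng = np.random.default_rng(1)
    for _ in range(5):
        theta = fit.theta + rng.normal(scale=0.3, size=fit.theta.size)
        assert hds_negloglik(theta, data2) == pytest.approx(
            2 * hds_negloglik(theta, data), rel=1e-12
        )
    fit2 = fit_hds(data2, init=fit.theta)
    assert fit2.loglik == pytest.approx(2 * fit.loglik, rel=1e-5)


def test_fit_aic_identity_and_se_shape(small_fit):
    fit = small_fit
    assert fit.converged
    assert fit.aic == pytest.approx(-2 * fit.loglik + 2 * fit.n_params)
    assert np.all(np.isnan(fit.se) | (fit.se >= 0))


def test_predict_intercept_only_inverse_links():
    segs = _toy_segments(4)
    rng = np.random.default_rng(0)
    det = pd.DataFrame(
        {
            "segment_id": rng.integers(1, 5, 30),
            "occasion": rng.integers(1, 4, 30),
            "distance_m": rng.uniform(0, 300, 30),
            "size": np.ones(30, dtype=int),
        }
    )
    spec = HDSModelSpec((), (), (), "uniform")
    data = build_hds_data(segs, det, spec, w=300.0, cutpoints=[0, 300], n_occasions=3)
    fit = fit_hds(data)
    fit.theta = np.array([np.log(2.0), 0.0])
    pred = predict_hds(fit)
    np.testing.assert_allclose(pred["lambda"]["lambda"], 2.0, atol=1e-12)
    np.testing.assert_allclose(pred["phi"]["phi"], 0.5, atol=1e-12)


def test_predictions_reproduce_fitted_means(small_fit):
    """lambda-hat and phi-hat recompose into the likelihood's fitted means."""
    fit = small_fit
    pred = predict_hds(fit)
    lam = pred["lambda"]["lambda"].to_numpy()
    phi = pred["phi"]["phi"].to_numpy().reshape(fit.data.n_segments, -1)
    mu = expected_counts(fit)
    from herddens.detection import cell_probabilities

    sigma = np.exp(fit.data.X_p @ fit.theta[-1:])
    pi = cell_probabilities("half-normal", fit.data.cutpoints, fit.data.w, sigma)
    recomposed = (lam * fit.data.area)[:, None, None] * phi[:, :, None] * pi[:, None, :]
    np.testing.assert_allclose(recomposed, mu, rtol=1e-10)


def test_predict_missing_covariate_rejected(small_fit):
    with pytest.raises(KeyError):
        predict_hds(small_fit, pd.DataFrame({"length_km": [1.0]}))


def test_detections_beyond_w_rejected():
    segs = _toy_segments(1)
    det = pd.DataFrame(
        {"segment_id": [1], "occasion": [1], "distance_m": [301.0], "size": [1]}
    )
    spec = HDSModelSpec((), None, (), "uniform")
    with pytest.raises(ValueError, match="truncate"):
        build_hds_data(segs, det, spec, w=300.0, n_occasions=1)


def test_saturated_deviance_zero_at_observed_means():
    y = np.array([[[2, 0], [1, 3]]])
    ll = saturated_loglik(y)
    mu = np.maximum(y, 1e-300)
    ref = (y * np.log(mu) - mu - gammaln(y + 1.0)).sum() - (
        0 * np.log(1e-300)
    )
    # cells with y=0 contribute -mu = 0 at the saturated means
    by_hand = sum(
        yi * np.log(yi) - yi - gammaln(yi + 1) for yi in y.ravel() if yi > 0
    )
    assert ll == pytest.approx(by_hand, abs=1e-12)


def test_deviance_gof_p_reasonable_under_truth(small_fit):
    res = deviance_gof(small_fit, n_boot=30, seed=4)
    assert res["deviance"] > 0
    assert 0.0 < res["p"] <= 1.0
    assert res["reference"].shape == (30,)


def test_deviance_gof_detects_gross_misfit(small_design, small_truth):
    """A model with lambda misspecified 10x low is rejected."""
    det = simulate_survey(small_design, small_truth, seed=30)
    spec = HDSModelSpec((), None, (), "uniform")
    data = build_hds_data(
        small_design.segments, det, spec, w=300.0, occasions=small_design.occasions
    )
    fit = fit_hds(data)
    # pin the estimate far from the MLE to emulate gross misspecification
    fit.theta = fit.theta - np.log(10.0)
    fit.loglik = -hds_negloglik(fit.theta, data)
    res = deviance_gof(fit, n_boot=40, seed=5)
    assert res["p"] < 0.05


def test_gof_validates_args(small_fit):
    with pytest.raises(ValueError):
        deviance_gof(small_fit, n_boot=0)
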