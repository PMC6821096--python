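"""Density composition, stratified bootstrap, counterfactual contrasts."""

import numpy as np
import pandas as pd
import pytest

from herddens import (
    TruthParams,
    bootstrap_strata,
    compose_density,
    counterfactual_contrasts,
    generate_design,
    simulate_survey,
    truncate_detections,
)
from herddens.formula import Term
from herddens.hds import HDSModelSpec, build_hds_data, fit_hds
from herddens.sizemodel import fit_ztp


def test_truncation_counts_and_identity():
    d = pd.DataFrame(
        {
            "species": ["a", "a", "a", "b"],
            "distance_m": [120.0, 299.0, 310.0, 500.0],
        }
    )
    kept, report = truncate_detections(d, {"a": 300.0, "b": np.inf})
    assert len(kept) == 3
    rep = report.set_index("species")
    assert rep.loc["a", "n_before"] == 3 and rep.loc["a", "n_after"] == 2
    assert rep.loc["b", "n_after"] == 1


def test_truncation_rejects_unknown_species():
    d = pd.DataFrame({"species": ["zebu"], "distance_m": [10.0]})
    with pytest.raises(ValueError, match="unknown species"):
        truncate_detections(d, {"a": 300.0})


def test_compose_density_product_and_masks():
    hd = pd.DataFrame({"segment_id": [1, 2, 3], "herd_density": [2.0, 0.0, 1.5]})
    ms = pd.DataFrame(
        {
            "segment_id": [1, 2, 3],
            "mean_size": [5.0, 7.0, 4.0],
            "masked": [False, False, True],
        }
    )
    out = compose_density(hd, ms)
    assert out.loc[0, "density"] == 10.0
    assert out.loc[1, "density"] == 0.0
    assert np.isnan(out.loc[2, "density"]) and out.loc[2, "masked"]


def test_compose_density_key_mismatch_rejected():
    hd = pd.DataFrame({"segment_id": [1, 2], "herd_density": [1.0, 2.0]})
    ms = pd.DataFrame({"segment_id": [1, 3], "mean_size": [2.0, 2.0]})
    with pytest.raises(ValueError):
        compose_density(hd, ms)


def test_bootstrap_degenerate_and_deterministic():
    surf = pd.DataFrame(
        {"region": ["a"] * 6 + ["b"] * 4, "density": [3.0] * 6 + [5.0] * 4}
    )
    res = bootstrap_strata(surf, ["region"], n_boot=200, seed=1)
    a = res[res["region"] == "a"].iloc[0]
    assert a["mean"] == 3.0
    assert a["ci95_lo"] == 3.0 and a["ci95_hi"] == 3.0
    res2 = bootstrap_strata(surf, ["region"], n_boot=200, seed=1)
    pd.testing.assert_frame_equal(res, res2)


def test_bootstrap_ci_nesting_and_mask_report():
    rng = np.random.default_rng(2)
    surf = pd.DataFrame(
        {
            "region": np.repeat(["a", "b"], 40),
            "density": rng.gamma(2.0, 2.0, 80),
        }
    )
    surf.loc[3, "density"] = np.nan
    res = bootstrap_strata(surf, ["region"], n_boot=500, seed=3)
    for _, r in res.iterrows():
        assert r["ci95_lo"] <= r["ci90_lo"] <= r["ci80_lo"]
        assert r["ci80_hi"] <= r["ci90_hi"] <= r["ci95_hi"]
    assert res.set_index("region").loc["a", "n_masked"] == 1


def test_bootstrap_converges_to_plugin_mean():
    rng = np.random.default_rng(4)
    surf = pd.DataFrame({"region": ["a"] * 50, "density": rng.gamma(3, 1, 50)})
    res = bootstrap_strata(surf, ["region"], n_boot=10_000, seed=5)
    row = res.iloc[0]
    mc_se = surf["density"].std(ddof=1) / np.sqrt(50) / np.sqrt(10_000) * 3
    assert row["boot_mean"] == pytest.approx(row["mean"], abs=3 * mc_se + 1e-3)


def test_bootstrap_rejects_bad_nboot():
    with pytest.raises(ValueError):
        bootstrap_strata(pd.DataFrame({"region": ["a"], "density": [1.0]}), ["region"], 0)


@pytest.fixture(scope="module")
def park_effect_fit():
    design = generate_design(8, 6, seed=51, n_occasions=8)
    truth = TruthParams(
        lam_intercept=np.log(3.0),
        phi_intercept=0.5,
        size_intercept=np.log(3.0),
        lam_coefs={"area=park": 1.0},
        phi_coefs={"survey_day": 1.0},
        det_key="half-normal",
        det_sigma=110.0,
        w=300.0,
    )
    det = simulate_survey(design, truth, seed=52)
    spec = HDSModelSpec(
        (Term("area", "cat"),), (Term("survey_day"),), (), "half-normal"
    )
    data = build_hds_data(
        design.segments, det, spec, w=300.0, occasions=design.occasions
    )
    fit = fit_hds(data)
    sizes = det.merge(design.segments, on="segment_id")
    ztp = fit_ztp(sizes, ())
    return design, fit, ztp


def test_contrast_recovers_park_fold(park_effect_fit):
    """True park effect e^1 on lambda only: fold ~ 2.72 within the 95% CI."""
    design, fit, ztp = park_effect_fit
    res = counterfactual_contrasts(
        fit, ztp, design.segments, "area",
        occasions=design.occasions, n_boot=400, seed=6,
    )
    row = res[res["level"] == "park"].iloc[0]
    assert row["fold_ci95_lo"] <= np.e <= row["fold_ci95_hi"]
    assert row["fold_change"] == pytest.approx(np.e, rel=0.35)


def test_contrast_zero_effect_straddles_one(park_effect_fit):
    design, fit, ztp = park_effect_fit
    import copy

    null = copy.copy(fit)
    null.theta = fit.theta.copy()
    null.theta[1] = 0.0  # remove the park coefficient
    res = counterfactual_contrasts(
        null, ztp, design.segments, "area",
        occasions=design.occasions, n_boot=400, seed=7,
    )
    row = res.iloc[0]
    assert row["fold_change"] == pytest.approx(1.0, abs=1e-9)
    assert row["fold_ci95_lo"] < 1.0 < row["fold_ci95_hi"]


def test_contrast_baseline_reciprocity(park_effect_fit):
    design, fit, ztp = park_effect_fit
    a = counterfactual_contrasts(
        fit, ztp, design.segments, "area",
        occasions=design.occasions, baseline="gma", n_boot=50, seed=8,
    )
    b = counterfactual_contrasts(
        fit, ztp, design.segments, "area",
        occasions=design.occasions, baseline="park", n_boot=50, seed=8,
    )
    fa = a[a["level"] == "park"]["fold_change"].iloc[0]
    fb = b[b["level"] == "gma"]["fold_change"].iloc[0]
    assert fa == pytest.approx(1.0 / fb, rel=1e-9)


def test_contrast_requires_variable_in_model(park_effect_fit):
    design, fit, ztp = park_effect_fit
    with pytest.raises(ValueError, match="contrast undefined"):
        counterfactual_contrasts(
            fit, ztp, design.segments, "veg_class",
            occasions=design.occasions, n_boot=10, seed=9,
        )
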