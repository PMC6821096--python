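"""AIC, Akaike weights, covariate screening, staged selection, averaging."""

import numpy as np
import pandas as pd
import pytest

from herddens import TruthParams, generate_design, simulate_survey
from herddens.formula import Term
from herddens.selection import (
    StagePools,
    aic,
    akaike_weights,
    enumerate_submodels,
    model_average,
    screen_covariates,
    staged_selection,
    term_variants,
)


@pytest.mark.parametrize("ll,k,expected", [(-100.0, 5, 210.0), (0.0, 1, 2.0)])
def test_aic_definition(ll, k, expected):
    assert aic(ll, k) == expected


def test_akaike_weights_sum_shift_invariance_and_symmetry():
    w = akaike_weights([120.0, 120.0])
    np.testing.assert_allclose(w, [0.5, 0.5])
    a = akaike_weights([10.0, 11.5, 14.0])
    b = akaike_weights([110.0, 111.5, 114.0])
    np.testing.assert_allclose(a, b, atol=1e-14)
    assert a.sum() == pytest.approx(1.0)


def test_akaike_weights_published_pair():
    """Two competitors split 0.72/0.28 at a 1.86 AIC gap."""
    w = akaike_weights([0.0, 1.86])
    assert round(float(w[0]), 2) == 0.72
    assert round(float(w[1]), 2) == 0.28


def test_screen_drops_duplicated_covariate():
    rng = np.random.default_rng(0)
    x = rng.normal(size=100)
    df = pd.DataFrame({"a": x, "b": x.copy(), "c": rng.normal(size=100)})
    res = screen_covariates(df, ["a", "b", "c"])
    assert len(res["continuous"]) == 2
    assert len(res["dropped_correlated"]) == 1
    assert "c" in res["continuous"]


def test_screen_keeps_independent_covariates():
    rng = np.random.default_rng(1)
    df = pd.DataFrame({f"v{i}": rng.normal(size=500) for i in range(4)})
    res = screen_covariates(df, list(df.columns))
    assert res["continuous"] == list(df.columns)
    assert res["dropped_correlated"] == []


def test_screen_threshold_boundary():
    rng = np.random.default_rng(2)
    n = 20000

    def make_pair(r):
        x = rng.normal(size=n)
        e = rng.normal(size=n)
        y = r * x + np.sqrt(1 - r * r) * e
        return x, y

    x, y = make_pair(0.61)
    got = screen_covariates(pd.DataFrame({"x": x, "y": y}), ["x", "y"], r_threshold=0.6)
    assert len(got["continuous"]) == 1
    x2, y2 = make_pair(0.40)
    kept = screen_covariates(pd.DataFrame({"x": x2, "y": y2}), ["x", "y"], r_threshold=0.6)
    assert len(kept["continuous"]) == 2


def test_screen_idempotent():
    rng = np.random.default_rng(3)
    x = rng.normal(size=200)
    df = pd.DataFrame({"a": x, "b": x + 0.1 * rng.normal(size=200), "c": rng.normal(size=200)})
    first = screen_covariates(df, ["a", "b", "c"])
    second = screen_covariates(df, first["continuous"])
    assert second["continuous"] == first["continuous"]
    assert second["dropped_correlated"] == []


def test_screen_flags_imbalanced_categorical():
    df = pd.DataFrame({"g": ["a"] * 98 + ["b"] * 2, "x": np.arange(100.0)})
    res = screen_covariates(df, ["x"], ["g"], min_level_count=5)
    assert res["imbalanced"] == ["g"]


def test_enumerate_submodels_counts():
    pool = [Term("g", "cat"), term_variants("x")]
    subs = enumerate_submodels(pool)
    # {} {g} {x:3 forms} {g+x:3} = 8
    assert len(subs) == 8
    capped = enumerate_submodels(pool, max_terms=1)
    assert all(len(s) <= 1 for s in capped)


@pytest.fixture(scope="module")
def selection_run():
    design = generate_design(8, 5, seed=31, n_occasions=8)
    truth = TruthParams(
        lam_intercept=np.log(4.0),
        phi_intercept=0.6,
        size_intercept=np.log(3.0),
        lam_coefs={"area=park": 1.0},
        phi_coefs={"survey_day": 1.0},
        det_key="half-normal",
        det_sigma=110.0,
        w=300.0,
    )
    det = simulate_survey(design, truth, seed=32)
    pools = StagePools(
        detection_variants=((), (Term("veg_class3", "cat"),)),
        detection_keys=("half-normal", "uniform"),
        phi_pool=[Term("survey_day")],
        lam_pools={
            "anthropogenic": [Term("area", "cat")],
            "abiotic": [Term("dist_river_km")],
        },
    )
    stages = staged_selection(
        design.segments, det, design.occasions, pools, w=300.0
    )
    return design, det, stages


def test_staged_selection_stage_structure(selection_run):
    _, _, stages = selection_run
    assert set(stages) == {
        "detection",
        "availability",
        "abundance_anthropogenic",
        "abundance_abiotic",
        "final",
    }
    for cs in stages.values():
        aics = [f.aic for f in cs.fits]
        assert aics == sorted(aics)


def test_staged_selection_recovers_active_terms(selection_run):
    """Only the park effect is active; the final best model carries it."""
    _, _, stages = selection_run
    best = stages["final"].best_spec
    names = {t.name for t in best.lam_terms}
    assert "area" in names
    assert stages["detection"].best_spec.det_key == "half-normal"
    phi_terms = stages["availability"].best_spec.phi_terms
    assert any(t.name == "survey_day" for t in phi_terms)


def test_family_winner_is_exhaustive_minimum(selection_run):
    """Each family's winner has the family's minimum AIC by brute-force refit."""
    _, _, stages = selection_run
    for fam in ("abundance_anthropogenic", "abundance_abiotic"):
        cs = stages[fam]
        assert cs.best.aic == min(f.aic for f in cs.fits)


def test_final_best_never_worse_than_family_winners(selection_run):
    _, _, stages = selection_run
    final_best = stages["final"].best.aic
    for fam in ("abundance_anthropogenic", "abundance_abiotic"):
        # the final pool contains each winner's terms alone
        assert final_best <= stages[fam].best.aic + 1e-6


def test_model_average_single_and_weights(selection_run):
    design, _, stages = selection_run
    final = stages["final"]
    avg = model_average(final, window=2.0)
    assert avg["lambda"].shape == (design.n_segments,)
    assert sum(avg["weights"].values()) == pytest.approx(1.0)
    only_best = model_average(final, window=-1e-12)
    np.testing.assert_allclose(
        sum(only_best["weights"].values()), 1.0
    )


def test_single_candidate_pools_give_single_final_model():
    design = generate_design(4, 4, seed=33, n_occasions=5)
    truth = TruthParams(
        lam_intercept=np.log(3.0), phi_intercept=1.0, size_intercept=0.7,
        det_key="half-normal", det_sigma=100.0, w=300.0,
    )
    det = simulate_survey(design, truth, seed=34)
    pools = StagePools(
        detection_variants=((),),
        detection_keys=("half-normal",),
        phi_pool=[],
        lam_pools={},
    )
    stages = staged_selection(design.segments, det, design.occasions, pools, w=300.0)
    assert len(stages["final"].fits) == 1
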