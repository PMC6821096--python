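import numpy as np
import pytest

from herddens import TruthParams, generate_design, simulate_survey
from herddens.formula import Term
from herddens.hds import HDSModelSpec, build_hds_data, fit_hds


@pytest.fixture(scope="session")
def small_design():
    return generate_design(5, 4, seed=11, n_occasions=4)


@pytest.fixture(scope="session")
def small_truth():
    return TruthParams(
        lam_intercept=np.log(3.0),
        phi_intercept=0.5,
        size_intercept=np.log(3.0),
        lam_coefs={"area=park": 0.6},
        phi_coefs={"survey_day": 1.0},
        size_coefs={"edge_density": 0.3},
        det_key="half-normal",
        det_sigma=120.0,
        w=300.0,
    )


@pytest.fixture(scope="session")
def small_survey(small_design, small_truth):
    return simulate_survey(small_design, small_truth, seed=7)


@pytest.fixture(scope="session")
def small_fit(small_design, small_survey):
    spec = HDSModelSpec(
        lam_terms=(Term("area", "cat"),),
        phi_terms=(Term("survey_day"),),
        p_terms=(),
        det_key="half-normal",
    )
    data = build_hds_data(
        small_design.segments,
        small_survey,
        spec,
        w=300.0,
        occasions=small_design.occasions,
    )
    return fit_hds(data)


@pytest.fixture(scope="session")
def survey_design():
    """Full-scale design: 15 transects, 97 segments, 10 occasions."""
    return generate_design(seed=42)
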