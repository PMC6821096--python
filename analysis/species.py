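"""Shared study conditions for the numbered analysis scripts.

Four synthetic species emulate the contrast structure of the surveyed
community: a very abundant mixed-feeder with strong west-side preference
(impala-like), a river-bound grazer concentrated in the eastern parklands
(puku-like), and two sparser species (zebra-like, warthog-like).  Herd
densities, protection effects, herd sizes and truncation distances follow
the magnitudes reported for the emulated survey; detection is half-normal
within species-specific truncation strips.
"""

from __future__ import annotations

import numpy as np

from herddens.synth import TruthParams

DESIGN_SEED = 42

SPECIES_TRUTH: dict[str, TruthParams] = {
    # abundant, herds ~7-8; large herds more detectable far out
    "impala": TruthParams(
        lam_intercept=float(np.log(1.2)),
        phi_intercept=1.0,
        size_intercept=float(np.log(6.0)),
        lam_coefs={"area=park": 0.6, "side=west": 0.6, "dist_river_km": -0.5},
        phi_coefs={"survey_day": 1.2, "water=present": 0.4},
        size_coefs={"edge_density": 0.25},
        det_key="half-normal",
        det_sigma=120.0,
        w=300.0,
        size_dist_coef=0.25,
    ),
    # strong park effect, east-side preference, river-bound
    "puku": TruthParams(
        lam_intercept=float(np.log(0.45)),
        phi_intercept=1.0,
        size_intercept=float(np.log(5.5)),
        lam_coefs={"area=park": 2.0, "side=west": -1.2, "dist_river_km": -1.0},
        phi_coefs={"survey_day": 1.2},
        size_coefs={"lagoon=present": 0.6},
        det_key="half-normal",
        det_sigma=150.0,
        w=400.0,
        size_dist_coef=0.2,
    ),
    # sparse, strong protection effect, no size-distance bias
    "zebra": TruthParams(
        lam_intercept=float(np.log(0.1)),
        phi_intercept=0.8,
        size_intercept=float(np.log(4.5)),
        lam_coefs={"area=park": 1.8, "side=west": 0.7},
        phi_coefs={"survey_day": 1.0},
        size_coefs={},
        det_key="half-normal",
        det_sigma=130.0,
        w=300.0,
    ),
    # sparse, small herds, moderate protection effect
    "warthog": TruthParams(
        lam_intercept=float(np.log(0.18)),
        phi_intercept=0.8,
        size_intercept=float(np.log(2.0)),
        lam_coefs={"area=park": 1.5},
        phi_coefs={"water=present": 1.0, "survey_day": 0.8},
        size_coefs={},
        det_key="half-normal",
        det_sigma=110.0,
        w=300.0,
    ),
}

TRUNCATION_W = {"impala": 300.0, "puku": 400.0, "zebra": 300.0, "warthog": 300.0}

#: herds recorded within this perpendicular distance count as "on the line"
ON_LINE_TOL_M = 15.0
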