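"""Staged AIC selection of the herd-density model per species.

For each species: truncate detections to the species' strip width, screen
collinear segment covariates, then run the three-step refinement —
detection structure first, availability second, abundance covariates by
family (anthropogenic, abiotic, top-down, bottom-up) third — and rank all
additive combinations of the family winners.  Writes the ranked tables and
the best model's coefficient summary per species.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).parent))
from species import TRUNCATION_W  # noqa: E402

import json

from herddens import screen_covariates, truncate_detections
from herddens.formula import Term
from herddens.io import spec_to_dict
from herddens.selection import StagePools, model_average, staged_selection

ROOT = Path(__file__).resolve().parents[1]
SURVEY = ROOT / "results" / "survey"
OUT = ROOT / "results" / "herd_density"

CONTINUOUS = [
    "edge_density",
    "pct_closed_scrub",
    "pct_closed_woodland",
    "pct_open_woodland",
    "pct_open_grassland",
    "lion_ud",
    "dist_roads_km",
    "dist_river_km",
    "dist_stream_km",
]


def pools_for(screened: list[str]) -> StagePools:
    keep = set(screened)
    veg = [
        Term(c, "log") for c in ("pct_closed_woodland", "pct_open_grassland")
        if c in keep
    ]
    return StagePools(
        detection_variants=((Term("veg_class3", "cat"),), (Term("veg_class", "cat"),)),
        detection_path_term=Term("path_type", "cat"),
        detection_keys=("half-normal", "hazard", "uniform"),
        phi_pool=[Term("survey_day"), Term("water", "cat")],
        lam_pools={
            "anthropogenic": [Term("area", "cat"), Term("side", "cat")],
            "abiotic": [Term("dist_river_km"), Term("dist_stream_km")]
            if "dist_river_km" in keep
            else [],
            "topdown": [Term("lion_ud")] if "lion_ud" in keep else [],
            "edge": [Term("edge_density")] if "edge_density" in keep else [],
            "vegetation": veg,
        },
        max_terms=2,
    )


def main() -> None:
    segments = pd.read_csv(SURVEY / "segments.csv", float_precision="round_trip")
    occasions = pd.read_csv(SURVEY / "occasions.csv", float_precision="round_trip")
    detections = pd.read_csv(SURVEY / "detections.csv", float_precision="round_trip")

    kept, report = truncate_detections(detections, TRUNCATION_W)
    print("truncation:")
    print(report.to_string(index=False))

    screened = screen_covariates(segments, CONTINUOUS, r_threshold=0.6)
    if screened["dropped_correlated"]:
        print("dropped correlated covariates:", screened["dropped_correlated"])
    pools = pools_for(screened["continuous"])

    OUT.mkdir(parents=True, exist_ok=True)
    for species in report["species"]:
        det = kept[kept["species"] == species]
        w = TRUNCATION_W[species]
        stages = staged_selection(
            segments, det, occasions, pools, w=w
        )
        final = stages["final"]
        for name, cs in stages.items():
            cs.table().to_csv(OUT / f"{species}_ranking_{name}.csv", index=False)
        best = final.best
        best.summary().to_csv(OUT / f"{species}_coefficients.csv", index=False)
        (OUT / f"{species}_best_spec.json").write_text(
            json.dumps(spec_to_dict(final.best_spec), indent=2)
        )
        avg = model_average(final, window=2.0)
        n_avg = len(avg["weights"])
        print(
            f"{species:8s}: best AIC {best.aic:.1f} with "
            f"{best.n_params} params; {n_avg} model(s) within the "
            f"averaging window; detection = {stages['detection'].best_spec.det_key}"
        )
        print(f"          best lambda terms: "
              f"{[t.label() for t in final.best_spec.lam_terms]}")
    print(f"wrote rankings and coefficients under {OUT}")


if __name__ == "__main__":
    main()
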