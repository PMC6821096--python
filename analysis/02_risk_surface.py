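"""Build the predator-risk covariate from simulated lion relocations.

Pools correlated-random-walk relocations of several prides around dry
season water points, takes the 90th percentile of daily displacement as
the kernel bandwidth, grids a bivariate-normal utilization distribution at
300 m resolution, and samples it (raw and z-scored) at every segment
midpoint.  The sampled column replaces the placeholder predator covariate
in the segment table.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).parent))
from species import DESIGN_SEED  # noqa: E402

from herddens import extract_standardized, kernel_ud, simulate_relocations, smoothing_bandwidth
from herddens.risk import write_ascii_grid
from herddens.synth import daily_displacements

ROOT = Path(__file__).resolve().parents[1]
SURVEY = ROOT / "results" / "survey"
OUT = ROOT / "results" / "risk"


def main() -> None:
    segments = pd.read_csv(SURVEY / "segments.csv", float_precision="round_trip")

    # prides center on water points strung along the river (x ~ 0 line)
    centers = [(1500.0 * i, 3000.0 * i) for i in range(6)]
    locs = simulate_relocations(
        18, 240, step_scale_m=2500.0, centers=centers, seed=DESIGN_SEED + 7
    )
    disp = daily_displacements(locs)
    h = smoothing_bandwidth(disp, 90)
    print(f"{len(locs)} relocations from {locs['animal_id'].nunique()} animals")
    print(f"daily displacement: median {pd.Series(disp).median():.0f} m, "
          f"90th percentile (bandwidth) {h:.0f} m")

    grid = kernel_ud(locs, h=h, cell_size=300.0)
    mass = grid.values.sum() * grid.cell**2
    print(f"UD grid {grid.values.shape}, integrates to {mass:.4f}")

    pts = segments[["x_mid", "y_mid"]].rename(columns={"x_mid": "x", "y_mid": "y"})
    res = extract_standardized(grid, pts)
    segments["lion_ud"] = res["raw"] / res["raw"].max() * 100.0  # 0-100 scale
    segments["lion_ud_z"] = res["standardized"]
    print(
        f"segment risk: raw range {segments['lion_ud'].min():.1f}-"
        f"{segments['lion_ud'].max():.1f}, z-scored mean 0"
    )

    OUT.mkdir(parents=True, exist_ok=True)
    write_ascii_grid(grid, OUT / "lion_ud.asc")
    segments.to_csv(SURVEY / "segments.csv", index=False, float_format="%.17g")
    print(f"wrote {OUT}/lion_ud.asc and updated segment risk covariate")


if __name__ == "__main__":
    main()
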