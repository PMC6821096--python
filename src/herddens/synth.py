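"""Synthetic stratified line-transect surveys with known ground truth.

The generator emulates the statistical structure of a driven line-transect
study of savanna ungulates across a protection gradient: 15 transects split
into 97 segments (maximum segment length 2 km) spanning three regions (a
national park west of a river, a smaller park section east of it, and a
partially protected game management area), surveyed on 10 occasions across
four dry seasons.  Per segment-occasion the herd super-population is
re-realized as Poisson with covariate-linked log density, thinned by a
logit-linked availability probability, placed uniformly in perpendicular
distance within the truncation strip, detected according to a distance
function, and assigned a covariate-linked zero-truncated Poisson herd size.

Static covariates are drawn to match the observed ranges of the emulated
survey (edge density 3.5-55.6 km/km^2, distances to river/streams/roads,
a predator utilization score, vegetation-cover fractions); dynamic
covariates (dry-season stage, grass condition, burn, water, lagoon) are
occasion-level categorical draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import poisson

from herddens.detection import DetectionFunctionSpec, detection_prob
from herddens.formula import linear_predictor

REGIONS = ("park_west", "park_east", "gma")

#: default region split of the 97 segments (west park / east park / GMA)
DEFAULT_REGION_COUNTS = {"park_west": 62, "park_east": 15, "gma": 20}

#: default transect layout: 15 transects totalling 97 segments
DEFAULT_SEGMENTS_PER_TRANSECT = (7, 7, 7, 7, 7, 7, 7, 6, 6, 6, 6, 6, 6, 6, 6)

VEG_CLASSES6 = (
    "closed_scrub",
    "closed_woodland",
    "open_scrub",
    "open_woodland",
    "open_grassland_flooded",
    "open_grassland_not_flooded",
)
VEG_CLASSES3 = ("scrub", "woodland", "grassland")
PATH_TYPES = ("off_road", "seasonal_track", "gravel_road")
YEARS = (2012, 2012, 2013, 2013, 2013, 2014, 2014, 2014, 2015, 2015)
SEASON_STAGES = ("early", "mid", "late")


@dataclass(frozen=True)
class SurveyDesign:
    """Static survey layout: segment table plus occasion-level conditions."""

    segments: pd.DataFrame
    occasions: pd.DataFrame
    n_occasions: int

    @property
    def n_segments(self) -> int:
        return len(self.segments)


@dataclass(frozen=True)
class TruthParams:
    """Ground-truth parameters for :func:`simulate_survey`.

    Coefficient mappings use :func:`herddens.formula.linear_predictor`
    conventions: continuous covariate names act on the standardized column,
    ``"col=Level"`` keys act on 0/1 indicators.  ``lam`` is log herd density
    (herds/km^2), ``phi`` logit availability, ``size`` the log of the
    zero-truncated Poisson rate.
    """

    lam_intercept: float
    phi_intercept: float
    size_intercept: float
    lam_coefs: Mapping[str, float] = field(default_factory=dict)
    phi_coefs: Mapping[str, float] = field(default_factory=dict)
    size_coefs: Mapping[str, float] = field(default_factory=dict)
    det_key: str = "half-normal"
    det_sigma: float = 100.0
    det_shape_b: float | None = None
    w: float = 300.0
    #: log herd size gained per 100 m of perpendicular distance; emulates
    #: size-biased detection (larger herds visible farther from the line)
    size_dist_coef: float = 0.0

    def detection_spec(self) -> DetectionFunctionSpec:
        if self.det_key == "uniform":
            return DetectionFunctionSpec("uniform")
        return DetectionFunctionSpec(self.det_key, self.det_sigma, self.det_shape_b)


def _region_assignment(total: int, counts: Mapping[str, int] | None) -> np.ndarray:
    if counts is None:
        counts = DEFAULT_REGION_COUNTS
    fracs = np.array([counts[r] for r in REGIONS], dtype=float)
    n = np.floor(fracs / fracs.sum() * total).astype(int)
    while n.sum() < total:
        n[np.argmax(fracs / fracs.sum() * total - n)] += 1
    return np.repeat(np.array(REGIONS, dtype=object), n)


def generate_design(
    n_transects: int = 15,
    segments_per_transect: int | Sequence[int] = DEFAULT_SEGMENTS_PER_TRANSECT,
    seed: int = 0,
    *,
    n_occasions: int = 10,
    region_counts: Mapping[str, int] | None = None,
    max_segment_length_km: float = 2.0,
) -> SurveyDesign:
    """Generate a stratified transect/segment layout with covariates.

    Segments are grouped into transects; contiguous blocks of segments are
    assigned to the three protection regions in proportion to
    ``region_counts`` (defaults: 62/15/20).  Continuous covariates are drawn
    from the ranges observed in the emulated survey; vegetation-cover
    fractions are a Dirichlet draw.
    """
    if n_transects < 1 or n_occasions < 1:
        raise ValueError("counts must be >= 1")
    if np.isscalar(segments_per_transect):
        spt = [int(segments_per_transect)] * n_transects
    else:
        spt = [int(s) for s in segments_per_transect][:n_transects]
        if len(spt) != n_transects:
            raise ValueError("segments_per_transect shorter than n_transects")
    if any(s < 1 for s in spt):
        raise ValueError("counts must be >= 1")
    total = int(sum(spt))
    rng = np.random.default_rng(seed)

    transect_id = np.repeat(np.arange(1, n_transects + 1), spt)
    region = _region_assignment(total, region_counts)
    side = np.where(region == "park_west", "west", "east")
    area = np.where(region == "gma", "gma", "park")

    length = rng.uniform(0.5, max_segment_length_km, size=total)
    cover = rng.dirichlet((0.3, 2.2, 3.6, 3.5), size=total) * 100.0
    # midpoints on a coarse planar grid (m): transects run east-west
    x_mid = np.concatenate([np.arange(s) * 1500.0 + 750.0 for s in spt])
    y_mid = np.repeat(np.arange(n_transects) * 3000.0, spt)

    segments = pd.DataFrame(
        {
            "segment_id": np.arange(1, total + 1),
            "transect_id": transect_id,
            "region": region,
            "side": side,
            "area": area,
            "length_km": length,
            "x_mid": x_mid,
            "y_mid": y_mid,
            "edge_density": rng.uniform(3.5, 55.6, total),
            "pct_closed_scrub": cover[:, 0],
            "pct_closed_woodland": cover[:, 1],
            "pct_open_woodland": cover[:, 2],
            "pct_open_grassland": cover[:, 3],
            "lion_ud": rng.uniform(6.0, 121.1, total),
            "dist_roads_km": rng.uniform(0.0, 2.4, total),
            "dist_river_km": rng.uniform(0.2, 14.7, total),
            "dist_stream_km": rng.uniform(0.0, 9.4, total),
            "veg_class": rng.choice(VEG_CLASSES6, total),
            "veg_class3": rng.choice(VEG_CLASSES3, total),
            "path_type": rng.choice(PATH_TYPES, total),
        }
    )

    occ = pd.MultiIndex.from_product(
        [segments["segment_id"], np.arange(1, n_occasions + 1)],
        names=["segment_id", "occasion"],
    ).to_frame(index=False)
    n = len(occ)
    years = np.array(YEARS, dtype=int)
    occ["year"] = years[(occ["occasion"].to_numpy() - 1) % len(years)]
    occ["season_stage"] = rng.choice(SEASON_STAGES, n)
    occ["grass_height"] = rng.choice(("short", "intermediate", "tall"), n)
    occ["grass_color"] = rng.choice(("green", "brown"), n)
    occ["burn"] = rng.choice(("absent", "present"), n, p=(0.8, 0.2))
    occ["water"] = rng.choice(("absent", "present"), n)
    occ["lagoon"] = rng.choice(("absent", "present"), n, p=(0.7, 0.3))
    # days since the start of the dry season; continuous companion to stage
    occ["survey_day"] = rng.uniform(0.0, 180.0, n)

    return SurveyDesign(segments=segments, occasions=occ, n_occasions=n_occasions)


def _rztp(rng: np.random.Generator, mu: np.ndarray) -> np.ndarray:
    """Zero-truncated Poisson draws by inverse-CDF on the truncated tail."""
    mu = np.asarray(mu, dtype=float)
    lo = np.exp(-mu)  # P(K = 0)
    u = rng.uniform(lo, 1.0)
    k = poisson.ppf(u, mu).astype(int)
    return np.maximum(k, 1)


def simulate_survey(
    design: SurveyDesign, truth: TruthParams, seed: int = 0
) -> pd.DataFrame:
    """Simulate detected herds for every segment-occasion.

    Returns one row per detected herd with ``segment_id``, ``occasion``,
    continuous perpendicular ``distance_m`` in ``[0, W]`` and herd ``size``
    (>= 1).  An empty table (zero detections) is a valid outcome.
    """
    segs = design.segments
    occs = design.occasions.merge(segs, on="segment_id", how="left", suffixes=("", "_seg"))
    rng = np.random.default_rng(seed)

    lam = np.exp(linear_predictor(segs, truth.lam_coefs, truth.lam_intercept))
    area = 2.0 * (truth.w / 1000.0) * segs["length_km"].to_numpy()
    lam_occ = lam[pd.Categorical(occs["segment_id"], categories=segs["segment_id"]).codes]
    area_occ = area[pd.Categorical(occs["segment_id"], categories=segs["segment_id"]).codes]
    phi = expit(linear_predictor(occs, truth.phi_coefs, truth.phi_intercept))
    mu_size = np.exp(linear_predictor(occs, truth.size_coefs, truth.size_intercept))

    n_herds = rng.poisson(lam_occ * area_occ)
    rows = []
    spec = truth.detection_spec()
    for i in np.flatnonzero(n_herds):
        n = n_herds[i]
        avail = rng.uniform(size=n) < phi[i]
        n_av = int(avail.sum())
        if n_av == 0:
            continue
        x = rng.uniform(0.0, truth.w, size=n_av)
        detected = rng.uniform(size=n_av) < detection_prob(spec, x)
        n_det = int(detected.sum())
        if n_det == 0:
            continue
        mu_det = mu_size[i] * np.exp(
            truth.size_dist_coef * x[detected] / 100.0
        )
        sizes = _rztp(rng, mu_det)
        rows.append(
            pd.DataFrame(
                {
                    "segment_id": occs["segment_id"].iat[i],
                    "occasion": occs["occasion"].iat[i],
                    "distance_m": x[detected],
                    "size": sizes,
                }
            )
        )
    if not rows:
        return pd.DataFrame(
            {"segment_id": pd.Series(dtype=int), "occasion": pd.Series(dtype=int),
             "distance_m": pd.Series(dtype=float), "size": pd.Series(dtype=int)}
        )
    return pd.concat(rows, ignore_index=True)


def simulate_relocations(
    n_animals: int,
    n_fixes: int,
    step_scale_m: float,
    centers: Sequence[tuple[float, float]],
    seed: int = 0,
    *,
    persistence: float = 0.6,
    attraction: float = 0.1,
) -> pd.DataFrame:
    """Correlated random-walk relocations around per-animal centers.

    Each animal takes exponential step lengths (mean ``step_scale_m``) with
    directionally persistent headings and a weak pull back toward its
    center.  One fix per animal-day; consecutive fixes yield daily
    displacement distances.
    """
    if n_animals < 1 or n_fixes < 1:
        raise ValueError("counts must be >= 1")
    centers = list(centers)
    if not centers:
        raise ValueError("at least one center required")
    rng = np.random.default_rng(seed)
    rows = []
    for a in range(n_animals):
        cx, cy = centers[a % len(centers)]
        x, y = float(cx), float(cy)
        heading = rng.uniform(0, 2 * np.pi)
        for t in range(n_fixes):
            rows.append((a + 1, t + 1, x, y))
            step = rng.exponential(step_scale_m)
            heading = (
                persistence * heading
                + (1 - persistence) * rng.uniform(0, 2 * np.pi)
            )
            dx, dy = step * np.cos(heading), step * np.sin(heading)
            x = x + dx + attraction * (cx - x)
            y = y + dy + attraction * (cy - y)
    return pd.DataFrame(rows, columns=["animal_id", "fix", "x", "y"])


def daily_displacements(locations: pd.DataFrame) -> np.ndarray:
    """Distances between consecutive fixes, pooled over animals."""
    out = []
    for _, g in locations.sort_values(["animal_id", "fix"]).groupby("animal_id"):
        dx = np.diff(g["x"].to_numpy())
        dy = np.diff(g["y"].to_numpy())
        out.append(np.hypot(dx, dy))
    return np.concatenate(out) if out else np.array([])
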