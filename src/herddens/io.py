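"""Table readers/writers, run configuration, and the end-to-end driver.

Tables are CSV-first (header row, UTF-8, "." decimal); XLSX is accepted
read-only for compatibility with spreadsheet-shaped field data.  The
numbered scripts under ``analysis/`` are the interactive entry points; the
same stages are callable programmatically through :func:`run_pipeline`,
which records seeds and a config hash in a manifest so a run can be
reproduced bit for bit.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from herddens.density import (
    bootstrap_strata,
    compose_density,
    counterfactual_contrasts,
    truncate_detections,
)
from herddens.formula import Term
from herddens.hds import build_hds_data, fit_hds
from herddens.selection import StagePools, model_average, staged_selection
from herddens.sizemodel import (
    fit_ztp,
    observed_ranges,
    predict_group_size,
    size_bias_test,
    stepwise_select,
)

SEGMENT_REQUIRED = ("segment_id", "length_km", "region")
DETECTION_REQUIRED = ("segment_id", "occasion", "distance_m", "size")
OCCASION_REQUIRED = ("segment_id", "occasion")
REGION_LEVELS = ("park_west", "park_east", "gma")


def _read_table(path: Path, rename: Mapping[str, str] | None = None) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() in (".xlsx", ".xls"):
        df = pd.read_excel(path)
    else:
        df = pd.read_csv(path, float_precision="round_trip")
    if rename:
        df = df.rename(columns=dict(rename))
    return df


def _require(df: pd.DataFrame, cols: Sequence[str], what: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{what} table missing columns {missing}")


def read_survey_tables(
    segments_path,
    detections_path,
    occasions_path=None,
    *,
    rename: Mapping[str, str] | None = None,
) -> dict[str, pd.DataFrame]:
    """Read and validate the segment/detection (and occasion) tables.

    Validation failures name the offending rows: negative distances, herd
    sizes below 1, unknown region labels, detections referencing unknown
    segments.
    """
    segments = _read_table(segments_path, rename)
    detections = _read_table(detections_path, rename)
    _require(segments, SEGMENT_REQUIRED, "segment")
    _require(detections, DETECTION_REQUIRED, "detection")

    bad_region = ~segments["region"].astype(str).isin(REGION_LEVELS)
    if bad_region.any():
        rows = segments.index[bad_region].tolist()
        raise ValueError(f"unknown region labels at rows {rows[:10]}")
    dist = detections["distance_m"].to_numpy(dtype=float)
    neg = np.flatnonzero(dist < 0)
    if neg.size:
        raise ValueError(f"negative distances at rows {neg.tolist()[:10]}")
    size = detections["size"].to_numpy(dtype=float)
    bad = np.flatnonzero((size < 1) | (size != np.floor(size)))
    if bad.size:
        raise ValueError(f"invalid herd sizes at rows {bad.tolist()[:10]}")
    unknown = ~detections["segment_id"].isin(segments["segment_id"])
    if unknown.any():
        rows = detections.index[unknown].tolist()
        raise ValueError(f"detections reference unknown segments at rows {rows[:10]}")

    out = {"segments": segments, "detections": detections}
    if occasions_path is not None:
        occasions = _read_table(occasions_path, rename)
        _require(occasions, OCCASION_REQUIRED, "occasion")
        out["occasions"] = occasions
    return out


def write_tables(outdir, **tables: pd.DataFrame) -> None:
    """Write each table as ``<name>.csv`` under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name, df in tables.items():
        # %.17g keeps doubles exact through a write/read cycle
        df.to_csv(outdir / f"{name}.csv", index=False, float_format="%.17g")


def spec_to_dict(spec) -> dict:
    """JSON-serializable record of an HDS model structure."""

    def terms(ts):
        return None if ts is None else [{"name": t.name, "form": t.form} for t in ts]

    return {
        "lam_terms": terms(spec.lam_terms),
        "phi_terms": terms(spec.phi_terms),
        "p_terms": terms(spec.p_terms),
        "det_key": spec.det_key,
    }


def spec_from_dict(d: Mapping) -> "HDSModelSpec":
    from herddens.hds import HDSModelSpec

    def terms(ts):
        return None if ts is None else tuple(Term(t["name"], t["form"]) for t in ts)

    return HDSModelSpec(
        lam_terms=terms(d["lam_terms"]) or (),
        phi_terms=terms(d["phi_terms"]),
        p_terms=terms(d["p_terms"]) or (),
        det_key=d["det_key"],
    )


def _terms_from_config(items) -> tuple[Term, ...]:
    out = []
    for it in items or ():
        if isinstance(it, str):
            out.append(Term(it))
        else:
            out.append(Term(it["name"], it.get("form", "lin")))
    return tuple(out)


@dataclass
class RunConfig:
    """Configuration of one full pipeline run (YAML-serializable)."""

    species: str = "species_a"
    w: float = 300.0
    cutpoints: list[float] | None = None
    n_boot_strata: int = 1000
    n_boot_contrast: int = 500
    stepwise_alpha: float = 0.05
    size_bias_threshold: float = 0.15
    delta_aic_window: float = 2.0
    seed: int = 1
    detection_variants: list[list[dict]] = field(default_factory=lambda: [[{"name": "veg_class3", "form": "cat"}]])
    detection_path: dict | None = None
    detection_keys: list[str] = field(default_factory=lambda: ["half-normal", "hazard", "uniform"])
    phi_pool: list[dict] = field(default_factory=list)
    lam_pools: dict[str, list[dict]] = field(default_factory=dict)
    size_candidates: list[dict] = field(default_factory=list)
    max_terms: int | None = 3

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    def pools(self) -> StagePools:
        return StagePools(
            detection_variants=[_terms_from_config(v) for v in self.detection_variants],
            detection_path_term=(
                Term(self.detection_path["name"], self.detection_path.get("form", "cat"))
                if self.detection_path
                else None
            ),
            detection_keys=tuple(self.detection_keys),
            phi_pool=list(_terms_from_config(self.phi_pool)),
            lam_pools={k: list(_terms_from_config(v)) for k, v in self.lam_pools.items()},
            max_terms=self.max_terms,
        )


def config_hash(config: RunConfig) -> str:
    blob = json.dumps(asdict(config), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def run_pipeline(
    config: RunConfig,
    segments: pd.DataFrame,
    detections: pd.DataFrame,
    occasions: pd.DataFrame,
    outdir,
) -> dict[str, object]:
    """Truncate -> select -> average -> size model -> compose -> bootstrap.

    Writes ranked model tables, fit records, the per-segment density
    surface, stratum summaries, contrasts, and a manifest under ``outdir``
    and returns the in-memory results.  Any stage failure raises with the
    stage name after persisting the outputs produced so far.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, object] = {
        "species": config.species,
        "seed": config.seed,
        "config_sha256": config_hash(config),
        "stages": [],
    }
    results: dict[str, object] = {}

    def _stage(name):
        manifest["stages"].append(name)
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))

    try:
        _stage("truncate")
        detections, trunc_report = truncate_detections(detections, config.w)
        trunc_report.to_csv(outdir / "truncation.csv", index=False)

        _stage("selection")
        stages = staged_selection(
            segments, detections, occasions, config.pools(),
            w=config.w, cutpoints=config.cutpoints,
        )
        for name, cs in stages.items():
            cs.table().to_csv(outdir / f"ranking_{name}.csv", index=False)
        final = stages["final"]
        results["stages"] = stages
        best = final.best
        best.summary().to_csv(outdir / "hds_coefficients.csv", index=False)
        (outdir / "hds_fit.json").write_text(
            json.dumps(
                {
                    "loglik": best.loglik,
                    "aic": best.aic,
                    "converged": best.converged,
                    "n_params": best.n_params,
                },
                indent=2,
            )
        )

        _stage("model_average")
        avg = model_average(final, window=config.delta_aic_window)
        herd_density = pd.DataFrame(
            {
                "segment_id": np.sort(segments["segment_id"].to_numpy()),
                "herd_density": avg["lambda"]
                * avg["phi"].reshape(len(segments), -1).mean(axis=1),
            }
        )
        results["herd_density"] = herd_density

        _stage("size_model")
        p_bias, size_data = size_bias_test(
            detections, threshold=config.size_bias_threshold
        )
        size_data = size_data.merge(segments, on="segment_id", how="left")
        cand = _terms_from_config(config.size_candidates)
        sel = stepwise_select(size_data, cand, alpha=config.stepwise_alpha)
        ztp = sel["fit"]
        ztp.summary().to_csv(outdir / "ztp_coefficients.csv", index=False)
        ranges = observed_ranges(size_data, ztp.terms)
        pred_size = predict_group_size(
            ztp, segments.sort_values("segment_id"), ranges
        )
        mean_size = pd.DataFrame(
            {
                "segment_id": np.sort(segments["segment_id"].to_numpy()),
                "mean_size": pred_size["mean_size"].to_numpy(),
                "masked": pred_size["masked"].to_numpy(),
            }
        )
        results["size_bias_p"] = p_bias
        results["ztp"] = ztp

        _stage("compose")
        surface = compose_density(herd_density, mean_size, on=["segment_id"])
        surface = surface.merge(
            segments[["segment_id", "region"]], on="segment_id", how="left"
        )
        surface.to_csv(outdir / "density_surface.csv", index=False)
        results["surface"] = surface

        _stage("bootstrap")
        strata = bootstrap_strata(
            surface, ["region"], n_boot=config.n_boot_strata, seed=config.seed,
        )
        strata.to_csv(outdir / "stratum_density.csv", index=False)
        results["strata"] = strata

        _stage("contrasts")
        fits_w = [
            (final.fits[i], wt) for i, wt in model_average(
                final, window=config.delta_aic_window
            )["weights"].items()
        ]
        vary = "area" if any(
            t.name == "area" for f, _ in fits_w for t in f.data.lam_info.terms
        ) else "region"
        try:
            contrasts = counterfactual_contrasts(
                fits_w,
                ztp if not ztp.all_ones else None,
                segments,
                vary,
                occasions=occasions,
                n_boot=config.n_boot_contrast,
                seed=config.seed + 1,
            )
            contrasts.to_csv(outdir / "contrasts.csv", index=False)
            results["contrasts"] = contrasts
        except ValueError as e:
            manifest["contrast_note"] = str(e)

        _stage("done")
    except Exception as e:
        manifest["failed_stage"] = manifest["stages"][-1]
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
        raise RuntimeError(
            f"pipeline failed in stage {manifest['stages'][-1]!r}: {e}"
        ) from e
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return results
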