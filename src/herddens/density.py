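"""Population-density composition, stratified bootstrap, and contrasts.

Population density (animals/km^2) per segment is the product of herd
density (herds/km^2, from the distance-sampling layer as ``lambda * phi``)
and expected herd size (from the zero-truncated Poisson layer).  Stratum
(region x year) means carry nonparametric bootstrap confidence intervals;
protection and year effects are isolated by predicting density over a
reference grid in which every covariate other than the stratum variable is
held fixed, propagating coefficient uncertainty by parametric bootstrap.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from herddens.hds import HDSFit, _n_params
from herddens.sizemodel import ZTPFit, ztp_mean

CI_LEVELS = (80, 90, 95)


def truncate_detections(
    detections: pd.DataFrame,
    w_by_species: Mapping[str, float] | float,
    *,
    species_col: str = "species",
    distance_col: str = "distance_m",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop detections beyond the species-specific truncation distance W.

    Returns the filtered table and a per-species report of counts before
    and after truncation.  Unknown species labels are rejected.
    """
    d = detections
    if isinstance(w_by_species, Mapping):
        if species_col not in d.columns:
            raise KeyError(f"detections lack a {species_col!r} column")
        species = d[species_col].astype(str)
        unknown = sorted(set(species) - set(map(str, w_by_species)))
        if unknown:
            raise ValueError(f"unknown species labels {unknown}")
        wmap = {str(k): float(v) for k, v in w_by_species.items()}
        limits = species.map(wmap).to_numpy()
    else:
        species = pd.Series(["all"] * len(d))
        limits = np.full(len(d), float(w_by_species))
    keep = d[distance_col].to_numpy() <= limits
    report = (
        pd.DataFrame({"species": species, "kept": keep})
        .groupby("species")
        .agg(n_before=("kept", "size"), n_after=("kept", "sum"))
        .reset_index()
    )
    return d[keep].reset_index(drop=True), report


def compose_density(
    herd_density: pd.DataFrame,
    mean_size: pd.DataFrame,
    on: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Population density = herd density x expected herd size, elementwise.

    ``herd_density`` must carry a ``herd_density`` column, ``mean_size`` a
    ``mean_size`` column and optionally a boolean ``masked`` column (from
    the covariate-support guard); masked rows propagate as masked density.
    """
    if on is None:
        on = [c for c in ("segment_id", "year") if c in herd_density and c in mean_size]
        if not on:
            raise ValueError("no common key columns to join on")
    merged = herd_density.merge(mean_size, on=list(on), how="inner", validate="1:1")
    if len(merged) != len(herd_density):
        raise ValueError("herd-density and mean-size keys do not align")
    masked = merged["masked"].to_numpy() if "masked" in merged else np.zeros(
        len(merged), dtype=bool
    )
    dens = merged["herd_density"].to_numpy() * np.where(
        masked, np.nan, merged["mean_size"].to_numpy()
    )
    out = merged.copy()
    out["density"] = dens
    out["masked"] = masked
    return out


def _percentile_cis(samples: np.ndarray) -> dict[str, float]:
    out = {}
    for lev in CI_LEVELS:
        a = (100 - lev) / 2
        lo, hi = np.percentile(samples, [a, 100 - a])
        out[f"ci{lev}_lo"] = float(lo)
        out[f"ci{lev}_hi"] = float(hi)
    return out


def bootstrap_strata(
    surface: pd.DataFrame,
    strata: Sequence[str],
    n_boot: int = 1000,
    seed: int = 0,
    *,
    value_col: str = "density",
) -> pd.DataFrame:
    """Stratum means with percentile bootstrap CIs (80/90/95%).

    Rows (segments) are resampled with replacement within each stratum;
    masked rows are excluded with their count reported.  Empty strata are
    reported with NaN summaries rather than dropped silently.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    rng = np.random.default_rng(seed)
    rows = []
    for key, g in surface.groupby(list(strata), dropna=False, sort=True):
        key = key if isinstance(key, tuple) else (key,)
        vals = g[value_col].to_numpy(dtype=float)
        ok = np.isfinite(vals)
        n_masked = int((~ok).sum())
        vals = vals[ok]
        rec = dict(zip(strata, key))
        rec["n"] = vals.size
        rec["n_masked"] = n_masked
        if vals.size == 0:
            rec["mean"] = np.nan
            for lev in CI_LEVELS:
                rec[f"ci{lev}_lo"] = np.nan
                rec[f"ci{lev}_hi"] = np.nan
            rows.append(rec)
            continue
        rec["mean"] = float(vals.mean())
        idx = rng.integers(0, vals.size, size=(n_boot, vals.size))
        boot_means = vals[idx].mean(axis=1)
        rec["boot_mean"] = float(boot_means.mean())
        rec.update(_percentile_cis(boot_means))
        rows.append(rec)
    return pd.DataFrame(rows)


def reference_grid(
    segments: pd.DataFrame,
    vary: str,
    levels: Sequence | None = None,
    occasions: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """One prediction row per level of ``vary``, everything else held fixed.

    Continuous covariates are fixed at their column means; categorical
    covariates at their first (sorted) level — the reference level, which
    is reported by being visible in the grid itself.
    """
    frames = [segments] if occasions is None else [segments, occasions]
    cols: dict[str, object] = {}
    for df in frames:
        for c in df.columns:
            if c in cols or c == vary:
                continue
            s = df[c]
            if pd.api.types.is_numeric_dtype(s):
                cols[c] = float(s.mean())
            else:
                cols[c] = sorted(s.astype(str).unique())[0]
    if levels is None:
        src = next(df for df in frames if vary in df.columns)
        levels = sorted(src[vary].astype(str).unique()) if not pd.api.types.is_numeric_dtype(
            src[vary]
        ) else sorted(src[vary].unique())
    grid = pd.DataFrame([{**cols, vary: lev} for lev in levels])
    return grid


def _predict_density_row(
    fits: Sequence[tuple[HDSFit, float]],
    ztp: ZTPFit | None,
    grid: pd.DataFrame,
    thetas: Sequence[np.ndarray] | None = None,
    beta_size: np.ndarray | None = None,
) -> np.ndarray:
    dens = np.zeros(len(grid))
    for m, (fit, wgt) in enumerate(fits):
        theta = fit.theta if thetas is None else thetas[m]
        p_lam, p_phi, _, _ = _n_params(fit.data)
        lam = np.exp(np.clip(fit.data.lam_info.transform(grid) @ theta[:p_lam], -30, 30))
        if fit.data.X_phi is not None:
            if fit.data.phi_info is not None and fit.data.phi_info.terms:
                Xf = fit.data.phi_info.transform(grid)
            else:
                Xf = np.ones((len(grid), 1))
            from scipy.special import expit

            phi = expit(Xf @ theta[p_lam : p_lam + p_phi])
        else:
            phi = np.ones(len(grid))
        dens += wgt * lam * phi
    if ztp is not None:
        beta = ztp.coef if beta_size is None else beta_size
        mu = np.exp(np.clip(ztp.info.transform(grid) @ beta, -30, 30))
        dens = dens * np.asarray(ztp_mean(mu))
    return dens


def counterfactual_contrasts(
    hds_fits: HDSFit | Sequence[tuple[HDSFit, float]],
    ztp_fit: ZTPFit | None,
    segments: pd.DataFrame,
    vary: str,
    *,
    occasions: pd.DataFrame | None = None,
    baseline: object | None = None,
    levels: Sequence | None = None,
    n_boot: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Protection/year contrasts with all other covariates held constant.

    Predicts density over the reference grid of ``vary`` (e.g. region or
    year), composes herd density x herd size, and reports the difference
    and fold-change of each level against ``baseline`` (default: first
    level).  Uncertainty is propagated by parametric bootstrap from the
    fits' asymptotic coefficient distributions; CIs are percentile at
    80/90/95%.
    """
    fits = [(hds_fits, 1.0)] if isinstance(hds_fits, HDSFit) else list(hds_fits)
    terms: set[str] = set()
    for f, _ in fits:
        if not f.converged:
            raise ValueError("contrasts require converged fits")
        terms |= {t.name for t in f.data.lam_info.terms}
        if f.data.phi_info is not None:
            terms |= {t.name for t in f.data.phi_info.terms}
    if ztp_fit is not None:
        terms |= {t.name for t in ztp_fit.info.terms}
    if vary not in terms:
        raise ValueError(
            f"stratum variable {vary!r} appears in neither model; contrast undefined"
        )

    grid = reference_grid(segments, vary, levels=levels, occasions=occasions)
    level_vals = grid[vary].tolist()
    if baseline is None:
        base_idx = 0
    else:
        if baseline not in level_vals:
            raise ValueError(f"baseline {baseline!r} not among levels {level_vals}")
        base_idx = level_vals.index(baseline)

    point = _predict_density_row(fits, ztp_fit, grid)
    rng = np.random.default_rng(seed)
    draws = np.empty((n_boot, len(grid)))
    chols = []
    for f, _ in fits:
        if f.vcov is None or not np.all(np.isfinite(f.vcov)):
            raise ValueError("coefficient covariance unavailable for a fit")
        V = 0.5 * (f.vcov + f.vcov.T)
        w_eig, U = np.linalg.eigh(V)
        chols.append(U * np.sqrt(np.maximum(w_eig, 0.0)))
    if ztp_fit is not None:
        Vz = 0.5 * (ztp_fit.vcov + ztp_fit.vcov.T)
        wz, Uz = np.linalg.eigh(Vz)
        chol_z = Uz * np.sqrt(np.maximum(wz, 0.0))
    for b in range(n_boot):
        thetas = [
            f.theta + chols[m] @ rng.standard_normal(f.theta.size)
            for m, (f, _) in enumerate(fits)
        ]
        beta_z = (
            ztp_fit.coef + chol_z @ rng.standard_normal(ztp_fit.coef.size)
            if ztp_fit is not None
            else None
        )
        draws[b] = _predict_density_row(fits, ztp_fit, grid, thetas, beta_z)

    rows = []
    base_point = point[base_idx]
    base_draws = draws[:, base_idx]
    for i, lev in enumerate(level_vals):
        if i == base_idx:
            continue
        fold_draws = draws[:, i] / np.maximum(base_draws, 1e-300)
        diff_draws = draws[:, i] - base_draws
        rec = {
            "comparison": f"{vary}={lev} vs {vary}={level_vals[base_idx]}",
            "level": lev,
            "baseline": level_vals[base_idx],
            "density": float(point[i]),
            "baseline_density": float(base_point),
            "fold_change": float(point[i] / base_point) if base_point > 0 else np.nan,
            "difference": float(point[i] - base_point),
        }
        for k, v in _percentile_cis(fold_draws).items():
            rec[f"fold_{k}"] = v
        for k, v in _percentile_cis(diff_draws).items():
            rec[f"diff_{k}"] = v
        rows.append(rec)
    return pd.DataFrame(rows)
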