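"""Generalized multinomial distance sampling with availability.

The model estimates, per transect segment ``i``, the super-population herd
density ``lambda_i`` (herds/km^2, log link), per segment-occasion ``(i, t)``
an availability probability ``phi_it`` (logit link, temporary emigration),
and a distance-dependent detection function ``g(x)`` whose scale ``sigma``
may depend on segment covariates (log link).  With herds placed uniformly in
perpendicular distance over the truncation strip ``[0, W]`` and the herd
super-population re-realized each survey occasion, the detected count in
distance bin ``j`` is Poisson:

    y_ijt ~ Poisson( lambda_i * A_i * phi_it * pi_ij ),

where ``A_i = 2 W L_i`` is the strip area (both sides of the line, km^2) and
``pi_ij`` is the multinomial cell probability of bin ``j`` under the
segment's detection scale.  The likelihood keeps all constant terms so
deviances are well defined.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit, gammaln
from statsmodels.tools.numdiff import approx_fprime, approx_hess

from herddens.detection import DETECTION_KEYS, cell_probabilities
from herddens.formula import DesignInfo, Term

_ETA_CLIP = 35.0


@dataclass(frozen=True)
class HDSModelSpec:
    """Model structure: terms per parameter, detection key, distance bins.

    ``phi_terms=None`` fixes availability at 1 (no phi block); an empty
    tuple fits an intercept-only phi.  The uniform detection key carries no
    parameters, so ``p_terms`` are ignored for it.
    """

    lam_terms: tuple[Term, ...] = ()
    phi_terms: tuple[Term, ...] | None = ()
    p_terms: tuple[Term, ...] = ()
    det_key: str = "half-normal"

    def __post_init__(self) -> None:
        if self.det_key not in DETECTION_KEYS:
            raise ValueError(f"unknown detection key {self.det_key!r}")


def default_cutpoints(w: float, bin_width: float = 50.0) -> np.ndarray:
    """Evenly spaced distance-bin edges from 0 to ``w`` (default 50 m bins)."""
    n = int(round(w / bin_width))
    return np.linspace(0.0, w, n + 1)


@dataclass
class HDSData:
    """Binned survey data plus fitted design matrices for one species."""

    y: np.ndarray  # (S, T, J) integer counts
    area: np.ndarray  # (S,) strip area, km^2
    X_lam: np.ndarray  # (S, p_lam)
    X_phi: np.ndarray | None  # (S*T, p_phi) or None when phi == 1
    X_p: np.ndarray | None  # (S, p_p) or None for uniform key
    cutpoints: np.ndarray
    w: float
    det_key: str
    lam_info: DesignInfo
    phi_info: DesignInfo | None
    p_info: DesignInfo | None
    segment_ids: np.ndarray
    occasion_ids: np.ndarray

    @property
    def n_segments(self) -> int:
        return self.y.shape[0]

    @property
    def n_occasions(self) -> int:
        return self.y.shape[1]

    @property
    def n_bins(self) -> int:
        return self.y.shape[2]


def build_hds_data(
    segments: pd.DataFrame,
    detections: pd.DataFrame,
    spec: HDSModelSpec,
    *,
    w: float,
    cutpoints: Sequence[float] | None = None,
    occasions: pd.DataFrame | None = None,
    n_occasions: int | None = None,
    segment_col: str = "segment_id",
    occasion_col: str = "occasion",
    distance_col: str = "distance_m",
    length_col: str = "length_km",
) -> HDSData:
    """Bin detections and assemble design matrices for :func:`fit_hds`.

    ``occasions`` (one row per segment x occasion, carrying the dynamic
    covariates) is required whenever ``spec.phi_terms`` references
    covariates; otherwise ``n_occasions`` suffices.
    """
    segs = segments.sort_values(segment_col).reset_index(drop=True)
    seg_ids = segs[segment_col].to_numpy()
    if len(np.unique(seg_ids)) != len(seg_ids):
        raise ValueError("duplicate segment ids in segment table")

    if cutpoints is None:
        cutpoints = default_cutpoints(w)
    c = np.asarray(cutpoints, dtype=float)

    if occasions is not None:
        occ_ids = np.sort(pd.unique(occasions[occasion_col]))
        occs = occasions.copy()
        occs["_seg_idx"] = pd.Categorical(
            occs[segment_col], categories=seg_ids
        ).codes
        occs["_occ_idx"] = pd.Categorical(
            occs[occasion_col], categories=occ_ids
        ).codes
        if (occs["_seg_idx"] < 0).any():
            raise ValueError("occasion table references unknown segment ids")
        occs = occs.sort_values(["_seg_idx", "_occ_idx"]).reset_index(drop=True)
        if len(occs) != len(seg_ids) * len(occ_ids):
            raise ValueError("occasion table must cover every segment x occasion")
    elif n_occasions is not None:
        occ_ids = np.arange(1, n_occasions + 1)
        occs = None
    else:
        raise ValueError("provide either an occasions table or n_occasions")

    S, T, J = len(seg_ids), len(occ_ids), len(c) - 1
    y = np.zeros((S, T, J), dtype=np.int64)
    if len(detections):
        d = detections
        dist = np.asarray(d[distance_col], dtype=float)
        bad = np.flatnonzero((dist < 0) | (dist > w))
        if bad.size:
            raise ValueError(
                f"detections outside [0, W={w}] at rows {bad.tolist()[:10]}; "
                "truncate first"
            )
        si = pd.Categorical(d[segment_col], categories=seg_ids).codes
        ti = pd.Categorical(d[occasion_col], categories=occ_ids).codes
        if np.any(si < 0) or np.any(ti < 0):
            raise ValueError("detections reference unknown segments or occasions")
        bi = np.clip(np.searchsorted(c, dist, side="right") - 1, 0, J - 1)
        np.add.at(y, (si, ti, bi), 1)

    lam_info = DesignInfo(spec.lam_terms).fit(segs)
    X_lam = lam_info.transform(segs)

    if spec.phi_terms is None:
        phi_info, X_phi = None, None
    elif len(spec.phi_terms) == 0:
        phi_info = DesignInfo(()).fit(segs)
        X_phi = np.ones((S * T, 1))
    else:
        if occs is None:
            raise ValueError("phi covariates require an occasions table")
        phi_info = DesignInfo(spec.phi_terms).fit(occs)
        X_phi = phi_info.transform(occs)

    if spec.det_key == "uniform":
        p_info, X_p = None, None
    else:
        p_info = DesignInfo(spec.p_terms).fit(segs)
        X_p = p_info.transform(segs)

    lengths = np.asarray(segs[length_col], dtype=float)
    if np.any(lengths <= 0):
        raise ValueError("segment lengths must be positive")
    area = 2.0 * (w / 1000.0) * lengths  # both sides of the line, km^2

    return HDSData(
        y=y,
        area=area,
        X_lam=X_lam,
        X_phi=X_phi,
        X_p=X_p,
        cutpoints=c,
        w=float(w),
        det_key=spec.det_key,
        lam_info=lam_info,
        phi_info=phi_info,
        p_info=p_info,
        segment_ids=seg_ids,
        occasion_ids=np.asarray(occ_ids),
    )


def _n_params(data: HDSData) -> tuple[int, int, int, bool]:
    p_lam = data.X_lam.shape[1]
    p_phi = 0 if data.X_phi is None else data.X_phi.shape[1]
    p_p = 0 if data.X_p is None else data.X_p.shape[1]
    hazard = data.det_key == "hazard"
    return p_lam, p_phi, p_p, hazard


def _unpack(theta: np.ndarray, data: HDSData):
    p_lam, p_phi, p_p, hazard = _n_params(data)
    k = p_lam + p_phi + p_p + int(hazard)
    if theta.shape != (k,):
        raise ValueError(f"theta has length {theta.size}, expected {k}")
    b_lam = theta[:p_lam]
    b_phi = theta[p_lam : p_lam + p_phi]
    b_p = theta[p_lam + p_phi : p_lam + p_phi + p_p]
    log_b = theta[-1] if hazard else None
    return b_lam, b_phi, b_p, log_b


def _expected_counts(theta: np.ndarray, data: HDSData) -> np.ndarray:
    b_lam, b_phi, b_p, log_b = _unpack(np.asarray(theta, dtype=float), data)
    S, T, _ = data.y.shape
    lam = np.exp(np.clip(data.X_lam @ b_lam, -_ETA_CLIP, _ETA_CLIP))
    if data.X_phi is None:
        phi = np.ones((S, T))
    else:
        phi = expit(np.clip(data.X_phi @ b_phi, -_ETA_CLIP, _ETA_CLIP)).reshape(S, T)
    if data.X_p is None:
        pi = cell_probabilities("uniform", data.cutpoints, data.w)
        pi = np.broadcast_to(pi, (S, pi.size))
    else:
        sigma = np.exp(np.clip(data.X_p @ b_p, -12.0, 20.0))
        shape_b = float(np.exp(np.clip(log_b, -10.0, 10.0))) if log_b is not None else None
        pi = cell_probabilities(data.det_key, data.cutpoints, data.w, sigma, shape_b)
    return (lam * data.area)[:, None, None] * phi[:, :, None] * pi[:, None, :]


def hds_negloglik(theta, data: HDSData) -> float:
    """Negative Poisson log-likelihood (constants included)."""
    y = data.y
    if np.any(y < 0):
        raise ValueError("negative counts")
    mu = _expected_counts(theta, data)
    mu = np.maximum(mu, 1e-300)
    nll = mu.sum() - float((y * np.log(mu)).sum()) + float(gammaln(y + 1).sum())
    if not np.isfinite(nll):
        return 1e12
    return nll


def saturated_loglik(y: np.ndarray) -> float:
    """Poisson log-likelihood with means set to the observed counts."""
    y = np.asarray(y, dtype=float)
    pos = y > 0
    return float((y[pos] * np.log(y[pos]) - y[pos] - gammaln(y[pos] + 1)).sum())


@dataclass
class HDSFit:
    """A fitted hierarchical distance-sampling model."""

    spec: HDSModelSpec
    data: HDSData
    theta: np.ndarray
    se: np.ndarray
    loglik: float
    converged: bool
    names: list[str] = field(default_factory=list)
    vcov: np.ndarray | None = None

    @property
    def n_params(self) -> int:
        return self.theta.size

    @property
    def aic(self) -> float:
        return -2.0 * self.loglik + 2.0 * self.n_params

    @property
    def nobs(self) -> int:
        return int(self.data.y.size)

    def summary(self) -> pd.DataFrame:
        z = self.theta / np.where(self.se > 0, self.se, np.nan)
        from scipy.stats import norm

        return pd.DataFrame(
            {
                "term": self.names,
                "estimate": self.theta,
                "se": self.se,
                "z": z,
                "p": 2 * norm.sf(np.abs(z)),
            }
        )


def _param_names(data: HDSData) -> list[str]:
    names = [f"lam:{n}" for n in data.lam_info.names]
    if data.X_phi is not None:
        phi_names = data.phi_info.names if data.phi_info is not None else ["(Intercept)"]
        names += [f"phi:{n}" for n in phi_names]
    if data.X_p is not None:
        names += [f"p:{n}" for n in data.p_info.names]
    if data.det_key == "hazard":
        names += ["p:log_b"]
    return names


def default_init(data: HDSData) -> np.ndarray:
    """Data-informed starting values on the link scales.

    lambda intercept starts at the naive density of detected herds (assuming
    availability x detectability ~ 0.5), sigma at W/2 and the hazard shape at
    2; everything else at zero.  Cold zero starts put sigma at 1 m, where the
    likelihood is numerically flat, so an informed start is used instead.
    """
    p_lam, p_phi, p_p, hazard = _n_params(data)
    theta = np.zeros(p_lam + p_phi + p_p + int(hazard))
    total = data.y.sum()
    T = data.n_occasions
    naive = max(total, 0.5) / (data.area.sum() * T * 0.5)
    theta[0] = np.log(naive)
    if p_p:
        theta[p_lam + p_phi] = np.log(data.w / 2.0)
    if hazard:
        theta[-1] = np.log(2.0)
    return theta


def fit_hds(
    data: HDSData,
    init: np.ndarray | None = None,
    *,
    n_restarts: int = 3,
    seed: int = 0,
    tol: float = 1e-8,
    compute_se: bool = True,
) -> HDSFit:
    """Maximum-likelihood fit by quasi-Newton minimization.

    On non-convergence the optimizer restarts from jittered initial values
    (up to ``n_restarts`` extra attempts); a fit that still fails is
    returned with ``converged=False``, never silently as converged.
    """
    if data.y.size == 0:
        raise ValueError("empty data")
    theta0 = default_init(data) if init is None else np.asarray(init, dtype=float)
    rng = np.random.default_rng(seed)

    best = None
    starts = [theta0] + [
        theta0 + rng.normal(scale=0.5, size=theta0.size) for _ in range(n_restarts)
    ]
    for k, start in enumerate(starts):
        res = minimize(
            hds_negloglik,
            start,
            args=(data,),
            method="L-BFGS-B",
            options={"maxiter": 2000, "ftol": tol, "gtol": 1e-7},
        )
        if best is None or res.fun < best.fun - 1e-10:
            best = res
        if res.success and k == 0:
            break
        if best.success and best.fun <= res.fun + 1e-6:
            break
    res = best

    theta = np.asarray(res.x, dtype=float)
    # Newton polish: quasi-Newton stops near the optimum; one or two exact
    # Newton steps sharpen the MLE to numerical-gradient precision
    fval = float(res.fun)
    for _ in range(2):
        try:
            g = np.atleast_1d(
                np.squeeze(
                    approx_fprime(theta, hds_negloglik, args=(data,), centered=True)
                )
            )
            H = approx_hess(theta, hds_negloglik, args=(data,))
            step = np.asarray(np.linalg.solve(H, g)).ravel()
        except np.linalg.LinAlgError:
            break
        trial = theta - step
        ftrial = hds_negloglik(trial, data)
        # near the optimum the objective change sits below float resolution,
        # so tiny Newton steps are trusted on the gradient alone
        tiny = np.linalg.norm(step) < 1e-4 * max(1.0, np.linalg.norm(theta))
        if np.isfinite(ftrial) and (ftrial <= fval or tiny):
            theta, fval = trial, float(min(ftrial, fval))
        else:
            break
    res.fun = fval

    vcov = None
    se = np.full(theta.size, np.nan)
    if compute_se:
        try:
            H = approx_hess(theta, hds_negloglik, args=(data,))
            vcov = np.linalg.inv(H)
            d = np.diag(vcov)
            se = np.where(d > 0, np.sqrt(np.abs(d)), np.nan)
        except np.linalg.LinAlgError:
            pass

    return HDSFit(
        spec=HDSModelSpec(
            lam_terms=tuple(data.lam_info.terms),
            phi_terms=None if data.X_phi is None else tuple(
                data.phi_info.terms if data.phi_info is not None else ()
            ),
            p_terms=() if data.p_info is None else tuple(data.p_info.terms),
            det_key=data.det_key,
        ),
        data=data,
        theta=theta,
        se=se,
        loglik=-float(res.fun),
        converged=bool(res.success),
        names=_param_names(data),
        vcov=vcov,
    )


def predict_hds(
    fit: HDSFit,
    segments: pd.DataFrame | None = None,
    occasions: pd.DataFrame | None = None,
) -> dict[str, pd.DataFrame]:
    """Inverse-link predictions of lambda (herds/km^2) and phi with SEs.

    With no new data, predicts at the fitting segments/occasions.  Delta
    method SEs use the corresponding block of the coefficient covariance.
    """
    data = fit.data
    p_lam, p_phi, _, _ = _n_params(data)
    out: dict[str, pd.DataFrame] = {}

    if segments is None:
        X = data.X_lam
        idx = data.segment_ids
    else:
        missing = [t.name for t in data.lam_info.terms if t.name not in segments]
        if missing:
            raise KeyError(f"missing covariate columns {missing}")
        X = data.lam_info.transform(segments)
        idx = segments.index.to_numpy()
    eta = X @ fit.theta[:p_lam]
    lam = np.exp(eta)
    se_eta = _block_se(fit, X, 0, p_lam)
    out["lambda"] = pd.DataFrame(
        {"segment_id": idx, "lambda": lam, "se": lam * se_eta}
    )

    if data.X_phi is not None:
        if occasions is None:
            Xf = data.X_phi
            key = pd.DataFrame(
                {
                    "segment_id": np.repeat(data.segment_ids, data.n_occasions),
                    "occasion": np.tile(data.occasion_ids, data.n_segments),
                }
            )
        else:
            if data.phi_info is not None and data.phi_info.terms:
                Xf = data.phi_info.transform(occasions)
            else:
                Xf = np.ones((len(occasions), 1))
            key = None
        eta_f = Xf @ fit.theta[p_lam : p_lam + p_phi]
        phi = expit(eta_f)
        se_f = _block_se(fit, Xf, p_lam, p_lam + p_phi)
        dfp = pd.DataFrame({"phi": phi, "se": phi * (1 - phi) * se_f})
        if key is not None:
            dfp = pd.concat([key, dfp], axis=1)
        out["phi"] = dfp
    else:
        out["phi"] = pd.DataFrame(
            {"phi": np.ones(len(out["lambda"])), "se": np.zeros(len(out["lambda"]))}
        )
    return out


def _block_se(fit: HDSFit, X: np.ndarray, a: int, b: int) -> np.ndarray:
    if fit.vcov is None:
        return np.full(X.shape[0], np.nan)
    V = fit.vcov[a:b, a:b]
    return np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", X, V, X), 0.0))


def expected_counts(fit: HDSFit) -> np.ndarray:
    """Fitted Poisson means, shape (segments, occasions, bins)."""
    return _expected_counts(fit.theta, fit.data)


def deviance_gof(
    fit: HDSFit, n_boot: int = 100, seed: int = 0
) -> dict[str, object]:
    """Deviance goodness of fit with a parametric-bootstrap reference.

    Simulates counts from the fitted means, refits (warm-started at the
    MLE), and returns the observed deviance, the bootstrap deviances and
    the upper-tail p-value.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    if not fit.converged:
        raise ValueError("goodness of fit requires a converged fit")
    mu = expected_counts(fit)
    dev_obs = 2.0 * (saturated_loglik(fit.data.y) - fit.loglik)
    rng = np.random.default_rng(seed)
    ref = np.empty(n_boot)
    for r in range(n_boot):
        yb = rng.poisson(mu)
        data_b = HDSData(
            y=yb,
            area=fit.data.area,
            X_lam=fit.data.X_lam,
            X_phi=fit.data.X_phi,
            X_p=fit.data.X_p,
            cutpoints=fit.data.cutpoints,
            w=fit.data.w,
            det_key=fit.data.det_key,
            lam_info=fit.data.lam_info,
            phi_info=fit.data.phi_info,
            p_info=fit.data.p_info,
            segment_ids=fit.data.segment_ids,
            occasion_ids=fit.data.occasion_ids,
        )
        fb = fit_hds(data_b, init=fit.theta, n_restarts=1, compute_se=False)
        ref[r] = 2.0 * (saturated_loglik(yb) - fb.loglik)
    p = float((np.sum(ref >= dev_obs) + 1) / (n_boot + 1))
    return {"deviance": float(dev_obs), "reference": ref, "p": p}
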