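"""Zero-truncated Poisson (ZTP) regression for herd size.

Herd sizes are integers >= 1: a herd must contain at least one animal to be
detected, so the Poisson is conditioned on exceeding zero,

    P(K = k | K >= 1) = exp(-mu) mu^k / (k! (1 - exp(-mu))),  k >= 1,

with a log link on the rate ``mu``.  The expected herd size is
``mu / (1 - exp(-mu))``.  The module also implements the herd-size
detection-bias rule (regress size on perpendicular distance; if the
association is detectable at p < 0.15, keep only herds recorded on the
transect line), backward/forward likelihood-ratio stepwise selection, a
Pearson-residual fit check, and a covariate-support guard against
extrapolated predictions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq, minimize
from scipy.special import gammaln
from scipy.stats import chi2, norm

from herddens.formula import DesignInfo, Term

_MU_MIN, _MU_MAX = 1e-10, 1e6


def ztp_logpmf(mu, k) -> np.ndarray:
    """Log pmf of the zero-truncated Poisson at ``k >= 1``."""
    mu = np.asarray(mu, dtype=float)
    k = np.asarray(k)
    if np.any(k < 1) or np.any(k != np.floor(k)):
        raise ValueError("zero-truncated support is integers k >= 1")
    if np.any(mu <= 0):
        raise ValueError("mu must be positive")
    k = k.astype(float)
    return k * np.log(mu) - mu - gammaln(k + 1.0) - np.log(-np.expm1(-mu))


def ztp_mean(mu) -> np.ndarray:
    """Expected herd size ``mu / (1 - exp(-mu))``; -> 1 as mu -> 0."""
    mu = np.asarray(mu, dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        m = np.where(mu > 0, mu / -np.expm1(-np.where(mu > 0, mu, 1.0)), 1.0)
    return m if m.ndim else float(m)


def ztp_variance(mu) -> np.ndarray:
    """Variance of the ZTP: ``m * (1 + mu - m)`` with ``m = ztp_mean(mu)``."""
    mu = np.asarray(mu, dtype=float)
    m = np.asarray(ztp_mean(mu))
    v = m * (1.0 + mu - m)
    return v if v.ndim else float(v)


@dataclass
class ZTPFit:
    """A fitted zero-truncated Poisson regression."""

    terms: tuple[Term, ...]
    info: DesignInfo
    coef: np.ndarray
    se: np.ndarray
    vcov: np.ndarray
    loglik: float
    nobs: int
    converged: bool
    names: list[str]
    fitted_mu: np.ndarray
    response: np.ndarray
    all_ones: bool = False

    @property
    def n_params(self) -> int:
        return self.coef.size

    @property
    def aic(self) -> float:
        return -2.0 * self.loglik + 2.0 * self.n_params

    def summary(self) -> pd.DataFrame:
        z = self.coef / np.where(self.se > 0, self.se, np.nan)
        return pd.DataFrame(
            {
                "term": self.names,
                "estimate": self.coef,
                "se": self.se,
                "z": z,
                "p": 2 * norm.sf(np.abs(z)),
                "multiplicative_change": np.exp(self.coef),
            }
        )


def _nll_grad_hess(beta: np.ndarray, X: np.ndarray, k: np.ndarray):
    eta = np.clip(X @ beta, -30.0, 30.0)
    mu = np.exp(eta)
    em = -np.expm1(-mu)  # 1 - exp(-mu)
    ll = k * eta - mu - gammaln(k + 1.0) - np.log(em)
    # d ll / d eta = k - mu - mu * exp(-mu) / (1 - exp(-mu))
    r = np.exp(-mu) / em
    g_eta = k - mu - mu * r
    grad = X.T @ g_eta
    # d2 ll / d eta2 = -mu - d/deta [mu r]; mu r = mu e^-mu/(1-e^-mu)
    # d(mu r)/dmu = r * (1 - mu - mu r); chain with dmu/deta = mu
    h_eta = -mu - mu * (r * (1.0 - mu - mu * r))
    hess = (X * h_eta[:, None]).T @ X
    return -float(ll.sum()), -grad, -hess


def fit_ztp(
    data: pd.DataFrame,
    terms: tuple[Term, ...] = (),
    *,
    response_col: str = "size",
) -> ZTPFit:
    """Maximum-likelihood ZTP regression by Newton-type optimization.

    SEs come from the inverse observed information at the MLE.  An all-ones
    response is flagged (``all_ones=True``) because the rate estimate then
    sits at the ``mu -> 0`` boundary.
    """
    k = np.asarray(data[response_col], dtype=float)
    if len(k) == 0:
        raise ValueError("no observations")
    if np.any(k < 1) or np.any(k != np.floor(k)):
        raise ValueError("herd sizes must be integers >= 1")
    info = DesignInfo(tuple(terms)).fit(data)
    X = info.transform(data)
    all_ones = bool(np.all(k == 1))

    beta0 = np.zeros(X.shape[1])
    beta0[0] = np.log(max(np.mean(k) - 1.0, 0.05))
    res = minimize(
        lambda b: _nll_grad_hess(b, X, k)[:2],
        beta0,
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": 1000, "ftol": 1e-12, "gtol": 1e-9},
    )
    beta = np.asarray(res.x, dtype=float)
    _, _, H = _nll_grad_hess(beta, X, k)
    try:
        vcov = np.linalg.inv(H)
        d = np.diag(vcov)
        se = np.where(d > 0, np.sqrt(np.abs(d)), np.nan)
    except np.linalg.LinAlgError:
        vcov = np.full((beta.size, beta.size), np.nan)
        se = np.full(beta.size, np.nan)
    eta = np.clip(X @ beta, -30.0, 30.0)
    return ZTPFit(
        terms=tuple(terms),
        info=info,
        coef=beta,
        se=se,
        vcov=vcov,
        loglik=-float(res.fun),
        nobs=len(k),
        converged=bool(res.success),
        names=info.names,
        fitted_mu=np.exp(eta),
        response=k,
        all_ones=all_ones,
    )


def size_bias_test(
    detections: pd.DataFrame,
    *,
    threshold: float = 0.15,
    on_line_tol: float = 0.0,
    statistic: str = "wald",
    distance_col: str = "distance_m",
    size_col: str = "size",
) -> tuple[float, pd.DataFrame]:
    """Test whether herd size depends on perpendicular distance.

    Fits a ZTP of size on distance.  If the association is detectable
    (p < ``threshold``; Wald by default, ``statistic="lr"`` for a
    likelihood-ratio test), large herds are over-represented far from the
    line and only herds recorded on the line (distance <= ``on_line_tol``)
    are returned; otherwise all herds are returned.
    """
    if statistic not in ("wald", "lr"):
        raise ValueError("statistic must be 'wald' or 'lr'")
    fit = fit_ztp(detections, (Term(distance_col),), response_col=size_col)
    if statistic == "wald":
        z = fit.coef[1] / fit.se[1]
        p = float(2 * norm.sf(abs(z)))
    else:
        null = fit_ztp(detections, (), response_col=size_col)
        lr = 2.0 * (fit.loglik - null.loglik)
        p = float(chi2.sf(max(lr, 0.0), df=1))
    if p < threshold:
        kept = detections[detections[distance_col] <= on_line_tol]
        if len(kept) == 0:
            raise ValueError(
                "distance-size bias detected but no herds recorded on the line"
            )
        return p, kept.reset_index(drop=True)
    return p, detections.reset_index(drop=True)


def _lr_pvalue(full, reduced) -> float:
    lr = 2.0 * (full.loglik - reduced.loglik)
    df = full.n_params - reduced.n_params
    if df < 1:
        raise ValueError("models must be strictly nested")
    return float(chi2.sf(max(lr, 0.0), df=df))


def stepwise_select(
    data: pd.DataFrame,
    candidate_terms: tuple[Term, ...],
    *,
    alpha: float = 0.05,
    response_col: str = "size",
) -> dict[str, object]:
    """Backward LR elimination confirmed by a forward pass.

    Starting from the full model, repeatedly drops the term with the
    largest LR p-value until every remaining term has p < ``alpha``; then
    attempts to re-add each dropped term and records any disagreement
    between the two passes instead of resolving it silently.
    """
    current = list(candidate_terms)
    fit = fit_ztp(data, tuple(current), response_col=response_col)
    while current:
        pvals = []
        for t in current:
            reduced = [u for u in current if u != t]
            rfit = fit_ztp(data, tuple(reduced), response_col=response_col)
            pvals.append(_lr_pvalue(fit, rfit))
        worst = int(np.argmax(pvals))
        if pvals[worst] < alpha:
            break
        current.pop(worst)
        fit = fit_ztp(data, tuple(current), response_col=response_col)

    dropped = [t for t in candidate_terms if t not in current]
    forward_added = []
    for t in dropped:
        trial = fit_ztp(data, tuple(current + [t]), response_col=response_col)
        if _lr_pvalue(trial, fit) < alpha:
            forward_added.append(t)

    return {
        "terms": tuple(current),
        "fit": fit,
        "forward_disagreement": tuple(forward_added),
    }


def residual_fit_check(fit: ZTPFit) -> dict[str, float]:
    """Regress Pearson residuals on predicted herd sizes.

    An adequate fit leaves both the intercept and slope statistically
    indistinguishable from zero.
    """
    if fit.nobs < 3:
        raise ValueError("need at least 3 observations")
    pred = np.asarray(ztp_mean(fit.fitted_mu))
    resid = (fit.response - pred) / np.sqrt(np.asarray(ztp_variance(fit.fitted_mu)))
    import statsmodels.api as sm

    if np.ptp(pred) == 0.0:
        # constant predictions (intercept-only fit): the slope is undefined,
        # only the mean residual is testable
        ols = sm.OLS(resid, np.ones_like(resid)).fit()
        return {
            "intercept": float(ols.params[0]),
            "slope": 0.0,
            "p_intercept": float(ols.pvalues[0]),
            "p_slope": 1.0,
        }
    X = sm.add_constant(pred)
    ols = sm.OLS(resid, X).fit()
    return {
        "intercept": float(ols.params[0]),
        "slope": float(ols.params[1]),
        "p_intercept": float(ols.pvalues[0]),
        "p_slope": float(ols.pvalues[1]),
    }


def observed_ranges(
    data: pd.DataFrame, terms: tuple[Term, ...]
) -> dict[str, tuple]:
    """Covariate support seen among the herds used for fitting."""
    out: dict[str, tuple] = {}
    for t in terms:
        if t.form == "cat":
            out[t.name] = tuple(sorted(pd.unique(data[t.name].astype(str))))
        else:
            x = np.asarray(data[t.name], dtype=float)
            out[t.name] = (float(x.min()), float(x.max()))
    return out


def predict_group_size(
    fit: ZTPFit,
    newdata: pd.DataFrame,
    ranges: dict[str, tuple] | None = None,
) -> pd.DataFrame:
    """Expected herd size per row, masked outside the observed support.

    Rows whose continuous covariates fall outside the range seen among the
    fitted herds (or whose categorical levels were unseen) get
    ``masked=True`` and no extrapolated value.
    """
    masked = np.zeros(len(newdata), dtype=bool)
    if ranges:
        for name, rng in ranges.items():
            if name not in newdata.columns:
                raise KeyError(f"missing covariate column {name!r}")
            col = newdata[name]
            if all(isinstance(v, str) for v in rng):
                masked |= ~col.astype(str).isin(rng).to_numpy()
            else:
                x = np.asarray(col, dtype=float)
                masked |= (x < rng[0]) | (x > rng[1])
    mean = np.full(len(newdata), np.nan)
    ok = ~masked
    if ok.any():
        X = fit.info.transform(newdata.loc[ok])
        mu = np.exp(np.clip(X @ fit.coef, -30.0, 30.0))
        mean[ok] = np.asarray(ztp_mean(mu))
    return pd.DataFrame(
        {"mean_size": mean, "masked": masked}, index=newdata.index
    )


def ztp_mu_from_mean(target_mean: float) -> float:
    """Invert ``ztp_mean``: the rate whose truncated mean equals ``target``.

    Used as an independent check of the intercept-only MLE, which equates
    the fitted truncated mean with the sample mean.
    """
    if target_mean <= 1.0:
        raise ValueError("a zero-truncated mean must exceed 1")
    f = lambda m: m / -np.expm1(-m) - target_mean
    lo, hi = 1e-8, max(10.0, 2.0 * target_mean)
    while f(hi) < 0:
        hi *= 2.0
    return brentq(f, lo, hi, xtol=1e-12)
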