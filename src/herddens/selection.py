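"""Covariate screening, staged AIC model selection, and model averaging.

Distance-sampling candidate models are refined in three steps so the
candidate space stays tractable: (1) choose the detection structure
(vegetation-class variant x path type x detection key) with intercept-only
availability and abundance; (2) with detection fixed, choose the
availability structure; (3) with both fixed, choose the best abundance
sub-model within each covariate family (abiotic, edge density, top-down,
vegetation availability, anthropogenic) separately, then fit all additive
combinations of the family winners and rank the final set.  Predictions may
then be averaged over closely competing final models using Akaike weights.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import chain, combinations, product
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from herddens.formula import Term
from herddens.hds import HDSData, HDSFit, HDSModelSpec, build_hds_data, fit_hds

CONTINUOUS_FORMS = ("lin", "log", "poly2")


def aic(loglik: float, n_params: int) -> float:
    """Akaike's information criterion, ``-2 loglik + 2 k``."""
    if n_params < 1:
        raise ValueError("n_params must be >= 1")
    return -2.0 * loglik + 2.0 * n_params


def akaike_weights(aics: Sequence[float]) -> np.ndarray:
    """Normalized ``exp(-delta/2)`` weights; invariant to AIC shifts."""
    a = np.asarray(aics, dtype=float)
    d = a - a.min()
    w = np.exp(-d / 2.0)
    return w / w.sum()


def screen_covariates(
    segments: pd.DataFrame,
    continuous: Sequence[str],
    categorical: Sequence[str] = (),
    *,
    r_threshold: float = 0.6,
    min_level_count: int = 5,
) -> dict[str, object]:
    """Drop collinear continuous covariates and flag imbalanced categoricals.

    Among each continuous pair with ``|r| > r_threshold`` the member with
    the smaller variance of its standardized ranks against the rest (i.e.
    lower marginal variance explained, measured as the mean squared
    correlation with the remaining covariates) is dropped — a deterministic
    rule, reported in full.  Categorical covariates with any level observed
    fewer than ``min_level_count`` times are flagged as imbalanced.
    """
    cont = list(continuous)
    dropped: list[tuple[str, str, float]] = []
    if len(cont) > 1:
        X = segments[cont].astype(float)
        while True:
            R = np.corrcoef(X.T) if X.shape[1] > 1 else np.ones((1, 1))
            np.fill_diagonal(R, 0.0)
            i, j = np.unravel_index(np.argmax(np.abs(R)), R.shape)
            if abs(R[i, j]) <= r_threshold:
                break
            # drop the member less correlated with everything else
            score_i = np.mean(R[i] ** 2)
            score_j = np.mean(R[j] ** 2)
            drop = j if score_j <= score_i else i
            keep = i if drop == j else j
            dropped.append((X.columns[drop], X.columns[keep], float(R[i, j])))
            X = X.drop(columns=X.columns[drop])
        cont = list(X.columns)
    imbalanced: list[str] = []
    for c in categorical:
        counts = segments[c].astype(str).value_counts()
        if (counts < min_level_count).any():
            imbalanced.append(c)
    return {
        "continuous": cont,
        "categorical": [c for c in categorical if c not in imbalanced],
        "dropped_correlated": dropped,
        "imbalanced": imbalanced,
    }


def term_variants(name: str, forms: Sequence[str] = CONTINUOUS_FORMS) -> list[Term]:
    """The functional forms considered for one continuous covariate."""
    return [Term(name, f) for f in forms]


def enumerate_submodels(
    pool: Sequence[object],
    *,
    max_terms: int | None = None,
    include_empty: bool = True,
) -> list[tuple[Term, ...]]:
    """All additive sub-models over a pool of terms.

    Pool entries are either a single :class:`Term` (categorical or fixed
    form) or a list of :class:`Term` variants of one covariate, of which at
    most one enters any sub-model.
    """
    groups = [[p] if isinstance(p, Term) else list(p) for p in pool]
    out: list[tuple[Term, ...]] = []
    idx = range(len(groups))
    sizes = range(0 if include_empty else 1, len(groups) + 1)
    for r in sizes:
        if max_terms is not None and r > max_terms:
            break
        for subset in combinations(idx, r):
            for choice in product(*(groups[i] for i in subset)):
                out.append(tuple(choice))
    return out


@dataclass
class CandidateSet:
    """Ranked fits for one selection stage."""

    stage: str
    specs: list[HDSModelSpec]
    fits: list[HDSFit]
    failed: list[HDSModelSpec] = field(default_factory=list)

    def __post_init__(self) -> None:
        order = self._rank_order()
        self.specs = [self.specs[i] for i in order]
        self.fits = [self.fits[i] for i in order]

    def _rank_order(self):
        keys = [
            (f.aic, f.n_params, _spec_label(s))
            for f, s in zip(self.fits, self.specs)
        ]
        return sorted(range(len(keys)), key=lambda i: keys[i])

    @property
    def best(self) -> HDSFit:
        return self.fits[0]

    @property
    def best_spec(self) -> HDSModelSpec:
        return self.specs[0]

    def table(self) -> pd.DataFrame:
        aics = np.array([f.aic for f in self.fits])
        return pd.DataFrame(
            {
                "model": [_spec_label(s) for s in self.specs],
                "n_params": [f.n_params for f in self.fits],
                "aic": aics,
                "delta_aic": aics - aics.min(),
                "weight": akaike_weights(aics),
            }
        )


def _terms_label(terms) -> str:
    if terms is None:
        return "1 (fixed)"
    if not terms:
        return "1"
    return " + ".join(t.label() for t in terms)


def _spec_label(spec: HDSModelSpec) -> str:
    return (
        f"lam~{_terms_label(spec.lam_terms)} | "
        f"phi~{_terms_label(spec.phi_terms)} | "
        f"p[{spec.det_key}]~{_terms_label(spec.p_terms)}"
    )


def model_average(
    cand: CandidateSet,
    newsegments: pd.DataFrame | None = None,
    newoccasions: pd.DataFrame | None = None,
    *,
    window: float = 2.0,
) -> dict[str, object]:
    """Akaike-weighted average of lambda/phi predictions.

    Only models within ``window`` AIC of the stage best enter the average;
    the best model is always included, so the window is never empty.
    """
    from herddens.hds import predict_hds

    aics = np.array([f.aic for f in cand.fits])
    keep = np.flatnonzero(aics - aics.min() <= max(window, 0.0))
    w = akaike_weights(aics[keep])
    lam = None
    phi = None
    for wi, i in zip(w, keep):
        pred = predict_hds(cand.fits[i], newsegments, newoccasions)
        li = pred["lambda"]["lambda"].to_numpy()
        pi = pred["phi"]["phi"].to_numpy()
        lam = wi * li if lam is None else lam + wi * li
        phi = wi * pi if phi is None else phi + wi * pi
    return {
        "lambda": lam,
        "phi": phi,
        "weights": dict(zip(keep.tolist(), w.tolist())),
        "models": [_spec_label(cand.specs[i]) for i in keep],
    }


@dataclass
class StagePools:
    """Candidate covariate pools for the three-step refinement.

    ``detection_variants`` lists alternative (mutually exclusive) detection
    covariate sets, e.g. the two vegetation-class descriptions; the path
    term, when given, may accompany any variant.  ``lam_pools`` maps a
    family name to its term pool (entries as in
    :func:`enumerate_submodels`).
    """

    detection_variants: Sequence[Sequence[Term]] = ((),)
    detection_path_term: Term | None = None
    detection_keys: Sequence[str] = ("half-normal", "hazard", "uniform")
    phi_pool: Sequence[object] = ()
    lam_pools: Mapping[str, Sequence[object]] = field(default_factory=dict)
    max_terms: int | None = None


def _fit_all(
    stage: str,
    specs: Sequence[HDSModelSpec],
    fitter: Callable[[HDSModelSpec], HDSFit],
) -> CandidateSet:
    ok_specs, fits, failed = [], [], []
    for s in specs:
        try:
            f = fitter(s)
        except Exception:
            failed.append(s)
            continue
        if f.converged:
            ok_specs.append(s)
            fits.append(f)
        else:
            failed.append(s)
    if not fits:
        raise RuntimeError(f"no converged candidates in stage {stage!r}")
    return CandidateSet(stage=stage, specs=ok_specs, fits=fits, failed=failed)


def staged_selection(
    segments: pd.DataFrame,
    detections: pd.DataFrame,
    occasions: pd.DataFrame,
    pools: StagePools,
    *,
    w: float,
    cutpoints: Sequence[float] | None = None,
) -> dict[str, CandidateSet]:
    """Run the three-step AIC refinement and the final combination stage.

    Returns every stage's ranked :class:`CandidateSet` under keys
    ``detection``, ``availability``, ``abundance_<family>`` and ``final``.
    Candidates that fail to converge are excluded and recorded in each
    stage's ``failed`` list.
    """

    def fitter(spec: HDSModelSpec) -> HDSFit:
        data = build_hds_data(
            segments, detections, spec, w=w, cutpoints=cutpoints, occasions=occasions
        )
        return fit_hds(data)

    stages: dict[str, CandidateSet] = {}

    det_specs = []
    for key in pools.detection_keys:
        if key == "uniform":
            # a uniform key has no scale to link covariates to
            det_specs.append(HDSModelSpec((), (), (), "uniform"))
            continue
        for variant in pools.detection_variants:
            for with_path in (False, True) if pools.detection_path_term else (False,):
                terms = tuple(variant) + (
                    (pools.detection_path_term,) if with_path else ()
                )
                det_specs.append(HDSModelSpec((), (), terms, key))
    stages["detection"] = _fit_all("detection", det_specs, fitter)
    p_terms = stages["detection"].best_spec.p_terms
    det_key = stages["detection"].best_spec.det_key

    phi_specs = [
        HDSModelSpec((), t, p_terms, det_key)
        for t in enumerate_submodels(pools.phi_pool, max_terms=pools.max_terms)
    ]
    stages["availability"] = _fit_all("availability", phi_specs, fitter)
    phi_terms = stages["availability"].best_spec.phi_terms

    winners: list[tuple[Term, ...]] = []
    for family, pool in pools.lam_pools.items():
        fam_specs = [
            HDSModelSpec(t, phi_terms, p_terms, det_key)
            for t in enumerate_submodels(pool, max_terms=pools.max_terms)
        ]
        cs = _fit_all(f"abundance_{family}", fam_specs, fitter)
        stages[f"abundance_{family}"] = cs
        if cs.best_spec.lam_terms:
            winners.append(cs.best_spec.lam_terms)

    final_specs = []
    seen = set()
    for r in range(len(winners) + 1):
        for combo in combinations(range(len(winners)), r):
            terms = tuple(chain.from_iterable(winners[i] for i in combo))
            if terms in seen:
                continue
            seen.add(terms)
            final_specs.append(HDSModelSpec(terms, phi_terms, p_terms, det_key))
    stages["final"] = _fit_all("final", final_specs, fitter)
    return stages
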