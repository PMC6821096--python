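"""Lightweight model terms and design-matrix construction.

Continuous covariates may enter a linear predictor as a standardized linear
term, a (standardized) log transform, or an orthogonalized second-order
polynomial; categorical covariates enter as treatment-coded indicators.
Transform statistics (means, SDs, log offsets, polynomial orthogonalization
coefficients, category levels) are learned from the fitting data and reused
verbatim for prediction, so fitted and predicted linear predictors share one
basis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

#: continuous forms; "cat" marks a categorical covariate
FORMS = ("lin", "log", "poly2", "poly2log", "cat")


@dataclass(frozen=True)
class Term:
    """One model term: a covariate name plus its functional form."""

    name: str
    form: str = "lin"

    def __post_init__(self) -> None:
        if self.form not in FORMS:
            raise ValueError(f"unknown term form {self.form!r}; expected one of {FORMS}")

    def label(self) -> str:
        if self.form == "lin":
            return self.name
        if self.form == "cat":
            return self.name
        if self.form == "log":
            return f"log({self.name})"
        if self.form == "poly2":
            return f"poly({self.name})"
        return f"poly(log({self.name}))"


def _as_float(x: pd.Series, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"covariate {name!r} contains non-finite values")
    return arr


@dataclass
class _ContinuousStats:
    log: bool
    offset: float
    mean: float
    sd: float
    # orthogonalization of z^2 against [1, z], then its own centering/scale
    poly: bool = False
    ortho: tuple[float, float] = (0.0, 0.0)
    q_mean: float = 0.0
    q_sd: float = 1.0


@dataclass
class DesignInfo:
    """Fitted design-matrix builder for a fixed set of terms.

    Parameters
    ----------
    terms
        Sequence of :class:`Term`.  An intercept column is always included
        first.
    """

    terms: tuple[Term, ...]
    _cont: dict[Term, _ContinuousStats] = field(default_factory=dict)
    _levels: dict[str, tuple] = field(default_factory=dict)
    _fitted: bool = False

    def __init__(self, terms: Sequence[Term] = ()):
        self.terms = tuple(terms)
        self._cont = {}
        self._levels = {}
        self._fitted = False

    def fit(self, df: pd.DataFrame) -> "DesignInfo":
        for t in self.terms:
            if t.name not in df.columns:
                raise KeyError(f"covariate {t.name!r} missing from data")
            if t.form == "cat":
                levels = tuple(sorted(pd.unique(df[t.name].astype(str))))
                if len(levels) < 2:
                    raise ValueError(
                        f"categorical covariate {t.name!r} has a single level"
                    )
                self._levels[t.name] = levels
            else:
                x = _as_float(df[t.name], t.name)
                use_log = t.form in ("log", "poly2log")
                offset = 0.0
                if use_log:
                    if np.any(x < 0):
                        raise ValueError(f"negative values under log for {t.name!r}")
                    if np.any(x == 0):
                        pos = x[x > 0]
                        offset = float(pos.min()) if pos.size else 1.0
                    x = np.log(x + offset)
                mean = float(x.mean())
                sd = float(x.std(ddof=0))
                if sd == 0.0:
                    sd = 1.0
                z = (x - mean) / sd
                st = _ContinuousStats(log=use_log, offset=offset, mean=mean, sd=sd)
                if t.form in ("poly2", "poly2log"):
                    # project z^2 off [1, z] so the two columns are orthogonal
                    z2 = z**2
                    A = np.column_stack([np.ones_like(z), z])
                    coef, *_ = np.linalg.lstsq(A, z2, rcond=None)
                    q = z2 - A @ coef
                    q_sd = float(q.std(ddof=0)) or 1.0
                    st.poly = True
                    st.ortho = (float(coef[0]), float(coef[1]))
                    st.q_mean = float(q.mean())
                    st.q_sd = q_sd
                self._cont[t] = st
        self._fitted = True
        return self

    def transform(self, df: pd.DataFrame) -> np.ndarray:
        if not self._fitted:
            raise RuntimeError("DesignInfo.transform called before fit")
        n = len(df)
        cols: list[np.ndarray] = [np.ones(n)]
        for t in self.terms:
            if t.form == "cat":
                levels = self._levels[t.name]
                vals = df[t.name].astype(str).to_numpy()
                unknown = set(vals) - set(levels)
                if unknown:
                    raise ValueError(
                        f"unseen level(s) {sorted(unknown)} for covariate {t.name!r}"
                    )
                for lev in levels[1:]:
                    cols.append((vals == lev).astype(float))
            else:
                st = self._cont[t]
                x = _as_float(df[t.name], t.name)
                if st.log:
                    x = np.log(x + st.offset)
                z = (x - st.mean) / st.sd
                cols.append(z)
                if st.poly:
                    q = z**2 - st.ortho[0] - st.ortho[1] * z
                    cols.append((q - st.q_mean) / st.q_sd)
        return np.column_stack(cols)

    @property
    def names(self) -> list[str]:
        out = ["(Intercept)"]
        for t in self.terms:
            if t.form == "cat":
                for lev in self._levels[t.name][1:]:
                    out.append(f"{t.name}:{lev}")
            else:
                out.append(t.label())
                if t.form in ("poly2", "poly2log"):
                    out.append(t.label() + "^2")
        return out

    @property
    def n_params(self) -> int:
        return len(self.names)

    def fit_transform(self, df: pd.DataFrame) -> np.ndarray:
        return self.fit(df).transform(df)


def linear_predictor(
    df: pd.DataFrame, coefs: Mapping[str, float], intercept: float = 0.0
) -> np.ndarray:
    """Evaluate ``intercept + sum(coef * column)`` for simulation truths.

    Keys of the form ``"col"`` use the column standardized in-place
    (mean 0, SD 1 over ``df``); keys of the form ``"col=Level"`` use the
    0/1 indicator of that level.  Constant columns contribute zero.
    """
    eta = np.full(len(df), float(intercept))
    for key, b in coefs.items():
        if "=" in key:
            col, lev = key.split("=", 1)
            x = (df[col].astype(str).to_numpy() == lev).astype(float)
            eta += b * x
        else:
            x = np.asarray(df[key], dtype=float)
            sd = x.std()
            z = (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)
            eta += b * z
    return eta
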