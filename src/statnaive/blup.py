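"""Stage 1: cleaning, standardization and longitudinal BLUPs.

Risk-factor measurement streams (SBP, total cholesterol, HDL, smoking)
are cleaned with biological-plausibility bounds, then modelled jointly
with a landmark-specific multivariate linear mixed model: per-factor
fixed intercept and linear trend in (measurement age - landmark age),
correlated person-level random intercepts across the four factors, and
factor-specific residual variances.  The fitted model yields best linear
unbiased predictors (BLUPs) — shrunken "error-free" factor values at the
landmark age — for every eligible person, including persons with some or
all factors unobserved (borrowing strength through the random-intercept
covariance).

The marginal likelihood is maximized by EM.  Because each observation
belongs to exactly one factor, the per-person information matrix
Z' R^-1 Z is diagonal (observation counts over residual variances), so
the E-step vectorizes over persons with batched 4x4 solves.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .synthetic import FACTORS

_FIDX = {f: i for i, f in enumerate(FACTORS)}
_STD_FACTORS = ("sbp", "tc", "hdl")  # smoking stays on the probability scale


@dataclass
class CleaningRules:
    """Per-factor plausibility bounds (closed at the bound)."""

    bounds: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "sbp": (60.0, 250.0),
            "tc": (1.75, 20.0),
            "hdl": (0.3, 3.1),
        }
    )

    def __post_init__(self) -> None:
        for f, (lo, hi) in self.bounds.items():
            if f not in _FIDX:
                raise ValueError(f"unknown factor {f!r}")
            if not lo < hi:
                raise ValueError(f"bounds for {f!r} must satisfy lower < upper")


def clean_measurements(
    measurements: pd.DataFrame, rules: CleaningRules | None = None
) -> tuple[pd.DataFrame, int]:
    """Set biologically implausible values to missing (value-wise).

    Returns the cleaned table and the number of values removed.
    """
    rules = rules or CleaningRules()
    unknown = set(measurements["factor"].unique()) - set(FACTORS)
    if unknown:
        raise ValueError(f"unknown factor name(s): {sorted(unknown)}")
    out = measurements.copy()
    removed = 0
    for f, (lo, hi) in rules.bounds.items():
        sel = out["factor"] == f
        bad = sel & ((out["value"] < lo) | (out["value"] > hi))
        removed += int(bad.sum())
        out.loc[bad, "value"] = np.nan
    return out, removed


def standardization_constants(
    measurements: pd.DataFrame, persons: pd.DataFrame
) -> dict[str, dict[str, tuple[float, float]]]:
    """Sex-specific (mean, SD) of the first post-entry measurement per
    person for SBP/TC/HDL; used to standardize BLUPs."""
    m = measurements.merge(persons[["id", "sex", "entry_age"]], on="id")
    m = m[(m["age"] >= m["entry_age"]) & m["value"].notna()]
    out: dict[str, dict[str, tuple[float, float]]] = {}
    for sex in ("M", "F"):
        out[sex] = {}
        for f in _STD_FACTORS:
            sub = m[(m["sex"] == sex) & (m["factor"] == f)]
            first = sub.sort_values("age", kind="stable").groupby("id")["value"].first()
            if len(first) >= 2 and first.std(ddof=1) > 0:
                out[sex][f] = (float(first.mean()), float(first.std(ddof=1)))
            else:
                out[sex][f] = (0.0, 1.0)
    return out


@dataclass
class MixedFit:
    """Fitted landmark-specific multivariate mixed model."""

    landmark_age: float
    sex: str
    intercepts: np.ndarray  # (4,) per-factor value at the landmark age
    slopes: np.ndarray  # (4,) per year of (age - landmark)
    Sigma_u: np.ndarray  # (4, 4) random-intercept covariance
    resid_var: np.ndarray  # (4,) residual variances
    standardization: dict  # sex -> factor -> (mean, sd)
    loglik: float = np.nan
    n_iter: int = 0
    converged: bool = True
    empty_factors: tuple = ()

    def to_json(self, path: str | Path) -> None:
        payload = {
            "format": "statnaive.MixedFit/1",
            "landmark_age": self.landmark_age,
            "sex": self.sex,
            "intercepts": self.intercepts.tolist(),
            "slopes": self.slopes.tolist(),
            "Sigma_u": self.Sigma_u.tolist(),
            "resid_var": self.resid_var.tolist(),
            "standardization": {
                s: {f: list(v) for f, v in d.items()}
                for s, d in self.standardization.items()
            },
            "loglik": self.loglik,
            "n_iter": self.n_iter,
            "converged": self.converged,
            "empty_factors": list(self.empty_factors),
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "MixedFit":
        d = json.loads(Path(path).read_text())
        if d.pop("format") != "statnaive.MixedFit/1":
            raise ValueError("unrecognized MixedFit file format")
        return cls(
            landmark_age=d["landmark_age"],
            sex=d["sex"],
            intercepts=np.array(d["intercepts"]),
            slopes=np.array(d["slopes"]),
            Sigma_u=np.array(d["Sigma_u"]),
            resid_var=np.array(d["resid_var"]),
            standardization={
                s: {f: tuple(v) for f, v in dd.items()}
                for s, dd in d["standardization"].items()
            },
            loglik=d["loglik"],
            n_iter=d["n_iter"],
            converged=d["converged"],
            empty_factors=tuple(d["empty_factors"]),
        )


_DIFFUSE_SIGMA = {"sbp": 15.0**2, "tc": 1.0, "hdl": 0.16, "smoking": 0.09}
_DIFFUSE_RESID = {"sbp": 10.0**2, "tc": 0.36, "hdl": 0.04, "smoking": 0.25}


def _prepare(measurements: pd.DataFrame, landmark_age: float, lookback: float):
    m = measurements[measurements["value"].notna()]
    m = m[(m["age"] >= landmark_age - lookback) & (m["age"] <= landmark_age)]
    pid, person_ids = pd.factorize(m["id"], sort=True)
    fidx = m["factor"].map(_FIDX).to_numpy()
    t = (m["age"] - landmark_age).to_numpy()
    y = m["value"].to_numpy(dtype=float)
    return pid, np.asarray(person_ids), fidx, t, y


def _estep(pid, fidx, t, y, n_persons, beta0, beta1, Sigma, resid_var):
    """Posterior moments of the random intercepts and the marginal loglik."""
    r = y - beta0[fidx] - beta1[fidx] * t
    w = 1.0 / resid_var[fidx]
    # per-person, per-factor sufficient statistics
    counts = np.zeros((n_persons, 4))
    np.add.at(counts, (pid, fidx), w)
    s = np.zeros((n_persons, 4))
    np.add.at(s, (pid, fidx), w * r)

    Sinv = np.linalg.inv(Sigma)
    prec = Sinv[None, :, :] + counts[:, :, None] * np.eye(4)[None, :, :]
    V = np.linalg.inv(prec)
    b = np.einsum("nij,nj->ni", V, s)

    # marginal loglik: sum over obs of N(r; 0, R) corrected by the
    # determinant lemma and the quadratic completion
    sign, logdet_prec = np.linalg.slogdet(prec)
    _, logdet_Sigma = np.linalg.slogdet(Sigma)
    quad = np.sum(w * r * r) - np.einsum("ni,ni->", s, b)
    loglik = -0.5 * (
        len(y) * np.log(2 * np.pi)
        + np.sum(np.log(resid_var[fidx]))
        + n_persons * logdet_Sigma
        + logdet_prec.sum()
        + quad
    )
    return b, V, loglik


def fit_multivariate_mixed(
    measurements: pd.DataFrame,
    landmark_age: float,
    sex: str,
    lookback: float = 10.0,
    standardization: dict | None = None,
    max_iter: int = 500,
    rtol: float = 1e-8,
) -> MixedFit:
    """Fit the four-factor mixed model by EM on measurements within
    [landmark_age - lookback, landmark_age].

    Non-convergence is flagged, not raised.  A factor with zero
    observations keeps diffuse default variances (uncorrelated with the
    rest) and is listed in ``empty_factors``; its BLUPs reduce to the
    population default.
    """
    pid, person_ids, fidx, t, y = _prepare(measurements, landmark_age, lookback)
    n_persons = len(person_ids)
    if n_persons < 2:
        raise ValueError("need measurements from at least 2 persons")

    n_f = np.bincount(fidx, minlength=4)
    empty = tuple(FACTORS[j] for j in range(4) if n_f[j] == 0)

    # initial values: factor means/variances split between levels
    beta0 = np.array(
        [y[fidx == j].mean() if n_f[j] else 0.0 for j in range(4)]
    )
    beta1 = np.zeros(4)
    var0 = np.array(
        [
            y[fidx == j].var() if n_f[j] > 1 else _DIFFUSE_SIGMA[FACTORS[j]]
            for j in range(4)
        ]
    )
    var0 = np.maximum(var0, 1e-8)
    Sigma = np.diag(np.where(n_f > 0, var0 / 2, [ _DIFFUSE_SIGMA[f] for f in FACTORS ]))
    resid_var = np.where(
        n_f > 0, var0 / 2, [_DIFFUSE_RESID[f] for f in FACTORS]
    ).astype(float)

    last = -np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        b, V, loglik = _estep(pid, fidx, t, y, n_persons, beta0, beta1, Sigma, resid_var)

        # M-step: random-effect covariance
        Sigma_new = (np.einsum("ni,nj->ij", b, b) + V.sum(axis=0)) / n_persons
        for j, f in enumerate(FACTORS):
            if n_f[j] == 0:  # keep diffuse, uncorrelated
                Sigma_new[j, :] = 0.0
                Sigma_new[:, j] = 0.0
                Sigma_new[j, j] = _DIFFUSE_SIGMA[f]
        Sigma = Sigma_new

        # M-step: fixed effects (per-factor WLS of y - b on [1, t]) and
        # residual variances
        r_fix = y - b[pid, fidx]
        for j in range(4):
            sel = fidx == j
            if not sel.any():
                continue
            X = np.column_stack([np.ones(sel.sum()), t[sel]])
            coef, *_ = np.linalg.lstsq(X, r_fix[sel], rcond=None)
            beta0[j], beta1[j] = coef
            resid = r_fix[sel] - X @ coef
            resid_var[j] = np.mean(resid**2 + V[pid[sel], j, j])
            resid_var[j] = max(resid_var[j], 1e-10)

        if np.isfinite(last) and np.abs(loglik - last) <= rtol * (np.abs(last) + 1.0):
            converged = True
            break
        last = loglik

    _, _, loglik = _estep(pid, fidx, t, y, n_persons, beta0, beta1, Sigma, resid_var)
    return MixedFit(
        landmark_age=landmark_age,
        sex=sex,
        intercepts=beta0,
        slopes=beta1,
        Sigma_u=Sigma,
        resid_var=resid_var,
        standardization=standardization
        or {s: {f: (0.0, 1.0) for f in _STD_FACTORS} for s in ("M", "F")},
        loglik=float(loglik),
        n_iter=it,
        converged=converged,
        empty_factors=empty,
    )


def predict_blups(
    fit: MixedFit,
    measurements: pd.DataFrame,
    ids,
    lookback: float = 10.0,
    standardize: bool = True,
) -> pd.DataFrame:
    """BLUP factor values at the landmark age for each requested person.

    The random-intercept posterior mean given the person's observed
    measurement subset (generalized-least-squares with the fitted
    covariance) is added to the fixed trend at the landmark age.  Persons
    with no usable measurements get the population fixed-trend value.
    SBP/TC/HDL are returned standardized with the fit's frozen sex-specific
    constants when ``standardize`` is True; smoking is clipped to [0, 1]
    (``smoking_clipped`` flags when clipping occurred).
    """
    ids = np.asarray(ids)
    m = measurements[measurements["id"].isin(ids) & measurements["value"].notna()]
    m = m[
        (m["age"] >= fit.landmark_age - lookback) & (m["age"] <= fit.landmark_age)
    ]

    order = pd.Index(ids)
    pid = order.get_indexer(m["id"])
    fidx = m["factor"].map(_FIDX).to_numpy()
    t = (m["age"] - fit.landmark_age).to_numpy()
    y = m["value"].to_numpy(dtype=float)

    r = y - fit.intercepts[fidx] - fit.slopes[fidx] * t
    w = 1.0 / fit.resid_var[fidx]
    counts = np.zeros((len(ids), 4))
    np.add.at(counts, (pid, fidx), w)
    s = np.zeros((len(ids), 4))
    np.add.at(s, (pid, fidx), w * r)

    Sinv = np.linalg.inv(fit.Sigma_u)
    prec = Sinv[None, :, :] + counts[:, :, None] * np.eye(4)[None, :, :]
    b = np.einsum("nij,nj->ni", np.linalg.inv(prec), s)
    pred = fit.intercepts[None, :] + b  # fixed trend at landmark + BLUP

    out = pd.DataFrame({"id": ids})
    std = fit.standardization[fit.sex]
    for j, f in enumerate(FACTORS):
        v = pred[:, j]
        if f == "smoking":
            out["smoking_clipped"] = (v < 0) | (v > 1)
            v = np.clip(v, 0.0, 1.0)
        elif standardize:
            mean, sd = std[f]
            v = (v - mean) / sd
        out[f] = v
    return out
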