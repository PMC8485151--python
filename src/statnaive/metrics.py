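"""Model-performance measures for 10-year risk predictions.

All measures operate on an :class:`EvalSet` — per-person predicted risk,
follow-up time and event indicator for one landmark age and sex.  The
same machinery evaluates the standard model against observed outcomes
and the statin-naive model against counterfactual outcomes: the
counterfactual transformation happens upstream, so no code path here is
special-cased.

Conventions
-----------
* "Restricted subset": persons with an event within the horizon or at
  least `horizon` years of follow-up (the Brier score, categorical NRI
  and IDI use it; persons censored early contribute nothing).
* Observed group risks use the product-limit (Kaplan-Meier) estimator at
  the horizon.
* Bootstrap quantities resample persons and are deterministic given a
  seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.utils import concordance_index

from .weibull import fit_weibull_ph

KAPPA2 = 8.0 / np.pi  # variance of the scaled rankit score


@dataclass
class EvalSet:
    """Predictions and outcomes for one landmark age and sex."""

    p: np.ndarray  # predicted risk within the horizon, in (0, 1)
    time: np.ndarray  # follow-up (possibly counterfactual), years
    event: np.ndarray  # 0/1
    ids: np.ndarray | None = None
    landmark_age: float = np.nan
    sex: str = ""
    horizon: float = 10.0

    def __post_init__(self):
        self.p = np.asarray(self.p, dtype=float)
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event, dtype=int)
        if self.ids is None:
            self.ids = np.arange(len(self.p))
        else:
            self.ids = np.asarray(self.ids)
        if np.any((self.p <= 0) | (self.p >= 1)):
            raise ValueError("predicted risks must lie strictly in (0, 1)")
        if np.any(self.time <= 0):
            raise ValueError("follow-up times must be positive")

    def __len__(self) -> int:
        return len(self.p)

    def restricted_mask(self) -> np.ndarray:
        ev = (self.event == 1) & (self.time <= self.horizon)
        return ev | (self.time >= self.horizon)

    def event_within(self) -> np.ndarray:
        return ((self.event == 1) & (self.time <= self.horizon)).astype(int)


def km_event_prob(time, event, horizon: float) -> float:
    """Product-limit event probability at the horizon (0 if no events)."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if len(time) == 0:
        return np.nan
    if event.sum() == 0:
        return 0.0
    km = KaplanMeierFitter()
    km.fit(np.minimum(time, horizon), (event == 1) & (time <= horizon))
    return float(1.0 - km.predict(horizon))


def _prognostic_index(p: np.ndarray) -> np.ndarray:
    """Log cumulative-hazard scale of a risk: ln(-ln(1 - p))."""
    return np.log(-np.log1p(-p))


def calibration(eval_set: EvalSet, n_groups: int = 10) -> tuple[pd.DataFrame, dict]:
    """Calibration table (tenths of predicted risk vs product-limit
    observed risk) and calibration slope.

    The slope is the coefficient of the centred log cumulative-hazard
    prognostic index in a refitted one-covariate Weibull model; 1 means
    perfectly calibrated risk spread.
    """
    if np.ptp(eval_set.p) == 0:
        raise ValueError("constant predictions: calibration slope undefined")
    groups = pd.qcut(eval_set.p, n_groups, labels=False, duplicates="drop")
    rows = []
    for g in np.unique(groups):
        sel = groups == g
        obs = km_event_prob(eval_set.time[sel], eval_set.event[sel], eval_set.horizon)
        rows.append(
            {
                "group": int(g),
                "n": int(sel.sum()),
                "mean_predicted": float(eval_set.p[sel].mean()),
                "observed": obs,
                "no_events": bool(eval_set.event[sel].sum() == 0),
            }
        )
    table = pd.DataFrame(rows)

    pi = _prognostic_index(eval_set.p)
    episodes = pd.DataFrame(
        {
            "start": 0.0,
            "stop": eval_set.time,
            "event_flag": eval_set.event,
            "pi": pi - pi.mean(),
        }
    )
    fit = fit_weibull_ph(episodes, constrained=False, covariates=("pi",))
    slope = float(fit.beta[0])
    slope_se = float(fit.se[2])
    return table, {
        "slope": slope,
        "se": slope_se,
        "ci": (slope - 1.96 * slope_se, slope + 1.96 * slope_se),
    }


def brier_10yr(eval_set: EvalSet) -> float:
    """Mean squared prediction error restricted to persons with an event
    within the horizon or at least `horizon` years of follow-up."""
    mask = eval_set.restricted_mask()
    if not mask.any():
        raise ValueError("restricted subset is empty")
    d = eval_set.event_within()[mask]
    return float(np.mean((d - eval_set.p[mask]) ** 2))


def harrell_c(
    eval_set: EvalSet, bootstrap_reps: int = 200, seed: int = 0
) -> dict:
    """Harrell's C for risk predictions (higher risk should mean shorter
    time), with person-resampling bootstrap SE and percentile CI."""
    if eval_set.event.sum() == 0:
        raise ValueError("no usable pairs: no events")
    c = concordance_index(eval_set.time, -eval_set.p, eval_set.event)
    rng = np.random.default_rng(seed)
    n = len(eval_set)
    reps = []
    for _ in range(bootstrap_reps):
        idx = rng.integers(0, n, n)
        if eval_set.event[idx].sum() == 0:
            continue
        reps.append(
            concordance_index(eval_set.time[idx], -eval_set.p[idx], eval_set.event[idx])
        )
    reps = np.array(reps)
    return {
        "c": float(c),
        "se": float(reps.std(ddof=1)) if len(reps) > 1 else np.nan,
        "ci": (
            (float(np.percentile(reps, 2.5)), float(np.percentile(reps, 97.5)))
            if len(reps) > 1
            else (np.nan, np.nan)
        ),
    }


def royston_d(eval_set: EvalSet) -> dict:
    """Royston-Sauerbrei D statistic and explained variation R2_D.

    The prognostic index is replaced by standard-normal order statistics
    (rankits) scaled by sqrt(8/pi); D is the coefficient of that score in
    a one-covariate Weibull model and R2_D = (D^2/s2) / (D^2/s2 + pi^2/6)
    with s2 = 8/pi.
    """
    from scipy import stats

    pi_ = _prognostic_index(eval_set.p)
    if len(np.unique(pi_)) < 2:
        raise ValueError("need at least 2 distinct predictions")
    n = len(pi_)
    ranks = stats.rankdata(pi_, method="average")
    rankits = stats.norm.ppf((ranks - 0.375) / (n + 0.25))
    z = rankits / np.sqrt(KAPPA2)
    episodes = pd.DataFrame(
        {"start": 0.0, "stop": eval_set.time, "event_flag": eval_set.event, "z": z}
    )
    fit = fit_weibull_ph(episodes, constrained=False, covariates=("z",))
    D = float(fit.beta[0])
    se = float(fit.se[2])
    r2 = (D**2 / KAPPA2) / (D**2 / KAPPA2 + np.pi**2 / 6.0)
    return {"d": D, "se": se, "ci": (D - 1.96 * se, D + 1.96 * se), "r2_d": float(r2)}


# ---------------------------------------------------------------------------
# reclassification


def _nri_component(up: int, down: int, n: int) -> tuple[float, float]:
    """Net proportion and asymptotic SE for one NRI component."""
    if n == 0:
        return np.nan, np.nan
    p_up, p_down = up / n, down / n
    nri = p_up - p_down
    var = (p_up + p_down - (p_up - p_down) ** 2) / n
    return nri, float(np.sqrt(max(var, 0.0)))


def categorical_nri_from_counts(
    event_counts: np.ndarray, nonevent_counts: np.ndarray
) -> dict:
    """Categorical NRI from 2x2 reclassification tables.

    Rows index the old (standard) risk category (<threshold, >=threshold),
    columns the new (statin-naive) category.  Returns event, nonevent and
    overall components with asymptotic normal 95% CIs.
    """
    ev = np.asarray(event_counts, dtype=float)
    ne = np.asarray(nonevent_counts, dtype=float)
    n_ev, n_ne = int(ev.sum()), int(ne.sum())
    flags = []
    if n_ev == 0:
        flags.append("no events in restricted set")
    if n_ne == 0:
        flags.append("no nonevents in restricted set")
    ev_nri, ev_se = _nri_component(int(ev[0, 1]), int(ev[1, 0]), n_ev)
    ne_nri, ne_se = _nri_component(int(ne[1, 0]), int(ne[0, 1]), n_ne)
    overall = ev_nri + ne_nri
    overall_se = float(np.sqrt(np.nansum([ev_se**2, ne_se**2])))

    def ci(x, s):
        return (x - 1.96 * s, x + 1.96 * s)

    return {
        "event": ev_nri,
        "event_se": ev_se,
        "event_ci": ci(ev_nri, ev_se),
        "nonevent": ne_nri,
        "nonevent_se": ne_se,
        "nonevent_ci": ci(ne_nri, ne_se),
        "overall": overall,
        "overall_se": overall_se,
        "overall_ci": ci(overall, overall_se),
        "n_events": n_ev,
        "n_nonevents": n_ne,
        "flags": flags,
    }


def reclassification_counts(
    eval_old: EvalSet, eval_new: EvalSet, threshold: float = 0.10
) -> tuple[np.ndarray, np.ndarray]:
    """2x2 reclassification tables (events, nonevents) on the restricted
    subset; new-model outcomes (counterfactual when the new model is the
    statin-naive one) define event status."""
    mask = eval_new.restricted_mask()
    d = eval_new.event_within()[mask]
    old_hi = (eval_old.p[mask] >= threshold).astype(int)
    new_hi = (eval_new.p[mask] >= threshold).astype(int)
    ev = np.zeros((2, 2))
    ne = np.zeros((2, 2))
    np.add.at(ev, (old_hi[d == 1], new_hi[d == 1]), 1)
    np.add.at(ne, (old_hi[d == 0], new_hi[d == 0]), 1)
    return ev, ne


def categorical_nri(
    eval_old: EvalSet, eval_new: EvalSet, threshold: float = 0.10
) -> dict:
    """Categorical NRI at a single risk threshold (default 10%), using
    persons not censored before the horizon."""
    ev, ne = reclassification_counts(eval_old, eval_new, threshold)
    out = categorical_nri_from_counts(ev, ne)
    out["threshold"] = threshold
    return out


def _continuous_nri_point(p_old, p_new, time, event, horizon) -> tuple[float, float, float]:
    up = p_new > p_old
    down = p_new < p_old
    groups = [up, down, ~(up | down)]
    probs = np.array([g.mean() for g in groups])
    pis = np.array(
        [km_event_prob(time[g], event[g], horizon) if g.any() else 0.0 for g in groups]
    )
    pi_all = float(np.sum(probs * pis))
    if pi_all in (0.0, 1.0):
        return np.nan, np.nan, np.nan
    p_up_ev = probs[0] * pis[0] / pi_all
    p_down_ev = probs[1] * pis[1] / pi_all
    p_up_ne = probs[0] * (1 - pis[0]) / (1 - pi_all)
    p_down_ne = probs[1] * (1 - pis[1]) / (1 - pi_all)
    ev = p_up_ev - p_down_ev
    ne = p_down_ne - p_up_ne
    return ev, ne, ev + ne


def continuous_nri(
    eval_old: EvalSet,
    eval_new: EvalSet,
    horizon: float | None = None,
    bootstrap_reps: int = 200,
    seed: int = 0,
) -> dict:
    """Prospective (survival) continuous NRI.

    Persons are split into up- and down-movers by the sign of
    p_new - p_old; event probabilities at the horizon within each mover
    group come from the product-limit estimator, so censored persons
    contribute.  CIs are person-resampling bootstrap percentiles.
    """
    horizon = eval_new.horizon if horizon is None else horizon
    p_old, p_new = eval_old.p, eval_new.p
    time, event = eval_new.time, eval_new.event
    movers = p_new != p_old
    if not movers.any():
        return {
            "event": 0.0, "nonevent": 0.0, "overall": 0.0,
            "event_ci": (0.0, 0.0), "nonevent_ci": (0.0, 0.0),
            "overall_ci": (0.0, 0.0), "flags": ["no movers"],
        }
    ev, ne, ov = _continuous_nri_point(p_old, p_new, time, event, horizon)
    rng = np.random.default_rng(seed)
    n = len(p_old)
    reps = []
    for _ in range(bootstrap_reps):
        idx = rng.integers(0, n, n)
        reps.append(
            _continuous_nri_point(p_old[idx], p_new[idx], time[idx], event[idx], horizon)
        )
    reps = np.array(reps, dtype=float)

    def ci(col):
        v = reps[:, col]
        v = v[np.isfinite(v)]
        if len(v) < 2:
            return (np.nan, np.nan)
        return (float(np.percentile(v, 2.5)), float(np.percentile(v, 97.5)))

    return {
        "event": ev, "nonevent": ne, "overall": ov,
        "event_ci": ci(0), "nonevent_ci": ci(1), "overall_ci": ci(2),
        "flags": [],
    }


def idi(eval_old: EvalSet, eval_new: EvalSet, horizon: float | None = None) -> dict:
    """Integrated discrimination improvement on the restricted subset:
    difference in discrimination slopes between new and old predictions."""
    horizon = eval_new.horizon if horizon is None else horizon
    mask = eval_new.restricted_mask()
    d = eval_new.event_within()[mask]
    delta = (eval_new.p - eval_old.p)[mask]
    flags = []
    if (d == 1).sum() == 0:
        flags.append("no events in restricted set")
    if (d == 0).sum() == 0:
        flags.append("no nonevents in restricted set")
    if flags:
        return {"idi": np.nan, "se": np.nan, "ci": (np.nan, np.nan), "flags": flags}
    d_ev, d_ne = delta[d == 1], delta[d == 0]
    value = float(d_ev.mean() - d_ne.mean())
    se = float(
        np.sqrt(d_ev.var(ddof=1) / len(d_ev) + d_ne.var(ddof=1) / len(d_ne))
    )
    return {
        "idi": value,
        "se": se,
        "ci": (value - 1.96 * se, value + 1.96 * se),
        "flags": [],
    }


def stack_and_summarize(
    eval_sets: list[EvalSet], bootstrap_reps: int = 200, seed: int = 0
) -> dict:
    """Overall Brier score and C index on the landmark-stacked data.

    Persons may appear at several landmark ages; the bootstrap resamples
    persons, keeping all of a person's landmark rows together.
    """
    p = np.concatenate([e.p for e in eval_sets])
    time = np.concatenate([e.time for e in eval_sets])
    event = np.concatenate([e.event for e in eval_sets])
    ids = np.concatenate([e.ids for e in eval_sets])
    horizon = eval_sets[0].horizon
    stacked = EvalSet(p=p, time=time, event=event, ids=ids, horizon=horizon)

    brier = brier_10yr(stacked)
    c = concordance_index(time, -p, event)

    uniq, inv = np.unique(ids, return_inverse=True)
    by_person = [np.flatnonzero(inv == k) for k in range(len(uniq))]
    rng = np.random.default_rng(seed)
    briers, cs = [], []
    for _ in range(bootstrap_reps):
        pick = rng.integers(0, len(uniq), len(uniq))
        idx = np.concatenate([by_person[k] for k in pick])
        bs = EvalSet(p=p[idx], time=time[idx], event=event[idx], horizon=horizon)
        if bs.restricted_mask().any() and bs.event.sum() > 0:
            briers.append(brier_10yr(bs))
            cs.append(concordance_index(bs.time, -bs.p, bs.event))

    def summ(x, point):
        x = np.array(x)
        if len(x) < 2:
            return {"value": point, "se": np.nan, "ci": (np.nan, np.nan)}
        return {
            "value": point,
            "se": float(x.std(ddof=1)),
            "ci": (float(np.percentile(x, 2.5)), float(np.percentile(x, 97.5))),
        }

    return {"brier": summ(briers, brier), "c": summ(cs, float(c)), "n": len(p)}
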