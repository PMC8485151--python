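"""Landmark risk sets and crude incidence / statin-initiation rates.

A landmark risk set at age L collects, for one sex, every person who was
under observation at L (entry_age <= L < exit_age) with no CVD event and
no statin prescription strictly before L.  Follow-up restarts at L and is
administratively truncated at the horizon (default 10 years).  Intervals
are half-open (L, L + horizon]: an event or prescription exactly at the
landmark age counts as after it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .synthetic import DAY, Cohort

LANDMARK_AGES = tuple(range(40, 86))
SEXES = ("M", "F")


@dataclass
class LandmarkRiskSet:
    """Eligible persons at one landmark age and sex.

    rows columns: id, time (years since landmark, capped at horizon,
    >= 1 day), event_flag, statin_time (years since landmark, NaN if no
    initiation within follow-up), diabetes_flag, htn_flag.

    Evaluation-support columns carry the uncapped follow-up: followup
    (years since landmark to exit), event_at_exit, statin_time_full
    (initiation within the full follow-up, not just the horizon) — used
    when counterfactual survival times decide 10-year status, which can
    depend on observed follow-up beyond the horizon.
    """

    landmark_age: float
    sex: str
    horizon: float
    rows: pd.DataFrame

    def __len__(self) -> int:
        return len(self.rows)


def build_risk_set(
    cohort: Cohort, landmark_age: float, sex: str, horizon: float = 10.0
) -> LandmarkRiskSet:
    p = cohort.persons
    if len(p) == 0:
        rows = pd.DataFrame(
            columns=["id", "time", "event_flag", "statin_time", "diabetes_flag",
                     "htn_flag", "followup", "event_at_exit", "statin_time_full"]
        )
        return LandmarkRiskSet(landmark_age, sex, horizon, rows)

    L = float(landmark_age)
    init = cohort.statin.set_index("id")["initiation_age"] if len(cohort.statin) else pd.Series(dtype=float)
    init_age = p["id"].map(init).to_numpy(dtype=float)  # NaN when never

    under_obs = (p["entry_age"].to_numpy() <= L) & (L < p["exit_age"].to_numpy())
    event_before = (p["event_flag"].to_numpy() == 1) & (p["event_age"].to_numpy() < L)
    statin_before = np.nan_to_num(init_age, nan=np.inf) < L
    eligible = (p["sex"].to_numpy() == sex) & under_obs & ~event_before & ~statin_before

    sub = p.loc[eligible]
    init_sub = init_age[eligible]

    followup = sub["exit_age"].to_numpy() - L
    time = np.minimum(followup, horizon)
    time = np.maximum(time, DAY)  # same-day boundary: Weibull needs time > 0
    event = (sub["event_flag"].to_numpy() == 1) & (followup <= horizon)

    statin_time = init_sub - L
    statin_time = np.where(statin_time <= 0, DAY, statin_time)  # prescription at L
    statin_time_full = np.where(statin_time <= followup, statin_time, np.nan)
    statin_time = np.where(statin_time <= time, statin_time, np.nan)

    cond = cohort.conditions
    dia = cond.loc[cond["condition"] == "diabetes"].set_index("id")["onset_age"]
    htn = cond.loc[cond["condition"] == "htn"].set_index("id")["onset_age"]
    dia_flag = (sub["id"].map(dia).to_numpy(dtype=float) <= L).astype(int)
    htn_flag = (sub["id"].map(htn).to_numpy(dtype=float) <= L).astype(int)

    rows = pd.DataFrame(
        {
            "id": sub["id"].to_numpy(),
            "time": time,
            "event_flag": event.astype(int),
            "statin_time": statin_time,
            "diabetes_flag": dia_flag,
            "htn_flag": htn_flag,
            "followup": np.maximum(followup, DAY),
            "event_at_exit": sub["event_flag"].to_numpy(),
            "statin_time_full": statin_time_full,
        }
    ).reset_index(drop=True)
    return LandmarkRiskSet(L, sex, horizon, rows)


def _poisson_ci(events: int, person_years: float) -> tuple[float, float]:
    """Exact (Garwood) 95% CI for a Poisson rate per 1,000 person-years."""
    if person_years <= 0:
        return (np.nan, np.nan)
    lo = 0.0 if events == 0 else stats.chi2.ppf(0.025, 2 * events) / 2 / person_years
    hi = stats.chi2.ppf(0.975, 2 * (events + 1)) / 2 / person_years
    return (lo * 1000, hi * 1000)


def crude_rates(
    cohort: Cohort,
    landmark_ages=LANDMARK_AGES,
    sexes=SEXES,
    horizon: float = 10.0,
) -> pd.DataFrame:
    """10-year crude CVD incidence and statin-initiation rates per 1,000
    person-years, with exact Poisson 95% CIs, by landmark age and sex.

    Initiation rates censor follow-up at the CVD event or exit; incidence
    uses the full capped follow-up.
    """
    out = []
    for L in landmark_ages:
        for sex in sexes:
            rs = build_risk_set(cohort, L, sex, horizon)
            r = rs.rows
            if len(r) == 0:
                out.append(
                    {"landmark_age": L, "sex": sex, "n": 0, "empty": True}
                )
                continue
            events = int(r["event_flag"].sum())
            py = float(r["time"].sum())
            cvd_rate = events / py * 1000
            cvd_lo, cvd_hi = _poisson_ci(events, py)

            initiated = r["statin_time"].notna().to_numpy()
            t_init = np.where(initiated, r["statin_time"].to_numpy(), r["time"].to_numpy())
            n_init = int(initiated.sum())
            py_init = float(t_init.sum())
            init_rate = n_init / py_init * 1000
            init_lo, init_hi = _poisson_ci(n_init, py_init)

            out.append(
                {
                    "landmark_age": L,
                    "sex": sex,
                    "n": len(r),
                    "empty": False,
                    "events": events,
                    "person_years": py,
                    "cvd_rate": cvd_rate,
                    "cvd_rate_lo": cvd_lo,
                    "cvd_rate_hi": cvd_hi,
                    "initiations": n_init,
                    "initiation_person_years": py_init,
                    "initiation_rate": init_rate,
                    "initiation_rate_lo": init_lo,
                    "initiation_rate_hi": init_hi,
                }
            )
    return pd.DataFrame(out)
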