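"""Synthetic longitudinal cohort generator.

Emulates the statistical structure of a primary-care cohort used for
landmark CVD risk modelling: correlated repeat measurements of systolic
blood pressure (SBP), total cholesterol (TC), HDL cholesterol and smoking;
age- and cholesterol-dependent statin initiation on a yearly grid; Weibull
event times with a proportional hazard reduction after initiation; and
administrative censoring.  Alongside the observable tables the generator
can store oracle quantities (latent random intercepts, true statin-naive
10-year risks, exactly coupled treated/untreated potential event times)
used to validate every downstream modelling stage.

Time conventions: ages in years; each person's event clock starts at study
entry; the event hazard is

    h(t) = exp(eta) * nu * t^(nu-1) * (statin_hr if t >= t_s else 1)

with eta = log baseline rate (sex- and entry-age-specific) + x'beta and x
the person's latent risk-factor vector frozen at entry.  Event times are
drawn by inverse transform on the closed-form piecewise cumulative hazard,
which makes treated and untreated potential outcomes exactly coupled
through the shared uniform variate.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

FACTORS = ("sbp", "tc", "hdl", "smoking")
#: hazard covariate order: standardized SBP/TC/HDL, smoking, diabetes, htn
HAZARD_COVARIATES = ("sbp", "tc", "hdl", "smoking", "diabetes", "htn")

DAY = 1.0 / 365.25


def _default_sigma_u() -> np.ndarray:
    sd = np.array([12.0, 0.9, 0.33, 0.25])
    corr = np.array(
        [
            [1.0, 0.10, -0.05, 0.05],
            [0.10, 1.0, -0.20, 0.05],
            [-0.05, -0.20, 1.0, -0.15],
            [0.05, 0.05, -0.15, 1.0],
        ]
    )
    return corr * np.outer(sd, sd)


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic data-generating process.

    Defaults are chosen to resemble a UK primary-care population aged
    40-85: mean SBP ~133 mm Hg rising with age, TC ~5.5 mmol/L,
    HDL ~1.45 mmol/L, smoking prevalence ~45% declining with age;
    roughly 15% of persons initiate statins within 10 years (higher at
    older ages and with higher cholesterol); true statin-naive 10-year
    risks span roughly 1%-40% across entry ages 40-85.
    """

    n_persons: int = 20_000
    seed: int = 0
    entry_age_range: tuple[float, float] = (40.0, 85.0)
    max_followup: float = 13.0
    max_age: float = 95.0
    visit_rate: float = 1.0  # expected measurement visits per person-year
    measurement_prob: float = 0.7  # per-factor observation prob per visit
    lookback: float = 10.0  # pre-entry measurement window, years

    # latent trajectory: mean + trend*(age-60) + person random intercept
    factor_means: dict[str, float] = field(
        default_factory=lambda: {"sbp": 133.0, "tc": 5.5, "hdl": 1.45, "smoking": 0.45}
    )
    factor_trends: dict[str, float] = field(
        default_factory=lambda: {"sbp": 0.5, "tc": 0.01, "hdl": 0.0, "smoking": -0.005}
    )
    Sigma_u: np.ndarray = field(default_factory=_default_sigma_u)
    resid_sd: dict[str, float] = field(
        default_factory=lambda: {"sbp": 9.0, "tc": 0.5, "hdl": 0.15, "smoking": 0.5}
    )

    # event model
    weibull_shape: float = 1.3
    log_baseline_rate: dict[str, float] = field(
        default_factory=lambda: {"M": -5.5, "F": -6.0}
    )
    log_baseline_age_slope: float = 0.06  # per year of entry age, centred at 60
    beta_true: np.ndarray = field(
        default_factory=lambda: np.array([0.25, 0.25, -0.20, 0.50, 0.60, 0.30])
    )
    # centring/scale used to standardize SBP/TC/HDL inside the hazard
    factor_center: tuple[float, float, float] = (135.0, 5.5, 1.45)
    factor_scale: tuple[float, float, float] = (18.0, 1.1, 0.4)

    # treatment drop-in
    statin_hr: float = 0.75
    statin_init_intercept: float = -4.0  # per-year log-odds at age 60, TC 5.5
    statin_init_age: float = 0.05
    statin_init_tc: float = 0.30

    diabetes_rate: float = 0.004  # onsets per person-year
    htn_rate: float = 0.015

    def validate(self) -> None:
        S = np.asarray(self.Sigma_u, dtype=float)
        if S.shape != (4, 4) or not np.allclose(S, S.T):
            raise ValueError("Sigma_u must be a symmetric 4x4 matrix")
        eigs = np.linalg.eigvalsh(S)
        if eigs.min() < -1e-10:
            raise ValueError("Sigma_u must be positive semi-definite")
        if self.weibull_shape <= 0:
            raise ValueError("weibull_shape must be positive")
        if not (0.0 < self.statin_hr <= 1.0):
            raise ValueError("statin_hr must lie in (0, 1]")
        if self.visit_rate < 0:
            raise ValueError("visit_rate must be nonnegative")
        p = self.factor_means["smoking"]
        if not (0.0 <= p <= 1.0):
            raise ValueError("smoking probability must lie in [0, 1]")


@dataclass
class Cohort:
    """Long-format synthetic cohort.

    persons:      id, sex, entry_age, exit_age, event_flag, event_age
    measurements: id, factor, age, value
    statin:       id, initiation_age
    conditions:   id, condition (diabetes/htn), onset_age
    truth:        optional per-person oracle table (latent intercepts,
                  hazard covariates, true naive 10-year risk from entry,
                  coupled untreated/treated potential event ages)
    """

    persons: pd.DataFrame
    measurements: pd.DataFrame
    statin: pd.DataFrame
    conditions: pd.DataFrame
    truth: pd.DataFrame | None = None

    def write(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.persons.to_csv(directory / "persons.csv", index=False)
        self.measurements.to_csv(directory / "measurements.csv", index=False)
        self.statin.to_csv(directory / "statin.csv", index=False)
        self.conditions.to_csv(directory / "conditions.csv", index=False)
        if self.truth is not None:
            self.truth.to_csv(directory / "truth.csv", index=False)

    @classmethod
    def read(cls, directory: str | Path) -> "Cohort":
        directory = Path(directory)
        truth_path = directory / "truth.csv"
        return cls(
            persons=pd.read_csv(directory / "persons.csv"),
            measurements=pd.read_csv(directory / "measurements.csv"),
            statin=pd.read_csv(directory / "statin.csv"),
            conditions=pd.read_csv(directory / "conditions.csv"),
            truth=pd.read_csv(truth_path) if truth_path.exists() else None,
        )

    def to_bytes(self) -> bytes:
        buf = io.BytesIO()
        for df in (self.persons, self.measurements, self.statin, self.conditions):
            df.to_csv(buf, index=False)
        return buf.getvalue()


def invert_piecewise_weibull(
    cum_hazard: np.ndarray,
    rate: np.ndarray,
    shape: float,
    t_s: np.ndarray,
    hr: float,
) -> np.ndarray:
    """Invert H(t) = rate * [min(t, t_s)^shape + hr*max(t^shape - t_s^shape, 0)]
    at the target cumulative hazard, i.e. the event time of the treated
    (post-t_s hazard multiplied by hr) process for a given exponential draw.
    """
    cum_hazard = np.asarray(cum_hazard, dtype=float)
    rate = np.asarray(rate, dtype=float)
    t_s = np.asarray(t_s, dtype=float)
    # untreated solution
    t0 = (cum_hazard / rate) ** (1.0 / shape)
    switched = t0 > t_s
    ts_safe = np.where(switched, t_s, 0.0)  # dead branch: keep finite, nonneg
    with np.errstate(invalid="ignore"):
        t = np.where(
            switched,
            (ts_safe**shape + (cum_hazard / rate - ts_safe**shape) / hr)
            ** (1.0 / shape),
            t0,
        )
    return t


def _latent_value(cfg: GeneratorConfig, factor_idx: int, age, u_col):
    name = FACTORS[factor_idx]
    return cfg.factor_means[name] + cfg.factor_trends[name] * (age - 60.0) + u_col


def _hazard_covariates(
    cfg: GeneratorConfig, sbp, tc, hdl, smoke_p, diab, htn
) -> np.ndarray:
    c, s = cfg.factor_center, cfg.factor_scale
    return np.column_stack(
        [
            (sbp - c[0]) / s[0],
            (tc - c[1]) / s[1],
            (hdl - c[2]) / s[2],
            smoke_p,
            diab.astype(float),
            htn.astype(float),
        ]
    )


def generate_cohort(
    config: GeneratorConfig,
    keep_truth: bool = True,
    statins_enabled: bool = True,
) -> Cohort:
    """Simulate a cohort under the generator's data-generating process.

    Reproducible given ``config.seed``.  ``statins_enabled=False`` disables
    the initiation process entirely (useful for null comparisons).
    """
    config.validate()
    cfg = config
    n = cfg.n_persons
    rng = np.random.default_rng(cfg.seed)

    empty = Cohort(
        persons=pd.DataFrame(
            columns=["id", "sex", "entry_age", "exit_age", "event_flag", "event_age"]
        ),
        measurements=pd.DataFrame(columns=["id", "factor", "age", "value"]),
        statin=pd.DataFrame(columns=["id", "initiation_age"]),
        conditions=pd.DataFrame(columns=["id", "condition", "onset_age"]),
        truth=pd.DataFrame() if keep_truth else None,
    )
    if n == 0:
        return empty

    ids = np.arange(n)
    sex = np.where(rng.random(n) < 0.5, "M", "F")
    lo, hi = cfg.entry_age_range
    # registration-age device: persons "turning lo" during the window enter
    # exactly at lo, producing a realistic atom at the first landmark age
    reg_age = rng.uniform(lo - cfg.lookback, hi, n)
    entry_age = np.maximum(lo, reg_age)

    # person random intercepts and latent values at entry
    u = rng.multivariate_normal(np.zeros(4), cfg.Sigma_u, size=n)
    sbp0 = _latent_value(cfg, 0, entry_age, u[:, 0])
    tc0 = _latent_value(cfg, 1, entry_age, u[:, 1])
    hdl0 = _latent_value(cfg, 2, entry_age, u[:, 2])
    smoke_p = np.clip(_latent_value(cfg, 3, entry_age, u[:, 3]), 0.0, 1.0)

    # chronic condition onsets (exponential waits from the lookback start)
    onset_dia = entry_age - cfg.lookback + rng.exponential(1.0 / cfg.diabetes_rate, n)
    onset_htn = entry_age - cfg.lookback + rng.exponential(1.0 / cfg.htn_rate, n)
    diab0 = onset_dia <= entry_age
    htn0 = onset_htn <= entry_age

    x = _hazard_covariates(cfg, sbp0, tc0, hdl0, smoke_p, diab0, htn0)
    log_base = np.array([cfg.log_baseline_rate[s] for s in sex])
    eta = log_base + cfg.log_baseline_age_slope * (entry_age - 60.0) + x @ cfg.beta_true
    rate = np.exp(eta)
    nu = cfg.weibull_shape

    # coupled potential outcomes via a shared exponential draw
    E = rng.exponential(1.0, n)
    t_untreated = (E / rate) ** (1.0 / nu)

    censor = np.minimum(cfg.max_followup, cfg.max_age - entry_age)
    censor = np.maximum(censor, DAY)

    # yearly statin-initiation grid, only while event-free and uncensored
    t_s = np.full(n, np.inf)
    t_event = t_untreated.copy()
    if statins_enabled:
        max_years = int(np.ceil(cfg.max_followup))
        for k in range(1, max_years + 1):
            at_risk = (t_s == np.inf) & (t_event > k) & (censor > k)
            if not at_risk.any():
                continue
            age_k = entry_age + k
            tc_k = _latent_value(cfg, 1, age_k, u[:, 1])
            logit = (
                cfg.statin_init_intercept
                + cfg.statin_init_age * (age_k - 60.0)
                + cfg.statin_init_tc * (tc_k - 5.5)
            )
            p = 1.0 / (1.0 + np.exp(-logit))
            hit = at_risk & (rng.random(n) < p)
            if hit.any():
                t_s[hit] = float(k)
                t_event[hit] = invert_piecewise_weibull(
                    E[hit], rate[hit], nu, t_s[hit], cfg.statin_hr
                )

    event_flag = t_event <= censor
    t_obs = np.minimum(t_event, censor)
    t_obs = np.maximum(t_obs, DAY)
    exit_age = entry_age + t_obs
    event_age = np.where(event_flag, exit_age, np.nan)

    persons = pd.DataFrame(
        {
            "id": ids,
            "sex": sex,
            "entry_age": entry_age,
            "exit_age": exit_age,
            "event_flag": event_flag.astype(int),
            "event_age": event_age,
        }
    )

    observed_init = np.isfinite(t_s) & (t_s < t_obs)
    statin = pd.DataFrame(
        {"id": ids[observed_init], "initiation_age": (entry_age + t_s)[observed_init]}
    )

    cond_frames = []
    for cond, onset in (("diabetes", onset_dia), ("htn", onset_htn)):
        keep = onset <= exit_age
        cond_frames.append(
            pd.DataFrame(
                {"id": ids[keep], "condition": cond, "onset_age": onset[keep]}
            )
        )
    conditions = (
        pd.concat(cond_frames, ignore_index=True)
        .sort_values(["id", "condition"], kind="stable")
        .reset_index(drop=True)
    )

    # measurement visits over [entry - lookback, exit]
    win_lo = entry_age - cfg.lookback
    win_len = exit_age - win_lo
    n_visits = rng.poisson(cfg.visit_rate * win_len)
    pid = np.repeat(ids, n_visits)
    visit_age = rng.random(n_visits.sum()) * np.repeat(win_len, n_visits) + np.repeat(
        win_lo, n_visits
    )
    meas_frames = []
    for j, factor in enumerate(FACTORS):
        seen = rng.random(len(pid)) < cfg.measurement_prob
        p_sub, a_sub = pid[seen], visit_age[seen]
        latent = _latent_value(cfg, j, a_sub, u[p_sub, j])
        if factor == "smoking":
            value = (rng.random(len(p_sub)) < np.clip(latent, 0.0, 1.0)).astype(float)
        else:
            value = latent + rng.normal(0.0, cfg.resid_sd[factor], len(p_sub))
        meas_frames.append(
            pd.DataFrame({"id": p_sub, "factor": factor, "age": a_sub, "value": value})
        )
    measurements = (
        pd.concat(meas_frames, ignore_index=True)
        .sort_values(["id", "age", "factor"], kind="stable")
        .reset_index(drop=True)
    )

    truth = None
    if keep_truth:
        truth = pd.DataFrame(
            {
                "id": ids,
                "u_sbp": u[:, 0],
                "u_tc": u[:, 1],
                "u_hdl": u[:, 2],
                "u_smoking": u[:, 3],
                "x_sbp": x[:, 0],
                "x_tc": x[:, 1],
                "x_hdl": x[:, 2],
                "x_smoking": x[:, 3],
                "x_diabetes": x[:, 4],
                "x_htn": x[:, 5],
                "eta": eta,
                "true_risk_10yr": 1.0 - np.exp(-rate * 10.0**nu),
                "untreated_event_age": entry_age + t_untreated,
                "treated_event_age": entry_age + t_event,
                "statin_time": np.where(np.isfinite(t_s), t_s, np.nan),
            }
        )

    return Cohort(persons, measurements, statin, conditions, truth)


def paired_counterfactual_times(
    config: GeneratorConfig,
    n: int,
    t_s: np.ndarray | float | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Draw exactly coupled (treated_time, untreated_time, t_s) triples.

    One uniform variate per draw is inverted under the untreated Weibull
    cumulative hazard and under the treated piecewise hazard (post-t_s
    hazard multiplied by ``statin_hr``).  If ``t_s`` is None, initiation
    times come from the generator's yearly logistic process run without
    conditioning on the event (draws that never initiate get t_s = inf,
    hence identical times).
    """
    config.validate()
    cfg = config
    rng = np.random.default_rng(cfg.seed if seed is None else seed)

    u = rng.multivariate_normal(np.zeros(4), cfg.Sigma_u, size=n)
    lo, hi = cfg.entry_age_range
    entry_age = np.maximum(lo, rng.uniform(lo - cfg.lookback, hi, n))
    sex = np.where(rng.random(n) < 0.5, "M", "F")
    sbp0 = _latent_value(cfg, 0, entry_age, u[:, 0])
    tc0 = _latent_value(cfg, 1, entry_age, u[:, 1])
    hdl0 = _latent_value(cfg, 2, entry_age, u[:, 2])
    smoke_p = np.clip(_latent_value(cfg, 3, entry_age, u[:, 3]), 0.0, 1.0)
    x = _hazard_covariates(
        cfg, sbp0, tc0, hdl0, smoke_p, np.zeros(n, bool), np.zeros(n, bool)
    )
    log_base = np.array([cfg.log_baseline_rate[s] for s in sex])
    eta = log_base + cfg.log_baseline_age_slope * (entry_age - 60.0) + x @ cfg.beta_true
    rate = np.exp(eta)
    nu = cfg.weibull_shape

    if t_s is None:
        ts = np.full(n, np.inf)
        for k in range(1, int(np.ceil(cfg.max_followup)) + 1):
            open_ = ts == np.inf
            age_k = entry_age + k
            tc_k = _latent_value(cfg, 1, age_k, u[:, 1])
            logit = (
                cfg.statin_init_intercept
                + cfg.statin_init_age * (age_k - 60.0)
                + cfg.statin_init_tc * (tc_k - 5.5)
            )
            p = 1.0 / (1.0 + np.exp(-logit))
            hit = open_ & (rng.random(n) < p)
            ts[hit] = float(k)
    else:
        ts = np.broadcast_to(np.asarray(t_s, dtype=float), (n,)).copy()

    E = rng.exponential(1.0, n)
    untreated = (E / rate) ** (1.0 / nu)
    treated = invert_piecewise_weibull(E, rate, nu, ts, cfg.statin_hr)
    return pd.DataFrame(
        {"treated_time": treated, "untreated_time": untreated, "t_s": ts}
    )


ENTRY_EPISODE_COVARIATES = (
    "sbp", "tc", "hdl", "smoking", "diabetes_flag", "htn_flag", "age_c", "male",
)


def entry_episodes(cohort: Cohort) -> pd.DataFrame:
    """Episode table on the study-entry clock with the oracle covariates.

    Each person's follow-up (time since entry) is split at statin
    initiation; covariates are the generator's stored hazard covariates
    plus centred entry age and sex, i.e. the exact design of the
    data-generating hazard.  Used to verify treatment-effect recovery
    with a freely estimated time-dependent statin coefficient.
    """
    if cohort.truth is None or len(cohort.truth) == 0:
        raise ValueError("cohort truth tables are required")
    p = cohort.persons
    tr = cohort.truth.set_index("id").loc[p["id"]]
    t = (p["exit_age"] - p["entry_age"]).to_numpy()
    d = p["event_flag"].to_numpy()
    init = (
        cohort.statin.set_index("id")["initiation_age"]
        if len(cohort.statin)
        else pd.Series(dtype=float)
    )
    ts = (p["id"].map(init) - p["entry_age"]).to_numpy(dtype=float)
    has = np.isfinite(ts)

    cov = pd.DataFrame(
        {
            "sbp": tr["x_sbp"].to_numpy(),
            "tc": tr["x_tc"].to_numpy(),
            "hdl": tr["x_hdl"].to_numpy(),
            "smoking": tr["x_smoking"].to_numpy(),
            "diabetes_flag": tr["x_diabetes"].to_numpy(),
            "htn_flag": tr["x_htn"].to_numpy(),
            "age_c": (p["entry_age"] - 60.0).to_numpy(),
            "male": (p["sex"] == "M").astype(float).to_numpy(),
        }
    )
    pre = pd.concat(
        [
            pd.DataFrame(
                {
                    "id": p["id"],
                    "start": 0.0,
                    "stop": np.where(has, ts, t),
                    "event_flag": np.where(has, 0, d),
                    "statin_on": 0,
                    "offset": 0.0,
                }
            ),
            cov,
        ],
        axis=1,
    )
    post = pd.concat(
        [
            pd.DataFrame(
                {
                    "id": p["id"][has].to_numpy(),
                    "start": ts[has],
                    "stop": t[has],
                    "event_flag": d[has],
                    "statin_on": 1,
                    "offset": np.log(0.75),
                }
            ),
            cov[has].reset_index(drop=True),
        ],
        axis=1,
    )
    return pd.concat([pre, post], ignore_index=True)


def null_config(config: GeneratorConfig) -> GeneratorConfig:
    """Copy of ``config`` with the statin effect switched off (hr = 1)."""
    return replace(config, statin_hr=1.0)
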