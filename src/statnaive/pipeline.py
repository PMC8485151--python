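"""End-to-end pipeline: simulate/ingest -> landmark -> stage 1 -> stage 2
-> predict -> counterfactual -> metrics -> impact -> reports.

The run is deterministic given the config seed.  Every stage's artifact
(risk sets, stage-1 and stage-2 fits, predictions, metric and impact
tables) is written under the output directory as delimited or structured
text, together with a manifest carrying the seed and a config hash.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import blup, impact as impact_mod, landmarking, metrics as metrics_mod, weibull
from .synthetic import Cohort, GeneratorConfig, generate_cohort

logger = logging.getLogger("statnaive")


@dataclass
class PipelineConfig:
    seed: int = 0
    cohort_dir: str | None = None  # read cohort CSVs instead of simulating
    n_persons: int = 20_000
    generator_overrides: dict = field(default_factory=dict)
    landmark_ages: tuple = tuple(range(40, 86))
    sexes: tuple = ("M", "F")
    horizon: float = 10.0
    derivation_fraction: float = 2.0 / 3.0
    lookback: float = 10.0
    min_events: int = 5  # smallest event count worth fitting
    metrics_landmark_ages: tuple = (40, 50, 60, 70)
    compute_metrics: bool = True
    bootstrap_reps: int = 200
    thresholds: tuple = (0.05, 0.10, 0.15, 0.20, 0.25, 0.30)
    std_pop_csv: str | None = None

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls(**raw)
        cfg.landmark_ages = tuple(cfg.landmark_ages)
        cfg.sexes = tuple(cfg.sexes)
        cfg.metrics_landmark_ages = tuple(cfg.metrics_landmark_ages)
        cfg.thresholds = tuple(cfg.thresholds)
        return cfg

    def hash(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


@dataclass
class LandmarkModels:
    landmark_age: float
    sex: str
    stage1: blup.MixedFit
    constrained: weibull.WeibullFit
    standard: weibull.WeibullFit


@dataclass
class PipelineResult:
    cohort: Cohort
    rates: pd.DataFrame
    models: dict  # (landmark_age, sex) -> LandmarkModels
    predictions: pd.DataFrame
    metrics: pd.DataFrame | None
    stacked: dict | None
    impact: pd.DataFrame | None
    proportions: pd.DataFrame | None
    skipped: list


def _covariate_frame(rs: landmarking.LandmarkRiskSet, blups: pd.DataFrame) -> pd.DataFrame:
    cov = rs.rows[["id", "diabetes_flag", "htn_flag"]].merge(blups, on="id")
    return cov[["id", "sbp", "tc", "hdl", "smoking", "diabetes_flag", "htn_flag"]]


def run_pipeline(config: PipelineConfig, outdir: str | Path | None = None) -> PipelineResult:
    # distinct stream from the generator's (same seed would replay its draws)
    rng = np.random.default_rng((config.seed, 929))
    out = Path(outdir) if outdir is not None else None
    if out is not None:
        (out / "fits").mkdir(parents=True, exist_ok=True)

    # --- cohort -----------------------------------------------------------
    if config.cohort_dir is not None:
        cohort = Cohort.read(config.cohort_dir)
    else:
        gcfg = GeneratorConfig(
            n_persons=config.n_persons, seed=config.seed, **config.generator_overrides
        )
        cohort = generate_cohort(gcfg)
    if out is not None:
        cohort.write(out / "cohort")

    # derivation / validation split (random by person)
    ids = cohort.persons["id"].to_numpy()
    deriv_mask = rng.random(len(ids)) < config.derivation_fraction
    deriv_ids = set(ids[deriv_mask])

    def subset(which_deriv: bool) -> Cohort:
        keep = cohort.persons["id"].isin(deriv_ids) == which_deriv
        kept = set(cohort.persons.loc[keep, "id"])
        return Cohort(
            persons=cohort.persons[keep].reset_index(drop=True),
            measurements=cohort.measurements[
                cohort.measurements["id"].isin(kept)
            ].reset_index(drop=True),
            statin=cohort.statin[cohort.statin["id"].isin(kept)].reset_index(drop=True),
            conditions=cohort.conditions[
                cohort.conditions["id"].isin(kept)
            ].reset_index(drop=True),
        )

    derivation, validation = subset(True), subset(False)

    # --- cleaning & standardization (derivation only) ----------------------
    clean_deriv, removed_d = blup.clean_measurements(derivation.measurements)
    clean_valid, removed_v = blup.clean_measurements(validation.measurements)
    logger.info(
        "cleaning removed %d derivation and %d validation values", removed_d, removed_v
    )
    std = blup.standardization_constants(clean_deriv, derivation.persons)

    rates = landmarking.crude_rates(
        cohort, config.landmark_ages, config.sexes, config.horizon
    )
    if out is not None:
        rates.to_csv(out / "crude_rates.csv", index=False)

    # --- per-landmark fits and validation predictions ----------------------
    models: dict = {}
    skipped: list = []
    pred_frames = []
    for L in config.landmark_ages:
        for sex in config.sexes:
            rs_d = landmarking.build_risk_set(derivation, L, sex, config.horizon)
            if len(rs_d) < 2 or rs_d.rows["event_flag"].sum() < config.min_events:
                skipped.append((L, sex, "too few persons or events"))
                continue
            meas = clean_deriv[clean_deriv["id"].isin(rs_d.rows["id"])]
            fit1 = blup.fit_multivariate_mixed(
                meas, L, sex, lookback=config.lookback, standardization=std
            )
            blups_d = blup.predict_blups(fit1, meas, rs_d.rows["id"].to_numpy(),
                                         lookback=config.lookback)
            cov_d = _covariate_frame(rs_d, blups_d)

            episodes = weibull.split_at_statin(rs_d, cov_d)
            fit_con = weibull.fit_weibull_ph(
                episodes, constrained=True, landmark_age=L, sex=sex
            )
            fit_std = weibull.fit_weibull_ph(
                weibull.risk_set_episodes(rs_d, cov_d),
                constrained=False,
                landmark_age=L,
                sex=sex,
            )
            fit_std.model_kind = "standard"
            models[(L, sex)] = LandmarkModels(L, sex, fit1, fit_con, fit_std)
            if out is not None:
                tag = f"{sex}_{int(L)}"
                fit1.to_json(out / "fits" / f"stage1_{tag}.json")
                fit_con.to_json(out / "fits" / f"weibull_naive_{tag}.json")
                fit_std.to_json(out / "fits" / f"weibull_standard_{tag}.json")

            # validation predictions + counterfactual times
            rs_v = landmarking.build_risk_set(validation, L, sex, config.horizon)
            if len(rs_v) == 0:
                continue
            meas_v = clean_valid[clean_valid["id"].isin(rs_v.rows["id"])]
            blups_v = blup.predict_blups(fit1, meas_v, rs_v.rows["id"].to_numpy(),
                                         lookback=config.lookback)
            cov_v = _covariate_frame(rs_v, blups_v)
            p_naive = weibull.predict_risk(fit_con, cov_v, config.horizon)
            p_std = weibull.predict_risk(fit_std, cov_v, config.horizon)
            # counterfactual times use the uncapped follow-up: 10-year
            # statin-naive status can hinge on observation beyond the horizon
            t_star, d_star = weibull.counterfactual_times(
                rs_v.rows["followup"].to_numpy(),
                rs_v.rows["event_at_exit"].to_numpy(),
                rs_v.rows["statin_time_full"].to_numpy(),
                shape=fit_con.shape,
            )
            pred_frames.append(
                pd.DataFrame(
                    {
                        "landmark_age": L,
                        "sex": sex,
                        "id": cov_v["id"].to_numpy(),
                        "p_naive": p_naive,
                        "p_standard": p_std,
                        "time": rs_v.rows["followup"].to_numpy(),
                        "event_flag": rs_v.rows["event_at_exit"].to_numpy(),
                        "time_cf": t_star,
                        "event_cf": d_star,
                        "initiated": rs_v.rows["statin_time_full"].notna().to_numpy(),
                    }
                )
            )

    predictions = (
        pd.concat(pred_frames, ignore_index=True)
        if pred_frames
        else pd.DataFrame(
            columns=["landmark_age", "sex", "id", "p_naive", "p_standard",
                     "time", "event_flag", "time_cf", "event_cf", "initiated"]
        )
    )
    if out is not None:
        predictions.to_csv(out / "predictions.csv", index=False)

    # --- metrics and impact -------------------------------------------------
    metric_rows: list = []
    stacked: dict | None = None
    impact_rows: list = []
    proportions = None
    if config.compute_metrics and len(predictions):
        eps = 1e-12

        def make_eval(sub, model):
            p = np.clip(sub[f"p_{model}"].to_numpy(), eps, 1 - eps)
            if model == "naive":
                t, d = sub["time_cf"].to_numpy(), sub["event_cf"].to_numpy()
            else:
                t, d = sub["time"].to_numpy(), sub["event_flag"].to_numpy()
            return metrics_mod.EvalSet(
                p=p, time=np.maximum(t, 1e-8), event=d,
                ids=sub["id"].to_numpy(), horizon=config.horizon,
            )

        for (L, sex), sub in predictions.groupby(["landmark_age", "sex"]):
            if L not in config.metrics_landmark_ages:
                continue
            e_std = make_eval(sub, "standard")
            e_nav = make_eval(sub, "naive")
            row = {"landmark_age": L, "sex": sex, "n": len(sub)}
            for name, ev in (("standard", e_std), ("naive", e_nav)):
                try:
                    row[f"brier_{name}"] = metrics_mod.brier_10yr(ev)
                    c = metrics_mod.harrell_c(
                        ev, bootstrap_reps=config.bootstrap_reps, seed=config.seed
                    )
                    row[f"c_{name}"], row[f"c_{name}_se"] = c["c"], c["se"]
                    dstat = metrics_mod.royston_d(ev)
                    row[f"d_{name}"], row[f"r2_{name}"] = dstat["d"], dstat["r2_d"]
                    _, cal = metrics_mod.calibration(ev)
                    row[f"cal_slope_{name}"] = cal["slope"]
                except ValueError as exc:
                    row[f"flag_{name}"] = str(exc)
            nri_c = metrics_mod.categorical_nri(e_std, e_nav)
            nri_k = metrics_mod.continuous_nri(
                e_std, e_nav, bootstrap_reps=config.bootstrap_reps, seed=config.seed
            )
            idi_ = metrics_mod.idi(e_std, e_nav)
            row.update(
                {
                    "nri_cat_event": nri_c["event"],
                    "nri_cat_nonevent": nri_c["nonevent"],
                    "nri_cat_overall": nri_c["overall"],
                    "nri_cont_event": nri_k["event"],
                    "nri_cont_nonevent": nri_k["nonevent"],
                    "nri_cont_overall": nri_k["overall"],
                    "idi": idi_["idi"],
                }
            )
            metric_rows.append(row)

            for name, ev in (("standard", e_std), ("naive", e_nav)):
                res = impact_mod.nns_nnt(ev, horizon=config.horizon)
                impact_rows.append(
                    {"landmark_age": L, "sex": sex, "model": name, **res}
                )

        # stacked overall metrics per sex, all landmark ages
        stacked = {}
        for sex in config.sexes:
            subs = predictions[predictions["sex"] == sex]
            if not len(subs):
                continue
            per_l = [
                make_eval(g, m)
                for _, g in subs.groupby("landmark_age")
                for m in ("standard",)
            ]
            per_l_naive = [
                make_eval(g, "naive") for _, g in subs.groupby("landmark_age")
            ]
            stacked[sex] = {
                "standard": metrics_mod.stack_and_summarize(
                    per_l, bootstrap_reps=min(config.bootstrap_reps, 50),
                    seed=config.seed,
                ),
                "naive": metrics_mod.stack_and_summarize(
                    per_l_naive, bootstrap_reps=min(config.bootstrap_reps, 50),
                    seed=config.seed,
                ),
            }

        std_pop = (
            impact_mod.StandardPopulation.from_csv(config.std_pop_csv)
            if config.std_pop_csv
            else impact_mod.StandardPopulation.uniform(
                ages=sorted(predictions["landmark_age"].unique())
            )
        )
        prop_frames = []
        for model in ("standard", "naive"):
            pr = predictions.rename(columns={f"p_{model}": "p"})[
                ["landmark_age", "sex", "p"]
            ]
            tab = impact_mod.threshold_proportions(pr, config.thresholds, std_pop)
            tab["model"] = model
            prop_frames.append(tab)
        proportions = pd.concat(prop_frames, ignore_index=True)

    metrics_df = pd.DataFrame(metric_rows) if metric_rows else None
    impact_df = pd.DataFrame(impact_rows) if impact_rows else None
    if out is not None:
        if metrics_df is not None:
            metrics_df.to_csv(out / "metrics.csv", index=False)
        if impact_df is not None:
            impact_df.to_csv(out / "impact.csv", index=False)
        if proportions is not None:
            proportions.to_csv(out / "threshold_proportions.csv", index=False)
        manifest = {
            "seed": config.seed,
            "config_hash": config.hash(),
            "n_models_constrained": len(models),
            "n_models_standard": len(models),
            "skipped": [list(s) for s in skipped],
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1))

    return PipelineResult(
        cohort=cohort,
        rates=rates,
        models=models,
        predictions=predictions,
        metrics=metrics_df,
        stacked=stacked,
        impact=impact_df,
        proportions=proportions,
        skipped=skipped,
    )
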