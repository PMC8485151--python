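"""Performance measures: hand-computable cases, brute-force oracles,
and published reclassification worked examples."""

import numpy as np
import pytest

import statnaive as sn
from statnaive.metrics import EvalSet

from conftest import truth_covariates


def eset(p, time, event, horizon=10.0):
    return EvalSet(p=np.asarray(p, float), time=np.asarray(time, float),
                   event=np.asarray(event, int), horizon=horizon)


# --------------------------------------------------------------------------
# Brier


def test_brier_hand_arithmetic():
    es = eset([0.8, 0.1, 0.4, 0.3], [5, 12, 7, 11], [1, 0, 1, 0])
    assert sn.brier_10yr(es) == pytest.approx((0.04 + 0.01 + 0.36 + 0.09) / 4)


def test_brier_constant_half_and_perfect():
    es = eset([0.5] * 4, [5, 12, 7, 11], [1, 0, 1, 0])
    assert sn.brier_10yr(es) == pytest.approx(0.25)
    es2 = eset([1 - 1e-12, 1e-12], [5, 11], [1, 0])
    assert sn.brier_10yr(es2) == pytest.approx(0.0, abs=1e-20)


def test_brier_excludes_early_censored():
    es = eset([0.9, 0.2], [3.0, 11.0], [0, 0])  # first is censored early
    assert sn.brier_10yr(es) == pytest.approx(0.04)
    with pytest.raises(ValueError):
        sn.brier_10yr(eset([0.5], [3.0], [0]))


# --------------------------------------------------------------------------
# Harrell's C


def brute_force_c(time, risk, event):
    """Exhaustive pair count: usable pairs have the shorter time as an
    event; concordant when the shorter-lived has the higher risk."""
    num = den = 0.0
    n = len(time)
    for i in range(n):
        for j in range(n):
            if time[i] < time[j] and event[i] == 1:
                den += 1
                if risk[i] > risk[j]:
                    num += 1
                elif risk[i] == risk[j]:
                    num += 0.5
    return num / den


@pytest.mark.parametrize("seed", [0, 1, 2, 3])
def test_c_matches_brute_force_pair_counting(seed):
    rng = np.random.default_rng(seed)
    n = 30
    time = rng.exponential(5, n)
    event = rng.integers(0, 2, n)
    event[rng.integers(0, n)] = 1
    p = np.round(rng.random(n), 1)  # rounded -> prediction ties occur
    pc = np.clip(p, 0.01, 0.99)
    es = eset(pc, time, event, horizon=10)
    got = sn.harrell_c(es, bootstrap_reps=10, seed=0)["c"]
    assert got == pytest.approx(brute_force_c(time, pc, event), abs=1e-12)


def test_c_perfect_and_uninformative():
    time = np.array([1.0, 2, 3, 4, 5])
    event = np.ones(5, int)
    p_perfect = np.array([0.9, 0.7, 0.5, 0.3, 0.1])  # shorter time, higher risk
    assert sn.harrell_c(eset(p_perfect, time, event), 10, 0)["c"] == pytest.approx(1.0)
    assert sn.harrell_c(eset([0.5] * 5, time, event), 10, 0)["c"] == pytest.approx(0.5)
    with pytest.raises(ValueError):
        sn.harrell_c(eset([0.5] * 5, time, np.zeros(5, int)))


def test_c_bootstrap_deterministic():
    rng = np.random.default_rng(3)
    es = eset(rng.uniform(0.1, 0.9, 50), rng.exponential(5, 50), rng.integers(0, 2, 50))
    a = sn.harrell_c(es, bootstrap_reps=50, seed=9)
    b = sn.harrell_c(es, bootstrap_reps=50, seed=9)
    assert a == b


# --------------------------------------------------------------------------
# calibration and Royston D


def test_self_calibration_slope_covers_one(nostatin60_cohort):
    """Predictions equal to the generating risks are perfectly calibrated:
    slope CI covers 1 and decile means sit near the diagonal."""
    cfg, cohort = nostatin60_cohort
    p = cohort.persons
    t = (p["exit_age"] - p["entry_age"]).to_numpy()
    es = EvalSet(
        p=np.clip(cohort.truth["true_risk_10yr"].to_numpy(), 1e-9, 1 - 1e-9),
        time=t, event=p["event_flag"].to_numpy(), horizon=10.0,
    )
    table, slope = sn.calibration(es)
    lo, hi = slope["ci"]
    assert lo <= 1.0 <= hi
    assert np.nanmax(np.abs(table["mean_predicted"] - table["observed"])) < 0.05


def test_doubling_log_hazard_halves_slope(nostatin60_cohort):
    cfg, cohort = nostatin60_cohort
    p = cohort.persons
    t = (p["exit_age"] - p["entry_age"]).to_numpy()
    risk = np.clip(cohort.truth["true_risk_10yr"].to_numpy(), 1e-9, 1 - 1e-9)
    H = -np.log1p(-risk)
    inflated = 1.0 - np.exp(-(H**2))  # doubles the log cumulative hazard
    es = EvalSet(p=np.clip(inflated, 1e-12, 1 - 1e-12), time=t,
                 event=p["event_flag"].to_numpy(), horizon=10.0)
    _, slope = sn.calibration(es)
    assert slope["slope"] == pytest.approx(0.5, abs=0.1)


def test_constant_predictions_flagged():
    with pytest.raises(ValueError):
        sn.calibration(eset([0.3] * 20, np.arange(1, 21), [1] * 20))


def test_royston_d_null_under_permutation(nostatin60_cohort):
    cfg, cohort = nostatin60_cohort
    rng = np.random.default_rng(0)
    p = cohort.persons.sample(4000, random_state=1)
    t = (p["exit_age"] - p["entry_age"]).to_numpy()
    risk = cohort.truth.set_index("id").loc[p["id"], "true_risk_10yr"].to_numpy()
    perm = rng.permutation(np.clip(risk, 1e-9, 1 - 1e-9))
    res = sn.royston_d(EvalSet(p=perm, time=t, event=p["event_flag"].to_numpy()))
    lo, hi = res["ci"]
    assert lo <= 0.0 <= hi
    assert res["r2_d"] < 0.01
    # closed form: D = 0 gives zero explained variation
    assert (0.0 / (8 / np.pi)) / (0.0 + np.pi**2 / 6) == 0.0


def test_royston_d_matches_independent_aft_implementation(nostatin60_cohort):
    """D from this module equals an independent scripted computation of the
    published estimator (rankit score fitted in a lifelines Weibull AFT
    model, reparameterised to the PH scale)."""
    import lifelines
    from scipy import stats

    cfg, cohort = nostatin60_cohort
    p = cohort.persons.sample(4000, random_state=2)
    t = (p["exit_age"] - p["entry_age"]).to_numpy()
    d = p["event_flag"].to_numpy()
    risk = np.clip(
        cohort.truth.set_index("id").loc[p["id"], "true_risk_10yr"].to_numpy(),
        1e-9, 1 - 1e-9,
    )
    res = sn.royston_d(EvalSet(p=risk, time=t, event=d))

    pi_ = np.log(-np.log1p(-risk))
    ranks = stats.rankdata(pi_, method="average")
    z = stats.norm.ppf((ranks - 0.375) / (len(pi_) + 0.25)) / np.sqrt(8 / np.pi)
    import pandas as pd

    aft = lifelines.WeibullAFTFitter()
    aft.fit(pd.DataFrame({"t": t, "d": d, "z": z}), "t", "d")
    rho = float(np.exp(aft.params_["rho_"].iloc[0]))  # log link on the shape
    d_oracle = -rho * float(aft.params_["lambda_"]["z"])
    assert res["d"] == pytest.approx(d_oracle, rel=1e-3)
    assert res["d"] > 0.5  # strong prognostic separation on generator data


# --------------------------------------------------------------------------
# reclassification: published worked examples

MEN_TABLES = {
    40: ([[413, 4], [0, 16]], [[1965, 3], [0, 13]]),
    50: ([[764, 55], [0, 480]], [[1368, 59], [0, 390]]),
    60: ([[187, 55], [0, 1743]], [[147, 62], [0, 1271]]),
    70: ([[0, 0], [0, 1901]], [[0, 0], [0, 613]]),
}
WOMEN_TABLES = {
    40: ([[329, 0], [0, 8]], [[3759, 3], [0, 6]]),
    50: ([[723, 10], [0, 59]], [[3073, 10], [0, 43]]),
    60: ([[948, 54], [0, 277]], [[2180, 82], [0, 226]]),
    70: ([[19, 8], [0, 1634]], [[7, 2], [0, 1084]]),
}
MEN_NRI = {40: 0.0077, 50: 0.0099, 60: -0.0142, 70: 0.0000}
WOMEN_NRI = {40: -0.0008, 50: 0.0094, 60: 0.0093, 70: 0.0030}


@pytest.mark.parametrize("age", [40, 50, 60, 70])
def test_categorical_nri_worked_examples_men(age):
    ev, ne = MEN_TABLES[age]
    res = sn.categorical_nri_from_counts(ev, ne)
    assert res["overall"] == pytest.approx(MEN_NRI[age], abs=5e-5)


@pytest.mark.parametrize("age", [40, 50, 60, 70])
def test_categorical_nri_worked_examples_women(age):
    ev, ne = WOMEN_TABLES[age]
    res = sn.categorical_nri_from_counts(ev, ne)
    assert res["overall"] == pytest.approx(WOMEN_NRI[age], abs=5e-5)


def test_categorical_nri_components_men_50():
    ev, ne = MEN_TABLES[50]
    res = sn.categorical_nri_from_counts(ev, ne)
    assert res["event"] == pytest.approx(0.0423, abs=5e-5)
    assert res["nonevent"] == pytest.approx(-0.0325, abs=5e-5)
    assert res["overall"] == pytest.approx(res["event"] + res["nonevent"])


def test_categorical_nri_identity_when_no_movement():
    res = sn.categorical_nri_from_counts([[10, 0], [0, 5]], [[20, 0], [0, 3]])
    assert res["event"] == res["nonevent"] == res["overall"] == 0.0


def test_categorical_nri_from_eval_sets_matches_counts():
    old = eset([0.05, 0.08, 0.12, 0.15, 0.09, 0.11], [3, 11, 5, 12, 11, 11],
               [1, 0, 1, 0, 0, 0])
    new = eset([0.12, 0.08, 0.11, 0.09, 0.12, 0.11], [3, 11, 5, 12, 11, 11],
               [1, 0, 1, 0, 0, 0])
    res = sn.categorical_nri(old, new)
    # events: one up (0.05->0.12); nonevents: one down (0.15->0.09), one up
    assert res["event"] == pytest.approx(1 / 2)
    assert res["nonevent"] == pytest.approx((1 - 1) / 4)


# --------------------------------------------------------------------------
# continuous NRI and IDI


def test_continuous_nri_all_up_degenerate():
    old = eset([0.1, 0.2, 0.3, 0.4], [5, 11, 6, 12], [1, 0, 1, 0])
    new = eset([0.15, 0.25, 0.35, 0.45], [5, 11, 6, 12], [1, 0, 1, 0])
    res = sn.continuous_nri(old, new, bootstrap_reps=10, seed=0)
    assert res["event"] == pytest.approx(1.0)
    assert res["nonevent"] == pytest.approx(-1.0)
    assert res["overall"] == pytest.approx(0.0)


def test_continuous_nri_uncensored_matches_direct_counting():
    rng = np.random.default_rng(4)
    n = 200
    d = rng.integers(0, 2, n)
    time = np.where(d == 1, rng.uniform(0.5, 9.5, n), 11.0)
    p_old = rng.uniform(0.05, 0.5, n)
    p_new = p_old + rng.normal(0, 0.05, n)
    p_new = np.clip(p_new, 0.01, 0.95)
    res = sn.continuous_nri(eset(p_old, time, d), eset(p_new, time, d),
                            bootstrap_reps=10, seed=0)
    up, down = p_new > p_old, p_new < p_old
    ev = ((up & (d == 1)).sum() - (down & (d == 1)).sum()) / (d == 1).sum()
    ne = ((down & (d == 0)).sum() - (up & (d == 0)).sum()) / (d == 0).sum()
    assert res["event"] == pytest.approx(ev, abs=1e-12)
    assert res["nonevent"] == pytest.approx(ne, abs=1e-12)


def test_continuous_nri_positive_for_informative_covariate(nostatin60_cohort):
    """Adding a truly informative covariate (total cholesterol) to the
    predictions yields positive overall continuous NRI."""
    cfg, cohort = nostatin60_cohort
    tr = cohort.truth
    p = cohort.persons
    t = (p["exit_age"] - p["entry_age"]).to_numpy()
    d = p["event_flag"].to_numpy()
    eta_full = tr["eta"].to_numpy()
    eta_no_tc = eta_full - cfg.beta_true[1] * tr["x_tc"].to_numpy()
    risk = lambda e: np.clip(1 - np.exp(-np.exp(e) * 10**cfg.weibull_shape), 1e-9, 1 - 1e-9)
    res = sn.continuous_nri(
        EvalSet(p=risk(eta_no_tc), time=t, event=d),
        EvalSet(p=risk(eta_full), time=t, event=d),
        bootstrap_reps=20, seed=0,
    )
    assert res["overall"] > 0


def test_continuous_nri_no_movers():
    old = eset([0.1, 0.2], [11, 11], [0, 1])
    res = sn.continuous_nri(old, old, bootstrap_reps=5, seed=0)
    assert res["overall"] == 0.0 and "no movers" in res["flags"]


def test_idi_hand_arithmetic_and_antisymmetry():
    old = eset([0.2, 0.2, 0.2, 0.2], [5, 6, 11, 12], [1, 1, 0, 0])
    new = eset([0.3, 0.3, 0.1, 0.1], [5, 6, 11, 12], [1, 1, 0, 0])
    assert sn.idi(old, new)["idi"] == pytest.approx(0.2)
    assert sn.idi(new, old)["idi"] == pytest.approx(-0.2)
    assert sn.idi(old, old)["idi"] == pytest.approx(0.0)


def test_idi_flags_degenerate_subsets():
    old = eset([0.2, 0.3], [11, 12], [0, 0])
    assert sn.idi(old, old)["flags"]


# --------------------------------------------------------------------------
# stacking


def test_stacked_single_set_is_identity():
    rng = np.random.default_rng(6)
    es = eset(rng.uniform(0.05, 0.9, 60), rng.exponential(6, 60),
              rng.integers(0, 2, 60))
    res = sn.stack_and_summarize([es], bootstrap_reps=10, seed=0)
    assert res["brier"]["value"] == pytest.approx(sn.brier_10yr(es))
    assert res["c"]["value"] == pytest.approx(sn.harrell_c(es, 10, 0)["c"])


def test_stacked_duplicate_preserves_c():
    rng = np.random.default_rng(7)
    es = eset(rng.uniform(0.05, 0.9, 40), rng.exponential(6, 40),
              rng.integers(0, 2, 40))
    res1 = sn.stack_and_summarize([es], bootstrap_reps=5, seed=0)
    res2 = sn.stack_and_summarize([es, es], bootstrap_reps=5, seed=0)
    assert res2["c"]["value"] == pytest.approx(res1["c"]["value"], abs=1e-9)


def test_stacked_c_matches_brute_force_on_concatenation():
    rng = np.random.default_rng(8)
    sets = []
    for _ in range(2):
        sets.append(
            eset(rng.uniform(0.05, 0.9, 15), rng.exponential(6, 15),
                 rng.integers(0, 2, 15))
        )
    res = sn.stack_and_summarize(sets, bootstrap_reps=5, seed=0)
    time = np.concatenate([s.time for s in sets])
    p = np.concatenate([s.p for s in sets])
    ev = np.concatenate([s.event for s in sets])
    if ev.sum():
        assert res["c"]["value"] == pytest.approx(brute_force_c(time, p, ev), abs=1e-12)
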