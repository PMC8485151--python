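"""Public-health impact measures.

Number needed to screen (NNS) and number needed to treat (NNT) to
prevent one CVD event under a treatment rule "treat everyone with
predicted 10-year risk >= threshold" and a relative risk reduction from
trial evidence; and proportions of the population exceeding a grid of
treatment thresholds, age-standardized to an external population.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .metrics import EvalSet, km_event_prob


@dataclass
class StandardPopulation:
    """External age-sex weights (counts or proportions) for combining
    per-landmark-age proportions."""

    table: pd.DataFrame  # columns: sex, age, weight

    def __post_init__(self):
        if (self.table["weight"] < 0).any():
            raise ValueError("weights must be nonnegative")

    @classmethod
    def uniform(cls, ages=range(40, 86), sexes=("M", "F")) -> "StandardPopulation":
        """Synthetic default: equal weight at every age and sex."""
        rows = [{"sex": s, "age": a, "weight": 1.0} for s in sexes for a in ages]
        return cls(pd.DataFrame(rows))

    @classmethod
    def from_csv(cls, path) -> "StandardPopulation":
        return cls(pd.read_csv(path))


def nns_nnt(
    eval_set: EvalSet,
    threshold: float = 0.10,
    treatment_rr: float = 0.25,
    horizon: float = 10.0,
) -> dict:
    """NNS and NNT to prevent one event within the horizon.

    Events prevented = treatment_rr x observed (product-limit) event risk
    among the high-risk group x size of the high-risk group.  The
    high-risk set is closed at the threshold (p >= threshold).  Zero
    preventable events yields infinite NNS/NNT.
    """
    if len(eval_set) == 0:
        raise ValueError("empty evaluation set")
    high = eval_set.p >= threshold
    n_high = int(high.sum())
    n_total = len(eval_set)
    if n_high == 0:
        return {"nns": np.inf, "nnt": np.inf, "n_high": 0, "risk_high": np.nan}
    risk_high = km_event_prob(eval_set.time[high], eval_set.event[high], horizon)
    prevented = treatment_rr * risk_high * n_high
    if prevented <= 0:
        return {"nns": np.inf, "nnt": np.inf, "n_high": n_high, "risk_high": risk_high}
    return {
        "nns": n_total / prevented,
        "nnt": n_high / prevented,
        "n_high": n_high,
        "risk_high": risk_high,
    }


def threshold_proportions(
    predictions: pd.DataFrame,
    thresholds,
    std_pop: StandardPopulation,
) -> pd.DataFrame:
    """Weighted proportion of persons with predicted risk exceeding each
    threshold, standardized across landmark ages.

    ``predictions`` columns: landmark_age, sex, p.  Per sex and
    threshold: sum_age w_age * prop_age / sum_age w_age.
    """
    out = []
    for sex, sub in predictions.groupby("sex"):
        ages = np.sort(sub["landmark_age"].unique())
        w = std_pop.table[std_pop.table["sex"] == sex].set_index("age")["weight"]
        missing = [a for a in ages if a not in w.index]
        if missing:
            raise ValueError(f"standard population missing ages {missing} for sex {sex}")
        weights = w.loc[ages].to_numpy(dtype=float)
        for thr in thresholds:
            props = np.array(
                [
                    (sub.loc[sub["landmark_age"] == a, "p"] >= thr).mean()
                    for a in ages
                ]
            )
            out.append(
                {
                    "sex": sex,
                    "threshold": float(thr),
                    "proportion": float(np.sum(weights * props) / weights.sum()),
                }
            )
    return pd.DataFrame(out)
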