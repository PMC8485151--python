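import numpy as np
import pandas as pd
import pytest

import statnaive as sn


@pytest.fixture(scope="session")
def default_cohort():
    """Default-configuration cohort used across modules."""
    cfg = sn.GeneratorConfig(n_persons=20_000, seed=11)
    return cfg, sn.generate_cohort(cfg)


@pytest.fixture(scope="session")
def entry60_cohort():
    """Cohort with everyone entering at age 60, so the landmark-60 clock
    coincides with the generating clock (exact-model recovery checks)."""
    cfg = sn.GeneratorConfig(n_persons=20_000, seed=12, entry_age_range=(60.0, 60.0))
    return cfg, sn.generate_cohort(cfg)


@pytest.fixture(scope="session")
def nostatin60_cohort():
    """Entry-60 cohort with the initiation process disabled."""
    cfg = sn.GeneratorConfig(n_persons=20_000, seed=13, entry_age_range=(60.0, 60.0))
    return cfg, sn.generate_cohort(cfg, statins_enabled=False)


def truth_covariates(cohort: sn.Cohort, ids) -> pd.DataFrame:
    """Oracle stage-2 covariate frame from the generator's truth table."""
    tr = cohort.truth.set_index("id").loc[np.asarray(ids)]
    return pd.DataFrame(
        {
            "id": np.asarray(ids),
            "sbp": tr["x_sbp"].to_numpy(),
            "tc": tr["x_tc"].to_numpy(),
            "hdl": tr["x_hdl"].to_numpy(),
            "smoking": tr["x_smoking"].to_numpy(),
            "diabetes_flag": tr["x_diabetes"].to_numpy(),
            "htn_flag": tr["x_htn"].to_numpy(),
        }
    )
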