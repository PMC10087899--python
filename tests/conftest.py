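import matplotlib
import numpy as np
import pytest

matplotlib.use("Agg")

import hac24 as h


@pytest.fixture(scope="session")
def act_cohort():
    """A mid-sized cohort at the default study conditions, preprocessed."""
    cfg = h.CohortConfig(n_persons=400, n_days=7, seed=20240)
    daily, persons, classes, truth = h.generate_cohort(cfg)
    table = h.aggregate_persons(daily, h.flag_valid_days(daily), persons)
    return {"daily": daily, "persons": persons, "classes": classes,
            "truth": truth, "table": table, "config": cfg}


@pytest.fixture(scope="session")
def covariates():
    return ["age_group", "female", "white", "bmi", "education", "cesd",
            "good_health"]


@pytest.fixture(scope="session")
def complete_table(act_cohort, covariates):
    """Complete-case person table (no missing covariates)."""
    t = act_cohort["table"]
    return t.dropna(subset=["bmi", "cesd", "white"]).reset_index(drop=True)


@pytest.fixture
def rng():
    return np.random.default_rng(7)
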