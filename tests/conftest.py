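import numpy as np
import pandas as pd
import pytest

from mhequity import SurveyDataset, cmhs_scenario, generate


def make_dataset(wealth, weight, outcome=None, outcome_name="y", **extra_cols):
    """Construct a minimal in-memory SurveyDataset from raw arrays."""
    n = len(wealth)
    df = pd.DataFrame({
        "id": np.arange(n),
        "weight": np.asarray(weight, float),
        "wealth_score": np.asarray(wealth, float),
        "anc_any": 1.0, "gave_birth": 1.0, "de_jure": 1.0, "has_missing": 0,
        "anc4plus": 1.0, "facility_delivery": 1.0, "pnc": 1.0,
    })
    if outcome is not None:
        df[outcome_name] = np.asarray(outcome, float)
    for name, vals in extra_cols.items():
        df[name] = vals
    return SurveyDataset(df, covariates=tuple(extra_cols), provenance="test")


@pytest.fixture(scope="session")
def scenario_dataset():
    """One n=50,000 draw of the packaged CMHS scenario (shared; do not mutate)."""
    return generate(cmhs_scenario())


@pytest.fixture(scope="session")
def scenario_config():
    return cmhs_scenario()
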