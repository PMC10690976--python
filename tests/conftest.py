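import pandas as pd
import pytest

import stagevar as sv


def make_table(rows):
    """Build a validated policy-holder table from compact row dicts."""
    defaults = {
        "age_cat": "0-40",
        "obesity": 0,
        "childbirth": 0,
        "sex_female": 0,
        "ses_cat": "high",
        "income_cat": "high",
        "urban_cat": "1",
        "initial_visit": 0,
        "treated": 0,
        "visit_observed": 0,
    }
    records = []
    for i, row in enumerate(rows):
        rec = {"person_id": f"id{i}", **defaults, **row}
        records.append(rec)
    return sv.validate_claims(pd.DataFrame(records))


@pytest.fixture(scope="session")
def regime_params():
    """Moderate-size DGP in the qualitative regime (large visit-stage
    dispersion, small conditional dispersion, nonzero covariate effects)."""
    return sv.referral_dominated_params(50_000, n_regions=10, seed=42)


@pytest.fixture(scope="session")
def regime_table(regime_params):
    return sv.simulate_claims(regime_params)
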