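import numpy as np
import pandas as pd
import pytest

import famstress as fs


@pytest.fixture(scope="session")
def calibrated_params():
    return fs.default_params()


@pytest.fixture(scope="session")
def cohort_20k(calibrated_params):
    return fs.generate_cohort(calibrated_params.replace(n_children=20_000, seed=42))


@pytest.fixture(scope="session")
def analysis_20k(cohort_20k):
    return fs.derive_analysis_set(cohort_20k, cutoffs=cohort_20k.cutoffs)


def make_toy_cohort():
    """Ten complete rows with hand-checkable flags.

    Single-adult childless households (equivalence factor 1), incomes
    1000..10000, DASS sums 1..10, closeness 21..30, conflict 11..20,
    SDQ 17 for children 1-2 and 5 otherwise.
    """
    ids = np.arange(1, 11)
    dass_sums = ids  # 1..10
    items = np.zeros((10, 6), dtype=int)
    for i, s in enumerate(dass_sums):
        left = int(s)
        for j in range(6):
            take = min(left, 3)
            items[i, j] = take
            left -= take
    return pd.DataFrame(
        {
            "child_id": ids,
            "income": ids * 1000.0,
            "n_adults": 1,
            "n_other_14_plus": 0,
            "n_children_under_14": 0,
            **{f"dass_{j+1}": items[:, j] for j in range(6)},
            "closeness": 20 + ids,
            "conflict": 10 + ids,
            "sdq_total": np.where(ids <= 2, 17, 5),
            "maternal_education": ["no_qualifications", "standard_grade"] + ["degree_or_vocational"] * 8,
            "maternal_age_band": ["<20"] + ["30-39"] * 9,
            "maternal_employed": [0.0] * 3 + [1.0] * 7,
            "one_parent": [1.0] * 2 + [0.0] * 8,
            "ethnic_minority": [1.0] + [0.0] * 9,
            "weight": 1.0,
        }
    )


@pytest.fixture()
def toy_cohort():
    return make_toy_cohort()
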