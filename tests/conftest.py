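import numpy as np
import pandas as pd
import pytest

import voclearn as vl
from voclearn.synthetic import default_is_mapping


@pytest.fixture(scope="session")
def planted_cohort():
    """49-subject cohort with 5 strong discriminating features among 50."""
    spec = vl.CohortSpec(n_features=50, n_informative=5, effect_size=2.0, seed=1)
    return vl.generate_cohort(spec)


@pytest.fixture(scope="session")
def planted_matrix(planted_cohort):
    table = planted_cohort.table
    return vl.preprocess_pipeline(table, default_is_mapping(table.feature_ids))


@pytest.fixture(scope="session")
def null_matrix():
    spec = vl.CohortSpec(n_features=50, n_informative=0, seed=11)
    cohort = vl.generate_null(spec)
    return vl.preprocess_pipeline(
        cohort.table, default_is_mapping(cohort.table.feature_ids)
    )


@pytest.fixture()
def small_table():
    """Hand-sized injection table: 2 subjects x 2 replicates, 3 features + 1 IS."""
    ab = pd.DataFrame(
        {
            "V1": [10.0, 12.0, 8.0, np.nan],
            "V2": [4.0, 6.0, 30.0, 2.0],
            "V3": [np.nan, np.nan, 5.0, 7.0],
            "IS1": [5.0, 4.0, 2.0, 2.0],
        }
    )
    return vl.FeatureTable(
        abundances=ab,
        subject_ids=pd.Series(["s1", "s1", "s2", "s2"]),
        groups=pd.Series(["NW", "NW", "OW/Ob", "OW/Ob"]),
        replicate_index=pd.Series([1, 2, 1, 2]),
        is_internal_standard=pd.Series(
            [False, False, False, True], index=["V1", "V2", "V3", "IS1"]
        ),
    )
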