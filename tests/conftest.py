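import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from mirmorph import (
    CohortBundle,
    ExpressionMatrix,
    default_config,
    filter_primary,
    generate,
    io,
)

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def make_matrix(values, feature_ids=None, sample_ids=None, kind="mirna"):
    """Small ExpressionMatrix from a 2D array, with generated ids."""
    values = np.asarray(values, dtype=float)
    n_feat, n_samp = values.shape
    feature_ids = feature_ids or [f"miR-{i:03d}" for i in range(n_feat)]
    sample_ids = sample_ids or [f"SYN-T-{i:04d}-01" for i in range(n_samp)]
    data = pd.DataFrame(values, index=feature_ids, columns=sample_ids)
    return ExpressionMatrix(data, pd.Series(kind, index=feature_ids))


def make_bundle(values, cohorts, **kwargs):
    """Bundle a small matrix with a minimal clinical table."""
    m = make_matrix(values, **kwargs)
    clinical = pd.DataFrame(
        {
            "sample_type_code": [io.sample_type_code(s) for s in m.sample_ids],
            "gender": np.nan,
            "race": np.nan,
            "ethnicity": np.nan,
            "cohort": list(cohorts),
        },
        index=pd.Index(m.sample_ids, name="sample"),
    )
    return CohortBundle(m, clinical)


@pytest.fixture(scope="session")
def default_bundle():
    """One synthetic cohort draw at the study conditions (fixed seed)."""
    return generate(default_config(seed=7))


@pytest.fixture(scope="session")
def primary_bundle(default_bundle):
    return filter_primary(default_bundle)
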